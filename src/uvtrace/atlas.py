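"""Template body atlas with nine standard anatomical zones.

The atlas is a schematic frontal body silhouette partitioned into the nine
regions used for zonal contamination analysis: head, neck, four thorax
quadrants, arms, hands and legs.  ``arms``, ``hands`` and ``legs`` each
cover both sides of the body as a single zone.  Zones are pairwise
disjoint boolean masks whose union lies inside the template foreground.

The template raster carries a fixed smooth intensity texture so that
intensity-based deformable registration is well conditioned everywhere
inside the silhouette, not just at its edge.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.morphology import dilation, disk as disk_footprint

#: Canonical zone order; also the label order in combined zone rasters.
ZONE_NAMES: tuple[str, ...] = (
    "head",
    "neck",
    "thorax_upper_left",
    "thorax_upper_right",
    "thorax_lower_left",
    "thorax_lower_right",
    "arms",
    "hands",
    "legs",
)


@dataclass
class BodyAtlas:
    """Template silhouette, nine zone masks and a named landmark set.

    Parameters
    ----------
    template : ndarray of uint8, shape (H, W)
        Textured grayscale rendering of the body on a dark background.
    zones : dict of str -> bool ndarray
        One boolean mask per zone name in :data:`ZONE_NAMES`.
    landmarks : list of (name, row, col)
        Anatomical reference points in template coordinates (0-based,
        origin top-left).
    """

    template: np.ndarray
    zones: dict[str, np.ndarray]
    landmarks: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def shape(self) -> tuple[int, int]:
        return self.template.shape  # type: ignore[return-value]

    @property
    def foreground(self) -> np.ndarray:
        """Body silhouette mask (zone union slightly dilated)."""
        return self.template > (int(self.template.min()) + 10)

    def zone_labels(self) -> np.ndarray:
        """Combined label raster: 0 = outside, 1..9 = zone index."""
        labels = np.zeros(self.shape, dtype=np.uint8)
        for i, name in enumerate(ZONE_NAMES, start=1):
            labels[self.zones[name]] = i
        return labels

    def validate(self) -> None:
        if set(self.zones) != set(ZONE_NAMES):
            raise ValueError(
                f"atlas must define exactly the nine zones {ZONE_NAMES}, "
                f"got {sorted(self.zones)}"
            )
        total = np.zeros(self.shape, dtype=np.int32)
        for name in ZONE_NAMES:
            mask = self.zones[name]
            if mask.shape != self.shape:
                raise ValueError(f"zone {name!r} shape {mask.shape} != template {self.shape}")
            total += mask.astype(np.int32)
        if total.max() > 1:
            raise ValueError("zone masks overlap; zones must be pairwise disjoint")


def _rect(shape: tuple[int, int], r0: float, r1: float, c0: float, c1: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    mask[int(round(r0 * h)) : int(round(r1 * h)), int(round(c0 * w)) : int(round(c1 * w))] = True
    return mask


def _ellipse(shape: tuple[int, int], rc: float, cc: float, rr: float, cr: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    h, w = shape
    rows, cols = np.ogrid[:h, :w]
    mask[((rows - rc * h) / (rr * h)) ** 2 + ((cols - cc * w) / (cr * w)) ** 2 <= 1.0] = True
    return mask


def default_atlas(shape: tuple[int, int] = (1024, 512)) -> BodyAtlas:
    """Build the packaged schematic frontal atlas at the given raster size.

    The default size is 1024 rows by 512 columns (portrait, head up);
    all proportions scale with the raster so smaller atlases remain
    geometrically similar.
    """
    h, w = shape
    cx = 0.5

    zones: dict[str, np.ndarray] = {}
    zones["head"] = _ellipse(shape, 0.090, cx, 0.062, 0.090)
    zones["neck"] = _rect(shape, 0.155, 0.185, cx - 0.050, cx + 0.050)
    # thorax block split at the vertical midline and a horizontal fraction
    thorax_top, thorax_split, thorax_bot = 0.185, 0.3225, 0.460
    half = 0.170
    zones["thorax_upper_left"] = _rect(shape, thorax_top, thorax_split, cx - half, cx)
    zones["thorax_upper_right"] = _rect(shape, thorax_top, thorax_split, cx, cx + half)
    zones["thorax_lower_left"] = _rect(shape, thorax_split, thorax_bot, cx - half, cx)
    zones["thorax_lower_right"] = _rect(shape, thorax_split, thorax_bot, cx, cx + half)
    arms = _rect(shape, 0.185, 0.520, cx - 0.260, cx - 0.180)
    arms |= _rect(shape, 0.185, 0.520, cx + 0.180, cx + 0.260)
    zones["arms"] = arms
    hands = _ellipse(shape, 0.565, cx - 0.220, 0.033, 0.045)
    hands |= _ellipse(shape, 0.565, cx + 0.220, 0.033, 0.045)
    zones["hands"] = hands
    legs = _rect(shape, 0.460, 0.920, cx - 0.160, cx - 0.020)
    legs |= _rect(shape, 0.460, 0.920, cx + 0.020, cx + 0.160)
    zones["legs"] = legs

    union = np.zeros(shape, dtype=bool)
    for mask in zones.values():
        union |= mask
    body = dilation(union, disk_footprint(max(2, h // 256)))

    # Fixed smooth texture: vertical gradient plus low-frequency modulation.
    rows, cols = np.mgrid[:h, :w].astype(np.float64)
    texture = (
        110.0
        + 35.0 * np.sin(2 * np.pi * 3.0 * rows / h) * np.cos(2 * np.pi * 2.5 * cols / w)
        + 45.0 * rows / h
        + 20.0 * np.cos(2 * np.pi * 5.0 * (rows / h + cols / w))
    )
    template = np.full(shape, 8.0)
    template[body] = np.clip(texture[body], 30.0, 250.0)
    template = template.astype(np.uint8)

    landmarks = [
        ("head_top", 0.030 * h, cx * w),
        ("chin", 0.150 * h, cx * w),
        ("left_shoulder", 0.195 * h, (cx - 0.165) * w),
        ("right_shoulder", 0.195 * h, (cx + 0.165) * w),
        ("left_hand", 0.565 * h, (cx - 0.220) * w),
        ("right_hand", 0.565 * h, (cx + 0.220) * w),
        ("pelvis", 0.460 * h, cx * w),
        ("left_foot", 0.910 * h, (cx - 0.090) * w),
        ("right_foot", 0.910 * h, (cx + 0.090) * w),
    ]
    return BodyAtlas(template=template, zones=zones, landmarks=landmarks)


def save_atlas(atlas: BodyAtlas, directory: str | Path) -> None:
    """Persist an atlas as template PNG + per-zone PNG masks + landmark CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / "template.png", atlas.template)
    for name, mask in atlas.zones.items():
        iio.imwrite(directory / f"zone_{name}.png", (mask.astype(np.uint8) * 255))
    with open(directory / "landmarks.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "row", "col"])
        for name, r, c in atlas.landmarks:
            writer.writerow([name, f"{r:.2f}", f"{c:.2f}"])


def load_atlas(directory: str | Path) -> BodyAtlas:
    directory = Path(directory)
    template = iio.imread(directory / "template.png")
    zones = {name: iio.imread(directory / f"zone_{name}.png") > 127 for name in ZONE_NAMES}
    landmarks: list[tuple[str, float, float]] = []
    lm_path = directory / "landmarks.csv"
    if lm_path.exists():
        with open(lm_path, newline="") as fh:
            for row in csv.DictReader(fh):
                landmarks.append((row["name"], float(row["row"]), float(row["col"])))
    return BodyAtlas(template=template, zones=zones, landmarks=landmarks)
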