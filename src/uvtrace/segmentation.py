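"""Fluorescent-dye detection in UV photographs.

Dye pixels are found by nearest-centroid classification in CIE L*a*b*
(D65 white point), with centroids ("dominant colours") extracted from a
reference photograph of the dye source by k-means clustering.  Distances
are plain Euclidean ΔE (CIE76).  Overexposed pixels — the bright-white
saturation typical of heavily dosed regions under UV — are flagged into a
separate ambiguous class rather than being silently assigned to a dye,
and manually drawn exclusion masks (fluorescing gloves, goggles, wipes)
remove pixels from dye counting altogether.

Label encoding: 0 background, 1..K dye index (order of the supplied dye
references), 254 excluded, 255 ambiguous/overexposed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.color import rgb2lab
from skimage.util import img_as_float
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

LABEL_BACKGROUND = 0
LABEL_EXCLUDED = 254
LABEL_OVEREXPOSED = 255

#: Default maximum ΔE (CIE76) for assigning a pixel to a dye centroid.
DEFAULT_TOLERANCE = 25.0
#: Default L* above which a pixel is treated as overexposed.
DEFAULT_OVEREXPOSURE_LSTAR = 97.0


@dataclass
class DyeReference:
    """A named dye (or background feature) with its dominant colour.

    ``centroid`` is (L*, a*, b*); ``tolerance`` is the maximum ΔE at which
    a pixel may still be assigned to this dye.
    """

    name: str
    centroid: tuple[float, float, float]
    tolerance: float = DEFAULT_TOLERANCE

    def __post_init__(self) -> None:
        L = self.centroid[0]
        if not 0.0 <= L <= 100.0:
            raise ValueError(f"L* must lie in [0, 100], got {L}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class LabelMask:
    """Per-pixel class raster plus bookkeeping."""

    labels: np.ndarray  # uint8
    dye_names: tuple[str, ...]

    def counts(self) -> dict[str, int]:
        """Pixel count per class; keys are dye names plus the three
        housekeeping classes. Counts sum to the image size."""
        out = {"background": int(np.sum(self.labels == LABEL_BACKGROUND))}
        for i, name in enumerate(self.dye_names, start=1):
            out[name] = int(np.sum(self.labels == i))
        out["excluded"] = int(np.sum(self.labels == LABEL_EXCLUDED))
        out["overexposed"] = int(np.sum(self.labels == LABEL_OVEREXPOSED))
        return out

    def dye_mask(self, name: str) -> np.ndarray:
        return self.labels == (self.dye_names.index(name) + 1)

    def save(self, png_path: str | Path, refs: list[DyeReference] | None = None) -> None:
        """Write the indexed label PNG and a JSON sidecar of counts."""
        png_path = Path(png_path)
        iio.imwrite(png_path, self.labels.astype(np.uint8))
        sidecar = {"dye_names": list(self.dye_names), "counts": self.counts()}
        if refs is not None:
            sidecar["centroids"] = {r.name: list(r.centroid) for r in refs}
        png_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def to_lab(image: np.ndarray) -> np.ndarray:
    """Convert an sRGB raster to CIE L*a*b* under the D65 white point.

    Accepts uint8 in [0, 255] or float in [0, 1]; output L* lies in
    [0, 100].
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected a 3-channel sRGB image, got shape {image.shape}")
    return rgb2lab(img_as_float(image))


def delta_e(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray:
    """Euclidean colour difference (CIE76) between L*a*b* values."""
    return np.linalg.norm(np.asarray(lab1, dtype=np.float64) - np.asarray(lab2), axis=-1)


def extract_dominant_colors(
    reference: np.ndarray,
    foreground: np.ndarray | None,
    k: int,
    seed: int = 0,
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[DyeReference]:
    """Cluster the reference photograph's L*a*b* pixels into ``k`` dominant
    colours, ordered by decreasing cluster size.

    Runs k-means (k-means++ seeding, fixed ``seed``) on the pixels inside
    ``foreground`` (all pixels when None).  If two returned centroids are
    closer than ΔE 1 a duplicate-centroid warning is raised: the image
    holds fewer distinct colours than ``k``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    lab = to_lab(reference)
    if foreground is None:
        pixels = lab.reshape(-1, 3)
    else:
        if not foreground.any():
            raise ValueError("foreground mask is empty")
        pixels = lab[foreground]
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(pixels)
    order = np.argsort(-np.bincount(km.labels_, minlength=k), kind="stable")
    centroids = km.cluster_centers_[order]
    for i in range(k):
        for j in range(i + 1, k):
            if delta_e(centroids[i], centroids[j]) < 1.0:
                warnings.warn(
                    f"clusters {i} and {j} have near-identical centroids; the "
                    f"reference image holds fewer than k={k} distinct colours",
                    UserWarning,
                    stacklevel=2,
                )
    return [
        DyeReference(name=f"cluster{i}", centroid=tuple(np.clip(c, [0, -128, -128], [100, 127, 127])), tolerance=tolerance)
        for i, c in enumerate(centroids)
    ]


def flag_overexposed(
    uv: np.ndarray, lstar_threshold: float = DEFAULT_OVEREXPOSURE_LSTAR
) -> np.ndarray:
    """Boolean mask of pixels with L* above the overexposure threshold."""
    if not 0.0 < lstar_threshold <= 100.0:
        raise ValueError("overexposure threshold must lie in (0, 100]")
    return to_lab(uv)[..., 0] > lstar_threshold


def segment(
    uv: np.ndarray,
    refs: list[DyeReference],
    background_refs: list[DyeReference] | None = None,
    exclusion: np.ndarray | None = None,
    overexposure_lstar: float = DEFAULT_OVEREXPOSURE_LSTAR,
) -> LabelMask:
    """Partition a UV photograph into dye / background / excluded /
    overexposed classes by nearest-centroid assignment in ΔE.

    Rules, in priority order: excluded pixels keep label 254; pixels with
    L* above ``overexposure_lstar`` get the ambiguous label 255; every
    other pixel goes to its nearest centroid, falling back to background
    when the nearest dye is farther than that dye's tolerance.  A tie in
    ΔE between a dye and a background centroid resolves to background
    (the lower class index); ties among dyes resolve to the lower dye
    index.
    """
    if not refs:
        raise ValueError("at least one dye reference is required")
    lab = to_lab(uv)
    h, w = lab.shape[:2]
    flat = lab.reshape(-1, 3)

    dye_d = np.stack([delta_e(flat, np.array(r.centroid)) for r in refs], axis=1)
    best_dye = np.argmin(dye_d, axis=1)  # first occurrence -> lowest dye index on ties
    best_dye_d = dye_d[np.arange(flat.shape[0]), best_dye]
    tolerances = np.array([r.tolerance for r in refs])

    if background_refs:
        bg_d = np.stack(
            [delta_e(flat, np.array(r.centroid)) for r in background_refs], axis=1
        ).min(axis=1)
    else:
        bg_d = np.full(flat.shape[0], np.inf)

    labels = np.zeros(flat.shape[0], dtype=np.uint8)
    is_dye = (best_dye_d < bg_d) & (best_dye_d <= tolerances[best_dye])
    labels[is_dye] = best_dye[is_dye] + 1

    labels = labels.reshape(h, w)
    labels[lab[..., 0] > overexposure_lstar] = LABEL_OVEREXPOSED
    if exclusion is not None:
        labels[np.asarray(exclusion).astype(bool)] = LABEL_EXCLUDED
    return LabelMask(labels=labels, dye_names=tuple(r.name for r in refs))


class DyeSegmenter(BaseEstimator):
    """Nearest-centroid dye classifier for UV photographs.

    ``fit`` extracts dominant colours from a reference photograph of the
    dye source by k-means in L*a*b* and matches them to the named dyes via
    their nominal sRGB colours; ``predict`` labels every pixel of a UV
    photograph.  Fitted attributes: ``dye_references_``,
    ``background_references_``.

    Parameters
    ----------
    dye_names, nominal_colors
        Names and approximate sRGB colours of the dyes to detect; used
        only to match k-means clusters to dyes, not as the centroids.
    n_background
        Number of additional background clusters (dark booth, skin/PPE
        tone) extracted alongside the dyes.
    tolerance, overexposure_lstar
        ΔE assignment tolerance and L* overexposure threshold.
    """

    def __init__(
        self,
        dye_names: tuple[str, ...] = ("green", "blue", "red"),
        nominal_colors: tuple[tuple[int, int, int], ...] = (
            (70, 235, 80),
            (60, 130, 240),
            (240, 70, 70),
        ),
        n_background: int = 2,
        tolerance: float = DEFAULT_TOLERANCE,
        overexposure_lstar: float = DEFAULT_OVEREXPOSURE_LSTAR,
        random_state: int = 0,
    ) -> None:
        self.dye_names = dye_names
        self.nominal_colors = nominal_colors
        self.n_background = n_background
        self.tolerance = tolerance
        self.overexposure_lstar = overexposure_lstar
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None, foreground: np.ndarray | None = None) -> "DyeSegmenter":
        """Extract dye + background centroids from a reference UV photo."""
        k = len(self.dye_names) + self.n_background
        clusters = extract_dominant_colors(
            X, foreground, k=k, seed=self.random_state, tolerance=self.tolerance
        )
        nominal_lab = to_lab(
            np.asarray(self.nominal_colors, dtype=np.uint8).reshape(1, -1, 3)
        ).reshape(-1, 3)
        centroids = np.array([c.centroid for c in clusters])
        taken: set[int] = set()
        dye_refs: list[DyeReference] = []
        for name, nom in zip(self.dye_names, nominal_lab):
            d = delta_e(centroids, nom)
            d[list(taken)] = np.inf
            idx = int(np.argmin(d))
            taken.add(idx)
            dye_refs.append(
                DyeReference(name=name, centroid=tuple(centroids[idx]), tolerance=self.tolerance)
            )
        self.dye_references_ = dye_refs
        self.background_references_ = [
            DyeReference(name=f"bg{j}", centroid=c.centroid, tolerance=c.tolerance)
            for j, (i, c) in enumerate(
                (i, c) for i, c in enumerate(clusters) if i not in taken
            )
        ]
        return self

    def predict(self, X: np.ndarray, exclusion: np.ndarray | None = None) -> LabelMask:
        """Label every pixel of a UV photograph."""
        if not hasattr(self, "dye_references_"):
            raise ValueError("DyeSegmenter is not fitted yet; call fit first")
        return segment(
            X,
            self.dye_references_,
            background_refs=self.background_references_,
            exclusion=exclusion,
            overexposure_lstar=self.overexposure_lstar,
        )
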