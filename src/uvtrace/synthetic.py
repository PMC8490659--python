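"""Synthetic visible/UV photograph pairs with ground-truth contamination.

No photographs from the original evaluation are deposited, so this module
generates the whole study in silico: schematic body silhouettes (the atlas
template under a smooth random pose warp), per-stage ground-truth dye
masks produced by role-specific contact-transfer kernels, and rendered
photo pairs with the imaging artefacts the real photographs suffered from
(overexposed near-white contamination, fluorescing gloves/goggles/wipes
close in colour to the blue dye, sensor noise).

Transfer phenomenology encoded in the default kernels: role one (head
control) receives the spit dye around the head and the face/torso dye on
hands and wrists; roles two and three (patient's sides) receive the
hand/arm dye in the axilla/hand regions, with role two additionally
catching a little spit; the patient carries the painted source areas; the
physical-observations control subject picks up a small hands-only
transfer.  Contamination accumulates across stages by union and is thinned
at post-doffing by a per-zone cleansing efficiency (per-pixel removal
probability), deliberately lower for hands and arms where cleansing is
hardest.

Each subject keeps one body pose (one random smooth warp) across all its
photo stages — a single frontal view per photo point — which keeps
ground-truth pixel counts exactly additive between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.transform import resize, warp as sk_warp

from .atlas import ZONE_NAMES, BodyAtlas, default_atlas
from .design import STAFF_ROLES, ExperimentDesign

#: Reference raster area against which deposit budgets are scaled.
_REFERENCE_AREA = 1024 * 512

UV_BACKGROUND = (6, 6, 14)
UV_BODY_TONE = (30, 28, 44)
UV_OVEREXPOSED = (253, 253, 250)


@dataclass
class Deposit:
    """One transfer target: ``area_px`` pixels of ``dye`` placed in
    ``zone`` with edge fuzziness ``spread_px`` (budgets are at the
    1024x512 reference raster and scale with image area)."""

    dye: str
    zone: str
    area_px: int
    spread_px: float = 6.0


@dataclass
class TransferKernel:
    """Per-role mapping from dye source to destination zones."""

    role: str
    deposits: list[Deposit]


@dataclass
class ArtefactModel:
    """Imaging artefacts applied at render time.

    overexposure_fraction
        Share of truly contaminated pixels rendered near-white, saturating
        the dye colour.
    confounder_items
        ``(zone, sRGB)`` patches emulating fluorescing gloves / goggles /
        wipes; their colour is deliberately close to the blue dye.
    noise_sd
        Additive Gaussian sensor noise (8-bit intensity units).
    """

    overexposure_fraction: float = 0.10
    confounder_items: list[tuple[str, tuple[int, int, int]]] = field(
        default_factory=lambda: [("hands", (80, 150, 225)), ("head", (95, 165, 230))]
    )
    noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overexposure_fraction <= 1.0:
            raise ValueError("overexposure_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


def artefact_free() -> ArtefactModel:
    """Artefact model with no overexposure, confounders or noise."""
    return ArtefactModel(overexposure_fraction=0.0, confounder_items=[], noise_sd=0.0)


@dataclass
class UVPhotoPair:
    """Co-registered visible/UV render for one subject at one stage."""

    visible: np.ndarray  # uint8 (H, W, 3)
    uv: np.ndarray  # uint8 (H, W, 3)
    exclusion: np.ndarray  # bool; confounder patches a human would mask out
    overexposed: np.ndarray  # bool; contaminated pixels rendered near-white


@dataclass
class SubjectTruth:
    """Ground truth for one subject: pose, true zones and per-stage masks."""

    team: str
    subject: str
    role: str
    visible_base: np.ndarray  # float32, warped textured template
    foreground: np.ndarray  # bool
    zones: dict[str, np.ndarray]  # true warped zone masks
    stage_masks: dict[str, dict[str, np.ndarray]]  # stage -> dye -> bool

    def total(self, stage: str, dye: str | None = None) -> int:
        masks = self.stage_masks[stage]
        if dye is not None:
            return int(masks[dye].sum())
        return int(sum(m.sum() for m in masks.values()))

    def zone_counts(self, stage: str, dye: str) -> dict[str, int]:
        mask = self.stage_masks[stage][dye]
        return {name: int((mask & zmask).sum()) for name, zmask in self.zones.items()}


@dataclass
class SceneGroundTruth:
    """Full synthetic study: design, atlas and per-subject truth."""

    design: ExperimentDesign
    atlas: BodyAtlas
    subjects: dict[str, SubjectTruth]

    def staff_subjects(self) -> list[SubjectTruth]:
        return [s for s in self.subjects.values() if s.role in STAFF_ROLES]

    def control_subject(self) -> SubjectTruth:
        controls = [s for s in self.subjects.values() if s.role == "control"]
        if not controls:
            raise ValueError("scene has no control subject")
        return controls[0]

    def staff_control_ratio(self, stage: str = "post_pi") -> float:
        """Ground-truth restraint-vs-observations contamination ratio:
        mean post-restraint staff total divided by the control total."""
        staff = [s.total(stage) for s in self.staff_subjects()]
        control = self.control_subject().total("post_pi")
        if control == 0:
            return float("nan")
        return float(np.mean(staff) / control)

    def truth_table(self) -> pd.DataFrame:
        """Long-form ground-truth zonal areas (same schema as the measured
        contamination table)."""
        rows = []
        for s in self.subjects.values():
            for stage, masks in s.stage_masks.items():
                for dye in self.design.dye_names:
                    counts = s.zone_counts(stage, dye)
                    for zone in ZONE_NAMES:
                        rows.append(
                            (s.team, s.subject, s.role, stage, dye, zone, counts[zone])
                        )
        return pd.DataFrame(
            rows, columns=["team", "subject", "role", "stage", "dye", "zone", "area_px"]
        )


def default_kernels() -> list[TransferKernel]:
    """Packaged role-specific transfer kernels (areas at the reference
    raster).  Chosen to reproduce the observed pattern: spit on roles one
    and two only, hand/arm dye in the side roles' axilla and hands,
    face/torso dye heaviest on role one's hands and wrists."""
    return [
        TransferKernel(
            role="one",
            deposits=[
                Deposit("red", "head", 900, 5.0),
                Deposit("red", "thorax_upper_left", 80, 4.0),
                Deposit("blue", "hands", 700, 7.0),
                Deposit("blue", "arms", 400, 7.0),
                Deposit("blue", "thorax_upper_left", 200, 8.0),
                Deposit("green", "hands", 150, 5.0),
                Deposit("green", "arms", 100, 5.0),
            ],
        ),
        TransferKernel(
            role="two",
            deposits=[
                Deposit("green", "hands", 600, 7.0),
                Deposit("green", "arms", 400, 8.0),
                Deposit("green", "thorax_lower_left", 200, 8.0),
                Deposit("blue", "hands", 250, 6.0),
                Deposit("blue", "thorax_upper_left", 150, 7.0),
                Deposit("red", "thorax_upper_right", 60, 4.0),
            ],
        ),
        TransferKernel(
            role="three",
            deposits=[
                Deposit("green", "hands", 600, 7.0),
                Deposit("green", "arms", 400, 8.0),
                Deposit("green", "thorax_lower_right", 200, 8.0),
                Deposit("blue", "hands", 250, 6.0),
                Deposit("blue", "thorax_upper_right", 150, 7.0),
            ],
        ),
    ]


def default_control_deposits() -> list[Deposit]:
    """Hands-only transfer picked up while recording physical
    observations; sized so the ground-truth restraint/observations ratio
    lands near the low twenties."""
    return [Deposit("green", "hands", 40, 4.0), Deposit("blue", "hands", 44, 4.0)]


def default_cleansing() -> dict[str, float]:
    """Per-zone post-doffing removal probability: high where PPE covered
    the body, lower for hands and arms where cleansing is hardest."""
    eff = {name: 0.95 for name in ZONE_NAMES}
    eff["hands"] = 0.70
    eff["arms"] = 0.85
    return eff


# ---------------------------------------------------------------------------
# geometry helpers


def _random_pose_map(
    shape: tuple[int, int], rng: np.random.Generator, amplitude: float | None = None
) -> np.ndarray:
    """Smooth random pull-back map (subject coords -> template coords):
    small global shift + scale plus a low-frequency random field."""
    h, w = shape
    if amplitude is None:
        amplitude = h / 128.0  # ~8 px at the reference raster
    rows, cols = np.mgrid[:h, :w].astype(np.float64)
    scale = rng.uniform(0.97, 1.03)
    shift = rng.uniform(-0.01, 0.01, size=2) * h
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    base_r = (rows - cr) * scale + cr + shift[0]
    base_c = (cols - cc) * scale + cc + shift[1]
    coarse = rng.normal(0.0, 1.0, size=(2, 10, 5))
    smooth = np.stack(
        [resize(gaussian_filter(coarse[i], 1.0), (h, w), order=3) for i in range(2)]
    )
    for i in range(2):
        peak = np.abs(smooth[i]).max()
        if peak > 0:
            smooth[i] *= amplitude / peak
    return np.stack([base_r + smooth[0], base_c + smooth[1]])


def _draw_blob(
    rng: np.random.Generator,
    allowed: np.ndarray,
    area: int,
    spread: float,
    droplet: bool = False,
    n_centers: int = 1,
) -> np.ndarray:
    """Pick exactly ``min(area, allowed.sum())`` pixels from ``allowed`` as
    a fuzzy blob (or droplet cluster) around random centre(s)."""
    out = np.zeros(allowed.shape, dtype=bool)
    idx = np.argwhere(allowed)
    if len(idx) == 0 or area <= 0:
        return out
    area = min(area, len(idx))
    centers = idx[rng.choice(len(idx), size=min(n_centers, len(idx)), replace=False)]
    d = np.linalg.norm(
        idx[:, None, :].astype(np.float64) - centers[None, :, :], axis=2
    ).min(axis=1)
    if droplet:
        score = d + rng.exponential(scale=max(spread, 1.0) * 2.0, size=len(idx))
    else:
        score = d - rng.exponential(scale=max(spread, 0.5), size=len(idx))
    chosen = idx[np.argsort(score, kind="stable")[:area]]
    out[chosen[:, 0], chosen[:, 1]] = True
    return out


# ---------------------------------------------------------------------------
# simulation


def _subject_rng(seed: int, index: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, index, *extra]))


def simulate_transfer(
    design: ExperimentDesign,
    kernels: list[TransferKernel],
    seed: int,
    *,
    cleansing: dict[str, float] | None = None,
    control_deposits: list[Deposit] | None = None,
    baseline_blue_px: int = 25,
    patient_fill_fraction: float = 0.5,
    atlas: BodyAtlas | None = None,
) -> SceneGroundTruth:
    """Simulate contact transfer for every participant and stage.

    Deterministic for a fixed ``seed``; random streams are split per
    subject so regenerating one subject never shifts another.  Deposits
    are drawn as fuzzy blobs inside the destination zone; budgets scale
    with image area relative to the 1024x512 reference raster.  Dye masks
    are kept pairwise disjoint (dyes claim pixels in design order) so
    per-dye counts are exact.

    ``baseline_blue_px`` emulates the faint pre-donning fluorescence the
    cleansing wipes leave on the hands.
    """
    kernel_roles = {k.role for k in kernels}
    missing = set(STAFF_ROLES) - kernel_roles
    if missing:
        raise ValueError(f"kernels must cover all staff roles; missing {sorted(missing)}")
    for k in kernels:
        for dep in k.deposits:
            if dep.zone not in ZONE_NAMES:
                raise ValueError(f"unknown zone {dep.zone!r} in kernel for role {k.role!r}")
            if dep.dye not in design.dye_names:
                raise ValueError(f"unknown dye {dep.dye!r} in kernel for role {k.role!r}")

    atlas = atlas or default_atlas(design.image_shape)
    cleansing = default_cleansing() if cleansing is None else cleansing
    control_deposits = (
        default_control_deposits() if control_deposits is None else control_deposits
    )
    h, w = design.image_shape
    area_scale = (h * w) / _REFERENCE_AREA
    len_scale = float(np.sqrt(area_scale))
    kernel_by_role = {k.role: k for k in kernels}
    blue_name = next((d.name for d in design.dyes if d.source_areas and "head" in d.source_areas), None)

    subjects: dict[str, SubjectTruth] = {}
    roster: list[tuple[str, str, str]] = []  # (team, subject, role)
    for team in design.teams:
        staff_i = 0
        for role in team.roles:
            if role == "patient":
                roster.append((team.name, f"{team.name}P", role))
            else:
                staff_i += 1
                roster.append((team.name, f"{team.name}{staff_i}", role))
    for i in range(design.control_subjects):
        roster.append(("obs", f"OBS{i + 1}", "control"))

    for index, (team_name, subject_id, role) in enumerate(roster):
        rng = _subject_rng(design.seed if seed is None else seed, index)
        pose = _random_pose_map((h, w), rng)
        visible_base = sk_warp(
            atlas.template.astype(np.float64), pose, order=1, mode="constant", cval=8.0
        )
        zone_labels = sk_warp(
            atlas.zone_labels().astype(np.float64), pose, order=0, mode="constant", cval=0
        ).astype(np.uint8)
        zones = {name: zone_labels == k for k, name in enumerate(ZONE_NAMES, start=1)}
        foreground = sk_warp(
            atlas.foreground.astype(np.float64), pose, order=0, mode="constant", cval=0
        ) > 0.5

        team_spec = next((t for t in design.teams if t.name == team_name), None)
        stages = team_spec.stages if team_spec is not None else ("post_pi",)

        cum = {dye: np.zeros((h, w), dtype=bool) for dye in design.dye_names}
        occupied = np.zeros((h, w), dtype=bool)

        def place(dye: str, zone: str, area: int, spread: float, droplet: bool = False,
                  n_centers: int = 1) -> None:
            allowed = zones[zone] & foreground & ~occupied
            blob = _draw_blob(rng, allowed, area, spread, droplet=droplet, n_centers=n_centers)
            cum[dye] |= blob
            occupied[blob] = True

        stage_masks: dict[str, dict[str, np.ndarray]] = {}
        for stage in stages:
            if stage == "pre_don":
                if role == "patient":
                    for dye_spec in design.dyes:
                        for zone in dye_spec.source_areas:
                            zone_px = int((zones[zone] & foreground).sum())
                            place(dye_spec.name, zone,
                                  int(round(patient_fill_fraction * zone_px)), 10.0 * len_scale)
                elif role in STAFF_ROLES and blue_name is not None and baseline_blue_px > 0:
                    place(blue_name, "hands",
                          int(round(baseline_blue_px * area_scale)), 3.0 * len_scale)
            elif stage == "post_pi":
                if role in STAFF_ROLES:
                    for dep in kernel_by_role[role].deposits:
                        area = int(round(dep.area_px * area_scale))
                        spread = dep.spread_px * len_scale
                        dye_spec = next(d for d in design.dyes if d.name == dep.dye)
                        if not dye_spec.source_areas and design.spit_events:
                            # spit dye: split across spray events; distance
                            # widens and sparsifies the droplet pattern
                            n_ev = len(design.spit_events)
                            for ev in design.spit_events:
                                rel = ev.distance_mm / design.spit_events[0].distance_mm
                                place(dep.dye, dep.zone, area // n_ev,
                                      spread * rel, droplet=True,
                                      n_centers=max(3, int(6 * rel)))
                        else:
                            place(dep.dye, dep.zone, area, spread)
                elif role == "control":
                    for dep in control_deposits:
                        place(dep.dye, dep.zone,
                              int(round(dep.area_px * area_scale)), dep.spread_px * len_scale)
                elif role == "patient" and "pre_don" not in stages:
                    for dye_spec in design.dyes:
                        for zone in dye_spec.source_areas:
                            zone_px = int((zones[zone] & foreground).sum())
                            place(dye_spec.name, zone,
                                  int(round(patient_fill_fraction * zone_px)), 10.0 * len_scale)
            if stage == "post_doff":
                doffed: dict[str, np.ndarray] = {}
                for dye, mask in cum.items():
                    keep = np.zeros((h, w), dtype=bool)
                    removal = rng.random((h, w))
                    outside = mask.copy()
                    for zone, zmask in zones.items():
                        eff = cleansing.get(zone, 0.95)
                        inzone = mask & zmask
                        keep |= inzone & (removal >= eff)
                        outside &= ~zmask
                    keep |= outside & (removal >= 0.95)
                    doffed[dye] = keep
                stage_masks[stage] = doffed
            else:
                stage_masks[stage] = {dye: mask.copy() for dye, mask in cum.items()}

        subjects[subject_id] = SubjectTruth(
            team=team_name,
            subject=subject_id,
            role=role,
            visible_base=visible_base.astype(np.float32),
            foreground=foreground,
            zones=zones,
            stage_masks=stage_masks,
        )
    return SceneGroundTruth(design=design, atlas=atlas, subjects=subjects)


# ---------------------------------------------------------------------------
# rendering


def render_photo_pair(
    truth: SceneGroundTruth,
    subject: str,
    stage: str,
    artefacts: ArtefactModel | None = None,
    seed: int = 0,
) -> UVPhotoPair:
    """Render the visible/UV photo pair for one subject at one stage.

    The visible frame is the subject's warped textured silhouette; the UV
    frame paints each ground-truth dye mask in its nominal colour, renders
    the configured fraction of contaminated pixels near-white
    (overexposed) and adds fluorescing confounder patches, which are also
    returned as the exclusion mask a human analyst would draw.
    Deterministic for fixed ``seed``.
    """
    artefacts = artefacts if artefacts is not None else ArtefactModel()
    try:
        subj = truth.subjects[subject]
    except KeyError:
        raise KeyError(f"unknown subject {subject!r}") from None
    if stage not in subj.stage_masks:
        raise KeyError(f"subject {subject!r} has no stage {stage!r}")
    h, w = subj.foreground.shape
    roster = sorted(truth.subjects)
    rng = _subject_rng(seed, roster.index(subject), list(subj.stage_masks).index(stage), 7)

    visible = np.repeat(subj.visible_base[..., None], 3, axis=2).astype(np.float64)

    uv = np.empty((h, w, 3), dtype=np.float64)
    uv[:] = UV_BACKGROUND
    uv[subj.foreground] = UV_BODY_TONE
    dye_colors = {d.name: d.color_rgb for d in truth.design.dyes}
    union = np.zeros((h, w), dtype=bool)
    for dye, mask in subj.stage_masks[stage].items():
        uv[mask] = dye_colors[dye]
        union |= mask
    overexposed = union & (rng.random((h, w)) < artefacts.overexposure_fraction)
    uv[overexposed] = UV_OVEREXPOSED

    exclusion = np.zeros((h, w), dtype=bool)
    for zone, color in artefacts.confounder_items:
        allowed = subj.zones[zone] & subj.foreground & ~union
        patch = _draw_blob(rng, allowed, max(30, int(0.06 * allowed.sum())), 4.0)
        uv[patch] = color
        exclusion |= patch

    if artefacts.noise_sd > 0:
        uv += rng.normal(0.0, artefacts.noise_sd, size=uv.shape)
        visible += rng.normal(0.0, artefacts.noise_sd * 0.5, size=visible.shape)
    return UVPhotoPair(
        visible=np.clip(visible, 0, 255).astype(np.uint8),
        uv=np.clip(uv, 0, 255).astype(np.uint8),
        exclusion=exclusion,
        overexposed=overexposed,
    )


def render_reference_photo(
    truth: SceneGroundTruth, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Dye-reference frame: the patient's pre-restraint UV photo with a
    spit-dye swatch sprayed beside the head, so all dye colours are
    measurable from one photograph.  Returns ``(uv_image, foreground)``.
    """
    patient = next(s for s in truth.subjects.values() if s.role == "patient")
    first_stage = next(iter(patient.stage_masks))
    pair = render_photo_pair(
        truth,
        patient.subject,
        first_stage,
        artefacts=ArtefactModel(0.0, [], 1.0),
        seed=seed,
    )
    uv = pair.uv.astype(np.float64)
    spit = next((d for d in truth.design.dyes if not d.source_areas), None)
    if spit is not None:
        rng = _subject_rng(seed, 9999)
        h, w = patient.foreground.shape
        swatch = np.zeros((h, w), dtype=bool)
        rr = slice(int(0.04 * h), int(0.14 * h))
        cc = slice(int(0.06 * w), int(0.20 * w))
        region = np.zeros((h, w), dtype=bool)
        region[rr, cc] = True
        swatch = _draw_blob(rng, region, int(0.6 * region.sum()), 5.0, droplet=True, n_centers=8)
        uv[swatch] = spit.color_rgb
    return np.clip(uv, 0, 255).astype(np.uint8), patient.foreground


# ---------------------------------------------------------------------------
# scene persistence


def write_scene(
    truth: SceneGroundTruth,
    outdir: str | Path,
    artefacts: ArtefactModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write the scene under ``<team>/<subject>/<stage>_{vis,uv}.png`` with
    truth masks, exclusion masks, the design YAML, the dye-reference frame
    and a manifest CSV; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.design.to_yaml(outdir / "design.yaml")
    ref_uv, ref_fg = render_reference_photo(truth, seed=seed)
    iio.imwrite(outdir / "reference_uv.png", ref_uv)
    iio.imwrite(outdir / "reference_foreground.png", ref_fg.astype(np.uint8) * 255)

    rows = []
    for subject_id, subj in truth.subjects.items():
        subj_dir = outdir / subj.team / subject_id
        subj_dir.mkdir(parents=True, exist_ok=True)
        labels = np.zeros(subj.foreground.shape, dtype=np.uint8)
        for k, name in enumerate(ZONE_NAMES, start=1):
            labels[subj.zones[name]] = k
        iio.imwrite(subj_dir / "zones_true.png", labels)
        for stage in subj.stage_masks:
            pair = render_photo_pair(truth, subject_id, stage, artefacts, seed=seed)
            vis_path = subj_dir / f"{stage}_vis.png"
            uv_path = subj_dir / f"{stage}_uv.png"
            iio.imwrite(vis_path, pair.visible)
            iio.imwrite(uv_path, pair.uv)
            exclude_path = ""
            if pair.exclusion.any():
                exclude_path = str(subj_dir / f"{stage}_exclude.png")
                iio.imwrite(exclude_path, pair.exclusion.astype(np.uint8) * 255)
            for dye, mask in subj.stage_masks[stage].items():
                iio.imwrite(
                    subj_dir / f"{stage}_truth_{dye}.png", mask.astype(np.uint8) * 255
                )
            rows.append(
                {
                    "team": subj.team,
                    "subject": subject_id,
                    "role": subj.role,
                    "stage": stage,
                    "vis_path": str(vis_path),
                    "uv_path": str(uv_path),
                    "exclude_path": exclude_path,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
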