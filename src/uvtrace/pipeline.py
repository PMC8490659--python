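"""End-to-end orchestration: generate/load → register → segment → quantify.

The pipeline mirrors the study's analysis chain.  Each subject's
visible-light photograph is registered to the body atlas and the nine
zones propagated onto it; dye centroids are extracted once from the dye
reference frame; every UV photograph is partitioned into dye classes;
zonal pixel counts feed the accumulation series, the normalised team and
role maps, the post-doffing residual summary and the
restraint-vs-observations contamination ratio.  A manifest records the
config hash, seed and all warnings so a run is reproducible byte for
byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import pandas as pd
import yaml

from .atlas import default_atlas, load_atlas
from .design import STAFF_ROLES, ExperimentDesign, default_design
from .quantify import (
    RESIDUAL_FRACTION,
    RESIDUAL_MIN_PX,
    NormalisedMap,
    RatioResult,
    aggregate_roles,
    contamination_ratio,
    empty_table,
    map_to_image,
    normalise_team_maps,
    stage_accumulation,
    zonal_areas,
)
from .registration import AtlasRegistrar
from .segmentation import DyeSegmenter, LabelMask
from .synthetic import (
    ArtefactModel,
    SceneGroundTruth,
    default_kernels,
    render_photo_pair,
    render_reference_photo,
    simulate_transfer,
)

logger = logging.getLogger("uvtrace")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run.

    With ``scene_dir`` unset the pipeline generates the default synthetic
    study at ``image_shape`` from ``seed``; otherwise photographs are read
    from the directory layout the generator writes (real photographs can
    be dropped into the same layout).
    """

    output_dir: str = "uvtrace_run"
    scene_dir: str | None = None
    atlas_dir: str | None = None
    seed: int = 0
    image_shape: tuple[int, int] = (1024, 512)
    tolerance: float = 25.0
    overexposure_lstar: float = 97.0
    residual_fraction: float = RESIDUAL_FRACTION
    residual_min_px: int = RESIDUAL_MIN_PX
    registration_downscale: int = 2
    register_per_stage: bool = False
    #: Extract dye centroids from the dye-reference photograph (k-means);
    #: when False the design's nominal dye colours are used directly —
    #: the path for supplying known dye references without a reference
    #: photo (e.g. a scene with no visible contamination to cluster).
    extract_references: bool = True
    baseline_subtraction: bool = False
    use_exclusion_masks: bool = True
    #: Count ambiguous/overexposed pixels as contamination of unknown dye
    #: in the subject totals behind the restraint-vs-observations ratio.
    #: Saturated pixels are contaminated — only their dye identity is
    #: uncertain — so excluding them would bias every total low.
    count_overexposed_in_totals: bool = True
    overexposure_fraction: float = 0.10
    noise_sd: float = 3.0
    confounders: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0 or self.overexposure_lstar <= 0:
            raise ValueError("thresholds must be positive")

    def artefacts(self) -> ArtefactModel:
        if self.confounders:
            items = ArtefactModel().confounder_items
        else:
            items = []
        return ArtefactModel(
            overexposure_fraction=self.overexposure_fraction,
            confounder_items=items,
            noise_sd=self.noise_sd,
        )

    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "image_shape" in raw:
            raw["image_shape"] = tuple(raw["image_shape"])
        return cls(**raw)


@dataclass
class RunReport:
    """In-memory results of one pipeline run."""

    config: RunConfig
    design: ExperimentDesign
    table: pd.DataFrame  # staff + patient rows
    control_table: pd.DataFrame
    qc: pd.DataFrame
    accumulation: pd.DataFrame
    residual_flags: pd.DataFrame
    team_maps: NormalisedMap
    role_maps: NormalisedMap
    ratio: RatioResult
    zones: dict[str, dict[str, np.ndarray]]  # subject -> propagated zone masks
    label_counts: dict[tuple[str, str], dict[str, int]]  # (subject, stage) -> counts
    warnings: list[str] = field(default_factory=list)
    failed_subjects: list[str] = field(default_factory=list)
    truth: SceneGroundTruth | None = None

    @property
    def full_table(self) -> pd.DataFrame:
        if len(self.control_table):
            return pd.concat([self.table, self.control_table], ignore_index=True)
        return self.table


def _load_scene(scene_dir: Path):
    """Read a generated (or drop-in) scene directory."""
    design = ExperimentDesign.from_yaml(scene_dir / "design.yaml")
    manifest = pd.read_csv(scene_dir / "manifest.csv", keep_default_na=False)
    reference_uv = iio.imread(scene_dir / "reference_uv.png")
    return design, manifest, reference_uv


def _subtract_baseline(series: pd.DataFrame) -> pd.DataFrame:
    """Optionally remove each subject/dye's pre-donning baseline (wipe
    fluorescence) from every stage total, clipping at zero."""
    out = series.copy()
    base = (
        series[series["stage"] == "pre_don"]
        .set_index(["subject", "dye"])["total_px"]
        .to_dict()
    )
    out["total_px"] = [
        max(0, t - base.get((s, d), 0))
        for s, d, t in zip(out["subject"], out["dye"], out["total_px"])
    ]
    return out


def run_pipeline(config: RunConfig, truth: SceneGroundTruth | None = None) -> RunReport:
    """Execute the full analysis and write all outputs under
    ``config.output_dir``.

    A per-subject failure (unreadable image, degenerate registration) is
    logged, recorded in the manifest and skipped; study-level outputs are
    computed over the remaining subjects.  An invalid atlas aborts.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    failed: list[str] = []

    scene_dir = Path(config.scene_dir) if config.scene_dir else None
    if truth is None and scene_dir is None:
        design = default_design(config.image_shape, seed=config.seed)
        truth = simulate_transfer(design, default_kernels(), seed=config.seed)
    if truth is not None:
        design = truth.design
        reference_uv = render_reference_photo(truth, seed=config.seed)[0]
        manifest_df = None
    else:
        design, manifest_df, reference_uv = _load_scene(scene_dir)

    if config.atlas_dir:
        atlas = load_atlas(config.atlas_dir)  # raises on an invalid atlas
    elif truth is not None:
        atlas = truth.atlas
    else:
        atlas = default_atlas(tuple(design.image_shape))

    segmenter = DyeSegmenter(
        dye_names=design.dye_names,
        nominal_colors=tuple(d.color_rgb for d in design.dyes),
        tolerance=config.tolerance,
        overexposure_lstar=config.overexposure_lstar,
        random_state=config.seed,
    )
    if config.extract_references:
        segmenter.fit(reference_uv)
    else:
        from .segmentation import DyeReference, to_lab

        segmenter.dye_references_ = [
            DyeReference(
                name=d.name,
                centroid=tuple(
                    to_lab(np.asarray(d.color_rgb, dtype=np.uint8).reshape(1, 1, 3))[0, 0]
                ),
                tolerance=config.tolerance,
            )
            for d in design.dyes
        ]
        segmenter.background_references_ = []

    artefacts = config.artefacts()

    # enumerate (subject, stage, loader) work items
    items: dict[str, list[tuple[str, object]]] = {}
    meta: dict[str, dict[str, str]] = {}
    if truth is not None:
        for sid, subj in truth.subjects.items():
            meta[sid] = {"team": subj.team, "subject": sid, "role": subj.role}
            items[sid] = [
                (stage, ("render", sid, stage)) for stage in subj.stage_masks
            ]
    else:
        for row in manifest_df.itertuples():
            meta.setdefault(
                row.subject, {"team": row.team, "subject": row.subject, "role": row.role}
            )
            items.setdefault(row.subject, []).append(
                (row.stage, ("load", row.vis_path, row.uv_path, row.exclude_path))
            )

    registrar = AtlasRegistrar(atlas=atlas, downscale=config.registration_downscale)
    all_rows, qc_rows = [], []
    zones_by_subject: dict[str, dict[str, np.ndarray]] = {}
    label_counts: dict[tuple[str, str], dict[str, int]] = {}

    for sid, stage_items in items.items():
        try:
            zones = None
            subj_rows, subj_qc, subj_counts = [], [], {}
            for stage, spec in stage_items:
                if spec[0] == "render":
                    pair = render_photo_pair(truth, sid, stage, artefacts, seed=config.seed)
                    visible, uv = pair.visible, pair.uv
                    exclusion = pair.exclusion if config.use_exclusion_masks else None
                else:
                    _, vis_path, uv_path, exclude_path = spec
                    visible = iio.imread(vis_path)
                    uv = iio.imread(uv_path)
                    exclusion = None
                    if config.use_exclusion_masks and exclude_path:
                        exclusion = iio.imread(exclude_path) > 127
                if zones is None or config.register_per_stage:
                    registrar.fit(visible)
                    if not registrar.field_.converged:
                        warnings_log.append(
                            f"{sid}/{stage}: registration flagged "
                            f"(MSE {registrar.field_.mse:.4f})"
                        )
                    zones = registrar.zones_
                labels: LabelMask = segmenter.predict(uv, exclusion=exclusion)
                rows, qc = zonal_areas(labels, zones, {**meta[sid], "stage": stage})
                subj_rows.append(rows)
                subj_qc.append(qc)
                subj_counts[(sid, stage)] = labels.counts()
            # commit only complete subjects so a failure never leaves
            # partial stage rows behind
            all_rows.extend(subj_rows)
            qc_rows.extend(subj_qc)
            label_counts.update(subj_counts)
            zones_by_subject[sid] = zones
        except Exception as exc:  # graceful degradation, never silent
            logger.exception("subject %s failed", sid)
            failed.append(sid)
            warnings_log.append(f"{sid}: failed ({exc})")

    combined = pd.concat(all_rows, ignore_index=True) if all_rows else empty_table()
    qc_table = pd.concat(qc_rows, ignore_index=True) if qc_rows else pd.DataFrame()
    if len(combined):
        is_control = combined["role"] == "control"
        table, control_table = combined[~is_control], combined[is_control]
    else:
        table, control_table = combined, empty_table()

    series, flags = stage_accumulation(table, residual_fraction=config.residual_fraction)
    if config.baseline_subtraction and len(series):
        series = _subtract_baseline(series)
    team_maps = normalise_team_maps(table)
    role_maps = aggregate_roles(table)
    ratio_proc, ratio_ctrl = table, control_table
    if config.count_overexposed_in_totals and len(qc_table):
        extra = qc_table.rename(columns={"overexposed_px": "area_px"})[
            ["team", "subject", "role", "stage", "zone", "area_px"]
        ].copy()
        extra["dye"] = "ambiguous"
        ratio_proc = pd.concat([table, extra[extra["role"] != "control"]],
                               ignore_index=True)
        ratio_ctrl = pd.concat([control_table, extra[extra["role"] == "control"]],
                               ignore_index=True)
    if len(control_table):
        ratio = contamination_ratio(ratio_proc, ratio_ctrl)
    else:
        ratio = RatioResult(float("nan"), "undefined", float("nan"), 0.0)
        warnings_log.append("no control subject; ratio undefined")

    report = RunReport(
        config=config,
        design=design,
        table=table.reset_index(drop=True),
        control_table=control_table.reset_index(drop=True),
        qc=qc_table,
        accumulation=series,
        residual_flags=flags,
        team_maps=team_maps,
        role_maps=role_maps,
        ratio=ratio,
        zones=zones_by_subject,
        label_counts=label_counts,
        warnings=warnings_log,
        failed_subjects=failed,
        truth=truth,
    )
    _write_outputs(report, outdir, elapsed=time.time() - t0)
    return report


def compare_stages(
    report: RunReport,
    residual_fraction: float | None = None,
    min_px: int | None = None,
    roles: tuple[str, ...] = STAFF_ROLES,
) -> pd.DataFrame:
    """Residual summary: staff subjects/zones where contamination persists
    after doffing above the threshold fraction of the post-restraint
    level.  ``min_px`` is defined at the 1024x512 reference raster and
    scales with image area, so reduced-size runs use an equivalent floor.
    """
    residual_fraction = (
        report.config.residual_fraction if residual_fraction is None else residual_fraction
    )
    min_px = report.config.residual_min_px if min_px is None else min_px
    h, w = report.design.image_shape
    min_px = max(1, int(round(min_px * (h * w) / (1024 * 512))))
    table = report.table[report.table["role"].isin(roles)]
    if not len(table):
        return pd.DataFrame(
            columns=["team", "subject", "role", "zone", "post_pi_px",
                     "post_doff_px", "residual_fraction"]
        )
    pivot = (
        table.groupby(["team", "subject", "role", "zone", "stage"])["area_px"]
        .sum()
        .unstack("stage", fill_value=0)
    )
    rows = []
    for (team, subject, role, zone), vals in pivot.iterrows():
        post_pi = int(vals.get("post_pi", 0))
        post_doff = int(vals.get("post_doff", 0))
        if post_pi > 0 and post_doff >= min_px and post_doff / post_pi > residual_fraction:
            rows.append(
                {"team": team, "subject": subject, "role": role, "zone": zone,
                 "post_pi_px": post_pi, "post_doff_px": post_doff,
                 "residual_fraction": post_doff / post_pi}
            )
    out = pd.DataFrame(
        rows, columns=["team", "subject", "role", "zone", "post_pi_px",
                       "post_doff_px", "residual_fraction"]
    )
    return out.sort_values("post_doff_px", ascending=False).reset_index(drop=True)


def _write_outputs(report: RunReport, outdir: Path, elapsed: float) -> None:
    report.table.to_csv(outdir / "contamination.csv", index=False)
    report.control_table.to_csv(outdir / "control.csv", index=False)
    report.qc.to_csv(outdir / "qc.csv", index=False)
    report.accumulation.to_csv(outdir / "accumulation.csv", index=False)
    report.residual_flags.to_csv(outdir / "residual_flags.csv", index=False)
    report.team_maps.table.to_csv(outdir / "team_maps.csv", index=False)
    report.role_maps.table.to_csv(outdir / "role_maps.csv", index=False)
    residuals = compare_stages(report)
    residuals.to_csv(outdir / "residuals.csv", index=False)

    maps_dir = outdir / "maps"
    maps_dir.mkdir(exist_ok=True)
    atlas = report.truth.atlas if report.truth is not None else default_atlas(
        tuple(report.design.image_shape)
    )
    for nmap, prefix in ((report.team_maps, "team"), (report.role_maps, "role")):
        if not len(nmap.table):
            continue
        for group in nmap.table[nmap.group_field].unique():
            for dye in nmap.table["dye"].unique():
                iio.imwrite(
                    maps_dir / f"{prefix}_{group}_{dye}.png",
                    map_to_image(nmap, atlas, group, dye),
                )

    manifest = {
        "config_hash": report.config.config_hash(),
        "seed": report.config.seed,
        "elapsed_s": round(elapsed, 2),
        "n_subjects_ok": len(report.zones),
        "n_subjects_failed": len(report.failed_subjects),
        "failed_subjects": report.failed_subjects,
        "warnings": report.warnings,
        "ratio": {
            "value": None if np.isnan(report.ratio.value) else round(report.ratio.value, 4),
            "status": report.ratio.status,
            "staff_mean_px": None
            if np.isnan(report.ratio.staff_mean)
            else report.ratio.staff_mean,
            "control_total_px": report.ratio.control_total,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
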