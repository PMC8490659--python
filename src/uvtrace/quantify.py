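"""Contamination statistics from label masks and zone masks.

Areas are raw pixel counts: the imaging protocol is fixed but uncalibrated,
so units are arbitrary yet comparable between subjects photographed under
the same protocol.  The module produces the study's summary surfaces:
long-form zonal area tables, per-subject stage-accumulation series with
post-doffing residual flags, team-normalised and role-aggregated regional
maps, and the restraint-vs-physical-observations contamination ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ZONE_NAMES, BodyAtlas
from .design import STAFF_ROLES, STAGES
from .segmentation import LABEL_EXCLUDED, LABEL_OVEREXPOSED, LabelMask

#: Fixed schema of the long-form contamination table.
TABLE_COLUMNS = ("team", "subject", "role", "stage", "dye", "zone", "area_px")

#: Default residual-contamination thresholds: a subject/zone is flagged
#: when its post-doffing area exceeds this fraction of its post-restraint
#: area and is at least ``RESIDUAL_MIN_PX`` pixels (the floor stops
#: near-empty zones from flagging on cleansing noise).
RESIDUAL_FRACTION = 0.10
RESIDUAL_MIN_PX = 20


def empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=list(TABLE_COLUMNS))


def validate_table(table: pd.DataFrame) -> None:
    missing = set(TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"contamination table is missing columns {sorted(missing)}")
    if len(table) and (table["area_px"] < 0).any():
        raise ValueError("area_px must be non-negative")
    dup = table.duplicated(subset=["team", "subject", "stage", "dye", "zone"])
    if dup.any():
        raise ValueError("duplicate (team, subject, stage, dye, zone) rows")


def zonal_areas(
    labels: LabelMask,
    zones: dict[str, np.ndarray],
    meta: dict[str, str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count labelled dye pixels per zone for one subject at one stage.

    Returns ``(table_rows, qc_rows)``: one row per (dye, zone) — exactly
    nine zones per dye — plus a QC table holding the per-zone overexposed
    and excluded counts, which are reported separately and never as dye
    area.
    """
    first = next(iter(zones.values()))
    if first.shape != labels.labels.shape:
        raise ValueError(
            f"label shape {labels.labels.shape} != zone shape {first.shape}"
        )
    base = {k: meta[k] for k in ("team", "subject", "role", "stage")}
    rows, qc_rows = [], []
    for zone in ZONE_NAMES:
        zmask = zones[zone]
        for i, dye in enumerate(labels.dye_names, start=1):
            rows.append(
                {**base, "dye": dye, "zone": zone,
                 "area_px": int(np.sum((labels.labels == i) & zmask))}
            )
        qc_rows.append(
            {**base, "zone": zone,
             "overexposed_px": int(np.sum((labels.labels == LABEL_OVEREXPOSED) & zmask)),
             "excluded_px": int(np.sum((labels.labels == LABEL_EXCLUDED) & zmask))}
        )
    return pd.DataFrame(rows), pd.DataFrame(qc_rows)


def stage_accumulation(
    table: pd.DataFrame,
    residual_fraction: float = RESIDUAL_FRACTION,
    stage_order: tuple[str, ...] = STAGES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject accumulation series and residual-contamination flags.

    Returns ``(series, flags)``.  ``series`` holds the total area per
    (subject, dye, stage) in stage order; ``flags`` marks subjects whose
    post-doffing all-dye total exceeds ``residual_fraction`` of their
    post-restraint total.
    """
    validate_table(table)
    if not len(table):
        return (
            pd.DataFrame(columns=["team", "subject", "role", "dye", "stage", "total_px"]),
            pd.DataFrame(columns=["team", "subject", "role", "post_pi_px",
                                  "post_doff_px", "residual_fraction", "flagged"]),
        )
    series = (
        table.groupby(["team", "subject", "role", "dye", "stage"], as_index=False)["area_px"]
        .sum()
        .rename(columns={"area_px": "total_px"})
    )
    series["_order"] = series["stage"].map({s: i for i, s in enumerate(stage_order)})
    series = (
        series.sort_values(["team", "subject", "dye", "_order"])
        .drop(columns="_order")
        .reset_index(drop=True)
    )

    totals = table.groupby(["team", "subject", "role", "stage"])["area_px"].sum()
    flags = []
    for (team, subject, role), sub in totals.groupby(level=[0, 1, 2]):
        by_stage = sub.droplevel([0, 1, 2])
        post_pi = int(by_stage.get("post_pi", 0))
        post_doff = int(by_stage.get("post_doff", 0))
        frac = post_doff / post_pi if post_pi > 0 else math.nan
        flags.append(
            {"team": team, "subject": subject, "role": role,
             "post_pi_px": post_pi, "post_doff_px": post_doff,
             "residual_fraction": frac,
             "flagged": bool(post_pi > 0 and frac > residual_fraction)}
        )
    return series, pd.DataFrame(flags)


@dataclass
class NormalisedMap:
    """Regional contamination map normalised per dye to [0, 1].

    ``table`` has columns ``(group, dye, zone, value)`` where ``group`` is
    a team or a staff role depending on ``scope``.
    """

    table: pd.DataFrame
    scope: str  # "across-teams" | "per-contamination-type"
    group_field: str  # "team" | "role"

    def value(self, group: str, dye: str, zone: str) -> float:
        sel = self.table[
            (self.table[self.group_field] == group)
            & (self.table["dye"] == dye)
            & (self.table["zone"] == zone)
        ]
        return float(sel["value"].iloc[0]) if len(sel) else 0.0

    def validate(self) -> None:
        vals = self.table["value"].to_numpy(dtype=float)
        if len(vals) and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("normalised map values must lie in [0, 1]")


def _normalise_per_dye(sums: pd.DataFrame, group_field: str) -> pd.DataFrame:
    """Divide each dye's (group, zone) sums by that dye's maximum; an
    all-zero dye stays all zero."""
    out = sums.copy()
    out["value"] = 0.0
    for dye, sub in sums.groupby("dye"):
        peak = sub["area_px"].max()
        if peak > 0:
            out.loc[sub.index, "value"] = sub["area_px"] / peak
    return out[[group_field, "dye", "zone", "value"]].reset_index(drop=True)


def normalise_team_maps(
    table: pd.DataFrame,
    stage: str | None = None,
    roles: tuple[str, ...] = STAFF_ROLES,
) -> NormalisedMap:
    """Team regional maps: per dye, staff areas summed over team members
    per (team, zone) and normalised to the maximum over all teams and
    zones for that dye.  Each contamination type is treated separately."""
    validate_table(table)
    sel = table[table["role"].isin(roles)]
    if stage is not None:
        sel = sel[sel["stage"] == stage]
    sums = sel.groupby(["team", "dye", "zone"], as_index=False)["area_px"].sum()
    return NormalisedMap(
        table=_normalise_per_dye(sums, "team"),
        scope="across-teams",
        group_field="team",
    )


def aggregate_roles(
    table: pd.DataFrame,
    stage: str = "post_pi",
    roles: tuple[str, ...] = STAFF_ROLES,
) -> NormalisedMap:
    """Role regional maps: post-restraint areas aggregated across teams
    per (role, zone) and normalised to the per-dye maximum."""
    validate_table(table)
    sel = table[(table["role"].isin(roles)) & (table["stage"] == stage)]
    sums = sel.groupby(["role", "dye", "zone"], as_index=False)["area_px"].sum()
    return NormalisedMap(
        table=_normalise_per_dye(sums, "role"),
        scope="per-contamination-type",
        group_field="role",
    )


@dataclass
class RatioResult:
    """Restraint-vs-observations contamination ratio with explicit
    undefined status when the control total is zero."""

    value: float
    status: str  # "ok" | "undefined"
    staff_mean: float
    control_total: float

    def __float__(self) -> float:
        return self.value


def contamination_ratio(
    procedure_table: pd.DataFrame,
    control_table: pd.DataFrame,
    stage: str = "post_pi",
    staff_roles: tuple[str, ...] = STAFF_ROLES,
) -> RatioResult:
    """Mean staff post-restraint total divided by the control subject's
    post-procedure total.  A zero control total yields an explicit
    ``undefined`` result, never a silent zero or an exception."""
    validate_table(procedure_table)
    validate_table(control_table)
    staff = procedure_table[
        (procedure_table["role"].isin(staff_roles))
        & (procedure_table["stage"] == stage)
    ]
    if not len(staff):
        raise ValueError(f"procedure table has no staff rows at stage {stage!r}")
    staff_totals = staff.groupby("subject")["area_px"].sum()
    control = control_table[control_table["role"] == "control"]
    if not len(control):
        raise ValueError("control table has no control-subject rows")
    control_total = float(control["area_px"].sum())
    staff_mean = float(staff_totals.mean())
    if control_total == 0:
        return RatioResult(math.nan, "undefined", staff_mean, control_total)
    return RatioResult(staff_mean / control_total, "ok", staff_mean, control_total)


def map_to_image(nmap: NormalisedMap, atlas: BodyAtlas, group: str, dye: str) -> np.ndarray:
    """Paint a normalised map onto the atlas as an 8-bit greyscale
    schematic (darker = more contamination), one panel per (group, dye)."""
    img = np.full(atlas.shape, 255, dtype=np.uint8)
    img[atlas.foreground] = 235
    for zone in ZONE_NAMES:
        v = nmap.value(group, dye, zone)
        img[atlas.zones[zone]] = int(round(235 - 215 * v))
    return img
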