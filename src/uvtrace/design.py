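"""Experiment design: teams, roles, dyes, stages and spit events.

The packaged default mirrors the evaluation layout it emulates: twelve
participants in three teams of four (three restraint-staff roles plus one
patient per team), three UV dyes placed on the patient (green on hands
and arms, blue on face and torso, red delivered as simulated spit at
150 mm and 300 mm), restraint episodes of 4.5 minutes, photographs at
pre-donning / post-donning / post-restraint / post-doffing (the
scrubs-only team skips the donning photo set), and a single
physical-observations control subject.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

#: Canonical photo-stage order.
STAGES: tuple[str, ...] = ("pre_don", "post_don", "post_pi", "post_doff")
STAFF_ROLES: tuple[str, ...] = ("one", "two", "three")
ROLES: tuple[str, ...] = STAFF_ROLES + ("patient", "control")


@dataclass
class DyeSpec:
    """A UV dye: name, the patient body areas it is painted on (atlas zone
    names; empty for the spit dye, which is delivered by spray events) and
    its nominal sRGB appearance under UV light."""

    name: str
    source_areas: tuple[str, ...]
    color_rgb: tuple[int, int, int]


@dataclass
class TeamSpec:
    """One restraint team: PPE set identifier and its ordered stage list."""

    name: str
    ppe_set: str
    stages: tuple[str, ...]
    roles: tuple[str, ...] = ("one", "two", "three", "patient")


@dataclass
class SpitEvent:
    """A simulated spit: spray distance (mm) and the stage it lands in."""

    distance_mm: float
    stage: str = "post_pi"


@dataclass
class ExperimentDesign:
    teams: list[TeamSpec]
    dyes: list[DyeSpec]
    spit_events: list[SpitEvent]
    episode_duration_min: float = 4.5
    control_subjects: int = 1
    seed: int = 0
    image_shape: tuple[int, int] = (1024, 512)  # rows, cols (portrait)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for team in self.teams:
            if team.roles.count("patient") != 1:
                raise ValueError(f"team {team.name!r} must have exactly one patient role")
            extra = [s for s in team.stages if s not in STAGES]
            if extra:
                raise ValueError(f"team {team.name!r} has unknown stages {extra}")
            order = [STAGES.index(s) for s in team.stages]
            if order != sorted(order):
                raise ValueError(f"team {team.name!r} stages are out of order")
        for ev in self.spit_events:
            if ev.distance_mm <= 0:
                raise ValueError("spit distances must be positive")
        if self.episode_duration_min <= 0:
            raise ValueError("episode duration must be positive")

    @property
    def n_participants(self) -> int:
        return sum(len(t.roles) for t in self.teams)

    @property
    def dye_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.dyes)

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "teams": [asdict(t) for t in self.teams],
            "dyes": [asdict(d) for d in self.dyes],
            "spit_events": [asdict(e) for e in self.spit_events],
            "episode_duration_min": self.episode_duration_min,
            "control_subjects": self.control_subjects,
            "seed": self.seed,
            "image_shape": list(self.image_shape),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            teams=[
                TeamSpec(
                    name=t["name"],
                    ppe_set=t["ppe_set"],
                    stages=tuple(t["stages"]),
                    roles=tuple(t.get("roles", ("one", "two", "three", "patient"))),
                )
                for t in raw["teams"]
            ],
            dyes=[
                DyeSpec(
                    name=d["name"],
                    source_areas=tuple(d["source_areas"]),
                    color_rgb=tuple(d["color_rgb"]),
                )
                for d in raw["dyes"]
            ],
            spit_events=[
                SpitEvent(distance_mm=e["distance_mm"], stage=e.get("stage", "post_pi"))
                for e in raw["spit_events"]
            ],
            episode_duration_min=raw.get("episode_duration_min", 4.5),
            control_subjects=raw.get("control_subjects", 1),
            seed=raw.get("seed", 0),
            image_shape=tuple(raw.get("image_shape", (1024, 512))),
        )


def default_design(
    image_shape: tuple[int, int] = (1024, 512), seed: int = 0
) -> ExperimentDesign:
    """The packaged study layout: 3 teams × (3 staff + 1 patient), three
    dyes, spit at 150 mm and 300 mm, 4.5 min episodes, one control
    subject; the scrubs-only team C has three photo stages."""
    full = ("pre_don", "post_don", "post_pi", "post_doff")
    return ExperimentDesign(
        teams=[
            TeamSpec(name="A", ppe_set="A", stages=full),
            TeamSpec(name="B", ppe_set="B", stages=full),
            TeamSpec(name="C", ppe_set="C", stages=("pre_don", "post_pi", "post_doff")),
        ],
        dyes=[
            DyeSpec(name="green", source_areas=("hands", "arms"), color_rgb=(70, 235, 80)),
            DyeSpec(
                name="blue",
                source_areas=("head", "thorax_upper_left", "thorax_upper_right"),
                color_rgb=(60, 130, 240),
            ),
            DyeSpec(name="red", source_areas=(), color_rgb=(240, 70, 70)),
        ],
        spit_events=[SpitEvent(distance_mm=150.0), SpitEvent(distance_mm=300.0)],
        episode_duration_min=4.5,
        control_subjects=1,
        seed=seed,
        image_shape=image_shape,
    )
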