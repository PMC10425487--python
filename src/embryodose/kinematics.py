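"""Embryo growth, staging, and georeferencing of structures in the source frame.

The embryo is staged by incubation time against Hamburger-Hamilton (HH)
anchor points, and its length is extrapolated linearly from the measured
growth velocity (series EA: 1.04 mm at 20 h incubation growing to 5 mm at
50 h; series EB: 1.5 mm at 24 h to 2.9 mm at 33 h).  Named structures
(head, the hind-head/presumptive-heart locus, Hensen's node, optic
vesicles, tail) are located on the axis either by interpolating between
two measured anchor offsets or as a fixed fraction of body length, and the
agar placement (cephalic, caudal, or lateral variants) converts the axial
offset into (x, y) coordinates in the diffusion source frame.

The geometric convention follows the observation that with a cephalic
source the head keeps a constant distance from the agar while the caudal
end recedes as the body elongates: the placement's reference structure
(head for cephalic-side classes, tail for caudal-side classes) holds the
printed distance, and the rest of the body extends away from the source.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .medium import ExposurePoint
from .units import h_to_s, mm_to_cm

__all__ = [
    "StageTimeline",
    "GrowthModel",
    "StructureMap",
    "Placement",
    "growth_velocity",
    "length_at",
    "stage_at",
    "structure_position",
    "load_stage_timeline",
    "load_structure_map",
    "load_growth_model",
]


def _load_data(name: str) -> dict:
    with resources.files("embryodose.data").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class StageTimeline:
    """HH stage anchors: rows of (incubation_h, numeric stage, label)."""

    incubation_h: tuple[float, ...]
    stages: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        hs = self.incubation_h
        if any(b <= a for a, b in zip(hs, hs[1:])):
            raise ValueError("incubation times must be strictly increasing")
        if any(b < a for a, b in zip(self.stages, self.stages[1:])):
            raise ValueError("stages must be non-decreasing")


def load_stage_timeline() -> StageTimeline:
    raw = _load_data("stage_timeline.json")
    rows = raw["anchors"]
    return StageTimeline(
        incubation_h=tuple(r["incubation_h"] for r in rows),
        stages=tuple(r["stage"] for r in rows),
        labels=tuple(r["label"] for r in rows),
    )


def stage_at(timeline: StageTimeline, incubation_h: float) -> str:
    """Nearest HH stage label at an incubation time within the table range.

    The numeric stage is interpolated piecewise-linearly between anchors
    and rounded to the nearest half-unit; anchor labels are reported
    verbatim (e.g. the 50 h anchor is the composite stage "HH14-15").
    """
    hs, stages = timeline.incubation_h, timeline.stages
    if not (hs[0] <= incubation_h <= hs[-1]):
        raise ValueError(
            f"incubation time {incubation_h} h outside table range [{hs[0]}, {hs[-1]}]"
        )
    for i, h in enumerate(hs):
        if incubation_h == h:
            return timeline.labels[i]
    k = max(i for i, h in enumerate(hs) if h < incubation_h)
    frac = (incubation_h - hs[k]) / (hs[k + 1] - hs[k])
    stage = stages[k] + frac * (stages[k + 1] - stages[k])
    # snap to an anchor label if the interpolant rounds onto an anchor stage
    rounded = round(stage * 2.0) / 2.0
    for s, label in zip(stages, timeline.labels):
        if rounded == s:
            return label
    if rounded == int(rounded):
        return f"HH{int(rounded)}"
    return f"HH{int(rounded)}-{int(rounded) + 1}"


def growth_velocity(L0_mm: float, Lf_mm: float, duration_h: float) -> float:
    """Mean growth velocity [mm/h] between two measured lengths."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    return (Lf_mm - L0_mm) / duration_h


@dataclass(frozen=True)
class GrowthModel:
    """Linear embryo growth: length L0 + v*t, t in hours since exposure start.

    ``sigma_L`` is the individual-variability spread used by the synthetic
    generator (mm, the printed +- on the final length).
    """

    L0: float  # mm at exposure start
    v: float  # mm/h
    t0: float = 20.0  # exposure start, hours of incubation
    sigma_L: float = 0.5  # mm

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if self.v <= 0:
            raise ValueError("growth velocity must be positive")


def length_at(model: GrowthModel, t_h: float) -> float:
    """Embryo length [mm] at t hours after exposure start."""
    if t_h < 0:
        raise ValueError("t must be >= 0")
    return model.L0 + model.v * t_h


@dataclass(frozen=True)
class StructureMap:
    """Axial position rules for named structures in one experimental series.

    ``anchors`` rules give the offset from the embryo top at t=0 and at the
    final sampling time ``duration_h``, interpolated linearly; ``fraction``
    rules place the structure at a fixed fraction of the body length.
    """

    series: str
    duration_h: float
    rules: dict[str, dict] = field(default_factory=dict)

    def axial_offset(self, structure: str, model: GrowthModel, t_h: float) -> float:
        """Offset [mm] from the embryo top, clipped to the body length."""
        if structure not in self.rules:
            raise KeyError(f"unknown structure: {structure!r}")
        rule = self.rules[structure]
        L = length_at(model, t_h)
        if rule["rule"] == "fraction":
            off = rule["fraction"] * L
        else:
            a0, a1 = rule["offsets_mm"]
            off = a0 + (a1 - a0) * (t_h / self.duration_h)
        return min(off, L)

    @property
    def structures(self) -> list[str]:
        return list(self.rules)


def load_structure_map(series: str = "EA") -> StructureMap:
    raw = _load_data("structures.json")
    if series not in raw or series == "description":
        raise KeyError(f"unknown series: {series!r}")
    entry = raw[series]
    return StructureMap(
        series=series, duration_h=entry["duration_h"], rules=entry["structures"]
    )


def load_growth_model(series: str = "EA") -> GrowthModel:
    """Growth model for a series, with v derived from the printed lengths."""
    raw = _load_data("structures.json")
    entry = raw[series]
    v = growth_velocity(entry["L0_mm"], entry["Lf_mm"], entry["duration_h"])
    return GrowthModel(
        L0=entry["L0_mm"],
        v=v,
        t0=entry["t0_incubation_h"],
        sigma_L=entry["sigma_Lf_mm"],
    )


#: Placement classes of the agar block relative to the embryo axis.
CEPHALIC_CLASSES = ("A", "C", "D")
CAUDAL_CLASSES = ("B", "E", "F")


@dataclass(frozen=True)
class Placement:
    """Agar placement: class A (cephalic), B (caudal), C/D (lateral
    cephalic), E/F (lateral caudal); ``distance_mm`` from the reference
    structure (head for cephalic-side, tail for caudal-side classes) and a
    lateral offset for the lateral classes."""

    klass: str
    distance_mm: float
    lateral_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.klass not in CEPHALIC_CLASSES + CAUDAL_CLASSES:
            raise ValueError(f"unknown placement class: {self.klass!r}")
        if self.distance_mm <= 0:
            raise ValueError("distance must be positive")

    @property
    def cephalic(self) -> bool:
        return self.klass in CEPHALIC_CLASSES


def structure_position(
    smap: StructureMap,
    model: GrowthModel,
    placement: Placement,
    structure: str,
    t_h: float,
) -> ExposurePoint:
    """Locate a structure in the source frame at t hours after placement.

    Cephalic-side placements: x = distance + axial offset from the top, so
    the head keeps the printed distance and caudal structures recede as the
    body grows.  Caudal-side placements mirror the axis: x = distance +
    (length - offset), anchoring the tail.  Lateral classes add the
    placement's y offset.  Returned coordinates are cm, time seconds.
    """
    off = smap.axial_offset(structure, model, t_h)
    if placement.cephalic:
        x_mm = placement.distance_mm + off
    else:
        x_mm = placement.distance_mm + (length_at(model, t_h) - off)
    return ExposurePoint(
        x=mm_to_cm(x_mm), y=mm_to_cm(placement.lateral_mm), t=h_to_s(t_h)
    )
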