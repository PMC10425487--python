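"""Synthetic experiment generator emulating the egg-exposure study design.

Each experiment uses groups of 60 eggs; the agar block lands at a distance
of a few millimetres from the embryo, mostly (70%) near the cephalic or
caudal ends of the body axis, with the remainder on the four lateral
placements.  Control lengths follow the linear growth model with Gaussian
individual variability (sd set to the printed spreads, truncated at zero).

The drug response is deliberately simple plumbing for pipeline and
recovery testing, not a measured dose-response curve: once a structure's
exposure exceeds the LOEC, the growth velocity is multiplied by a factor
that is logistic in log10(exposure/LOEC) -- below 1 for the antagonist
atropine (which slowed development) and above 1 for the agonist carbachol
(which accelerated growth).  Only the direction and the LOEC gating mirror
the observations; the slope and saturation are artifact choices documented
in docs/methods.md.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .assessment import LOEC
from .kinematics import GrowthModel, Placement, length_at

__all__ = [
    "ExperimentDesign",
    "EggConfig",
    "SyntheticOutcome",
    "ResponseModel",
    "generate_experiment",
    "simulate_outcomes",
    "recover_growth",
    "write_synthetic_csv",
]

#: Placement probabilities: cephalic+caudal together 70%, lateral classes share the rest.
DEFAULT_PLACEMENT_PROBS = {
    "A": 0.35,
    "B": 0.35,
    "C": 0.075,
    "D": 0.075,
    "E": 0.075,
    "F": 0.075,
}


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one synthetic experiment (defaults are the study conditions)."""

    series: str = "EA"
    drug: str = "AT"
    placement_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLACEMENT_PROBS)
    )
    distance_range_mm: tuple[float, float] = (2.0, 10.0)
    lateral_range_mm: tuple[float, float] = (1.0, 3.0)
    n_eggs: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.placement_probs.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.placement_probs.values()):
            raise ValueError("placement probabilities must be non-negative and sum to 1")
        if self.n_eggs <= 0:
            raise ValueError("n_eggs must be positive")
        lo, hi = self.distance_range_mm
        if not (0 < lo <= hi):
            raise ValueError("distance range must be positive and ordered")


@dataclass(frozen=True)
class EggConfig:
    """One egg's realised configuration."""

    egg_id: int
    placement: Placement
    series: str
    drug: str


@dataclass(frozen=True)
class SyntheticOutcome:
    """Simulated endpoint for one egg: the measured final length and the
    exposure summary that produced it."""

    egg_id: int
    placement_class: str
    distance_mm: float
    time_h: float
    length_mm: float
    apparent_stage: str
    exposure_M: float
    exposed_above_loec: bool
    seed: int


@dataclass(frozen=True)
class ResponseModel:
    """Velocity multiplier, logistic in log10(exposure / LOEC) above the LOEC.

    factor(E) = 1 + (f_max - 1) / (1 + exp(-k * log10(E / LOEC)))  for E >= LOEC,
    and 1 below the LOEC.  f_max < 1 slows growth (atropine), > 1
    accelerates it (carbachol).
    """

    f_max: float
    k: float = 2.0
    loec: float = 1e-4

    def factor(self, exposure: float) -> float:
        if exposure < self.loec or exposure <= 0:
            return 1.0
        z = self.k * math.log10(exposure / self.loec)
        return 1.0 + (self.f_max - 1.0) / (1.0 + math.exp(-z))


#: Default response factors: direction only is observation-driven.
DEFAULT_RESPONSES = {
    "AT": ResponseModel(f_max=0.7, loec=LOEC["AT"]),
    "CCh": ResponseModel(f_max=1.25, loec=LOEC["CCh"]),
    "control": ResponseModel(f_max=1.0, loec=1.0),
}


def generate_experiment(
    design: ExperimentDesign, seed: Optional[int] = None
) -> list[EggConfig]:
    """Draw reproducible per-egg placements from the design distribution."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    classes = list(design.placement_probs)
    probs = [design.placement_probs[k] for k in classes]
    configs = []
    for i in range(design.n_eggs):
        klass = classes[int(rng.choice(len(classes), p=probs))]
        distance = float(rng.uniform(*design.distance_range_mm))
        lateral = 0.0
        if klass in ("C", "E"):
            lateral = -float(rng.uniform(*design.lateral_range_mm))
        elif klass in ("D", "F"):
            lateral = float(rng.uniform(*design.lateral_range_mm))
        configs.append(
            EggConfig(
                egg_id=i,
                placement=Placement(klass=klass, distance_mm=distance, lateral_mm=lateral),
                series=design.series,
                drug=design.drug,
            )
        )
    return configs


def simulate_outcomes(
    configs: Sequence[EggConfig],
    growth_model: GrowthModel,
    response_model: ResponseModel,
    seed: int,
    duration_h: float = 30.0,
    exposure_fn=None,
    stage_fn=None,
) -> list[SyntheticOutcome]:
    """Simulate final lengths under the exposure-gated velocity response.

    ``exposure_fn(config) -> M`` supplies the peak exposure of the growth-
    driving structure; the default is a 1D erfc evaluation at the placement
    distance and the final time with the drug's standard source.  Lengths
    are L0 + v_eff * T plus zero-mean Gaussian noise (sd = the growth
    model's spread), truncated at zero.
    """
    from .diffusion import conc_point_1d
    from .medium import Calibration, MediumProperties, agar_block
    from .units import h_to_s, mm_to_cm

    rng = np.random.default_rng(seed)
    if exposure_fn is None:
        medium = MediumProperties.isotropic()
        sources = {
            "AT": agar_block((2, 2, 3), 3.0, 1e-3, Calibration.DILUTED),
            "CCh": agar_block((2, 2, 3), 2.0, 0.1, Calibration.DILUTED),
            "control": agar_block((2, 2, 3), 3.0, 0.0),
        }

        def exposure_fn(cfg: EggConfig) -> float:
            src = sources.get(cfg.drug, sources["control"])
            r = math.hypot(
                mm_to_cm(cfg.placement.distance_mm),
                mm_to_cm(cfg.placement.lateral_mm),
            )
            return conc_point_1d(r, h_to_s(duration_h), medium, src.c0)

    outcomes = []
    for cfg in configs:
        exposure = float(exposure_fn(cfg))
        factor = response_model.factor(exposure)
        v_eff = growth_model.v * factor
        mean_len = growth_model.L0 + v_eff * duration_h
        length = max(0.0, float(rng.normal(mean_len, growth_model.sigma_L)))
        stage = stage_fn(length) if stage_fn is not None else ""
        outcomes.append(
            SyntheticOutcome(
                egg_id=cfg.egg_id,
                placement_class=cfg.placement.klass,
                distance_mm=cfg.placement.distance_mm,
                time_h=duration_h,
                length_mm=length,
                apparent_stage=stage,
                exposure_M=exposure,
                exposed_above_loec=exposure >= response_model.loec,
                seed=seed,
            )
        )
    return outcomes


def recover_growth(samples: Sequence[tuple[float, float]]) -> float:
    """Least-squares growth velocity [mm/h] from (time_h, length_mm) samples.

    Requires at least two distinct sampling times; with all lengths equal
    the slope is zero.
    """
    times = np.asarray([s[0] for s in samples], dtype=float)
    lengths = np.asarray([s[1] for s in samples], dtype=float)
    if len(np.unique(times)) < 2:
        raise ValueError("need at least two distinct sampling times")
    slope, _ = np.polyfit(times, lengths, 1)
    return float(slope)


def write_synthetic_csv(
    outcomes: Sequence[SyntheticOutcome],
    design: ExperimentDesign,
    csv_path,
    sidecar_path=None,
) -> pd.DataFrame:
    """One row per egg to CSV, with a JSON sidecar recording design and seed."""
    df = pd.DataFrame([o.__dict__ for o in outcomes])
    df.to_csv(csv_path, index=False)
    if sidecar_path is not None:
        meta = {
            "series": design.series,
            "drug": design.drug,
            "placement_probs": design.placement_probs,
            "distance_range_mm": list(design.distance_range_mm),
            "n_eggs": design.n_eggs,
            "seed": design.seed,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
    return df
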