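"""Recompute the study's headline quantities from scratch.

Everything here is derived at run time from the package's own machinery:
the growth velocities from the printed control lengths, the head exposure
under the documented calibration (diluted source concentration, axial
wide-lateral evaluation; see docs/methods.md), the LOEC crossing time, the
printed within-embryo concentration differentials, the finite-difference
verification of the analytic strip solution, the synthetic growth-velocity
recovery study, and the event-interference tallies.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

from .assessment import (
    LOEC,
    ThresholdSet,
    assess_experiment,
    load_event_table,
    structure_difference,
    time_to_threshold,
)
from .diffusion import conc_point_1d, conc_strip, uncertainty_band
from .kinematics import (
    Placement,
    growth_velocity,
    load_growth_model,
    load_structure_map,
)
from .medium import (
    Calibration,
    ExposurePoint,
    MediumProperties,
    agar_block,
    WATER_D_CM2_S,
    WATER_SIGMA_D_CM2_S,
)
from .oracle import FDGrid, compare_to_analytic, solve_fd
from .synthetic import recover_growth
from .units import h_to_s, mm_to_cm

__all__ = ["run_all"]

#: Documented calibration for reproducing the printed exposure values.
CALIBRATED = dict(calibration=Calibration.DILUTED, mode="axial")


def _head_exposure(medium: MediumProperties, x_mm: float, t_h: float):
    """Head-point exposure under the documented calibration, with D band."""
    source = agar_block((2, 2, 3), 3.0, 1e-3, CALIBRATED["calibration"])

    def ev(med: MediumProperties) -> float:
        return conc_point_1d(mm_to_cm(x_mm), h_to_s(t_h), med, source.c0)

    return uncertainty_band(ev, medium)


def _fd_check() -> float:
    """Max relative FD-vs-analytic error on the documented small configuration.

    Strip source (c0 = 2.5e-4 M volumetric, Ly = 1 mm), D = 6e-6 cm^2/s,
    domain truncated at five diffusion lengths, dx = dy = 0.01 cm, probes
    on and off axis at 0.5-2 h.
    """
    medium = MediumProperties.isotropic(WATER_D_CM2_S)
    source = agar_block((2, 2, 3), 3.0, 1e-3, Calibration.VOLUMETRIC)
    t_final = 7200.0
    L = 5.0 * math.sqrt(WATER_D_CM2_S * t_final)
    dx = dy = 0.01
    grid = FDGrid(
        nx=int(L / dx) + 1,
        ny=2 * int((source.Ly + L) / dy) + 1,
        dx=dx,
        dy=dy,
        dt=4.0,
    )
    history = solve_fd(medium, source, grid, [1800.0, 3600.0, 7200.0])
    probes = [(0.1, 0.0), (0.2, 0.0), (0.3, 0.05), (0.15, -0.05), (0.4, 0.0)]
    return compare_to_analytic(
        history, lambda p: conc_strip(p, medium, source), probes, source.c0
    )


def _wide_strip_limit_error() -> float:
    """Relative gap between the wide strip and the 1D closed form."""
    medium = MediumProperties.isotropic(WATER_D_CM2_S)
    t = 7200.0
    wide = agar_block((2, 2000.0, 3), 3.0, 1e-3)  # Ly = 1 m >> sqrt(D t)
    worst = 0.0
    for x_mm in (1.0, 2.0, 5.0):
        a = conc_strip(ExposurePoint(x=mm_to_cm(x_mm), t=t), medium, wide)
        b = conc_point_1d(mm_to_cm(x_mm), t, medium, wide.c0)
        worst = max(worst, abs(a - b) / b)
    return worst


def _recovery_study(seed: int, n_rep: int = 100, n_eggs: int = 60, noise_sd: float = 0.3):
    """Fraction of replicates recovering the growth velocity within 15%.

    Each replicate measures n_eggs control embryos split between the start
    and end of series EA (lengths with Gaussian noise, sd 0.3 mm) and fits
    the least-squares slope.
    """
    model = load_growth_model("EA")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_rep):
        samples = []
        for i in range(n_eggs):
            t = 0.0 if i % 2 == 0 else 30.0
            length = model.L0 + model.v * t + rng.normal(0.0, noise_sd)
            samples.append((t, length))
        v_hat = recover_growth(samples)
        if abs(v_hat - model.v) <= 0.15 * model.v:
            hits += 1
    return hits / n_rep


def _event_classification():
    """Classify the inductive events for the calibrated AT experiment and
    tally the expected interference flags per drug."""
    medium = MediumProperties.isotropic(WATER_D_CM2_S, WATER_SIGMA_D_CM2_S)
    source = agar_block((2, 2, 3), 3.0, 1e-3, CALIBRATED["calibration"])
    events = load_event_table()
    smap = load_structure_map("EA")
    model = load_growth_model("EA")
    placement = Placement(klass="A", distance_mm=2.0)
    report = assess_experiment(
        "AT",
        placement,
        source,
        medium,
        smap,
        model,
        events=events,
        mode=CALIBRATED["mode"],
    )
    table = report.events
    at_flags = sum(1 for r in events.rows if r["AT"] == "interferes")
    cch_flags = sum(1 for r in events.rows if r["CCh"] == "interferes")
    return report, table, at_flags, cch_flags


def run_all(seed: int = 0) -> dict:
    """Compute every headline quantity; returns {name: {"value", "n"}}."""
    results: dict[str, dict] = {}

    def put(name: str, value, n) -> None:
        results[name] = {"value": float(value), "n": int(n)}

    # growth velocities from the printed control lengths
    put("growth_velocity_ea_mm_per_h", growth_velocity(1.04, 5.0, 30.0), 2)
    put("growth_velocity_eb_mm_per_h", growth_velocity(1.5, 2.9, 9.0), 2)

    # head exposure at 2 mm under the documented calibration
    medium = MediumProperties.isotropic(WATER_D_CM2_S, WATER_SIGMA_D_CM2_S)
    lo2, mid2, hi2 = _head_exposure(medium, 2.0, 2.0)
    lo4, mid4, hi4 = _head_exposure(medium, 2.0, 4.0)
    put("at_head_conc_2mm_2h_M", mid2, 1)
    put("at_head_conc_2mm_2h_halfband_M", 0.5 * (hi2 - lo2), 3)
    put("at_head_conc_2mm_4h_M", mid4, 1)

    # time for the AT LOEC (1e-4 M) to reach a structure 2 mm away
    central = MediumProperties.isotropic(WATER_D_CM2_S)
    source = agar_block((2, 2, 3), 3.0, 1e-3, CALIBRATED["calibration"])

    def head_conc(t_h: float) -> float:
        return conc_point_1d(mm_to_cm(2.0), h_to_s(t_h), central, source.c0)

    times = np.arange(0.0, 30.0 + 1e-9, 0.1)
    from .assessment import ExposureSeries

    conc = np.array([head_conc(t) for t in times])
    series = ExposureSeries("head", times, conc, conc, conc)
    ttl = time_to_threshold(series, LOEC["AT"], head_conc)
    put("at_time_to_loec_2mm_h", ttl if ttl is not None else float("nan"), len(times))

    # printed within-embryo differentials from printed inputs
    put(
        "optic_vesicle_at_difference_M",
        structure_difference(1.0288e-5, 0.912e-5),
        2,
    )
    put("tail_head_cch_difference_M", structure_difference(1.08e-3, 4.48e-4), 2)
    put("left_right_cch_difference_M", structure_difference(1.17e-3, 9.65e-4), 2)

    # verification quantities
    put("fd_oracle_max_rel_error_pct", 100.0 * _fd_check(), 15)
    put("wide_strip_limit_max_rel_error", _wide_strip_limit_error(), 3)

    # synthetic growth-velocity recovery
    put(
        "growth_recovery_within_15pct_rate_pct",
        100.0 * _recovery_study(seed),
        100,
    )

    # event-interference tallies
    _, table, at_flags, cch_flags = _event_classification()
    put("at_interfering_event_count", at_flags, len(table))
    put("cch_interfering_event_count", cch_flags, len(table))
    put(
        "events_exposed_above_loec_count",
        int(table["exposed_above_loec"].sum()),
        len(table),
    )
    return results
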