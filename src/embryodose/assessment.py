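"""Exposure assessment: concentration histories at moving embryo structures,
LOEC threshold crossings, spatial differentials, and classification of the
inductive developmental events against expected drug interference.

The lowest-observed-effect concentrations are 1e-4 M for the muscarinic
antagonist atropine (AT) and 1e-3 M for the agonist carbachol (CCh); the
optic-vesicle analysis additionally suggests an eye-specific LOEC near
1.0288e-5 M, available as a per-structure override.

Two evaluator modes are exposed.  ``strip`` uses the full quasi-2D strip
solution with the physical lateral half-width of the agar face.  ``axial``
uses the 1D erfc solution in the Euclidean distance from the releasing
face, i.e. the wide-lateral limit; combined with the ``diluted`` source
calibration this is the convention that reproduces the printed
head-exposure values (see docs/methods.md).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .diffusion import conc_point_1d, conc_strip, uncertainty_band
from .kinematics import GrowthModel, Placement, StructureMap, structure_position
from .medium import (
    DEFAULT_QUADRATURE,
    ExposurePoint,
    MediumProperties,
    QuadratureSettings,
    SourceSpec,
)
from .units import h_to_s

__all__ = [
    "LOEC",
    "ExposureSeries",
    "ThresholdSet",
    "EventTable",
    "ExposureReport",
    "exposure_timeseries",
    "time_to_threshold",
    "structure_difference",
    "segment_average",
    "classify_events",
    "load_event_table",
    "assess_experiment",
]

#: Lowest observed effect concentrations [M] per drug.
LOEC = {"AT": 1e-4, "CCh": 1e-3}


@dataclass(frozen=True)
class ThresholdSet:
    """Drug LOECs with optional per-structure overrides, all molar."""

    loec: dict[str, float] = field(default_factory=lambda: dict(LOEC))
    overrides: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.loec.values()) or any(
            v <= 0 for v in self.overrides.values()
        ):
            raise ValueError("thresholds must be positive")

    def for_structure(self, drug: str, structure: str) -> float:
        return self.overrides.get((drug, structure), self.loec[drug])


@dataclass
class ExposureSeries:
    """Concentration history at a (possibly moving) structure.

    ``times_h`` are hours since agar placement; ``conc``/``lo``/``hi`` are
    molar, with the band from the diffusion-coefficient uncertainty.
    """

    structure: str
    times_h: np.ndarray
    conc: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.lo > self.conc) or np.any(self.conc > self.hi):
            raise ValueError("band must bracket the central value")

    @property
    def peak(self) -> float:
        return float(np.max(self.conc))


def _make_evaluator(
    medium: MediumProperties,
    source: SourceSpec,
    mode: str,
    quad_settings: QuadratureSettings,
) -> Callable[[ExposurePoint, MediumProperties], float]:
    if mode == "axial":

        def ev(pt: ExposurePoint, med: MediumProperties) -> float:
            r = math.hypot(pt.x, pt.y)
            return conc_point_1d(r, pt.t, med, source.c0) * source.release_fn(pt.t)

    elif mode == "strip":

        def ev(pt: ExposurePoint, med: MediumProperties) -> float:
            return conc_strip(pt, med, source, quad_settings)

    else:
        raise ValueError("mode must be 'strip' or 'axial'")
    return ev


def exposure_timeseries(
    structure: str,
    placement: Placement,
    source: SourceSpec,
    medium: MediumProperties,
    t_grid_h: Sequence[float],
    smap: StructureMap,
    model: GrowthModel,
    mode: str = "strip",
    quad_settings: QuadratureSettings = DEFAULT_QUADRATURE,
) -> ExposureSeries:
    """Concentration-vs-time at a named structure's moving position."""
    evaluator = _make_evaluator(medium, source, mode, quad_settings)
    times = np.asarray(sorted(t_grid_h), dtype=float)
    conc, lo, hi = [], [], []
    for t_h in times:
        pt = structure_position(smap, model, placement, structure, float(t_h))
        if medium.sigma_D > 0:
            lo_i, mid_i, hi_i = uncertainty_band(lambda m, _p=pt: evaluator(_p, m), medium)
        else:
            mid_i = evaluator(pt, medium)
            lo_i = hi_i = mid_i
        conc.append(mid_i)
        lo.append(lo_i)
        hi.append(hi_i)
    return ExposureSeries(
        structure=structure,
        times_h=times,
        conc=np.asarray(conc),
        lo=np.asarray(lo),
        hi=np.asarray(hi),
    )


def time_to_threshold(
    series: ExposureSeries,
    threshold: float,
    evaluator: Optional[Callable[[float], float]] = None,
    refine_to_h: float = 0.01,
) -> Optional[float]:
    """First time [h] the central concentration reaches the threshold.

    Returns the first grid time with conc >= threshold, refined by
    bisection on ``evaluator`` (a continuous map t_h -> conc) to 0.01 h
    when one is supplied; None if the threshold is never crossed.
    """
    if len(series.times_h) == 0:
        raise ValueError("series is empty")
    above = np.nonzero(series.conc >= threshold)[0]
    if len(above) == 0:
        return None
    k = int(above[0])
    t_hi = float(series.times_h[k])
    if evaluator is None or k == 0:
        return t_hi
    t_lo = float(series.times_h[k - 1])
    while t_hi - t_lo > refine_to_h:
        mid = 0.5 * (t_lo + t_hi)
        if evaluator(mid) >= threshold:
            t_hi = mid
        else:
            t_lo = mid
    return t_hi


def structure_difference(c_a: float, c_b: float) -> float:
    """Signed concentration difference c_a - c_b [M] between two structures."""
    if not (math.isfinite(c_a) and math.isfinite(c_b)):
        raise ValueError("concentrations must be finite")
    return c_a - c_b


def segment_average(
    evaluator: Callable[[ExposurePoint], float],
    p0: tuple[float, float],
    p1: tuple[float, float],
    t: float,
    n_samples: int = 11,
) -> float:
    """Mean concentration over equispaced points on a segment (cm endpoints).

    A zero-length segment degenerates to the point value; for a field
    linear along the segment the mean equals the midpoint value.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    (x0, y0), (x1, y1) = p0, p1
    if x0 == x1 and y0 == y1:
        return evaluator(ExposurePoint(x=x0, y=y0, t=t))
    fracs = np.linspace(0.0, 1.0, n_samples)
    vals = [
        evaluator(ExposurePoint(x=x0 + f * (x1 - x0), y=y0 + f * (y1 - y0), t=t))
        for f in fracs
    ]
    return float(np.mean(vals))


@dataclass(frozen=True)
class EventTable:
    """Inductive developmental events with exposure windows and the
    expected interference flag per drug ('interferes' or 'no')."""

    rows: tuple[dict, ...]
    window_halfwidth_h: float = 1.0

    def __post_init__(self) -> None:
        for row in self.rows:
            for drug in ("AT", "CCh"):
                if row[drug] not in ("interferes", "no"):
                    raise ValueError(f"bad flag {row[drug]!r} for {row['event']!r}")

    def window(self, row: dict) -> tuple[float, float]:
        """Exposure window [h]: the labelled span widened by the halfwidth,
        clipped at zero (point labels get a +-1 h window by default)."""
        lo = max(0.0, row["t_start_h"] - self.window_halfwidth_h)
        hi = row["t_end_h"] + self.window_halfwidth_h
        return (lo, hi)


def load_event_table() -> EventTable:
    with resources.files("embryodose.data").joinpath("events.json").open() as fh:
        raw = json.load(fh)
    return EventTable(
        rows=tuple(raw["events"]), window_halfwidth_h=raw["window_halfwidth_h"]
    )


@dataclass
class ExposureReport:
    """Assessment summary: per-structure threshold crossings and peaks,
    per-pair concentration differences at final time, and the per-event
    classification table."""

    drug: str
    series: dict[str, ExposureSeries]
    time_to_loec_h: dict[str, Optional[float]]
    peak_conc_M: dict[str, float]
    pair_differences_M: dict[str, float]
    events: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        out = {
            "drug": self.drug,
            "time_to_loec_h": self.time_to_loec_h,
            "peak_conc_M": self.peak_conc_M,
            "pair_differences_M": self.pair_differences_M,
        }
        if self.events is not None:
            out["events"] = self.events.to_dict(orient="records")
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)


def classify_events(
    report: "ExposureReport",
    events: EventTable,
    thresholds: ThresholdSet,
) -> pd.DataFrame:
    """Join modelled exposure onto the event table.

    For each event the structure's central concentration is compared with
    the drug LOEC over the event window; ``exposed_above_loec`` holds the
    model outcome, ``band_status`` flags 'uncertain' when the uncertainty
    band straddles the threshold, and ``expected_interference`` carries the
    observed interference flag for the report's drug.
    """
    drug = report.drug
    rows = []
    for row in events.rows:
        structure = row["structure"]
        if structure not in report.series:
            raise KeyError(f"no exposure series for structure {structure!r}")
        series = report.series[structure]
        lo_t, hi_t = events.window(row)
        if hi_t > series.times_h[-1] + 1e-9:
            raise ValueError(
                f"event window [{lo_t}, {hi_t}] h outside simulated range"
            )
        mask = (series.times_h >= lo_t) & (series.times_h <= hi_t)
        threshold = thresholds.for_structure(drug, structure)
        exposed = bool(np.any(series.conc[mask] >= threshold))
        if exposed:
            # certain only if the low band edge also clears the threshold
            certain = bool(np.any(series.lo[mask] >= threshold))
        else:
            certain = not bool(np.any(series.hi[mask] >= threshold))
        band_status = "certain" if certain else "uncertain"
        rows.append(
            {
                "label": row["label"],
                "event": row["event"],
                "structure": structure,
                "window_start_h": lo_t,
                "window_end_h": hi_t,
                "exposed_above_loec": exposed,
                "band_status": band_status,
                "expected_interference": row[drug],
            }
        )
    return pd.DataFrame(rows)


def assess_experiment(
    drug: str,
    placement: Placement,
    source: SourceSpec,
    medium: MediumProperties,
    smap: StructureMap,
    model: GrowthModel,
    t_grid_h: Optional[Sequence[float]] = None,
    structures: Optional[Sequence[str]] = None,
    thresholds: Optional[ThresholdSet] = None,
    events: Optional[EventTable] = None,
    mode: str = "strip",
    grid_res_h: float = 0.1,
) -> ExposureReport:
    """End-to-end assessment for one experiment configuration.

    Builds exposure series for every mapped structure on a 0.1 h grid over
    the series duration, computes time-to-LOEC and peaks, pairwise final
    differences, and (when an event table is supplied) the per-event
    classification.
    """
    if thresholds is None:
        thresholds = ThresholdSet()
    if structures is None:
        structures = smap.structures
    if t_grid_h is None:
        n = int(round(smap.duration_h / grid_res_h))
        t_grid_h = [i * grid_res_h for i in range(n + 1)]
    series: dict[str, ExposureSeries] = {}
    ttl: dict[str, Optional[float]] = {}
    peaks: dict[str, float] = {}
    evaluator = _make_evaluator(medium, source, mode, DEFAULT_QUADRATURE)
    for s in structures:
        es = exposure_timeseries(
            s, placement, source, medium, t_grid_h, smap, model, mode=mode
        )
        series[s] = es

        def cont(t_h: float, _s=s) -> float:
            pt = structure_position(smap, model, placement, _s, t_h)
            return evaluator(pt, medium)

        ttl[s] = time_to_threshold(es, thresholds.for_structure(drug, s), cont)
        peaks[s] = es.peak
    diffs: dict[str, float] = {}
    names = list(series)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            diffs[f"{a}-{b}"] = structure_difference(
                float(series[a].conc[-1]), float(series[b].conc[-1])
            )
    report = ExposureReport(
        drug=drug,
        series=series,
        time_to_loec_h=ttl,
        peak_conc_M=peaks,
        pair_differences_M=diffs,
    )
    if events is not None:
        report.events = classify_events(report, events, thresholds)
    return report
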