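"""Analytical solutions of the diffusion-decay equation for the agar source.

Three evaluators cover the geometries used in practice:

``conc_point_1d``
    Semi-infinite 1D Dirichlet problem with constant boundary value c0 and
    optional first-order decay; closed form in erfc.

``conc_strip``
    The quasi-2D picture: the releasing face is a strip of lateral
    half-width Ly held at c0*f(t) on the x=0 boundary of a semi-infinite
    x-domain with infinite lateral extent.  The solution is the Duhamel
    superposition

        c(x,y,t) = c0 x / (4 sqrt(pi Dx)) *
                   Integral_0^t f(t-tau) tau^(-3/2)
                   exp(-lam tau - x^2/(4 Dx tau))
                   [erfc((y-Ly)/(2 sqrt(Dy tau))) - erfc((y+Ly)/(2 sqrt(Dy tau)))] dtau

    evaluated by adaptive quadrature after the substitution
    u = x / (2 sqrt(Dx tau)), which removes the essential singularity at
    tau -> 0 (the integrand becomes exp(-u^2) times a bounded factor).
    In the wide-strip limit the lateral bracket tends to 2 and the formula
    collapses to the 1D closed form.

``conc_box``
    The general box source in an infinite domain: a volumetric generation
    rate r0*f(t) inside the box [0,x0]x[y1,y2]x[z1,z2] produces the
    erfc-product (Green's superposition) integral

        c = (r0/8) Integral_0^t f(t-tau) exp(-lam tau)
            [erfc((x-x0)/2 sqrt(Dx tau)) - erfc(x/2 sqrt(Dx tau))]
            [erfc((y-y2)/2 sqrt(Dy tau)) - erfc((y-y1)/2 sqrt(Dy tau))]
            [erfc((z-z2)/2 sqrt(Dz tau)) - erfc((z-z1)/2 sqrt(Dz tau))] dtau

All evaluators accept a raw medium and fold the retardation factor in at
entry, so (D, lam, R) and (D/R, lam/R, 1) give bitwise-identical results.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.special import erfc, erfcx

from .medium import (
    DEFAULT_QUADRATURE,
    DomainSpec,
    ExposurePoint,
    MediumProperties,
    QuadratureSettings,
    SourceSpec,
    make_effective_medium,
)
from .units import h_to_s, mm_to_cm, s_to_h

__all__ = [
    "conc_point_1d",
    "conc_strip",
    "conc_box",
    "uncertainty_band",
    "conc_profile",
]

_SQRT_PI = math.sqrt(math.pi)


def conc_point_1d(
    x: float, t: float, medium: MediumProperties, c0: float
) -> float:
    """Closed-form semi-infinite Dirichlet solution at distance x [cm], time t [s].

    For lam=0 this is c0*erfc(x / (2 sqrt(D t))); with decay it is the
    standard two-term erfc form.  The decayed branch is evaluated through
    erfcx to avoid overflow of exp(+x sqrt(lam/D)).
    """
    if x < 0:
        raise ValueError("x must be >= 0 for the semi-infinite solution")
    if t < 0:
        raise ValueError("t must be >= 0")
    medium = make_effective_medium(medium)
    if t == 0.0:
        return c0 if x == 0.0 else 0.0
    D, lam = medium.Dx, medium.lam
    arg = x / (2.0 * math.sqrt(D * t))
    if lam == 0.0:
        return c0 * erfc(arg)
    b = x * math.sqrt(lam / D)
    root_lt = math.sqrt(lam * t)
    term1 = math.exp(-b) * erfc(arg - root_lt)
    # exp(+b)*erfc(arg + root_lt) = erfcx(arg + root_lt)*exp(b - (arg+root_lt)^2)
    # and b - (arg + root_lt)^2 = -(x^2/(4 D t)) - lam t, always negative.
    term2 = erfcx(arg + root_lt) * math.exp(-(arg * arg) - lam * t)
    return 0.5 * c0 * (term1 + term2)


def _lateral_factor(y: float, Ly: float, Dy: float, tau: float) -> float:
    """Half the lateral erfc bracket: 1 inside a wide strip, -> 0 far outside.

    Evaluated at |y| so the symmetry of the kernel in y is exact in floating
    point, not just up to rounding.
    """
    s = 2.0 * math.sqrt(Dy * tau)
    y = abs(y)
    return 0.5 * (erfc((y - Ly) / s) - erfc((y + Ly) / s))


def conc_strip(
    point: ExposurePoint,
    medium: MediumProperties,
    source: SourceSpec,
    quad_settings: QuadratureSettings = DEFAULT_QUADRATURE,
    domain: Optional[DomainSpec] = None,
) -> float:
    """Strip-source concentration [M] at a space-time point.

    The integration variable is substituted as u = x/(2 sqrt(Dx tau));
    the essential singularity at tau -> 0 maps to u -> inf where the
    integrand is exp(-u^2)-small.  At x = 0 the boundary value
    c0 * f(t) * lateral-indicator is returned directly.
    """
    if domain is not None:
        domain.require_strip()
    if point.x < 0:
        raise ValueError("strip solution requires x >= 0")
    medium = make_effective_medium(medium)
    x, y, t = point.x, point.y, point.t
    c0, Ly, f = source.c0, source.Ly, source.release_fn
    if t == 0.0 or c0 == 0.0:
        return 0.0 if x > 0 or c0 == 0.0 else c0 * f(t)
    Dx, Dy, lam = medium.Dx, medium.Dy, medium.lam
    if x == 0.0:
        if abs(y) < Ly:
            return c0 * f(t)
        if abs(y) == Ly:
            return 0.5 * c0 * f(t)
        return 0.0

    tau_scale = x * x / (4.0 * Dx)  # tau(u) = tau_scale / u^2
    u_min = x / (2.0 * math.sqrt(Dx * t))

    def integrand(u: float) -> float:
        tau = tau_scale / (u * u)
        val = math.exp(-u * u - lam * tau) * _lateral_factor(y, Ly, Dy, tau)
        if f is not None:
            val *= f(t - tau)
        return val

    integral, _ = quad(
        integrand,
        u_min,
        math.inf,
        epsabs=quad_settings.abs_tol,
        epsrel=quad_settings.rel_tol,
        limit=quad_settings.max_subdivisions,
    )
    return (2.0 / _SQRT_PI) * c0 * integral


def conc_box(
    point: ExposurePoint,
    medium: MediumProperties,
    source: SourceSpec,
    domain: Optional[DomainSpec] = None,
    quad_settings: QuadratureSettings = DEFAULT_QUADRATURE,
    r0: Optional[float] = None,
) -> float:
    """Box-source concentration [M] in an infinite domain.

    ``r0`` is the volumetric generation rate [M s^-1] inside the box
    ``0 < x < x0, y1 < y < y2, z1 < z < z2``; by default it is read from
    ``source.c0`` interpreted as rate (callers doing physics with the box
    form normally pass r0 explicitly).
    """
    medium = make_effective_medium(medium)
    if r0 is None:
        r0 = source.c0
    x, y, z, t = point.x, point.y, point.z, point.t
    if t == 0.0 or r0 == 0.0:
        return 0.0
    Dx, Dy, Dz, lam = medium.Dx, medium.Dy, medium.Dz, medium.lam
    x0, y1, y2, z1, z2 = source.x0, source.y1, source.y2, source.z1, source.z2
    f = source.release_fn

    def bracket(c: float, lo: float, hi: float, D: float, tau: float) -> float:
        s = 2.0 * math.sqrt(D * tau)
        return erfc((c - hi) / s) - erfc((c - lo) / s)

    def integrand(tau: float) -> float:
        val = (
            math.exp(-lam * tau)
            * bracket(x, 0.0, x0, Dx, tau)
            * bracket(y, y1, y2, Dy, tau)
            * bracket(z, z1, z2, Dz, tau)
        )
        if f is not None:
            val *= f(t - tau)
        return val

    integral, _ = quad(
        integrand,
        0.0,
        t,
        epsabs=quad_settings.abs_tol,
        epsrel=quad_settings.rel_tol,
        limit=quad_settings.max_subdivisions,
    )
    return (r0 / 8.0) * integral


def uncertainty_band(
    evaluator: Callable[[MediumProperties], float],
    medium: MediumProperties,
) -> tuple[float, float, float]:
    """Propagate the diffusion-coefficient uncertainty by three-point evaluation.

    ``evaluator`` maps a medium to a concentration; it is called at
    D - sigma_D, D and D + sigma_D (all axes scaled together) and the band
    (lo, mid, hi) is the min/central/max of the three values, so the band
    is correct even where the response is not monotone in D.
    """
    if medium.sigma_D >= min(medium.Dx, medium.Dy, medium.Dz):
        raise ValueError("sigma_D must be smaller than the diffusion coefficient")
    mid = evaluator(medium)
    if medium.sigma_D == 0.0:
        return (mid, mid, mid)
    values = [mid]
    for sign in (-1.0, 1.0):
        shifted = MediumProperties(
            Dx=medium.Dx + sign * medium.sigma_D,
            Dy=medium.Dy + sign * medium.sigma_D,
            Dz=medium.Dz + sign * medium.sigma_D,
            sigma_D=0.0,
            lam=medium.lam,
            R=medium.R,
        )
        values.append(evaluator(shifted))
    return (min(values), mid, max(values))


def conc_profile(
    points_mm: Sequence[tuple[float, float]],
    times_h: Iterable[float],
    medium: MediumProperties,
    source: SourceSpec,
    quad_settings: QuadratureSettings = DEFAULT_QUADRATURE,
    with_band: bool = True,
    mode: str = "strip",
) -> pd.DataFrame:
    """Concentration-profile table over (time, point) pairs.

    ``points_mm`` are (x_mm, y_mm) probe positions in the source frame and
    ``times_h`` hours since agar placement; output columns are
    time_h, x_mm, y_mm, conc_M, conc_lo_M, conc_hi_M (one row per pair).
    ``mode`` selects the evaluator geometry: the full quasi-2D ``strip``
    kernel or the ``axial`` wide-lateral erfc form (1D in the Euclidean
    distance from the releasing face).
    """
    points_mm = list(points_mm)
    times_h = list(times_h)
    if not points_mm or not times_h:
        raise ValueError("points and times must be non-empty")
    if mode not in ("strip", "axial"):
        raise ValueError("mode must be 'strip' or 'axial'")
    rows = []
    for t_h in times_h:
        for x_mm, y_mm in points_mm:
            pt = ExposurePoint(x=mm_to_cm(x_mm), y=mm_to_cm(y_mm), t=h_to_s(t_h))

            def ev(m: MediumProperties, _pt=pt) -> float:
                if mode == "axial":
                    r = math.hypot(_pt.x, _pt.y)
                    return conc_point_1d(r, _pt.t, m, source.c0) * source.release_fn(_pt.t)
                return conc_strip(_pt, m, source, quad_settings)

            if with_band and medium.sigma_D > 0:
                lo, mid, hi = uncertainty_band(ev, medium)
            else:
                mid = ev(medium)
                lo = hi = mid
            rows.append(
                {
                    "time_h": t_h,
                    "x_mm": x_mm,
                    "y_mm": y_mm,
                    "conc_M": mid,
                    "conc_lo_M": lo,
                    "conc_hi_M": hi,
                }
            )
    return pd.DataFrame(rows)
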