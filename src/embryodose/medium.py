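"""Domain types for the diffusion-decay-sorption transport problem.

The physical picture: a small agar parallelepiped soaked with a drug sits on
the vitelline membrane above an early chick embryo.  The drug leaves the
releasing face and spreads through the thin aqueous layer of the germinal
chamber, treated as a quasi-2D domain (the vertical direction is well mixed
over the sub-membrane layer).  Transport obeys

    R dc/dt = Dx d2c/dx2 + Dy d2c/dy2 + Dz d2c/dz2 - lambda c

with first-order decay ``lambda`` and a retardation factor ``R`` folding in
linear, reversible, instantaneous sorption.  ``x`` points from the releasing
face toward the embryo, ``y`` is lateral with y=0 on the source centreline.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

from .units import cm3_to_liters, mm_to_cm, ul_to_cm3

__all__ = [
    "MediumProperties",
    "SourceSpec",
    "DomainSpec",
    "ExposurePoint",
    "QuadratureSettings",
    "Calibration",
    "make_effective_medium",
    "source_concentration",
    "agar_block",
    "WATER_D_CM2_S",
    "WATER_SIGMA_D_CM2_S",
]

#: Drug diffusion coefficient in water, cm^2/s, with its half-width uncertainty.
WATER_D_CM2_S = 6e-6
WATER_SIGMA_D_CM2_S = 3e-6


@dataclass(frozen=True)
class MediumProperties:
    """Transport properties of the aqueous layer.

    Parameters
    ----------
    Dx, Dy, Dz : float
        Diffusion coefficients along the longitudinal, lateral and vertical
        axes [cm^2 s^-1].  The germinal-chamber liquid is taken isotropic,
        so normally ``Dx == Dy == Dz``.
    sigma_D : float
        Half-width of the uncertainty band on the diffusion coefficient
        [cm^2 s^-1]; propagated by three-point evaluation.
    lam : float
        First-order decay constant lambda [s^-1].  Zero by default: neither
        drug is measurably degraded over the exposure times considered.
    R : float
        Retardation factor (dimensionless, >= 1) for linear reversible
        instantaneous sorption, e.g. binding to albumin proteins.
    """

    Dx: float = WATER_D_CM2_S
    Dy: float = WATER_D_CM2_S
    Dz: float = WATER_D_CM2_S
    sigma_D: float = 0.0
    lam: float = 0.0
    R: float = 1.0

    def __post_init__(self) -> None:
        if min(self.Dx, self.Dy, self.Dz) <= 0:
            raise ValueError("diffusion coefficients must be positive")
        if self.sigma_D < 0:
            raise ValueError("sigma_D must be >= 0")
        if self.lam < 0:
            raise ValueError("decay constant must be >= 0")
        if self.R < 1:
            raise ValueError("retardation factor must be >= 1")

    @classmethod
    def isotropic(
        cls,
        D: float = WATER_D_CM2_S,
        sigma_D: float = 0.0,
        lam: float = 0.0,
        R: float = 1.0,
    ) -> "MediumProperties":
        return cls(Dx=D, Dy=D, Dz=D, sigma_D=sigma_D, lam=lam, R=R)


def make_effective_medium(medium: MediumProperties) -> MediumProperties:
    """Fold the retardation factor into the transport coefficients.

    Dividing Dx, Dy, Dz and lambda by R removes R from the governing
    equation; every evaluator consumes the effective medium, so solutions
    for (D, lambda, R) and (D/R, lambda/R, 1) are identical by construction.
    """
    if medium.R == 1.0:
        return medium
    return replace(
        medium,
        Dx=medium.Dx / medium.R,
        Dy=medium.Dy / medium.R,
        Dz=medium.Dz / medium.R,
        sigma_D=medium.sigma_D / medium.R,
        lam=medium.lam / medium.R,
        R=1.0,
    )


class Calibration(str, enum.Enum):
    """Convention for the boundary concentration c0 of the agar source.

    volumetric
        Injected moles divided by the agar block volume (the stated rule:
        average volumetric concentration of the chemical inside the agar).
    diluted
        Injected moles divided by block volume plus soak volume, i.e. the
        soak liquid is counted as part of the releasing phase.
    soak
        The soak solution molarity used directly as boundary value.
    """

    VOLUMETRIC = "volumetric"
    DILUTED = "diluted"
    SOAK = "soak"


def source_concentration(
    soak_volume_cm3: float,
    soak_molarity: float,
    block_dims_cm: Sequence[float],
    calibration: Calibration = Calibration.VOLUMETRIC,
) -> float:
    """Boundary concentration c0 [M] of the soaked agar block.

    Injected moles are ``soak_molarity * soak_volume``; the default
    convention spreads them over the block volume.
    """
    block_volume_cm3 = 1.0
    for d in block_dims_cm:
        block_volume_cm3 *= d
    if block_volume_cm3 <= 0:
        raise ValueError("block volume must be positive")
    if soak_volume_cm3 < 0 or soak_molarity < 0:
        raise ValueError("soak volume and molarity must be >= 0")
    calibration = Calibration(calibration)
    if calibration is Calibration.SOAK:
        return soak_molarity
    moles = soak_molarity * cm3_to_liters(soak_volume_cm3)
    if calibration is Calibration.DILUTED:
        return moles / cm3_to_liters(block_volume_cm3 + soak_volume_cm3)
    return moles / cm3_to_liters(block_volume_cm3)


def _const_one(t: float) -> float:
    return 1.0


@dataclass(frozen=True)
class SourceSpec:
    """Geometry and strength of the releasing agar block.

    Half-dimensions ``Lx, Ly, Lz`` are in cm; for the strip (quasi-2D)
    solution only ``Ly`` matters -- the lateral half-width of the releasing
    face.  The general box form uses the extents ``x0, y1..z2``.  The
    release function ``f(t)`` is dimensionless in [0, 1]; the default
    constant 1 reflects that residual drug remains in the agar at the end
    of the experiments, so the boundary value stays at c0.
    """

    Lx: float = mm_to_cm(1.0)
    Ly: float = mm_to_cm(1.0)
    Lz: float = mm_to_cm(1.5)
    x0: float = 0.0
    y1: float = 0.0
    y2: float = 0.0
    z1: float = 0.0
    z2: float = 0.0
    soak_volume: float = 0.0  # cm^3
    soak_molarity: float = 0.0  # M
    c0: float = 0.0  # M
    release_fn: Callable[[float], float] = _const_one
    flux_fn: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise ValueError("c0 must be >= 0")
        box_used = self.x0 != 0 or self.y1 != self.y2 or self.z1 != self.z2
        if box_used and not (self.y1 < self.y2 and self.z1 < self.z2):
            raise ValueError("box extents require y1 < y2 and z1 < z2")


def agar_block(
    dims_mm: Sequence[float] = (2.0, 2.0, 3.0),
    soak_volume_ul: float = 3.0,
    soak_molarity: float = 1e-3,
    calibration: Calibration = Calibration.VOLUMETRIC,
    release_fn: Callable[[float], float] = _const_one,
) -> SourceSpec:
    """Build the experimental agar source from bench-side quantities.

    ``dims_mm`` is the full block (width across x, lateral extent, height);
    the lateral half-width Ly is half the second dimension.  The default
    (2 x 2 x 3 mm, 3 uL of 1 mM soak) is the standard preparation.
    """
    dims_cm = [mm_to_cm(d) for d in dims_mm]
    soak_cm3 = ul_to_cm3(soak_volume_ul)
    c0 = source_concentration(soak_cm3, soak_molarity, dims_cm, calibration)
    return SourceSpec(
        Lx=dims_cm[0] / 2.0,
        Ly=dims_cm[1] / 2.0,
        Lz=dims_cm[2] / 2.0,
        soak_volume=soak_cm3,
        soak_molarity=soak_molarity,
        c0=c0,
        release_fn=release_fn,
    )


@dataclass(frozen=True)
class DomainSpec:
    """Boundary layout: each axis is semi-infinite, infinite or finite.

    The strip solution requires a semi-infinite x-domain (releasing face at
    x=0) with infinite lateral extent; the box solution lives in an infinite
    domain.  Finite extents are used only by the finite-difference oracle.
    """

    x_kind: str = "semi-infinite"
    y_kind: str = "infinite"
    z_kind: str = "infinite"
    x_extent: Optional[float] = None
    y_extent: Optional[float] = None
    z_extent: Optional[float] = None

    _KINDS = ("semi-infinite", "infinite", "finite")

    def __post_init__(self) -> None:
        for kind in (self.x_kind, self.y_kind, self.z_kind):
            if kind not in self._KINDS:
                raise ValueError(f"unknown domain kind: {kind!r}")

    def require_strip(self) -> None:
        if self.x_kind != "semi-infinite" or self.y_kind != "infinite":
            raise ValueError(
                "strip solution requires a semi-infinite x-domain and infinite y-domain"
            )


@dataclass(frozen=True)
class ExposurePoint:
    """A space-time probe in the source frame: x from the releasing face
    (x >= 0 for the strip form), y lateral, z vertical, all cm; t seconds
    since agar placement."""

    x: float
    y: float = 0.0
    z: float = 0.0
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError("time must be >= 0")


@dataclass(frozen=True)
class QuadratureSettings:
    """Tolerances for the adaptive quadrature over the internal time variable."""

    rel_tol: float = 1e-9
    abs_tol: float = 1e-14
    max_subdivisions: int = 200

    def __post_init__(self) -> None:
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")


DEFAULT_QUADRATURE = QuadratureSettings()
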