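"""Finite-difference oracle for the diffusion-decay equation.

A deliberately plain explicit solver used only to verify the analytical
evaluators on small instances: 2D (x, y) for the quasi-2D strip problem and
a coarse 3D variant for the box source.  The infinite domain is truncated
at several diffusion lengths with zero-value far boundaries; comparisons
must probe well inside the truncation (the caller keeps probes at least two
diffusion lengths from the far edges).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .medium import (
    ExposurePoint,
    MediumProperties,
    SourceSpec,
    make_effective_medium,
)
from .units import cm_to_mm, s_to_h

__all__ = ["FDGrid", "FieldHistory", "solve_fd", "solve_fd_box", "compare_to_analytic"]


@dataclass(frozen=True)
class FDGrid:
    """Uniform 2D grid for the explicit scheme.

    x runs 0..(nx-1)*dx from the releasing boundary; y is centred on the
    source, spanning (-(ny-1)/2..+(ny-1)/2)*dy.  The stability bound for
    the explicit 5-point scheme, dt <= 1 / (2 D (1/dx^2 + 1/dy^2)), is
    checked against the medium before stepping.
    """

    nx: int
    ny: int
    dx: float
    dy: float
    dt: float

    def __post_init__(self) -> None:
        if self.nx < 3 or self.ny < 3:
            raise ValueError("grid must be at least 3x3")
        if min(self.dx, self.dy, self.dt) <= 0:
            raise ValueError("spacings and time step must be positive")

    @property
    def x(self) -> np.ndarray:
        return np.arange(self.nx) * self.dx

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.dy

    def stability_limit(self, medium: MediumProperties) -> float:
        medium = make_effective_medium(medium)
        return 1.0 / (2.0 * (medium.Dx / self.dx**2 + medium.Dy / self.dy**2))

    def check_stability(self, medium: MediumProperties) -> None:
        limit = self.stability_limit(medium)
        if self.dt > limit * (1.0 + 1e-12):
            raise ValueError(
                f"unstable explicit step: dt={self.dt:g} exceeds limit {limit:g}"
            )


@dataclass
class FieldHistory:
    """Concentration snapshots on a grid: ``fields[k]`` is c(x, y, times[k])."""

    grid: FDGrid
    times: list[float] = field(default_factory=list)
    fields: list[np.ndarray] = field(default_factory=list)

    def append(self, t: float, c: np.ndarray) -> None:
        self.times.append(t)
        self.fields.append(c.copy())

    def value_at(self, t: float, x: float, y: float) -> float:
        """Nearest-node sample of the stored field closest in time to t."""
        k = int(np.argmin(np.abs(np.asarray(self.times) - t)))
        ix = int(round(x / self.grid.dx))
        iy = int(round(y / self.grid.dy + (self.grid.ny - 1) / 2.0))
        if not (0 <= ix < self.grid.nx and 0 <= iy < self.grid.ny):
            raise ValueError("probe outside grid")
        return float(self.fields[k][ix, iy])

    def to_frame(self) -> pd.DataFrame:
        """Long-format dump (time_h, x_mm, y_mm, conc_M) for inspection."""
        rows = []
        xs, ys = self.grid.x, self.grid.y
        for t, f in zip(self.times, self.fields):
            xi, yi = np.meshgrid(np.arange(self.grid.nx), np.arange(self.grid.ny), indexing="ij")
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": s_to_h(t),
                        "x_mm": cm_to_mm(xs[xi.ravel()]),
                        "y_mm": cm_to_mm(ys[yi.ravel()]),
                        "conc_M": f.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def solve_fd(
    medium: MediumProperties,
    source: Optional[SourceSpec],
    grid: FDGrid,
    times: Sequence[float],
    init: Optional[np.ndarray] = None,
    far_bc: str = "dirichlet0",
) -> FieldHistory:
    """Explicit time-stepping of R dc/dt = D lap(c) - lam c on the 2D grid.

    If ``source`` is given, the x=0 edge carries the Dirichlet strip value
    c0*f(t) for |y| <= Ly and 0 elsewhere on that edge.  ``far_bc`` is
    either zero-value ("dirichlet0", truncation of the infinite domain) or
    zero-flux ("neumann0", a closed box for conservation checks).
    """
    medium = make_effective_medium(medium)
    grid.check_stability(medium)
    if far_bc not in ("dirichlet0", "neumann0"):
        raise ValueError("far_bc must be 'dirichlet0' or 'neumann0'")

    c = np.zeros((grid.nx, grid.ny)) if init is None else init.astype(float).copy()
    if c.shape != (grid.nx, grid.ny):
        raise ValueError("initial field shape does not match grid")

    # Strip weights on the x=0 edge: 1 strictly inside |y| < Ly, 1/2 on a node
    # sitting exactly at the strip edge (the analytic boundary half-value),
    # else the covered fraction of the half-cell straddling the edge.
    strip_weight = None
    if source is not None:
        cover = (source.Ly - (np.abs(grid.y) - grid.dy / 2.0)) / grid.dy
        strip_weight = np.clip(cover, 0.0, 1.0)

    times = sorted(float(t) for t in times)
    history = FieldHistory(grid=grid)
    Dx, Dy, lam = medium.Dx, medium.Dy, medium.lam
    ax, ay = Dx * grid.dt / grid.dx**2, Dy * grid.dt / grid.dy**2

    def apply_bc(c: np.ndarray, t: float) -> None:
        if far_bc == "dirichlet0":
            c[-1, :] = 0.0
            c[:, 0] = 0.0
            c[:, -1] = 0.0
            if source is None:
                c[0, :] = 0.0
        else:  # reflective edges via ghost-free copy
            c[-1, :] = c[-2, :]
            c[:, 0] = c[:, 1]
            c[:, -1] = c[:, -2]
            if source is None:
                c[0, :] = c[1, :]
        if source is not None:
            c[0, :] = source.c0 * source.release_fn(t) * strip_weight

    t = 0.0
    apply_bc(c, t)
    next_out = 0
    while next_out < len(times) and times[next_out] <= t + 1e-12:
        history.append(times[next_out], c)
        next_out += 1
    t_final = times[-1] if times else 0.0
    while t < t_final - 1e-12:
        dt = min(grid.dt, t_final - t)
        lap = np.zeros_like(c)
        lap[1:-1, 1:-1] = ax * (c[2:, 1:-1] - 2 * c[1:-1, 1:-1] + c[:-2, 1:-1]) + ay * (
            c[1:-1, 2:] - 2 * c[1:-1, 1:-1] + c[1:-1, :-2]
        )
        c[1:-1, 1:-1] += (dt / grid.dt) * lap[1:-1, 1:-1]
        c *= math.exp(-lam * dt)
        t += dt
        apply_bc(c, t)
        while next_out < len(times) and times[next_out] <= t + 1e-9:
            history.append(times[next_out], c)
            next_out += 1
    return history


def solve_fd_box(
    medium: MediumProperties,
    source: SourceSpec,
    r0: float,
    n: int,
    extent: float,
    dt: float,
    t_final: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Coarse 3D explicit solve for the box source in a truncated infinite domain.

    The cube [-extent, extent]^3 is discretised with n nodes per axis; the
    generation rate r0 [M/s] acts inside the box ``0<x<x0, y1<y<y2,
    z1<z<z2``.  Returns (axes, field at t_final).
    """
    medium = make_effective_medium(medium)
    ax = np.linspace(-extent, extent, n)
    h = ax[1] - ax[0]
    D = max(medium.Dx, medium.Dy, medium.Dz)
    if dt > h * h / (6.0 * D):
        raise ValueError("unstable 3D step")
    def cell_cover(lo: float, hi: float) -> np.ndarray:
        # fraction of each node's cell [x-h/2, x+h/2] covered by [lo, hi]
        left = np.maximum(ax - h / 2.0, lo)
        right = np.minimum(ax + h / 2.0, hi)
        return np.clip((right - left) / h, 0.0, 1.0)

    in_box = (
        cell_cover(0.0, source.x0)[:, None, None]
        * cell_cover(source.y1, source.y2)[None, :, None]
        * cell_cover(source.z1, source.z2)[None, None, :]
    )
    c = np.zeros((n, n, n))
    lam = medium.lam
    steps = int(math.ceil(t_final / dt))
    dt = t_final / steps
    k = medium.Dx * dt / (h * h)
    for _ in range(steps):
        lap = np.zeros_like(c)
        lap[1:-1, 1:-1, 1:-1] = (
            c[2:, 1:-1, 1:-1] + c[:-2, 1:-1, 1:-1]
            + c[1:-1, 2:, 1:-1] + c[1:-1, :-2, 1:-1]
            + c[1:-1, 1:-1, 2:] + c[1:-1, 1:-1, :-2]
            - 6.0 * c[1:-1, 1:-1, 1:-1]
        )
        c += k * lap
        c += dt * r0 * source.release_fn(0.0) * in_box
        c *= math.exp(-lam * dt)
        c[0, :, :] = c[-1, :, :] = 0.0
        c[:, 0, :] = c[:, -1, :] = 0.0
        c[:, :, 0] = c[:, :, -1] = 0.0
    return ax, c


def compare_to_analytic(
    history: FieldHistory,
    evaluator: Callable[[ExposurePoint], float],
    probes: Sequence[tuple[float, float]],
    c0: float,
    floor_frac: float = 1e-3,
) -> float:
    """Max relative deviation between the FD field and an analytic evaluator.

    The denominator is floored at ``floor_frac * c0`` so far-field noise
    does not blow up the ratio.  Probes are (x, y) in cm and must be
    interior to the grid.
    """
    floor = floor_frac * c0
    worst = 0.0
    for t in history.times:
        if t <= 0:
            continue
        for x, y in probes:
            c_fd = history.value_at(t, x, y)
            c_an = evaluator(ExposurePoint(x=x, y=y, t=t))
            err = abs(c_fd - c_an) / max(abs(c_an), floor)
            worst = max(worst, err)
    return worst
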