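"""Electric field of one periodic unit cell of an interdigitated electrode array.

The array is modelled in 2D cross-section (fingers are long compared with the
gap, so the field is translationally invariant along them).  One unit cell
spans a +V/4 finger, a gap, a −V/4 finger and a second gap, so the
peak-to-peak differential between neighbouring fingers equals the applied
V_pp.  The potential obeys Laplace's equation with Dirichlet values on the
electrode segments of the channel floor, an insulating (Neumann) top wall and
floor gaps, and periodic lateral boundaries.  Copper relief is folded into a
flat-boundary approximation (h ≪ gap).

The solve is a 5-point finite-difference discretization passed to a direct
sparse solver; the relative residual of the discrete system is checked after
the solve.  |E|² and ∇|E|² are then formed by central differences — these are
what the DEP force needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import InvalidGeometryError, OutOfDomainError, SolverError

__all__ = ["UnitCellGeometry", "FieldMap", "solve_unit_cell", "solve_parallel_plate", "field_at"]

_RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class UnitCellGeometry:
    """Geometry and drive of one electrode-array unit cell (all lengths m)."""

    electrode_width: float
    gap: float
    channel_height: float
    applied_v_pp: float
    copper_height: float = 35e-6

    def __post_init__(self) -> None:
        for name in ("electrode_width", "gap", "channel_height"):
            if getattr(self, name) <= 0.0:
                raise InvalidGeometryError(f"{name} must be > 0")
        if self.applied_v_pp < 0.0:
            raise InvalidGeometryError("applied_v_pp must be >= 0")

    @property
    def period(self) -> float:
        """Lateral period 2·(width + gap) of the electrode pattern."""
        return 2.0 * (self.electrode_width + self.gap)

    @property
    def edge_positions(self) -> tuple[float, ...]:
        """x-coordinates of the four finger edges within one period."""
        w, g = self.electrode_width, self.gap
        return (0.0, w, w + g, 2.0 * w + g)


@dataclass(frozen=True)
class FieldMap:
    """Discretized potential, |E|² and ∇|E|² on the unit-cell grid.

    Arrays are indexed ``[iy, ix]``; ``x`` is periodic with period
    ``period``.  ``e_sq`` is in V²/m², the gradient components in V²/m³.
    """

    x: np.ndarray
    y: np.ndarray
    phi: np.ndarray
    e_sq: np.ndarray
    ge_x: np.ndarray
    ge_y: np.ndarray
    period: float
    geometry: UnitCellGeometry | None = None

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    def scaled(self, v_pp_new: float) -> "FieldMap":
        """Rescale to a different drive voltage using field linearity.

        Laplace's equation is linear, so φ ∝ V, |E|² ∝ V² and ∇|E|² ∝ V²;
        one solve serves every voltage.
        """
        if self.geometry is None or self.geometry.applied_v_pp == 0.0:
            raise ValueError("cannot rescale a map without a nonzero reference voltage")
        s = v_pp_new / self.geometry.applied_v_pp
        geom = UnitCellGeometry(
            electrode_width=self.geometry.electrode_width,
            gap=self.geometry.gap,
            channel_height=self.geometry.channel_height,
            applied_v_pp=v_pp_new,
            copper_height=self.geometry.copper_height,
        )
        return FieldMap(
            x=self.x,
            y=self.y,
            phi=self.phi * s,
            e_sq=self.e_sq * s * s,
            ge_x=self.ge_x * s * s,
            ge_y=self.ge_y * s * s,
            period=self.period,
            geometry=geom,
        )

    def to_dataframe(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame(
            {
                "x_m": xx.ravel(),
                "y_m": yy.ravel(),
                "phi_v": self.phi.ravel(),
                "e_sq": self.e_sq.ravel(),
                "ge_x": self.ge_x.ravel(),
                "ge_y": self.ge_y.ravel(),
            }
        )


def _solve_laplace_periodic(
    nx: int,
    ny: int,
    dx: float,
    dy: float,
    dirichlet: np.ndarray,
    dirichlet_values: np.ndarray,
) -> np.ndarray:
    """Solve ∇²φ = 0 on an nx×ny grid, periodic in x, Neumann in y except
    where ``dirichlet`` marks fixed-potential nodes.

    Returns φ as an (ny, nx) array.  The discrete residual is verified after
    the direct solve.
    """
    n = nx * ny
    idx = lambda iy, ix: iy * nx + (ix % nx)  # noqa: E731 - tight local helper

    rows, cols, vals = [], [], []
    b = np.zeros(n)
    # rows scaled by dx^2 so coefficients are O(1) and the residual check is meaningful
    cx, cy = 1.0, (dx / dy) ** 2

    for iy in range(ny):
        for ix in range(nx):
            i = idx(iy, ix)
            if dirichlet[iy, ix]:
                rows.append(i)
                cols.append(i)
                vals.append(1.0)
                b[i] = dirichlet_values[iy, ix]
                continue
            # x-direction: always periodic
            rows += [i, i, i]
            cols += [idx(iy, ix - 1), idx(iy, ix + 1), i]
            vals += [cx, cx, -2.0 * cx]
            # y-direction: Neumann ghost reflection at the walls
            if iy == 0:
                rows += [i, i]
                cols += [idx(1, ix), i]
                vals += [2.0 * cy, -2.0 * cy]
            elif iy == ny - 1:
                rows += [i, i]
                cols += [idx(ny - 2, ix), i]
                vals += [2.0 * cy, -2.0 * cy]
            else:
                rows += [i, i, i]
                cols += [idx(iy - 1, ix), idx(iy + 1, ix), i]
                vals += [cy, cy, -2.0 * cy]

    a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    phi = spla.spsolve(a, b)
    scale = max(np.abs(b).max(), 1.0)
    residual = float(np.abs(a @ phi - b).max() / scale)
    if residual > _RESIDUAL_TOL:
        raise SolverError(
            f"Laplace solve residual {residual:.2e} exceeds {_RESIDUAL_TOL:.0e}",
            residual=residual,
        )
    return phi.reshape(ny, nx)


def _differentiate(phi: np.ndarray, dx: float, dy: float, period_x: bool = True):
    """E = −∇φ with periodic x (central differences) and one-sided y at walls."""
    if period_x:
        ex = -(np.roll(phi, -1, axis=1) - np.roll(phi, 1, axis=1)) / (2.0 * dx)
    else:
        ex = -np.gradient(phi, dx, axis=1)
    ey = -np.gradient(phi, dy, axis=0)
    return ex, ey


def _build_field_map(
    x: np.ndarray,
    y: np.ndarray,
    phi: np.ndarray,
    period: float,
    geometry: UnitCellGeometry | None,
) -> FieldMap:
    dx = float(x[1] - x[0])
    dy = float(y[1] - y[0])
    ex, ey = _differentiate(phi, dx, dy)
    e_sq = ex * ex + ey * ey
    gx = (np.roll(e_sq, -1, axis=1) - np.roll(e_sq, 1, axis=1)) / (2.0 * dx)
    gy = np.gradient(e_sq, dy, axis=0)
    return FieldMap(x=x, y=y, phi=phi, e_sq=e_sq, ge_x=gx, ge_y=gy, period=period, geometry=geometry)


def solve_unit_cell(geom: UnitCellGeometry, resolution: int = 128) -> FieldMap:
    """Solve the unit-cell field at ``resolution`` nodes per lateral period.

    Electrodes sit on the floor at ±V_pp/4 (differential amplitude V_pp/2,
    i.e. peak-to-peak V_pp between neighbouring fingers).
    """
    if resolution < 32:
        raise InvalidGeometryError("resolution must be >= 32 nodes per period")
    period = geom.period
    nx = int(resolution)
    dx = period / nx
    ny = max(int(round(geom.channel_height / dx)) + 1, 8)
    dy = geom.channel_height / (ny - 1)
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy

    v_amp = geom.applied_v_pp / 4.0
    w, g = geom.electrode_width, geom.gap
    tol = 1e-9
    on_a = x <= w + tol
    on_b = (x >= w + g - tol) & (x <= 2.0 * w + g + tol)
    dirichlet = np.zeros((ny, nx), dtype=bool)
    values = np.zeros((ny, nx))
    dirichlet[0, on_a] = True
    values[0, on_a] = +v_amp
    dirichlet[0, on_b] = True
    values[0, on_b] = -v_amp

    phi = _solve_laplace_periodic(nx, ny, dx, dy, dirichlet, values)
    return _build_field_map(x, y, phi, period, geom)


def solve_parallel_plate(voltage: float, plate_gap: float, resolution: int = 128) -> FieldMap:
    """Degenerate configuration: full-width floor electrode at ``voltage``,
    grounded plate at height ``plate_gap``.  The analytic interior field is
    uniform, |E| = V/gap — the solver's sanity oracle.
    """
    if plate_gap <= 0.0:
        raise InvalidGeometryError("plate_gap must be > 0")
    nx = int(resolution)
    ny = int(resolution)
    dx = plate_gap / nx  # lateral extent chosen equal to the gap; field is x-invariant
    dy = plate_gap / (ny - 1)
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    dirichlet = np.zeros((ny, nx), dtype=bool)
    values = np.zeros((ny, nx))
    dirichlet[0, :] = True
    values[0, :] = voltage
    dirichlet[-1, :] = True
    values[-1, :] = 0.0
    phi = _solve_laplace_periodic(nx, ny, dx, dy, dirichlet, values)
    return _build_field_map(x, y, phi, plate_gap, None)


def field_at(fmap: FieldMap, x: float, y: float) -> tuple[float, np.ndarray]:
    """Bilinearly interpolated (|E|², ∇|E|²) at a point; x wraps periodically.

    Exact at grid nodes.  Raises :class:`OutOfDomainError` if y lies outside
    the channel.
    """
    y0, y1 = float(fmap.y[0]), float(fmap.y[-1])
    if not (y0 <= y <= y1):
        raise OutOfDomainError(f"y = {y:g} outside channel [{y0:g}, {y1:g}]")
    nx = fmap.x.size
    dx, dy = fmap.dx, fmap.dy
    xw = x % fmap.period
    fx = xw / dx
    ix = int(np.floor(fx))
    tx = fx - ix
    ix0, ix1 = ix % nx, (ix + 1) % nx
    fy = (y - y0) / dy
    iy = min(int(np.floor(fy)), fmap.y.size - 2)
    ty = fy - iy

    def interp(a: np.ndarray) -> float:
        return float(
            a[iy, ix0] * (1 - tx) * (1 - ty)
            + a[iy, ix1] * tx * (1 - ty)
            + a[iy + 1, ix0] * (1 - tx) * ty
            + a[iy + 1, ix1] * tx * ty
        )

    e_sq = interp(fmap.e_sq)
    grad = np.array([interp(fmap.ge_x), interp(fmap.ge_y)])
    return e_sq, grad
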