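"""Overdamped particle transport: DEP versus centrifugal force on a spinning disc.

Micron-scale particles in water are firmly in the Stokes regime (Re ≪ 1,
particle response time ≪ µs), so inertia is dropped and the velocity is the
instantaneous force balance

    v = F_net / (6πµr),      F_net = F_DEP + F_centrifugal,

with the centrifugal body force (4/3)πr³(ρ_p − ρ_m)·ω²R taken as constant
along the unit cell's lateral axis (electrode fingers perpendicular to the
disc radius).  The DEP force is time-averaged — at MHz drive the AC period is
many orders below the transport timescale.  Trajectories are integrated with
explicit Euler (fixed or speed-adaptive step) over the periodic unit cell and
classified as trapped (held at an electrode edge), washed (swept beyond a
cumulative drift bound) or undecided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dep import clausius_mossotti
from .errors import InvalidGeometryError, SolverError
from .field import FieldMap, field_at
from .materials import Suspension

__all__ = [
    "SpinCondition",
    "TrajectoryResult",
    "TrappingMap",
    "net_force",
    "simulate_trajectory",
    "trapping_map",
    "minimum_holding_voltage",
]

#: Trapped when slower than this (m/s) within the capture radius of an edge.
SPEED_THRESHOLD = 1.0e-7
#: Capture radius around an electrode edge, in lateral grid cells.
CAPTURE_RADIUS_CELLS = 1.5
#: Washed once the cumulative lateral drift exceeds this many unit-cell periods.
WASH_PERIODS = 5.0
#: Confinement window: trapped if net displacement over this many consecutive
#: in-capture steps stays below a quarter grid cell (regularises the speed
#: criterion at the singular edge attractor, where the discrete field keeps
#: the pointwise speed finite).
CONFINE_STEPS = 20


@dataclass(frozen=True)
class SpinCondition:
    """Disc rotation: speed in RPM and the electrode region's radius from the axis."""

    rpm: float
    radial_position: float = 25e-3

    def __post_init__(self) -> None:
        if self.rpm < 0.0:
            raise InvalidGeometryError("rpm must be >= 0")
        if self.radial_position <= 0.0:
            raise InvalidGeometryError("radial_position must be > 0")

    @property
    def omega(self) -> float:
        """Angular speed, rad/s."""
        return self.rpm * 2.0 * math.pi / 60.0

    @property
    def centripetal_acceleration(self) -> float:
        """ω²R, m/s²."""
        return self.omega**2 * self.radial_position


@dataclass(frozen=True)
class TrajectoryResult:
    """A single particle path and its trap/wash classification."""

    times: np.ndarray
    positions: np.ndarray  # (n, 2): wrapped x, y
    outcome: str  # 'trapped' | 'washed' | 'undecided'
    final_speed: float
    drift: float  # cumulative (unwrapped) lateral displacement, m


@dataclass(frozen=True)
class TrappingMap:
    """Outcomes of trajectories launched from a lattice of start positions."""

    starts: np.ndarray  # (n, 2)
    outcomes: list[str]
    fraction_trapped: float


def terminal_drift_speed(suspension: Suspension, spin: SpinCondition) -> float:
    """Closed-form centrifugal terminal speed (2/9)·(ρ_p−ρ_m)·ω²R·r²/µ.

    The Stokes balance of the constant body force against drag; the field-free
    trajectory oracle.
    """
    r = suspension.particle.radius
    return (
        2.0
        / 9.0
        * (suspension.density_particle - suspension.density_medium)
        * spin.centripetal_acceleration
        * r**2
        / suspension.viscosity
    )


def _dep_prefactor(suspension: Suspension, f: float) -> float:
    """2πr³ε_m·Re[K(f)] — multiplies ∇|E|² to give the DEP force."""
    re_k = clausius_mossotti(suspension.particle, suspension.medium, f).real
    return 2.0 * math.pi * suspension.particle.radius**3 * suspension.medium.epsilon * re_k


def centrifugal_force(suspension: Suspension, spin: SpinCondition) -> float:
    """Constant lateral body force (4/3)πr³(ρ_p−ρ_m)·ω²R, N (along +x)."""
    return suspension.buoyant_mass_factor * spin.centripetal_acceleration


def net_force(
    suspension: Suspension,
    f: float,
    fmap: FieldMap,
    spin: SpinCondition,
    position,
) -> np.ndarray:
    """DEP + centrifugal force (N) at a position in the unit cell."""
    x, y = position
    _, grad = field_at(fmap, x, y)
    force = _dep_prefactor(suspension, f) * grad
    force[0] += centrifugal_force(suspension, spin)
    return force


def _edge_distance(fmap: FieldMap, x: float, y: float) -> float:
    """Distance to the nearest electrode edge (at the floor), periodic in x."""
    geom = fmap.geometry
    edges = geom.edge_positions if geom is not None else (0.0,)
    p = fmap.period
    best = math.inf
    for xe in edges:
        d = abs((x - xe + 0.5 * p) % p - 0.5 * p)
        best = min(best, math.hypot(d, y))
    return best


def simulate_trajectory(
    suspension: Suspension,
    f: float,
    fmap: FieldMap,
    spin: SpinCondition,
    start,
    dt: float | None = None,
    t_max: float = 120.0,
    speed_threshold: float = SPEED_THRESHOLD,
    capture_radius_cells: float = CAPTURE_RADIUS_CELLS,
    wash_periods: float = WASH_PERIODS,
    max_steps: int = 500_000,
    record_every: int = 20,
) -> TrajectoryResult:
    """Integrate one particle until trapped, washed, or t_max.

    ``fmap`` must already be scaled to the electrode drive voltage (see
    :meth:`FieldMap.scaled`).  With ``dt=None`` the step adapts so each move
    is about a fifth of a grid cell; a fixed ``dt`` is honoured but halved
    and retried if a step would jump more than 10 grid cells.
    """
    if dt is not None and dt <= 0.0:
        raise InvalidGeometryError("dt must be > 0")
    drag = suspension.drag_coefficient
    pre = _dep_prefactor(suspension, f)
    f_cent = centrifugal_force(suspension, spin)
    dx = fmap.dx
    height = float(fmap.y[-1])
    capture_r = capture_radius_cells * dx
    wash_bound = wash_periods * fmap.period
    dt_cap = dt if dt is not None else max(t_max / 200.0, 1e-6)

    x, y = float(start[0]) % fmap.period, float(start[1])
    if not (0.0 <= y <= height):
        from .errors import OutOfDomainError

        raise OutOfDomainError(f"start y = {y:g} outside channel [0, {height:g}]")

    t = 0.0
    drift = 0.0
    confined = 0
    confine_anchor = (x, y)
    times = [0.0]
    path = [(x, y)]
    outcome = "undecided"
    speed = 0.0

    step = 0
    while t < t_max and step < max_steps:
        step += 1
        _, grad = field_at(fmap, x, y)
        vx = (pre * grad[0] + f_cent) / drag
        vy = pre * grad[1] / drag
        speed = math.hypot(vx, vy)

        in_capture = _edge_distance(fmap, x, y) < capture_r
        if in_capture and speed < speed_threshold:
            outcome = "trapped"
            break
        if in_capture:
            # confinement check at the singular edge attractor
            d_anchor = math.hypot(
                (x - confine_anchor[0] + 0.5 * fmap.period) % fmap.period - 0.5 * fmap.period,
                y - confine_anchor[1],
            )
            if d_anchor < 0.25 * dx:
                confined += 1
                if confined >= CONFINE_STEPS:
                    outcome = "trapped"
                    break
            else:
                confined = 0
                confine_anchor = (x, y)
        else:
            confined = 0
            confine_anchor = (x, y)

        if speed == 0.0:
            h = dt_cap
        elif dt is None:
            h = min(0.2 * dx / speed, dt_cap)
        else:
            h = dt
            halvings = 0
            while speed * h > 10.0 * dx and halvings < 40:
                h *= 0.5
                halvings += 1
            if speed * h > 10.0 * dx:
                raise SolverError("step instability: position jump exceeds 10 grid cells")
        h = min(h, t_max - t)
        if h <= 0.0:
            break

        x = (x + vx * h) % fmap.period
        y = min(max(y + vy * h, 0.0), height)
        drift += vx * h
        t += h
        if step % record_every == 0:
            times.append(t)
            path.append((x, y))

        if abs(drift) > wash_bound:
            outcome = "washed"
            break

    times.append(t)
    path.append((x, y))
    return TrajectoryResult(
        times=np.asarray(times),
        positions=np.asarray(path),
        outcome=outcome,
        final_speed=speed,
        drift=drift,
    )


def trapping_map(
    suspension: Suspension,
    f: float,
    fmap: FieldMap,
    spin: SpinCondition,
    n_starts: int = 16,
    start_height_fraction: tuple[float, float] = (0.2, 0.8),
    **sim_kwargs,
) -> TrappingMap:
    """Classify a lattice of start positions as trapped or washed.

    Starts form an approximately square lattice over one period laterally and
    the given height band vertically.
    """
    if n_starts < 4:
        raise InvalidGeometryError("need n_starts >= 4")
    height = float(fmap.y[-1])
    n_x = max(int(math.ceil(math.sqrt(n_starts))), 2)
    n_y = int(math.ceil(n_starts / n_x))
    xs = (np.arange(n_x) + 0.5) / n_x * fmap.period
    lo, hi = start_height_fraction
    ys = np.linspace(lo * height, hi * height, n_y)
    starts = np.array([(x0, y0) for y0 in ys for x0 in xs])[:n_starts]

    outcomes = [
        simulate_trajectory(suspension, f, fmap, spin, s, **sim_kwargs).outcome for s in starts
    ]
    frac = sum(o == "trapped" for o in outcomes) / len(outcomes)
    return TrappingMap(starts=starts, outcomes=outcomes, fraction_trapped=frac)


def minimum_holding_voltage(
    suspension: Suspension,
    f: float,
    fmap_ref: FieldMap,
    spin: SpinCondition,
    start=None,
    v_cap: float = 200.0,
    rtol: float = 0.02,
    v_atol: float = 1e-3,
    **sim_kwargs,
) -> float:
    """Smallest electrode Vpp that traps a reference trajectory, by bisection.

    Exploits the V² scaling of |E|² — the reference field map is solved once
    and rescaled per candidate voltage.  Returns ``inf`` if even ``v_cap``
    does not trap (e.g. a negative-DEP particle over edge-maxima geometry).
    """
    geom = fmap_ref.geometry
    if geom is None:
        raise InvalidGeometryError("reference field map must carry its geometry")
    if start is None:
        # just off the downstream edge of the positive finger, near the floor
        start = (geom.electrode_width + 0.3 * geom.gap, 0.15 * float(fmap_ref.y[-1]))

    def trapped(v_pp: float) -> bool:
        if v_pp <= 0.0:
            fmap = fmap_ref.scaled(1e-30) if geom.applied_v_pp else fmap_ref
        else:
            fmap = fmap_ref.scaled(v_pp)
        res = simulate_trajectory(suspension, f, fmap, spin, start, **sim_kwargs)
        return res.outcome == "trapped"

    if not trapped(v_cap):
        return math.inf
    lo, hi = 0.0, v_cap
    while (hi - lo) > max(rtol * hi, v_atol):
        mid = 0.5 * (lo + hi)
        if trapped(mid):
            hi = mid
        else:
            lo = mid
    return hi
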