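"""The two-programme toggle-switch dynamical system.

Two antagonistic transcriptional programmes — immunogenic activity ``I``
and tolerogenic activity ``T`` — each auto-amplify through a sigmoidal
Hill response, repress the opposing programme through a repressive Hill
term, and decay at a constant rate::

    dI/dt = a·Iⁿ/(θⁿ + Iⁿ) + b·θⁿ/(θⁿ + Tⁿ) − k·I
    dT/dt = a·Tⁿ/(θⁿ + Tⁿ) + b·θⁿ/(θⁿ + Iⁿ) − k·T

With the default parameters (a = b = k = 1, n = 4, θ = 0.5) the landscape
is tri-stable: a high-I/low-T attractor (label ``A_immunogenic``), its
mirror image (``B_tolerogenic``), and a balanced attractor on the
diagonal (``C_ambivalent``).  On the diagonal I = T the two Hill terms
sum to one, so the dynamics reduce exactly to dx/dt = 1 − x and the
balanced attractor sits at (1, 1).

Fixed points are located by multi-start Newton iteration with the
analytic Jacobian and classified by Jacobian eigenvalues.  Trajectories
are integrated with an adaptive Dormand–Prince Runge–Kutta scheme
(``scipy.integrate.solve_ivp``, method ``RK45``) until the velocity norm
drops below ``conv_tol`` or ``t_max`` is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "ToggleParams",
    "StatePoint",
    "FixedPoint",
    "Trajectory",
    "FATE_LABELS",
    "UNCONVERGED",
    "velocity_field",
    "jacobian",
    "find_fixed_points",
    "stable_attractors",
    "integrate_trajectory",
    "integrate_ensemble",
    "assign_attractor",
    "classify_starting_points",
    "basin_map",
]

#: Fate names keyed by attractor label.
FATE_LABELS = {
    "A_immunogenic": "immunogenic",
    "B_tolerogenic": "tolerogenic",
    "C_ambivalent": "ambivalent",
}
UNCONVERGED = "unconverged"

_DEDUP_TOL = 1e-6
_ROOT_TOL = 1e-9
_EIG_TOL = 1e-8


@dataclass(frozen=True)
class ToggleParams:
    """Constants of the toggle switch and its numerical treatment.

    Attributes
    ----------
    a, b, k
        Auto-amplification strength, cross-inhibition strength and linear
        decay rate (all unitless rates; defaults 1).
    n
        Hill coefficient (sigmoid steepness; default 4).
    theta
        Hill threshold θ at which each response is half-maximal
        (default 0.5).
    x_max
        Upper bound of the phase-portrait window per axis.  At saturation
        a programme approaches (a + b) / k = 2, so the default 2.2
        contains every attractor.
    t_max
        Maximum integration time per trajectory (time units).
    conv_tol
        Velocity-norm threshold below which a trajectory is converged.
    attract_eps
        Radius around a stable fixed point within which a terminal state
        is assigned to that attractor.
    """

    a: float = 1.0
    b: float = 1.0
    k: float = 1.0
    n: int = 4
    theta: float = 0.5
    x_max: float = 2.2
    t_max: float = 100.0
    conv_tol: float = 1e-6
    attract_eps: float = 0.05

    def __post_init__(self) -> None:
        for name in ("a", "b", "k", "theta", "x_max", "t_max", "conv_tol", "attract_eps"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ToggleParams.{name} must be positive")
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError("ToggleParams.n must be an integer >= 1")

    def with_(self, **kwargs) -> "ToggleParams":
        return replace(self, **kwargs)


class StatePoint(NamedTuple):
    """A point in programme space: immunogenic and tolerogenic levels."""

    I: float
    T: float


@dataclass(frozen=True)
class FixedPoint:
    """An equilibrium of the system with its linear stability."""

    location: StatePoint
    stability: str  # stable | saddle | unstable
    eigenvalues: tuple[float, float]
    label: str | None = None  # A_immunogenic / B_tolerogenic / C_ambivalent


@dataclass(frozen=True)
class Trajectory:
    """A time-ordered path through programme space."""

    times: np.ndarray
    states: np.ndarray  # (n_steps, 2)
    converged: bool

    @property
    def terminal(self) -> StatePoint:
        return StatePoint(*self.states[-1])


def _field(I, T, p: ToggleParams):
    tn = p.theta**p.n
    In, Tn = I**p.n, T**p.n
    dI = p.a * In / (tn + In) + p.b * tn / (tn + Tn) - p.k * I
    dT = p.a * Tn / (tn + Tn) + p.b * tn / (tn + In) - p.k * T
    return dI, dT


def velocity_field(state, params: ToggleParams | None = None):
    """Time derivatives (dI/dt, dT/dt) at ``state`` (scalar or arrays).

    ``state`` is a pair ``(I, T)``; both components may be arrays of equal
    shape.  Components must be non-negative.
    """
    params = params or ToggleParams()
    I = np.asarray(state[0], dtype=float)
    T = np.asarray(state[1], dtype=float)
    if np.any(I < 0) or np.any(T < 0):
        raise ValueError("programme levels must be non-negative")
    dI, dT = _field(I, T, params)
    if I.ndim == 0:
        return float(dI), float(dT)
    return dI, dT


def jacobian(state, params: ToggleParams | None = None) -> np.ndarray:
    """Analytic 2×2 Jacobian of the vector field at ``state``."""
    p = params or ToggleParams()
    I, T = float(state[0]), float(state[1])
    tn = p.theta**p.n
    # d/dx [x^n/(tn+x^n)] = n·tn·x^(n-1)/(tn+x^n)^2 ; repressor is its negative
    d_act_I = p.n * tn * I ** (p.n - 1) / (tn + I**p.n) ** 2
    d_act_T = p.n * tn * T ** (p.n - 1) / (tn + T**p.n) ** 2
    return np.array(
        [
            [p.a * d_act_I - p.k, -p.b * d_act_T],
            [-p.b * d_act_I, p.a * d_act_T - p.k],
        ]
    )


def _classify_eigs(eigs: np.ndarray) -> str:
    real = np.sort(np.real(eigs))
    if real[-1] < -_EIG_TOL:
        return "stable"
    if real[0] < -_EIG_TOL < _EIG_TOL < real[-1]:
        return "saddle"
    return "unstable"


def find_fixed_points(
    params: ToggleParams | None = None,
    seed_grid_resolution: int = 25,
) -> list[FixedPoint]:
    """Locate and classify all fixed points on ``[0, x_max]²``.

    Newton iterations are started from a ``seed_grid_resolution``² lattice
    of seeds; converged roots are deduplicated within 1e-6 and classified
    by the sign pattern of the Jacobian eigenvalue real parts.  Stable
    points are labelled ``A_immunogenic`` (I > T), ``B_tolerogenic``
    (T > I) or ``C_ambivalent`` (|I − T| < 1e-6).  Parameter sets that are
    not tri-stable simply return fewer stable points.
    """
    p = params or ToggleParams()
    if seed_grid_resolution < 10:
        raise ValueError("seed_grid_resolution must be at least 10")

    def fun(x):
        I, T = np.maximum(x, 0.0)
        dI, dT = _field(I, T, p)
        return [dI, dT]

    def jac(x):
        return jacobian(np.maximum(x, 0.0), p)

    axis = np.linspace(0.0, p.x_max, seed_grid_resolution)
    roots: list[np.ndarray] = []
    for i_seed in axis:
        for t_seed in axis:
            sol = root(fun, [i_seed, t_seed], jac=jac, method="hybr")
            if not sol.success:
                continue
            x = np.maximum(sol.x, 0.0)
            if np.linalg.norm(fun(x)) > _ROOT_TOL:
                continue
            if np.any(x < -_DEDUP_TOL) or np.any(x > 2 * p.x_max):
                continue
            if not any(np.linalg.norm(x - r) < _DEDUP_TOL for r in roots):
                roots.append(x)

    points: list[FixedPoint] = []
    for x in sorted(roots, key=lambda r: (round(r[0], 9), round(r[1], 9))):
        eigs = np.linalg.eigvals(jacobian(x, p))
        stability = _classify_eigs(eigs)
        label = None
        if stability == "stable":
            if abs(x[0] - x[1]) < _DEDUP_TOL:
                label = "C_ambivalent"
            elif x[0] > x[1]:
                label = "A_immunogenic"
            else:
                label = "B_tolerogenic"
        points.append(
            FixedPoint(
                location=StatePoint(float(x[0]), float(x[1])),
                stability=stability,
                eigenvalues=(complex(eigs[0]).real, complex(eigs[1]).real),
                label=label,
            )
        )
    return points


def stable_attractors(fixed_points: Iterable[FixedPoint]) -> list[FixedPoint]:
    """The stable, labelled fixed points from ``find_fixed_points`` output."""
    return [fp for fp in fixed_points if fp.stability == "stable"]


def _rhs(n_cells: int, p: ToggleParams):
    def rhs(t, y):
        y = np.maximum(y, 0.0)  # the flow is forward-invariant on the quadrant
        I, T = y[:n_cells], y[n_cells:]
        dI, dT = _field(I, T, p)
        return np.concatenate([np.atleast_1d(dI), np.atleast_1d(dT)])

    return rhs


def _speed_event(n_cells: int, p: ToggleParams):
    def event(t, y):
        yc = np.maximum(y, 0.0)
        I, T = yc[:n_cells], yc[n_cells:]
        dI, dT = _field(I, T, p)
        speed = np.sqrt(np.atleast_1d(dI) ** 2 + np.atleast_1d(dT) ** 2)
        # stop at half the tolerance so terminal speeds sit strictly below it
        return float(speed.max() - 0.5 * p.conv_tol)

    event.terminal = True
    event.direction = -1.0
    return event


def integrate_trajectory(start, params: ToggleParams | None = None) -> Trajectory:
    """Integrate one trajectory from ``start`` until convergence or ``t_max``.

    Convergence means the velocity norm fell below ``conv_tol``.  States
    are clipped to the non-negative quadrant (the exact flow never leaves
    it, so clipping only removes solver round-off).
    """
    p = params or ToggleParams()
    start = np.asarray(start, dtype=float)
    if start.shape != (2,):
        raise ValueError("start must be a single (I, T) point")
    if np.any(start < 0):
        raise ValueError("start must be non-negative")
    speed0 = float(np.linalg.norm(_field(start[0], start[1], p)))
    if speed0 < p.conv_tol:
        times = np.array([0.0])
        return Trajectory(times=times, states=start[None, :].copy(), converged=True)
    sol = solve_ivp(
        _rhs(1, p),
        (0.0, p.t_max),
        start,
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
        events=_speed_event(1, p),
    )
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    states = np.maximum(sol.y.T, 0.0)
    if not np.all(np.isfinite(states)):
        raise RuntimeError("trajectory produced non-finite states")
    terminal_speed = float(np.linalg.norm(_field(states[-1, 0], states[-1, 1], p)))
    return Trajectory(times=sol.t, states=states, converged=terminal_speed < p.conv_tol)


def integrate_ensemble(
    starts: np.ndarray,
    params: ToggleParams | None = None,
    t_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate many trajectories at once; return (terminals, converged).

    The field acts element-wise across cells, so the whole population is
    integrated as one stacked ODE system — identical results to per-cell
    integration, at a fraction of the cost.  Integration stops when every
    trajectory's velocity norm is below ``conv_tol`` (or at ``t_max``);
    the per-cell converged flag is evaluated at the terminal states.
    """
    p = params or ToggleParams()
    starts = np.asarray(starts, dtype=float)
    if starts.ndim != 2 or starts.shape[1] != 2:
        raise ValueError("starts must have shape (n_cells, 2)")
    if np.any(starts < 0):
        raise ValueError("starts must be non-negative")
    n = starts.shape[0]
    horizon = p.t_max if t_max is None else float(t_max)
    y0 = np.concatenate([starts[:, 0], starts[:, 1]])
    event = _speed_event(n, p)
    if event(0.0, y0) < 0:  # already everywhere below tolerance
        return starts.copy(), np.ones(n, dtype=bool)
    sol = solve_ivp(
        _rhs(n, p),
        (0.0, horizon),
        y0,
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
        events=event,
    )
    if not sol.success:
        raise RuntimeError(f"ensemble integration failed: {sol.message}")
    yT = np.maximum(sol.y[:, -1], 0.0)
    terminals = np.column_stack([yT[:n], yT[n:]])
    dI, dT = _field(terminals[:, 0], terminals[:, 1], p)
    converged = np.hypot(dI, dT) < p.conv_tol
    return terminals, converged


def assign_attractor(
    terminal,
    attractors: Sequence[FixedPoint],
    attract_eps: float,
) -> str:
    """Fate label of the nearest attractor within ``attract_eps``.

    Returns ``"unconverged"`` when no stable attractor lies within the
    radius.  ``attractors`` must be non-empty stable fixed points.
    """
    if not attractors:
        raise ValueError("attractor set is empty")
    point = np.asarray(terminal, dtype=float)
    locations = np.array([fp.location for fp in attractors])
    distances = np.linalg.norm(locations - point, axis=1)
    best = int(np.argmin(distances))
    if distances[best] >= attract_eps:
        return UNCONVERGED
    return FATE_LABELS[attractors[best].label]


def classify_starting_points(
    starts: np.ndarray,
    params: ToggleParams | None = None,
    attractors: Sequence[FixedPoint] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate ``starts`` to their attractors; return (labels, terminals).

    Trajectories not settled within ``attract_eps`` of a stable attractor
    after ``t_max`` are continued for another 10 × ``t_max`` (this also
    resolves starts that crawl along a separatrix) and labelled
    ``"unconverged"`` if still unresolved.
    """
    p = params or ToggleParams()
    if attractors is None:
        attractors = stable_attractors(find_fixed_points(p))
    if not attractors:
        raise ValueError("the parameter set has no stable attractor")
    starts = np.asarray(starts, dtype=float)
    terminals, _ = integrate_ensemble(starts, p)
    labels = np.array(
        [assign_attractor(t, attractors, p.attract_eps) for t in terminals], dtype=object
    )
    pending = labels == UNCONVERGED
    if pending.any():
        extra, _ = integrate_ensemble(terminals[pending], p, t_max=10 * p.t_max)
        terminals[pending] = extra
        labels[pending] = [assign_attractor(t, attractors, p.attract_eps) for t in extra]
    return labels, terminals


def basin_map(
    params: ToggleParams | None = None,
    grid_resolution: int = 41,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force basin-of-attraction map on a regular lattice.

    Every point of a ``grid_resolution``² lattice on ``[0, x_max]²`` is
    integrated to its attractor.  Returns ``(axis, labels)`` where
    ``labels[i, j]`` is the fate of the start ``(axis[i], axis[j])``.
    """
    p = params or ToggleParams()
    axis = np.linspace(0.0, p.x_max, grid_resolution)
    grid_I, grid_T = np.meshgrid(axis, axis, indexing="ij")
    starts = np.column_stack([grid_I.ravel(), grid_T.ravel()])
    labels, _ = classify_starting_points(starts, p)
    return axis, labels.reshape(grid_resolution, grid_resolution)
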