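"""Core dynamical system: heterogeneous Gompertz growth under angiogenic signaling.

The tumor is split into a chemotherapy-sensitive compartment ``N1`` and a
fully resistant compartment ``N2`` (volumes, mm^3).  Both grow Gompertzian
against a shared, dynamic carrying capacity ``K`` that tracks the tumor
vasculature.  ``K`` is stimulated by the tumor, inhibited through an
area-to-volume interaction (the ``d (N1+N2)^{2/3} K`` term), and killed by
both the cytotoxic drug (dose ``u``, fraction of MTD) and the
anti-angiogenic agent (dose ``v``).  Mutation shuttles cells between the
two compartments at constant per-cell rates ``tau1`` (to resistance) and
``tau2`` (back).  Cell kill follows the log-kill hypothesis and acts on the
sensitive compartment only.

Units are fixed package-wide: volumes in mm^3, time in days, drug doses as
dimensionless fractions of the maximum tolerated dose (MTD) in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "ModelParams",
    "TumorState",
    "DoseSchedule",
    "Trajectory",
    "SteadyStateReport",
    "NOMINAL_PARAMS",
    "NOMINAL_INITIAL",
    "rhs",
    "rhs_jacobian",
    "simulate",
    "doubling_time_numeric",
    "doubling_time_formula",
    "find_steady_state",
]

#: Floor below which a simulated state is considered to have left the
#: positive orthant (the Gompertz logarithm is undefined at zero volume).
POSITIVITY_FLOOR = 1e-12


@dataclass(frozen=True)
class ModelParams:
    """Rate constants of the resistance-structured angiogenesis model.

    Defaults are the nominal values used throughout the package: Hahnfeldt-type
    vascular kinetics (``mu``, ``b``, ``d``) with a 0.192/day sensitive-cell
    proliferation rate, a resistant compartment proliferating at half that
    rate, and slow mutation (2e-5 and 1e-5 per day).

    Parameters
    ----------
    lambda1, lambda2 : float
        Proliferation rates of sensitive / resistant cells (1/day).
    tau1, tau2 : float
        Mutation rates sensitive->resistant and resistant->sensitive (1/day).
    mu : float
        Spontaneous endothelial (vascular) loss rate (1/day).
    b : float
        Vascular stimulation rate by tumor cells (1/day).
    d : float
        Vascular inhibition rate by tumor cells (1/(day * mm^2)).
    beta1 : float
        Log-kill sensitivity of sensitive cells to chemotherapy (1/(day * MTD)).
    beta : float
        Sensitivity of the vasculature to chemotherapy (1/(day * MTD)).
    gamma : float
        Sensitivity of the vasculature to the anti-angiogenic agent
        (1/(day * MTD)).
    """

    lambda1: float = 0.192
    lambda2: float = 0.096
    tau1: float = 2.0e-5
    tau2: float = 1.0e-5
    mu: float = 0.0
    b: float = 5.85
    d: float = 8.73e-3
    beta1: float = 0.3
    beta: float = 0.1
    gamma: float = 2.0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "tau1", "tau2", "mu", "b", "d",
                     "beta1", "beta", "gamma"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValueError(f"parameter {name!r} must be finite and >= 0, got {value}")
        if self.lambda1 <= 0:
            raise ValueError("lambda1 must be > 0")
        if self.d <= 0:
            raise ValueError("d must be > 0")
        if self.b <= self.mu:
            raise ValueError(
                "b must exceed mu for a positive untreated saturating volume"
            )

    def replace(self, **changes: float) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    def as_vector(self) -> np.ndarray:
        """Pack into the flat layout used by the numerical kernels."""
        return np.array(
            [self.lambda1, self.lambda2, self.tau1, self.tau2, self.mu,
             self.b, self.d, self.beta1, self.beta, self.gamma]
        )


@dataclass(frozen=True)
class TumorState:
    """State triple (N1, N2, K): sensitive, resistant, carrying capacity (mm^3)."""

    n1: float
    n2: float
    k: float

    def __post_init__(self) -> None:
        if not (self.n1 > 0 and self.n2 > 0 and self.k > 0):
            raise ValueError(
                f"TumorState must be strictly positive, got ({self.n1}, {self.n2}, {self.k})"
            )

    @property
    def total(self) -> float:
        """Total tumor volume N = N1 + N2."""
        return self.n1 + self.n2

    @property
    def resistant_fraction(self) -> float:
        return self.n2 / self.total

    def as_array(self) -> np.ndarray:
        return np.array([self.n1, self.n2, self.k])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "TumorState":
        return cls(float(x[0]), float(x[1]), float(x[2]))


NOMINAL_PARAMS = ModelParams()
#: Initial condition used by most published experiments: a 300 mm^3 tumor
#: (280 sensitive + 20 resistant) with a 650 mm^3 vasculature.
NOMINAL_INITIAL = TumorState(280.0, 20.0, 650.0)


@dataclass(frozen=True)
class DoseSchedule:
    """Chemotherapy control on a horizon, plus a constant anti-angiogenic dose.

    ``u`` is either a scalar (constant dosing) or a vector of piecewise-constant
    values on a uniform grid of ``len(u)`` intervals covering ``[0, horizon]``.
    Controls are applied left-continuously: ``u[k]`` acts on
    ``[k*h, (k+1)*h)`` with ``h = horizon / len(u)``.
    """

    u: float | np.ndarray
    v: float = 0.0
    horizon: float = 14.0

    def __post_init__(self) -> None:
        u = np.atleast_1d(np.asarray(self.u, dtype=float))
        if u.ndim != 1 or u.size == 0:
            raise ValueError("u must be a scalar or a 1-d array")
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("chemotherapy dose u must lie in [0, 1]")
        if not 0 <= self.v <= 1:
            raise ValueError("anti-angiogenic dose v must lie in [0, 1]")
        if not self.horizon > 0:
            raise ValueError("horizon must be positive")
        object.__setattr__(self, "u", u)

    @property
    def n_intervals(self) -> int:
        return int(np.size(self.u))

    @property
    def breakpoints(self) -> np.ndarray:
        """Grid times 0 = t_0 < ... < t_M = horizon delimiting the intervals."""
        return np.linspace(0.0, self.horizon, self.n_intervals + 1)

    def u_at(self, t: float) -> float:
        """Dose in effect at time ``t`` (left-continuous)."""
        h = self.horizon / self.n_intervals
        k = min(int(t / h), self.n_intervals - 1)
        return float(np.asarray(self.u)[k])

    @classmethod
    def constant(cls, u: float, v: float = 0.0, horizon: float = 14.0) -> "DoseSchedule":
        return cls(u=u, v=v, horizon=horizon)


@dataclass
class Trajectory:
    """A simulated path: states and applied controls on a time grid."""

    times: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    k: np.ndarray
    u: np.ndarray
    v: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        for name in ("n1", "n2", "k", "u"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.times.size
        if not all(getattr(self, f).size == n for f in ("n1", "n2", "k", "u")):
            raise ValueError("times, states and controls must have equal length")
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def total(self) -> np.ndarray:
        return self.n1 + self.n2

    @property
    def final_state(self) -> TumorState:
        return TumorState(float(self.n1[-1]), float(self.n2[-1]), float(self.k[-1]))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.times, "N1": self.n1, "N2": self.n2, "K": self.k,
             "u": self.u, "v": np.full(self.times.size, self.v)}
        )


@dataclass(frozen=True)
class SteadyStateReport:
    """Numerical equilibrium of the controlled system with local stability info."""

    state: TumorState
    residual_norm: float
    eigenvalues: np.ndarray
    stable: bool


def rhs(state: TumorState | Sequence[float], u: float, v: float,
        params: ModelParams) -> np.ndarray:
    """Right-hand side (dN1/dt, dN2/dt, dK/dt) in mm^3/day.

    Raises ``ValueError`` if any component of the state is non-positive
    (the Gompertz logarithm is then undefined).
    """
    x = state.as_array() if isinstance(state, TumorState) else np.asarray(state, float)
    n1, n2, k = x
    if not (n1 > 0 and n2 > 0 and k > 0):
        raise ValueError(f"rhs requires a strictly positive state, got {x}")
    p = params
    n = n1 + n2
    log_ratio = math.log(n / k)
    dn1 = -p.lambda1 * n1 * log_ratio - p.tau1 * n1 + p.tau2 * n2 - p.beta1 * n1 * u
    dn2 = -p.lambda2 * n2 * log_ratio + p.tau1 * n1 - p.tau2 * n2
    dk = (-p.mu * k + p.b * n - p.d * n ** (2.0 / 3.0) * k
          - p.beta * k * u - p.gamma * k * v)
    return np.array([dn1, dn2, dk])


def rhs_jacobian(state: TumorState | Sequence[float], u: float, v: float,
                 params: ModelParams) -> np.ndarray:
    """Analytic Jacobian of :func:`rhs` with respect to the state."""
    x = state.as_array() if isinstance(state, TumorState) else np.asarray(state, float)
    n1, n2, k = x
    p = params
    n = n1 + n2
    log_ratio = math.log(n / k)
    dvdn = (2.0 / 3.0) * p.d * n ** (-1.0 / 3.0) * k
    return np.array([
        [-p.lambda1 * log_ratio - p.lambda1 * n1 / n - p.tau1 - p.beta1 * u,
         -p.lambda1 * n1 / n + p.tau2,
         p.lambda1 * n1 / k],
        [-p.lambda2 * n2 / n + p.tau1,
         -p.lambda2 * log_ratio - p.lambda2 * n2 / n - p.tau2,
         p.lambda2 * n2 / k],
        [p.b - dvdn,
         p.b - dvdn,
         -p.mu - p.d * n ** (2.0 / 3.0) - p.beta * u - p.gamma * v],
    ])


def _ode(t: float, x: np.ndarray, u: float, v: float, params: ModelParams) -> list:
    # fast path for the integrator; infinite rates on a non-positive trial
    # state force the adaptive controller to reject and shrink the step
    n1, n2, k = x
    if n1 <= 0 or n2 <= 0 or k <= 0:
        return [math.inf, math.inf, math.inf]
    p = params
    n = n1 + n2
    log_ratio = math.log(n / k)
    return [
        -p.lambda1 * n1 * log_ratio - p.tau1 * n1 + p.tau2 * n2 - p.beta1 * n1 * u,
        -p.lambda2 * n2 * log_ratio + p.tau1 * n1 - p.tau2 * n2,
        -p.mu * k + p.b * n - p.d * n ** (2.0 / 3.0) * k - p.beta * k * u
        - p.gamma * k * v,
    ]


class IntegrationError(RuntimeError):
    """Raised when the adaptive integrator fails or positivity is lost."""


def _check_positive(y: np.ndarray, context: str) -> None:
    if np.any(y <= POSITIVITY_FLOOR):
        raise IntegrationError(
            f"state left the positive orthant during {context}: min component "
            f"{y.min():.3e} <= {POSITIVITY_FLOOR:.0e}"
        )


def simulate(params: ModelParams, initial: TumorState, schedule: DoseSchedule,
             t_span: tuple[float, float] | None = None, rel_tol: float = 1e-6,
             abs_tol: float = 1e-8, t_eval: np.ndarray | None = None,
             events: Callable | None = None) -> Trajectory:
    """Integrate the model with adaptive RK45 under a dose schedule.

    Piecewise-constant controls are applied left-continuously and the
    integrator is restarted at every control breakpoint, so bang-bang inputs
    are handled exactly.  A zero-length ``t_span`` returns a single-point
    trajectory equal to the initial state.

    Parameters
    ----------
    t_span
        Interval to integrate over; defaults to ``(0, schedule.horizon)``.
    events
        Optional terminal event ``g(t, x)`` (sign change detected); used
        internally for first-passage problems.  If the event fires the
        trajectory ends at the event time.
    """
    if t_span is None:
        t_span = (0.0, schedule.horizon)
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 < t0:
        raise ValueError("t_span must be non-decreasing")
    x0 = initial.as_array()
    if t1 == t0:
        return Trajectory(np.array([t0]), np.array([x0[0]]), np.array([x0[1]]),
                          np.array([x0[2]]), np.array([schedule.u_at(t0)]),
                          schedule.v)

    breaks = schedule.breakpoints
    cut = np.unique(np.concatenate([[t0, t1], breaks[(breaks > t0) & (breaks < t1)]]))
    times: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    x = x0.copy()
    terminated = False
    for a, b_end in zip(cut[:-1], cut[1:]):
        u_seg = schedule.u_at(a)
        kwargs = {}
        if t_eval is not None:
            mask = (t_eval >= a) & (t_eval <= b_end)
            kwargs["t_eval"] = np.unique(np.concatenate([[a], t_eval[mask], [b_end]]))
        sol = solve_ivp(_ode, (a, b_end), x, args=(u_seg, schedule.v, params),
                        method="RK45", rtol=rel_tol, atol=abs_tol,
                        max_step=b_end - a, events=events, **kwargs)
        if not sol.success:
            raise IntegrationError(f"solve_ivp failed on [{a}, {b_end}]: {sol.message}")
        _check_positive(sol.y, f"integration on [{a:.3f}, {b_end:.3f}]")
        times.append(sol.t)
        cols.append(sol.y)
        controls.append(np.full(sol.t.size, u_seg))
        x = sol.y[:, -1]
        if events is not None and sol.status == 1:
            terminated = True
            break
    t_all = np.concatenate(times)
    y_all = np.concatenate(cols, axis=1)
    u_all = np.concatenate(controls)
    # drop duplicated segment joints
    keep = np.concatenate([[True], np.diff(t_all) > 0])
    del terminated  # (event info is carried by the final time)
    return Trajectory(t_all[keep], y_all[0, keep], y_all[1, keep], y_all[2, keep],
                      u_all[keep], schedule.v)


def first_passage_time(params: ModelParams, initial: TumorState,
                       schedule: DoseSchedule, threshold: float,
                       t_max: float) -> float | None:
    """First time the total volume N1+N2 crosses ``threshold`` from below.

    Returns ``None`` if the threshold is not reached by ``t_max``.  The
    crossing is located by the integrator's root refinement on its dense
    output, well below 1e-6 day resolution.
    """
    if initial.total >= threshold:
        return 0.0

    def crossing(t, x, *args):
        return x[0] + x[1] - threshold

    crossing.terminal = True
    crossing.direction = 1
    traj = simulate(params, initial, schedule, t_span=(0.0, t_max), events=crossing)
    t_end = float(traj.times[-1])
    if t_end < t_max and abs(traj.total[-1] - threshold) < 1e-3:
        return t_end
    # event may coincide with t_max; check the final value
    if abs(traj.total[-1] - threshold) < 1e-3:
        return t_end
    return None


def doubling_time_numeric(params: ModelParams, initial: TumorState,
                          cap_days: float = 100.0) -> float | None:
    """Untreated tumor doubling time in hours, by event-detected first passage.

    Integrates the drug-free system from ``initial`` and locates the first
    time the total volume reaches twice its initial value.  Returns ``None``
    when doubling is not reached within ``cap_days`` (e.g. starting at the
    saturating volume).
    """
    target = 2.0 * initial.total
    schedule = DoseSchedule.constant(0.0, 0.0, horizon=cap_days)
    t = first_passage_time(params, initial, schedule, target, cap_days)
    return None if t is None else 24.0 * t


def doubling_time_formula(lam: float, n_sat: float, n_init: float) -> float:
    """Closed-form doubling time ln2 / (lam * (ln N_sat - ln N_init)), in days.

    Treats ``lam * (ln N_sat - ln N_init)`` as the instantaneous per-capita
    growth rate of a Gompertz tumor of size ``n_init`` saturating at ``n_sat``.
    """
    if not (lam > 0):
        raise ValueError("lam must be positive")
    if not (n_sat > n_init > 0):
        raise ValueError("need n_sat > n_init > 0")
    return math.log(2.0) / (lam * (math.log(n_sat) - math.log(n_init)))


def find_steady_state(params: ModelParams, u: float, v: float,
                      guess: TumorState, tol: float = 1e-11) -> SteadyStateReport:
    """Locate an equilibrium of the constant-dose system and assess stability.

    The root of :func:`rhs` is searched in log-coordinates, which keeps the
    iterates strictly positive.  Stability is judged from the eigenvalues of
    the analytic Jacobian at the root.
    """
    x0 = np.log(guess.as_array())

    def wrapped(z):
        return rhs(np.exp(z), u, v, params)

    sol = root(wrapped, x0, method="hybr", tol=tol)
    x_star = np.exp(sol.x)
    residual = float(np.max(np.abs(rhs(x_star, u, v, params))))
    if not sol.success and residual > 1e-6:
        # fall toward the attractor first (stiff-capable integrator over a few
        # mutation time constants, the slowest relaxation direction), then
        # polish the root from there
        horizon = 5.0 / max(params.tau1 + params.tau2, 1e-6)
        relax = solve_ivp(_ode, (0.0, horizon), guess.as_array(),
                          args=(u, v, params), method="LSODA",
                          rtol=1e-10, atol=1e-8)
        if relax.success:
            sol = root(wrapped, np.log(relax.y[:, -1]), method="hybr", tol=tol)
            x_star = np.exp(sol.x)
            residual = float(np.max(np.abs(rhs(x_star, u, v, params))))
    if not sol.success and residual > 1e-6:
        raise RuntimeError(
            f"steady-state search did not converge (last residual {residual:.3e})"
        )
    jac = rhs_jacobian(x_star, u, v, params)
    eig = np.linalg.eigvals(jac)
    return SteadyStateReport(
        state=TumorState.from_array(x_star),
        residual_norm=residual,
        eigenvalues=eig,
        stable=bool(np.max(eig.real) < 0),
    )
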