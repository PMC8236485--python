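"""Therapy objective: tumor burden, terminal size, and a smooth resistance penalty.

The functional scores a treatment course on [0, T] as

    J(u) = omega1*N1(T) + omega2*N2(T)
           + int_0^T [ eta1*N1 + eta2*N2 + f(N1, N2) + theta*u ] dt,

where ``f(N1, N2) = (xi/2) * (1 + tanh((N2 - N1)/epsilon))`` is a smoothed
step that charges roughly ``xi`` per day whenever resistant cells outnumber
sensitive ones.  Minimizing J trades off shrinking the tumor against keeping
it drug-sensitive — the "maintenance" rather than "eradication" goal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .model import Trajectory

__all__ = ["ObjectiveWeights", "ObjectiveValue", "resistance_penalty",
           "evaluate_objective"]


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights of the objective functional (defaults are the nominal study values).

    ``eta1`` defaults to 1 so the running cost reduces to the displayed
    integrand ``N1 + eta2*N2 + f + theta*u``; ``theta`` defaults to 0, making
    the explicit dose penalty inert unless requested.
    """

    omega1: float = 5.0
    omega2: float = 25.0
    eta1: float = 1.0
    eta2: float = 5.0
    xi: float = 1000.0
    epsilon: float = 10.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega1", "omega2", "eta1", "eta2", "xi", "theta"):
            if getattr(self, name) < 0:
                raise ValueError(f"weight {name!r} must be non-negative")
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")

    def replace(self, **changes: float) -> "ObjectiveWeights":
        return replace(self, **changes)

    def as_vector(self) -> np.ndarray:
        return np.array([self.omega1, self.omega2, self.eta1, self.eta2,
                         self.xi, self.epsilon, self.theta])


NOMINAL_WEIGHTS = ObjectiveWeights()


@dataclass(frozen=True)
class ObjectiveValue:
    """Objective J decomposed into its four additive parts."""

    total: float
    terminal_part: float
    running_tumor_part: float
    resistance_part: float
    dose_part: float

    def __post_init__(self) -> None:
        parts = (self.terminal_part + self.running_tumor_part
                 + self.resistance_part + self.dose_part)
        if abs(parts - self.total) > 1e-9 * max(1.0, abs(self.total)):
            raise ValueError("objective parts do not sum to the total")

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "terminal_part": self.terminal_part,
            "running_tumor_part": self.running_tumor_part,
            "resistance_part": self.resistance_part,
            "dose_part": self.dose_part,
        }

    @classmethod
    def from_parts(cls, terminal: float, running_tumor: float,
                   resistance: float, dose: float) -> "ObjectiveValue":
        return cls(terminal + running_tumor + resistance + dose,
                   terminal, running_tumor, resistance, dose)


def resistance_penalty(n1, n2, xi: float = 1000.0, epsilon: float = 10.0):
    """Smoothed resistance switch ``(xi/2) * (1 + tanh((n2 - n1)/epsilon))``.

    Vectorized over ``n1``/``n2``.  Ranges over (0, xi); equals ``xi/2`` on
    the diagonal ``n1 == n2``; saturates to ``xi`` once the resistant excess
    exceeds a few multiples of ``epsilon``.
    """
    if not epsilon > 0:
        raise ValueError("epsilon must be positive")
    return 0.5 * xi * (1.0 + np.tanh((np.asarray(n2) - np.asarray(n1)) / epsilon))


def evaluate_objective(traj: Trajectory, weights: ObjectiveWeights,
                       quadrature: str = "trapezoid") -> ObjectiveValue:
    """Evaluate J on a trajectory carrying its controls.

    ``quadrature`` selects the running-integral rule: ``"trapezoid"`` (the
    natural choice on an adaptive integrator's output grid) or ``"left"``
    (left-rectangle, matching the forward-Euler transcription used by the
    optimizer, where ``u[i]`` and the state at node ``i`` are held over
    ``[t_i, t_{i+1})``).
    """
    w = weights
    t = traj.times
    if w.theta > 0 and traj.u is None:
        raise ValueError("dose penalty requested but trajectory has no controls")
    tumor = w.eta1 * traj.n1 + w.eta2 * traj.n2
    pen = resistance_penalty(traj.n1, traj.n2, w.xi, w.epsilon)
    dose = w.theta * traj.u

    if quadrature == "trapezoid":
        def integral(y):
            return float(np.trapezoid(y, t))
    elif quadrature == "left":
        dt = np.diff(t)

        def integral(y):
            return float(np.sum(y[:-1] * dt))
    else:
        raise ValueError(f"unknown quadrature {quadrature!r}")

    terminal = w.omega1 * float(traj.n1[-1]) + w.omega2 * float(traj.n2[-1])
    return ObjectiveValue.from_parts(
        terminal, integral(tumor), integral(pen), integral(dose)
    )
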