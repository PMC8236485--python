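"""Robustness of optimal schedules to the (unmeasurable) mutation rates.

Mutation rates toward and away from resistance are essentially impossible
to estimate in vivo, so the scheduling conclusions are stress-tested by
re-solving the short-horizon control problem for randomized (tau1, tau2)
pairs under several chemotherapy-sensitivity / anti-angiogenic-dose
scenarios.  Outputs are percentile bands of the optimal control over time,
the distribution of time-averaged doses, and a full-dose vs
intermediate-dose classification on the (log10 tau1, log10 tau2) plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .model import ModelParams, TumorState
from .objective import ObjectiveWeights
from .ocp import (TranscriptionSettings, average_dose, classify_protocol,
                  solve_ocp, transcribe)

__all__ = ["Scenario", "SensitivityDesign", "SensitivityResult",
           "sample_mutation_rates", "run_sensitivity", "percentile_curves",
           "classify_map", "DEFAULT_SCENARIOS"]


class Scenario(NamedTuple):
    """Chemo sensitivity of cells (beta1) and vasculature (beta), plus v."""

    beta1: float
    beta: float
    v: float

    @property
    def name(self) -> str:
        return f"beta1={self.beta1:g},beta={self.beta:g},v={self.v:g}"


#: The four study scenarios: high/low chemotherapy sensitivity crossed with
#: half/full anti-angiogenic dose.
DEFAULT_SCENARIOS: tuple[Scenario, ...] = (
    Scenario(0.60, 0.20, 0.5),
    Scenario(0.60, 0.20, 1.0),
    Scenario(0.30, 0.10, 0.5),
    Scenario(0.30, 0.10, 1.0),
)


@dataclass(frozen=True)
class SensitivityDesign:
    """Sampling plan for the randomized mutation-rate study.

    ``sampling="log-uniform"`` draws log10(tau) uniformly over the log-range
    — the natural choice when results are examined on the log plane; plain
    ``"uniform"`` is kept for comparison.  The seed is recorded in all
    outputs so a run is exactly reproducible.
    """

    n_samples: int = 400
    tau_range: tuple[float, float] = (1e-5, 5e-2)
    sampling: str = "log-uniform"
    seed: int = 0
    scenarios: tuple[Scenario, ...] = DEFAULT_SCENARIOS

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.tau_range
        if not (0 < lo <= hi < 1):
            raise ValueError("tau_range must satisfy 0 < lo <= hi < 1")
        if self.sampling not in ("log-uniform", "uniform"):
            raise ValueError("sampling must be 'log-uniform' or 'uniform'")

    def replace(self, **changes) -> "SensitivityDesign":
        return replace(self, **changes)


def sample_mutation_rates(design: SensitivityDesign) -> np.ndarray:
    """Draw (tau1, tau2) pairs per the design; shape (n_samples, 2).

    Reproducible for a fixed seed; a degenerate range [a, a] returns the
    single pair (a, a) repeated.
    """
    rng = np.random.default_rng(design.seed)
    lo, hi = design.tau_range
    if design.sampling == "log-uniform":
        draws = rng.uniform(np.log10(lo), np.log10(hi), size=(design.n_samples, 2))
        return 10.0 ** draws
    return rng.uniform(lo, hi, size=(design.n_samples, 2))


@dataclass
class SensitivityResult:
    """Per-sample schedule summaries for one scenario."""

    scenario: Scenario
    samples: np.ndarray                 # (n, 2) tau pairs
    controls: np.ndarray                # (n, M) optimal controls (NaN rows = failed)
    average_dose_pct: np.ndarray        # (n,)
    labels: list                        # protocol class labels
    statuses: list                      # per-sample solver status strings
    times: np.ndarray                   # control-interval midpoint times
    seed: int

    @property
    def n_failures(self) -> int:
        return int(sum(s != "ok" for s in self.statuses))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "tau1": self.samples[:, 0],
            "tau2": self.samples[:, 1],
            "scenario": self.scenario.name,
            "avg_dose_pct": self.average_dose_pct,
            "class": self.labels,
            "status": self.statuses,
        })


def run_sensitivity(params: ModelParams, initial: TumorState,
                    weights: ObjectiveWeights, design: SensitivityDesign,
                    settings: TranscriptionSettings | None = None,
                    ) -> list[SensitivityResult]:
    """Solve one scheduling problem per mutation-rate sample per scenario.

    Per-sample multistart is reduced to constant seeds {0.5, 1} to bound
    runtime; failures are recorded with a status label rather than resampled
    so the sample count stays interpretable.  A scenario with more than 10%
    failures gets a loud status marker in every affected row.
    """
    settings = settings or TranscriptionSettings(multistart=(0.5, 1.0),
                                                 restarts=1)
    samples = sample_mutation_rates(design)
    m = settings.n_intervals
    results = []
    for scenario in design.scenarios:
        base = params.replace(beta1=scenario.beta1, beta=scenario.beta)
        controls = np.full((design.n_samples, m), np.nan)
        avg = np.full(design.n_samples, np.nan)
        labels: list = [None] * design.n_samples
        statuses: list = ["ok"] * design.n_samples
        for i, (tau1, tau2) in enumerate(samples):
            p = base.replace(tau1=float(tau1), tau2=float(tau2))
            try:
                sol = solve_ocp(transcribe(p, initial, weights, scenario.v,
                                           settings))
                controls[i] = sol.control
                avg[i] = sol.average_dose_pct
                labels[i] = classify_protocol(sol).label
            except Exception as exc:  # noqa: BLE001 - record, keep going
                statuses[i] = f"failed: {exc}"
        n_failed = sum(s != "ok" for s in statuses)
        if n_failed > 0.1 * design.n_samples:
            statuses = [s if s == "ok" else s + " [scenario failure rate >10%]"
                        for s in statuses]
        times = (np.arange(m) + 0.5) * settings.step
        results.append(SensitivityResult(
            scenario=scenario, samples=samples, controls=controls,
            average_dose_pct=avg, labels=labels, statuses=statuses,
            times=times, seed=design.seed))
    return results


def percentile_curves(result: SensitivityResult,
                      percentiles=(5, 25, 50, 75, 95)) -> pd.DataFrame:
    """Pointwise control percentiles across samples, long format (t, percentile, u).

    Uses the linear-interpolation quantile convention.  Failed samples are
    excluded; an all-failed result raises.
    """
    ok = ~np.isnan(result.controls).any(axis=1)
    if not ok.any():
        raise ValueError("no successful samples to summarize")
    curves = np.percentile(result.controls[ok], percentiles, axis=0)
    frames = [pd.DataFrame({"t": result.times, "percentile": q, "u": curves[j]})
              for j, q in enumerate(percentiles)]
    return pd.concat(frames, ignore_index=True)


def classify_map(result: SensitivityResult) -> pd.DataFrame:
    """Class labels on the (log10 tau1, log10 tau2) plane.

    One row per successful sample with columns ``log10_tau1, log10_tau2,
    avg_dose_pct, class``.
    """
    ok = np.array([s == "ok" for s in result.statuses])
    return pd.DataFrame({
        "log10_tau1": np.log10(result.samples[ok, 0]),
        "log10_tau2": np.log10(result.samples[ok, 1]),
        "avg_dose_pct": result.average_dose_pct[ok],
        "class": [l for l, o in zip(result.labels, ok) if o],
    })
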