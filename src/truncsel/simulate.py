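"""Monte-Carlo oracle: simulate (SC, TGV) pairs with the assumed joint
structure and measure selection outcomes empirically.

The generative model draws, for each set k, the selection criterion first and
the true genetic value conditionally:

    sc  ~ N(mu_k, sigma_k^2)
    tgv | sc ~ N(mu_k + b_k * (sc - mu_k), v_k)

with residual variance ``v_k = sigma_u^2 * (1 - rho^2)`` for BLUP sets and
``sigma_u^2 * (1 - h^2)`` for BLUE sets.  This encodes exactly the two
quantities the closed-form theory uses — the SC variance and the TGV-on-SC
regression slope — and, by the law of total variance, recovers the marginal
genetic variance ``b^2 sigma^2 + v = sigma_u^2`` for both criterion types.

Randomness comes from a single master seed; per-set substreams are spawned
deterministically from it so adding a set never perturbs the draws of
earlier sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSelectionError, InvalidInputError
from .optimize import ThresholdSolution, solve_optimal_thresholds
from .scenario import BLUP, Scenario, derive_scale_and_slope, total_response

__all__ = [
    "SimulationConfig",
    "simulate_candidates",
    "empirical_total_response",
    "empirical_optimality_check",
    "OptimalityReport",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Number of candidates per set and the master seed."""

    n_per_set: int
    seed: int

    def __post_init__(self):
        if not (isinstance(self.n_per_set, (int, np.integer)) and self.n_per_set >= 1):
            raise InvalidInputError(
                f"n_per_set must be a positive integer; got {self.n_per_set!r}"
            )
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise InvalidInputError(f"seed must be a non-negative integer; got {self.seed!r}")


def residual_sd(params) -> float:
    """Conditional SD of TGV given SC.  Zero at perfect accuracy, where the
    criterion determines the TGV (BLUP, rho=1) up to the slope (BLUE)."""
    if params.criterion == BLUP:
        var = params.sigma_u**2 * (1.0 - params.accuracy**2)
    else:
        var = params.sigma_u**2 * (1.0 - params.accuracy)
    return float(np.sqrt(max(var, 0.0)))


def simulate_candidates(scenario: Scenario, config: SimulationConfig) -> pd.DataFrame:
    """Draw ``n_per_set`` (sc, tgv) pairs for every set of the scenario.

    Returns a DataFrame with columns ``set`` (label), ``sc``, ``tgv``.
    Bit-identical for identical configs.
    """
    streams = np.random.SeedSequence(config.seed).spawn(scenario.n_sets)
    frames = []
    for params, ss in zip(scenario.sets, streams):
        rng = np.random.default_rng(ss)
        sigma, b = derive_scale_and_slope(params)
        sc = rng.normal(params.mu, sigma, size=config.n_per_set)
        tgv = params.mu + b * (sc - params.mu) + rng.normal(
            0.0, residual_sd(params), size=config.n_per_set
        )
        frames.append(pd.DataFrame({"set": params.label, "sc": sc, "tgv": tgv}))
    return pd.concat(frames, ignore_index=True)


def empirical_total_response(
    population: pd.DataFrame, thresholds, scenario: Scenario
) -> tuple[float, np.ndarray, float]:
    """Empirical (alpha_hat, gamma_hat per set, deltaG_hat) at per-set
    thresholds: candidates with sc >= t_k in their set are selected; the
    response is the mean TGV of the selected minus the overall mean TGV."""
    t = np.asarray(thresholds, dtype=float).ravel()
    if t.size != scenario.n_sets:
        raise InvalidInputError(
            f"expected {scenario.n_sets} thresholds, got {t.size}"
        )
    by_label = dict(zip([s.label for s in scenario.sets], t))
    unknown = set(population["set"]) - set(by_label)
    if unknown:
        raise InvalidInputError(f"population has sets absent from scenario: {unknown}")
    cut = population["set"].map(by_label)
    selected = population["sc"] >= cut
    n_sel = int(selected.sum())
    if n_sel == 0:
        raise DegenerateSelectionError("no candidate exceeds its threshold")
    alpha_hat = n_sel / len(population)
    counts = population.loc[selected, "set"].value_counts()
    gamma_hat = np.array(
        [counts.get(s.label, 0) / n_sel for s in scenario.sets], dtype=float
    )
    deltaG_hat = float(
        population.loc[selected, "tgv"].mean() - population["tgv"].mean()
    )
    return float(alpha_hat), gamma_hat, deltaG_hat


@dataclass(frozen=True)
class OptimalityReport:
    """Grid check that the analytic optimum really is the constrained max."""

    solver: ThresholdSolution
    grid_alpha1: np.ndarray
    grid_deltaG: np.ndarray
    argmax_thresholds: np.ndarray
    grid_max: float
    solver_at_least_grid_max: bool


def empirical_optimality_check(scenario: Scenario, n_grid: int = 201) -> OptimalityReport:
    """Sweep budget-respecting threshold pairs and verify the solver's
    optimum dominates the grid (within 1e-9) and sits within one grid step
    of the argmax.  Two-set scenarios only (the grid is one-dimensional)."""
    if scenario.n_sets != 2:
        raise InvalidInputError("optimality grid check is defined for K = 2")
    if n_grid < 3:
        raise InvalidInputError("n_grid must be at least 3")
    pi1, pi2 = scenario.pis
    aT = scenario.alpha_T
    eps = 1e-9
    a1_lo = max(eps, (aT - pi2) / pi1 + eps)
    a1_hi = min(1.0 - eps, aT / pi1 - eps)
    alpha1 = np.linspace(a1_lo, a1_hi, n_grid)
    alpha2 = (aT - alpha1 * pi1) / pi2

    from .core import threshold_for_proportion  # local to avoid cycle noise

    s1, s2 = scenario.sets
    dG = np.empty(n_grid)
    thresholds = np.empty((n_grid, 2))
    for j, (a1, a2) in enumerate(zip(alpha1, alpha2)):
        t = np.array(
            [
                threshold_for_proportion(a1, mu=s1.mu, sigma=s1.sigma_sc),
                threshold_for_proportion(a2, mu=s2.mu, sigma=s2.sigma_sc),
            ]
        )
        thresholds[j] = t
        dG[j] = total_response(t, scenario).deltaG_tot

    solver = solve_optimal_thresholds(scenario)
    j_max = int(np.argmax(dG))
    return OptimalityReport(
        solver=solver,
        grid_alpha1=alpha1,
        grid_deltaG=dG,
        argmax_thresholds=thresholds[j_max],
        grid_max=float(dG[j_max]),
        solver_at_least_grid_max=bool(
            solver.outcome.deltaG_tot >= dG[j_max] - 1e-9
        ),
    )
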