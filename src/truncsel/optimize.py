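"""Optimal truncation thresholds under a fixed selection budget.

Given a multi-set scenario with total budget ``alpha_T``, three solvers are
provided:

``solve_identical_threshold``
    The single threshold t applied to every set with
    ``alpha_Tot(t, ..., t) = alpha_T``.  alpha_Tot is strictly decreasing in
    t, so the root is unique; found by Brent's method.

``solve_optimal_thresholds``
    Thresholds maximizing DG_Tot subject to the budget.  The Lagrange
    stationarity condition requires ``b_k (t_k - mu_k) + mu_k`` to take a
    common value c across all sets; substituting
    ``t_k(c) = mu_k + (c - mu_k)/b_k`` reduces the problem to a
    one-dimensional root of the budget constraint in c, again monotone and
    solved by Brent's method.  For all-BLUP scenarios (b_k = 1) the
    stationarity manifold collapses to equal thresholds, so the optimum
    coincides with the identical-threshold solution — the uniform-threshold
    optimality property of BLUPs.

``direct_constrained_maximize``
    An independent numerical cross-check: parameterize the last set's
    selected proportion through the budget and maximize DG_Tot over the free
    proportions directly.  Serves as the in-repo oracle for the Lagrange
    solution.

``percent_improvement`` quantifies the gain of optimal over identical
thresholds, Psi_Tot = 100 * (DG_opt - DG_ident) / DG_ident.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar

from .core import threshold_for_proportion
from .errors import InvalidInputError, SolverError, UndefinedRatioError
from .scenario import (
    BLUP,
    Scenario,
    TotalResponse,
    total_response,
    total_selected_proportion,
)

__all__ = [
    "ThresholdSolution",
    "solve_identical_threshold",
    "solve_optimal_thresholds",
    "solve_blup_common_threshold",
    "percent_improvement",
    "direct_constrained_maximize",
]

logger = logging.getLogger(__name__)

_XTOL = 1e-14
_BRACKET_SD = 10.0  # search thresholds within mu +/- 10 sigma per set
_MAX_EXPANSIONS = 6


@dataclass(frozen=True)
class ThresholdSolution:
    """Per-set thresholds satisfying the budget, with the achieved outcome.

    ``residual`` is the remaining budget violation |alpha_Tot - alpha_T|;
    ``boundary`` flags solutions clamped to the search-box edge (never the
    case for interior-feasible budgets).
    """

    mode: str
    thresholds: np.ndarray
    outcome: TotalResponse
    converged: bool
    residual: float
    boundary: bool = False

    @property
    def deltaG_tot(self) -> float:
        return self.outcome.deltaG_tot


def _bracket(scenario: Scenario) -> tuple[float, float]:
    lo = float(np.min(scenario.mus - _BRACKET_SD * scenario.sigmas))
    hi = float(np.max(scenario.mus + _BRACKET_SD * scenario.sigmas))
    return lo, hi


def _solve_monotone(f, lo: float, hi: float, what: str) -> float:
    """Brent root of a strictly decreasing f with bracket expansion."""
    flo, fhi = f(lo), f(hi)
    width = hi - lo
    n = 0
    while flo * fhi > 0.0 and n < _MAX_EXPANSIONS:
        lo, hi = lo - width, hi + width
        flo, fhi = f(lo), f(hi)
        n += 1
    if flo * fhi > 0.0:
        raise SolverError(
            f"{what}: no sign change in [{lo}, {hi}] "
            f"(f(lo)={flo:.3e}, f(hi)={fhi:.3e}); budget unreachable"
        )
    return float(brentq(f, lo, hi, xtol=_XTOL))


def _package(mode, thresholds, scenario, boundary=False) -> ThresholdSolution:
    t = np.asarray(thresholds, dtype=float)
    outcome = total_response(t, scenario)
    residual = abs(outcome.alpha_tot - scenario.alpha_T)
    sol = ThresholdSolution(
        mode=mode,
        thresholds=t,
        outcome=outcome,
        converged=residual <= 1e-9,
        residual=residual,
        boundary=boundary,
    )
    logger.info(
        "solver mode=%s thresholds=%s alpha_tot=%.6g residual=%.3g dG_tot=%.6g",
        mode, np.round(t, 6).tolist(), outcome.alpha_tot, residual,
        outcome.deltaG_tot,
    )
    return sol


def solve_identical_threshold(scenario: Scenario) -> ThresholdSolution:
    """Unique threshold t applied identically to all sets that meets the
    budget ``alpha_Tot(t, ..., t) = alpha_T``."""
    lo, hi = _bracket(scenario)
    K = scenario.n_sets

    def f(t):
        return total_selected_proportion(np.full(K, t), scenario) - scenario.alpha_T

    t = _solve_monotone(f, lo, hi, "identical-threshold solve")
    return _package("identical", np.full(K, t), scenario)


def solve_optimal_thresholds(scenario: Scenario) -> ThresholdSolution:
    """Budget-constrained maximizer of DG_Tot via the stationarity condition.

    At an interior optimum ``b_k (t_k - mu_k) + mu_k`` is equal across sets
    (value c); the budget then pins down c.  The achieved DG_Tot is >= the
    identical-threshold response up to solver tolerance; for all-BLUP
    scenarios the thresholds come out equal.
    """
    mus, slopes = scenario.mus, scenario.slopes

    def thresholds_of(c):
        return mus + (c - mus) / slopes

    # c ranges monotonically with every t_k, hence with alpha_Tot.
    lo, hi = _bracket(scenario)
    c_lo = float(np.min(slopes * (lo - mus) + mus))
    c_hi = float(np.max(slopes * (hi - mus) + mus))

    def f(c):
        return total_selected_proportion(thresholds_of(c), scenario) - scenario.alpha_T

    c = _solve_monotone(f, c_lo, c_hi, "optimal-threshold solve")
    return _package("optimal", thresholds_of(c), scenario)


def solve_blup_common_threshold(scenario: Scenario) -> ThresholdSolution:
    """Common optimal threshold for an all-BLUP scenario (dedicated entry
    point; identical thresholds are provably optimal when b_k = 1)."""
    if not scenario.all_blup:
        raise InvalidInputError(
            "blup_common solve requires every set to use the BLUP criterion"
        )
    sol = solve_identical_threshold(scenario)
    return ThresholdSolution(
        mode="blup_common",
        thresholds=sol.thresholds,
        outcome=sol.outcome,
        converged=sol.converged,
        residual=sol.residual,
        boundary=sol.boundary,
    )


def percent_improvement(scenario: Scenario) -> float:
    """Psi_Tot: percent gain of optimal over identical thresholds,
    100 * (DG_Tot(optimal) - DG_Tot(identical)) / DG_Tot(identical).

    Raises :class:`UndefinedRatioError` when the identical-threshold response
    is not positive (the ratio's denominator changes sign)."""
    ident = solve_identical_threshold(scenario)
    opt = solve_optimal_thresholds(scenario)
    base = ident.outcome.deltaG_tot
    if base <= 0.0:
        raise UndefinedRatioError(
            f"identical-threshold response is {base:.6g} <= 0; "
            "Psi_Tot is undefined"
        )
    return 100.0 * (opt.outcome.deltaG_tot - base) / base


def _alpha_bounds_last(scenario: Scenario, alphas_free: np.ndarray) -> float:
    """Selected proportion of the last set implied by the budget."""
    pis = scenario.pis
    rest = float(np.dot(alphas_free, pis[:-1]))
    return (scenario.alpha_T - rest) / pis[-1]


def _thresholds_from_alphas(alphas: np.ndarray, scenario: Scenario) -> np.ndarray:
    return np.array(
        [
            threshold_for_proportion(a, mu=s.mu, sigma=s.sigma_sc)
            for a, s in zip(alphas, scenario.sets)
        ]
    )


def direct_constrained_maximize(scenario: Scenario) -> ThresholdSolution:
    """Maximize DG_Tot under the budget by direct numerical optimization.

    The last set's selected proportion is eliminated through the constraint;
    the remaining K-1 proportions are free variables.  K = 2 uses bounded
    scalar minimization; K > 2 uses Nelder-Mead started from the
    identical-threshold solution with an infeasibility penalty.  Returns the
    better of the direct and Lagrange solutions and logs a warning if they
    disagree beyond 1e-6 in DG_Tot.
    """
    lagrange = solve_optimal_thresholds(scenario)
    K = scenario.n_sets
    if K == 1:
        return lagrange

    pis, aT = scenario.pis, scenario.alpha_T
    eps = 1e-12

    def neg_dG(alphas_free):
        alphas_free = np.atleast_1d(np.asarray(alphas_free, dtype=float))
        a_last = _alpha_bounds_last(scenario, alphas_free)
        if np.any(alphas_free <= 0) or np.any(alphas_free >= 1) or not (
            0.0 < a_last < 1.0
        ):
            return np.inf
        alphas = np.append(alphas_free, a_last)
        t = _thresholds_from_alphas(alphas, scenario)
        return -total_response(t, scenario).deltaG_tot

    if K == 2:
        # feasible alpha_1 interval: alpha_2 = (aT - a1*pi1)/pi2 in (0, 1)
        a1_lo = max(eps, (aT - pis[1]) / pis[0] + eps)
        a1_hi = min(1.0 - eps, aT / pis[0] - eps)
        if not a1_lo < a1_hi:
            raise SolverError("empty feasible interval for the free proportion")
        res = minimize_scalar(
            lambda a1: neg_dG([a1]),
            bounds=(a1_lo, a1_hi),
            method="bounded",
            options={"xatol": 1e-13},
        )
        if not res.success:
            raise SolverError(f"direct maximization failed: {res.message}")
        best_alphas = np.array([res.x, _alpha_bounds_last(scenario, np.array([res.x]))])
    else:
        start = np.array(
            [o.alpha for o in solve_identical_threshold(scenario).outcome.outcomes]
        )[:-1]
        res = minimize(
            neg_dG,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000},
        )
        if not res.success:
            raise SolverError(f"direct maximization failed: {res.message}")
        free = np.atleast_1d(res.x)
        best_alphas = np.append(free, _alpha_bounds_last(scenario, free))

    direct = _package("optimal", _thresholds_from_alphas(best_alphas, scenario), scenario)
    gap = direct.outcome.deltaG_tot - lagrange.outcome.deltaG_tot
    if abs(gap) > 1e-6:
        logger.warning(
            "direct and Lagrange optima disagree by %.3g in dG_Tot; "
            "returning the better one", gap,
        )
        return direct if gap > 0 else lagrange
    return direct
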