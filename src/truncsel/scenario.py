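"""Heterogeneous candidate sets and the multi-set selection response.

A breeding program evaluates K disjoint sets of candidates together.  Set k
holds a proportion ``pi_k`` of the combined pool; its selection criterion (SC)
is distributed N(mu_k, sigma_k^2) and the regression slope of true genetic
values (TGVs) on the SC is ``b_k``.  The two standard criteria fix
(sigma_k, b_k) from the genetic standard deviation ``sigma_u`` and the
criterion quality:

* BLUP with prediction accuracy rho:  sigma = rho * sigma_u,  b = 1
  (shrinkage makes the predictor's spread smaller than the genetic spread,
  and TGVs regress on BLUPs with unit slope);
* BLUE (phenotypic entry mean) with heritability h^2:  sigma = sigma_u / h,
  b = h^2  (the classical regression of genotype on phenotype).

Applying per-set truncation thresholds ``t_k`` selects the upper tail
``alpha_k = 1 - Phi((t_k - mu_k)/sigma_k)`` of each set.  The module provides
the closed forms for

* the total selected proportion  alpha_Tot = sum_k alpha_k * pi_k,
* the post-selection composition  gamma_k = alpha_k * pi_k / alpha_Tot,
* the within-set response  DG_k = b_k * sigma_k * i(alpha_k)  (breeder's
  equation), and
* the total response of the union,

      DG_Tot = sum_k DG_k * gamma_k + sum_k mu_k * (gamma_k - pi_k),

  i.e. the mean TGV of the selected union minus the unselected-union mean
  ``sum_k pi_k * mu_k`` (the baseline convention used throughout).

For all-BLUP scenarios a common threshold t* admits the equivalent direct
form :func:`blup_total_response_closed_form`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import selection_intensity, upper_tail_proportion
from .errors import DegenerateSelectionError, InvalidInputError

__all__ = [
    "BLUP",
    "BLUE",
    "SetParams",
    "Scenario",
    "SetOutcome",
    "TotalResponse",
    "derive_scale_and_slope",
    "total_selected_proportion",
    "post_selection_composition",
    "within_set_response",
    "total_response",
    "blup_total_response_closed_form",
    "read_scenario_csv",
    "scenario_to_frame",
    "total_response_to_frame",
]

BLUP = "BLUP"
BLUE = "BLUE"

_PI_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SetParams:
    """Population parameters of one candidate set.

    Parameters
    ----------
    label : str
        Identifier used in outputs and in simulated populations.
    pi : float
        Proportion of this set in the combined candidate pool, in (0, 1]
        (1 only for a single-set scenario).
    mu : float
        Mean of the selection criterion, trait units.
    sigma_u : float
        Genetic standard deviation of TGVs, trait units; > 0.
    criterion : {"BLUP", "BLUE"}
        Type of selection criterion.
    accuracy : float
        Prediction accuracy rho for BLUP, heritability h^2 for BLUE;
        in (0, 1].
    """

    label: str
    pi: float
    mu: float
    sigma_u: float
    criterion: str
    accuracy: float

    def __post_init__(self):
        object.__setattr__(self, "criterion", str(self.criterion).upper())
        if self.criterion not in (BLUP, BLUE):
            raise InvalidInputError(
                f"criterion must be 'BLUP' or 'BLUE'; got {self.criterion!r}"
            )
        if not (0.0 < self.pi <= 1.0):
            raise InvalidInputError(f"pi must lie in (0, 1]; got {self.pi!r}")
        if not (np.isfinite(self.mu)):
            raise InvalidInputError(f"mu must be finite; got {self.mu!r}")
        if not (np.isfinite(self.sigma_u) and self.sigma_u > 0.0):
            raise InvalidInputError(
                f"sigma_u must be positive; got {self.sigma_u!r}"
            )
        if not (0.0 < self.accuracy <= 1.0):
            raise InvalidInputError(
                f"accuracy (rho or h^2) must lie in (0, 1]; got {self.accuracy!r}"
            )

    @property
    def sigma_sc(self) -> float:
        """Standard deviation of the selection criterion."""
        return derive_scale_and_slope(self)[0]

    @property
    def slope(self) -> float:
        """Regression slope b of TGV on the selection criterion."""
        return derive_scale_and_slope(self)[1]


def derive_scale_and_slope(params: SetParams) -> tuple[float, float]:
    """SC standard deviation and TGV-on-SC regression slope for one set.

    BLUP: ``(rho * sigma_u, 1.0)``;  BLUE: ``(sigma_u / h, h^2)`` with
    ``h = sqrt(h^2)``.  A BLUE set with h^2 = 1 coincides with a BLUP set
    with rho = 1 (perfect accuracy).
    """
    if params.criterion == BLUP:
        return params.accuracy * params.sigma_u, 1.0
    h = float(np.sqrt(params.accuracy))
    return params.sigma_u / h, params.accuracy


@dataclass(frozen=True)
class Scenario:
    """Ordered collection of candidate sets plus the selection budget.

    ``alpha_T`` is the fixed total proportion of candidates to be selected
    from the combined pool.  Set proportions must sum to 1; proportions of 0
    or 1 are rejected for K >= 2 because they make the composition formulas
    degenerate.
    """

    sets: tuple[SetParams, ...]
    alpha_T: float

    def __init__(self, sets: Iterable[SetParams], alpha_T: float):
        sets = tuple(sets)
        if len(sets) < 1:
            raise InvalidInputError("a scenario needs at least one set")
        if len(sets) > 1 and any(s.pi >= 1.0 for s in sets):
            raise InvalidInputError(
                "pi must be strictly below 1 in a multi-set scenario"
            )
        total_pi = sum(s.pi for s in sets)
        if abs(total_pi - 1.0) > _PI_SUM_TOL:
            raise InvalidInputError(
                f"set proportions must sum to 1; got {total_pi!r}"
            )
        if not (0.0 < alpha_T < 1.0):
            raise InvalidInputError(
                f"alpha_T must lie strictly inside (0, 1); got {alpha_T!r}"
            )
        labels = [s.label for s in sets]
        if len(set(labels)) != len(labels):
            raise InvalidInputError(f"set labels must be unique; got {labels}")
        object.__setattr__(self, "sets", sets)
        object.__setattr__(self, "alpha_T", float(alpha_T))

    @property
    def n_sets(self) -> int:
        return len(self.sets)

    @property
    def pis(self) -> np.ndarray:
        return np.array([s.pi for s in self.sets])

    @property
    def mus(self) -> np.ndarray:
        return np.array([s.mu for s in self.sets])

    @property
    def sigmas(self) -> np.ndarray:
        """SC standard deviations per set."""
        return np.array([s.sigma_sc for s in self.sets])

    @property
    def slopes(self) -> np.ndarray:
        return np.array([s.slope for s in self.sets])

    @property
    def all_blup(self) -> bool:
        return all(s.criterion == BLUP for s in self.sets)

    @property
    def pool_mean(self) -> float:
        """Mean TGV of the unselected union, sum_k pi_k * mu_k."""
        return float(np.dot(self.pis, self.mus))


@dataclass(frozen=True)
class SetOutcome:
    """Per-set quantities at given thresholds."""

    label: str
    threshold: float
    alpha: float
    intensity: float
    deltaG: float
    gamma: float


@dataclass(frozen=True)
class TotalResponse:
    """Selection outcome of the combined set at given thresholds."""

    alpha_tot: float
    outcomes: tuple[SetOutcome, ...] = field(repr=False)
    deltaG_tot: float

    @property
    def gammas(self) -> np.ndarray:
        return np.array([o.gamma for o in self.outcomes])

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([o.threshold for o in self.outcomes])


def _check_thresholds(thresholds, scenario: Scenario) -> np.ndarray:
    t = np.asarray(thresholds, dtype=float).ravel()
    if t.size != scenario.n_sets:
        raise InvalidInputError(
            f"expected {scenario.n_sets} thresholds, got {t.size}"
        )
    if not np.all(np.isfinite(t)):
        raise InvalidInputError(f"thresholds must be finite; got {thresholds!r}")
    return t


def _set_alphas(t: np.ndarray, scenario: Scenario) -> np.ndarray:
    z = (t - scenario.mus) / scenario.sigmas
    return np.asarray(upper_tail_proportion(z))


def total_selected_proportion(thresholds, scenario: Scenario) -> float:
    """Proportion selected from the union: sum_k alpha_k * pi_k."""
    t = _check_thresholds(thresholds, scenario)
    return float(np.dot(_set_alphas(t, scenario), scenario.pis))


def post_selection_composition(thresholds, scenario: Scenario) -> np.ndarray:
    """Composition gamma_k = alpha_k * pi_k / alpha_Tot of the selected set.

    Sums to 1 exactly (normalized in place).  Raises
    :class:`DegenerateSelectionError` if the selected fraction is numerically
    empty.
    """
    t = _check_thresholds(thresholds, scenario)
    weighted = _set_alphas(t, scenario) * scenario.pis
    alpha_tot = weighted.sum()
    if alpha_tot <= 0.0:
        raise DegenerateSelectionError(
            "total selected proportion is zero; composition undefined"
        )
    return weighted / alpha_tot


def within_set_response(t: float, params: SetParams) -> float:
    """Breeder's-equation response b * sigma * i(alpha) of one set at
    threshold ``t`` (trait units, relative to the set's own mean)."""
    sigma, b = derive_scale_and_slope(params)
    alpha = upper_tail_proportion((float(t) - params.mu) / sigma)
    if alpha >= 1.0:  # saturated tail: everyone selected, zero response
        return 0.0
    return b * sigma * selection_intensity(alpha)


def total_response(thresholds, scenario: Scenario) -> TotalResponse:
    """Total selection response of the union at per-set thresholds.

        DG_Tot = sum_k DG_k * gamma_k + sum_k mu_k * (gamma_k - pi_k)

    The second sum is the shift of the selected union's baseline away from
    the unselected pool mean when the composition changes.  For K = 1 this
    reduces exactly to the classical breeder's equation.
    """
    t = _check_thresholds(thresholds, scenario)
    alphas = _set_alphas(t, scenario)
    weighted = alphas * scenario.pis
    alpha_tot = float(weighted.sum())
    if alpha_tot <= 0.0:
        raise DegenerateSelectionError(
            "total selected proportion is zero; response undefined"
        )
    gammas = weighted / alpha_tot
    # A set whose tail underflows to 0 contributes nothing (gamma = 0); a
    # fully selected set (alpha saturates at 1) has tail mean = set mean,
    # i.e. zero intensity.  Both are exact limits of i(alpha).
    intensities = np.zeros_like(alphas)
    interior = (alphas > 0.0) & (alphas < 1.0)
    intensities[interior] = np.asarray(selection_intensity(alphas[interior]))
    dG = scenario.slopes * scenario.sigmas * intensities
    dG_tot = float(
        np.dot(dG, gammas) + np.dot(scenario.mus, gammas - scenario.pis)
    )
    outcomes = tuple(
        SetOutcome(
            label=s.label,
            threshold=float(t[k]),
            alpha=float(alphas[k]),
            intensity=float(intensities[k]),
            deltaG=float(dG[k]),
            gamma=float(gammas[k]),
        )
        for k, s in enumerate(scenario.sets)
    )
    return TotalResponse(alpha_tot=alpha_tot, outcomes=outcomes, deltaG_tot=dG_tot)


def blup_total_response_closed_form(t_star: float, scenario: Scenario) -> float:
    """Direct closed form for the all-BLUP total response at a common
    threshold ``t_star``:

        DG_Tot = (1/alpha_T) * [ sum_k sigma_k * phi(z_k) * pi_k
                  + sum_k mu_k * pi_k * (alpha(z_k) - alpha_T) ],

    with ``z_k = (t* - mu_k) / sigma_k``.  Requires every set to use the BLUP
    criterion (b = 1); assumes ``t_star`` satisfies the budget constraint
    ``alpha_Tot(t*, ..., t*) = alpha_T``, under which it coincides with
    :func:`total_response` to 1e-10.
    """
    if not scenario.all_blup:
        raise InvalidInputError(
            "closed form requires every set to use the BLUP criterion"
        )
    t_star = float(t_star)
    if not np.isfinite(t_star):
        raise InvalidInputError(f"t_star must be finite; got {t_star!r}")
    z = (t_star - scenario.mus) / scenario.sigmas
    alphas = np.asarray(upper_tail_proportion(z))
    aT = scenario.alpha_T
    tail_means = np.dot(scenario.sigmas * norm.pdf(z), scenario.pis)
    mean_shift = np.dot(scenario.mus * scenario.pis, alphas - aT)
    return float((tail_means + mean_shift) / aT)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

_SCENARIO_COLUMNS = ["label", "pi", "mu", "sigma_u", "criterion", "accuracy"]


def read_scenario_csv(path_or_buffer, alpha_T: float) -> Scenario:
    """Read a scenario table with columns (label, pi, mu, sigma_u, criterion,
    accuracy); ``criterion`` is BLUP or BLUE, ``accuracy`` holds rho or h^2
    respectively.  ``alpha_T`` is supplied separately (config or CLI flag)."""
    df = pd.read_csv(path_or_buffer, comment="#")
    missing = [c for c in _SCENARIO_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"scenario CSV is missing columns: {missing}")
    sets = [
        SetParams(
            label=str(row.label),
            pi=float(row.pi),
            mu=float(row.mu),
            sigma_u=float(row.sigma_u),
            criterion=str(row.criterion),
            accuracy=float(row.accuracy),
        )
        for row in df.itertuples(index=False)
    ]
    return Scenario(sets, alpha_T)


def scenario_to_frame(scenario: Scenario) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [s.label for s in scenario.sets],
            "pi": [s.pi for s in scenario.sets],
            "mu": [s.mu for s in scenario.sets],
            "sigma_u": [s.sigma_u for s in scenario.sets],
            "criterion": [s.criterion for s in scenario.sets],
            "accuracy": [s.accuracy for s in scenario.sets],
        }
    )


def total_response_to_frame(result: TotalResponse) -> pd.DataFrame:
    """One row per set plus a TOTAL row (threshold/alpha/intensity blank on
    the TOTAL row, gamma = 1)."""
    rows = [
        {
            "label": o.label,
            "threshold": o.threshold,
            "alpha": o.alpha,
            "intensity": o.intensity,
            "deltaG": o.deltaG,
            "gamma": o.gamma,
        }
        for o in result.outcomes
    ]
    rows.append(
        {
            "label": "TOTAL",
            "threshold": np.nan,
            "alpha": result.alpha_tot,
            "intensity": np.nan,
            "deltaG": result.deltaG_tot,
            "gamma": 1.0,
        }
    )
    return pd.DataFrame(rows)
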