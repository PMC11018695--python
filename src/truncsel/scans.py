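"""Parameter-grid scans over the multi-set and hybrid optimizers.

Three scan kinds map the behavior of the method over population-parameter
grids, each returning a tidy DataFrame (one row per grid point) that can be
written as CSV or rendered as a contour plot:

* ``gamma_ratio`` — BLUP selection with a common optimal threshold: how the
  post-selection share gamma_1* of set 1 shifts away from its initial
  proportion pi_1 as the second set's mean mu_2 and accuracy rho_2 vary.
* ``psi_tot`` — BLUE selection: the percent gain Psi_Tot of optimal over
  identical thresholds over a (mu_2, h_2) grid (h_2 = sqrt of the
  heritability, the natural contour axis).
* ``hybrid`` — factorial GCA selection: Psi_Hyb and the optimal/equal
  proportion ratio over the pool SD ratio sigma_2:sigma_1 for a list of
  hybrid budgets alpha_H.

Scans are pure functions of their spec: re-running one yields identical
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .hybrid import HybridParams, equal_proportion_baseline, solve_optimal_hybrid
from .optimize import (
    percent_improvement,
    solve_blup_common_threshold,
    solve_identical_threshold,
    solve_optimal_thresholds,
)
from .scenario import BLUE, BLUP, Scenario, SetParams

__all__ = ["ScanSpec", "scan_gamma_ratio", "scan_psi_tot", "scan_hybrid", "run_scan"]

_SCAN_KINDS = ("gamma_ratio", "psi_tot", "hybrid")


def _grid(spec: dict, key: str) -> np.ndarray:
    """Build an axis from flat config keys ``<key>_min/_max/_num`` or an
    explicit list under ``<key>_values``."""
    if f"{key}_values" in spec:
        vals = np.asarray(spec[f"{key}_values"], dtype=float)
        if vals.size < 1:
            raise InvalidInputError(f"{key}_values must be non-empty")
        return vals
    try:
        lo = float(spec[f"{key}_min"])
        hi = float(spec[f"{key}_max"])
        num = int(spec[f"{key}_num"])
    except KeyError as e:
        raise InvalidInputError(f"scan config is missing key {e.args[0]!r}") from e
    if num < 2:
        raise InvalidInputError(f"{key}_num must be >= 2; got {num}")
    return np.linspace(lo, hi, num)


@dataclass(frozen=True)
class ScanSpec:
    """A scan kind plus its grid axes and fixed parameters.

    Built from a flat key-value mapping (e.g. a YAML config): axes are given
    either as ``<name>_min``/``<name>_max``/``<name>_num`` or as
    ``<name>_values`` lists; everything else is a fixed scalar.
    """

    kind: str
    axes: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in _SCAN_KINDS:
            raise InvalidInputError(
                f"scan kind must be one of {_SCAN_KINDS}; got {self.kind!r}"
            )

    @classmethod
    def from_dict(cls, spec: dict) -> "ScanSpec":
        spec = dict(spec)
        try:
            kind = spec.pop("kind")
        except KeyError:
            raise InvalidInputError("scan config is missing key 'kind'") from None
        axis_names = {
            "gamma_ratio": ("mu2", "rho2"),
            "psi_tot": ("mu2", "h2"),
            "hybrid": ("ratio", "alpha_H"),
        }[kind] if kind in _SCAN_KINDS else ()
        axes, fixed = {}, {}
        for name in axis_names:
            axes[name] = _grid(spec, name)
            for suffix in ("_min", "_max", "_num", "_values"):
                spec.pop(f"{name}{suffix}", None)
        for key, value in spec.items():
            fixed[key] = value
        return cls(kind=kind, axes=axes, fixed=fixed)


def scan_gamma_ratio(
    mu2_grid,
    rho2_grid,
    pi1: float,
    alpha_T: float,
    rho1: float = 0.5,
    mu1: float = 0.0,
    sigma_u: float = 1.0,
) -> pd.DataFrame:
    """gamma_1* and gamma_1*/pi_1 for BLUP selection at the common optimal
    threshold, over a (mu_2, rho_2) grid with set 1 fixed at (mu1, rho1)."""
    rows = []
    for mu2 in np.asarray(mu2_grid, dtype=float):
        for rho2 in np.asarray(rho2_grid, dtype=float):
            scenario = Scenario(
                [
                    SetParams("set1", pi1, mu1, sigma_u, BLUP, rho1),
                    SetParams("set2", 1.0 - pi1, mu2, sigma_u, BLUP, rho2),
                ],
                alpha_T,
            )
            sol = solve_blup_common_threshold(scenario)
            g1 = sol.outcome.outcomes[0].gamma
            rows.append(
                {
                    "mu2": mu2,
                    "rho2": rho2,
                    "pi1": pi1,
                    "alpha_T": alpha_T,
                    "gamma1": g1,
                    "gamma1_over_pi1": g1 / pi1,
                }
            )
    return pd.DataFrame(rows)


def scan_psi_tot(
    mu2_grid,
    h2_grid,
    pi1: float,
    alpha_T: float,
    h1_sq: float = 0.5,
    mu1: float = 0.0,
    sigma_u: float = 1.0,
) -> pd.DataFrame:
    """Psi_Tot plus gamma_1 under optimal and identical thresholds for BLUE
    selection over a (mu_2, h_2) grid; ``h2_grid`` holds h_2 = sqrt(h_2^2)."""
    rows = []
    for mu2 in np.asarray(mu2_grid, dtype=float):
        for h2 in np.asarray(h2_grid, dtype=float):
            scenario = Scenario(
                [
                    SetParams("set1", pi1, mu1, sigma_u, BLUE, h1_sq),
                    SetParams("set2", 1.0 - pi1, mu2, sigma_u, BLUE, h2**2),
                ],
                alpha_T,
            )
            psi = percent_improvement(scenario)
            g1_opt = solve_optimal_thresholds(scenario).outcome.outcomes[0].gamma
            g1_ident = solve_identical_threshold(scenario).outcome.outcomes[0].gamma
            rows.append(
                {
                    "mu2": mu2,
                    "h2": h2,
                    "pi1": pi1,
                    "alpha_T": alpha_T,
                    "psi_tot": psi,
                    "gamma1_opt": g1_opt,
                    "gamma1_ident": g1_ident,
                }
            )
    return pd.DataFrame(rows)


def scan_hybrid(
    ratio_grid,
    alpha_H_values,
    sigma1: float = 1.0,
    b1: float = 1.0,
    b2: float = 1.0,
) -> pd.DataFrame:
    """Psi_Hyb and the optimal-vs-equal proportion ratio over the pool SD
    ratio sigma_2:sigma_1 for each hybrid budget alpha_H."""
    rows = []
    for alpha_H in np.asarray(alpha_H_values, dtype=float):
        for ratio in np.asarray(ratio_grid, dtype=float):
            params = HybridParams(
                sigma1=sigma1, sigma2=ratio * sigma1, b1=b1, b2=b2, alpha_H=alpha_H
            )
            opt = solve_optimal_hybrid(params)
            base = equal_proportion_baseline(params)
            rows.append(
                {
                    "ratio": ratio,
                    "alpha_H": alpha_H,
                    "psi_hyb": 100.0
                    * (opt.deltaG_hyb - base.deltaG_hyb)
                    / base.deltaG_hyb,
                    "alpha1_opt": opt.alpha1,
                    "alpha1_over_equal": opt.alpha1 / base.alpha1,
                }
            )
    return pd.DataFrame(rows)


def _require(fixed: dict, key: str) -> float:
    try:
        return float(fixed.pop(key))
    except KeyError:
        raise InvalidInputError(f"scan config is missing key {key!r}") from None


def run_scan(spec: ScanSpec) -> pd.DataFrame:
    """Dispatch a ScanSpec to the matching scan function."""
    fixed = dict(spec.fixed)
    if spec.kind == "gamma_ratio":
        return scan_gamma_ratio(
            spec.axes["mu2"],
            spec.axes["rho2"],
            pi1=_require(fixed, "pi1"),
            alpha_T=_require(fixed, "alpha_T"),
            rho1=float(fixed.pop("rho1", 0.5)),
            mu1=float(fixed.pop("mu1", 0.0)),
            sigma_u=float(fixed.pop("sigma_u", 1.0)),
            **_reject_extras(fixed),
        )
    if spec.kind == "psi_tot":
        return scan_psi_tot(
            spec.axes["mu2"],
            spec.axes["h2"],
            pi1=_require(fixed, "pi1"),
            alpha_T=_require(fixed, "alpha_T"),
            h1_sq=float(fixed.pop("h1_sq", 0.5)),
            mu1=float(fixed.pop("mu1", 0.0)),
            sigma_u=float(fixed.pop("sigma_u", 1.0)),
            **_reject_extras(fixed),
        )
    return scan_hybrid(
        spec.axes["ratio"],
        spec.axes["alpha_H"],
        sigma1=float(fixed.pop("sigma1", 1.0)),
        b1=float(fixed.pop("b1", 1.0)),
        b2=float(fixed.pop("b2", 1.0)),
        **_reject_extras(fixed),
    )


def _reject_extras(fixed: dict) -> dict:
    if fixed:
        raise InvalidInputError(
            f"unknown scan config keys: {sorted(fixed)}"
        )
    return {}
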