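"""Shared fixtures: the two documented reference scenarios and randomized
scenario factories used by the property tests."""

import numpy as np
import pytest

from truncsel import BLUE, BLUP, Scenario, SetParams


@pytest.fixture
def blue_scenario() -> Scenario:
    """Two equal BLUE sets from one population (mu=0, sigma_u=1) that differ
    only in heritability (0.36 vs 0.81); budget alpha_T = 0.10."""
    return Scenario(
        [
            SetParams("P1", 0.5, 0.0, 1.0, BLUE, 0.36),
            SetParams("P2", 0.5, 0.0, 1.0, BLUE, 0.81),
        ],
        alpha_T=0.10,
    )


@pytest.fixture
def blup_scenario() -> Scenario:
    """Same population pair selected on BLUPs with accuracies 0.6 vs 0.9."""
    return Scenario(
        [
            SetParams("P1", 0.5, 0.0, 1.0, BLUP, 0.6),
            SetParams("P2", 0.5, 0.0, 1.0, BLUP, 0.9),
        ],
        alpha_T=0.10,
    )


@pytest.fixture
def extreme_scenario() -> Scenario:
    """Inferior small set vs. superior set two genetic SDs ahead.  The quoted
    SC standard deviations are 1 and 2, so sigma_u = sigma_sc * h: 0.6 and
    1.8.  Mild selection on set 1 (alpha_1 = 0.45) and stringent selection on
    set 2 (alpha_2 = 0.0125) makes the total response negative."""
    return Scenario(
        [
            SetParams("P1", 0.2, 0.0, 0.6, BLUE, 0.36),
            SetParams("P2", 0.8, 2.0, 1.8, BLUE, 0.81),
        ],
        alpha_T=0.10,
    )


def random_scenario(rng: np.random.Generator, criterion: str, n_sets: int = 2) -> Scenario:
    """A valid random scenario with interior parameters: means within a few
    trait units, genetic SDs 0.3-2, accuracies/heritabilities 0.2-1, set
    proportions bounded away from 0/1, and a budget in [0.005, 0.5]."""
    pis = rng.dirichlet(np.full(n_sets, 5.0))
    pis = 0.9 * pis + 0.1 / n_sets  # keep proportions off the boundary
    pis = pis / pis.sum()
    sets = [
        SetParams(
            label=f"S{k}",
            pi=float(pis[k]),
            mu=float(rng.uniform(-2.0, 2.0)),
            sigma_u=float(rng.uniform(0.3, 2.0)),
            criterion=criterion,
            accuracy=float(rng.uniform(0.2, 1.0)),
        )
        for k in range(n_sets)
    ]
    return Scenario(sets, alpha_T=float(rng.uniform(0.005, 0.5)))
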