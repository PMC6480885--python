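"""Shared fixtures: small simulated datasets and pre-fitted models.

Everything is generated programmatically with fixed seeds; session scope
keeps the slower tensor-model fits to one per test run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pytest

import tegam as tg


@dataclass(frozen=True)
class ToyMargin:
    """Duck-typed marginal basis for small-dimension tensor oracles."""

    variable_name: str
    dimension: int
    funcs: tuple[Callable[[np.ndarray], np.ndarray], ...]
    penalty: np.ndarray
    knots: np.ndarray

    def evaluate(self, x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return np.column_stack([f(x) for f in self.funcs])


def make_toy_margin(name: str, seed: int) -> ToyMargin:
    """Dimension-2 margin {1, x} with a random PSD penalty."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((2, 2))
    return ToyMargin(
        variable_name=name,
        dimension=2,
        funcs=(lambda x: np.ones_like(x), lambda x: x),
        penalty=A @ A.T,
        knots=np.array([0.0, 1.0]),
    )


@pytest.fixture(scope="session")
def toy_margins():
    return tuple(make_toy_margin(n, s) for n, s in (("pm10", 1), ("no2", 2), ("so2", 3)))


@pytest.fixture(scope="session")
def sim_config():
    return tg.SimulationConfig(n_days=600, seed=11, dispersion=1.5)


@pytest.fixture(scope="session")
def ds600(sim_config):
    return tg.simulate_dataset(sim_config)


@pytest.fixture(scope="session")
def built2(ds600):
    return tg.build_model(ds600, tg.ModelSpec(model="II"))


@pytest.fixture(scope="session")
def fit2(built2):
    return tg.pirls_fit(built2.design, [])


@pytest.fixture(scope="session")
def built4(ds600):
    return tg.build_model(ds600, tg.ModelSpec(model="IV", tensor_dims=(4, 4, 4)))


@pytest.fixture(scope="session")
def fit4(built4):
    return tg.pirls_fit(built4.design, [1.0, 1.0, 1.0])
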