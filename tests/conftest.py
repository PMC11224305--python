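"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hsfluor.simulate import class_profiles, simulate_dataset
from hsfluor.spectral import WavelengthGrid, build_synthetic_basis


@pytest.fixture(scope="session")
def grid310() -> WavelengthGrid:
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def coarse_grid() -> WavelengthGrid:
    """5 nm instrument-style grid (63 bands), used for cube-scale tests."""
    return WavelengthGrid.from_step(420.0, 729.0, 5.0)


@pytest.fixture(scope="session")
def basis(grid310):
    return build_synthetic_basis(grid310)


@pytest.fixture(scope="session")
def coarse_basis(coarse_grid):
    return build_synthetic_basis(coarse_grid)


@pytest.fixture(scope="session")
def margin_profiles():
    return class_profiles("margin", delta=1.0)


@pytest.fixture(scope="session")
def small_margin_dataset():
    """Margin-task dataset small enough for fast classifier tests."""
    return simulate_dataset("margin", n_biopsies_per_class=4, seed=7, delta=1.0)


def nnls_objective(B: np.ndarray, y: np.ndarray, c: np.ndarray) -> float:
    r = y - B @ c
    return 0.5 * float(r @ r)


def bruteforce_nnls(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive-support oracle for small NNLS problems.

    Solves the unconstrained least-squares problem restricted to every subset
    of columns, keeps the feasible (non-negative) solutions, and returns the
    one with the smallest objective.  Independent of the active-set solver.
    """
    n = B.shape[1]
    best_c = np.zeros(n)
    best_obj = nnls_objective(B, y, best_c)
    for k in range(1, n + 1):
        for support in itertools.combinations(range(n), k):
            sub = B[:, support]
            coef, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.any(coef < 0):
                continue
            full = np.zeros(n)
            full[list(support)] = coef
            obj = nnls_objective(B, y, full)
            if obj < best_obj:
                best_obj = obj
                best_c = full
    return best_c, best_obj


def random_nnls_instance(rng: np.random.Generator, n_bands: int = 10, n_cols: int = 5):
    """A random small unmixing problem with noise (so the support is nontrivial)."""
    B = rng.uniform(0.0, 1.0, size=(n_bands, n_cols))
    c_true = np.where(rng.random(n_cols) < 0.5, 0.0, rng.uniform(0.2, 2.0, n_cols))
    y = B @ c_true + rng.normal(0.0, 0.3, size=n_bands)
    return B, y
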