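"""Shared fixtures: deterministic synthetic data, built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from virtucrania.synthetic import (
    generate_population,
    generate_template,
)


@pytest.fixture(scope="session")
def template():
    """Bumpy synthetic cranial template (the general-purpose fixture)."""
    return generate_template(seed=7)


@pytest.fixture(scope="session")
def smooth_template():
    """Exact-ellipsoid template: analytic volume/geometry oracles apply."""
    return generate_template(seed=7, bump_amplitude=0.0)


@pytest.fixture(scope="session")
def population(template):
    """Twelve individuals in four groups, with known ground truth."""
    return generate_population(template, n=12, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform-ish random proper rotation matrix."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
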