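import numpy as np
import pytest

from oncoassign import (
    BiomarkerMatrix,
    PlantedTreeSpec,
    SensitivityMatrix,
    compute_ic50_star,
    generate_planted_tree_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def small_benefit():
    """4 patients x 2 drugs on the benefit scale (larger = better)."""
    return SensitivityMatrix(
        np.array([[3.0, 1.0], [2.0, 2.0], [0.0, 4.0], [1.0, 3.0]]),
        [f"p{i}" for i in range(4)],
        ["d0", "d1"],
        scale="benefit",
    )


@pytest.fixture
def small_markers():
    return BiomarkerMatrix(
        np.array([[1.0, 0.0], [1.0, 1.0], [0.0, 0.0], [0.0, 1.0]]),
        [f"p{i}" for i in range(4)],
        ["g1", "g2"],
    )


@pytest.fixture
def planted_cohort():
    """Centered planted-tree cohort with known truth (depth 2, n=200)."""
    y, x, truth = generate_planted_tree_cohort(PlantedTreeSpec(seed=42))
    return compute_ic50_star(y), x, truth


def random_sensitivity(rng, p=6, d=4, scale="log_ic50", missing_rate=0.0):
    vals = rng.standard_normal((p, d))
    if missing_rate:
        mask = rng.random((p, d)) < missing_rate
        # keep at least one observation per row and column
        mask[0, :] = False
        mask[:, 0] = False
        vals = np.where(mask, np.nan, vals)
    return SensitivityMatrix(
        vals, [f"p{i}" for i in range(p)], [f"d{j}" for j in range(d)], scale=scale
    )
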