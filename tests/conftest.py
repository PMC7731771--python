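import numpy as np
import pytest

from rbeconv.plan import DoseGrid, StructureMask
from rbeconv.synthetic import (
    SyntheticPlanSpec,
    calibrate_ground_truth,
    generate_paired_plans,
)


@pytest.fixture(scope="session")
def truth_curve():
    """Ground-truth factor curve calibrated to the published shell endpoints."""
    return calibrate_ground_truth()


@pytest.fixture(scope="session")
def noise_free_pair(truth_curve):
    """One noise-free, ripple-free synthetic paired plan (default geometry)."""
    spec = SyntheticPlanSpec(seed=42)
    lem, mkm, masks = generate_paired_plans(spec, truth_curve)
    return spec, lem, mkm, masks


def random_grid(rng, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), max_dose=60.0,
                duplicates=False, n_fractions=1, model_tag="LEM"):
    """Random dose grid; with duplicates=True, doses are drawn from a coarse set."""
    if duplicates:
        values = rng.choice(np.linspace(0.0, max_dose, 12), size=shape)
    else:
        values = rng.uniform(0.0, max_dose, size=shape)
    return DoseGrid(values, spacing, n_fractions=n_fractions, model_tag=model_tag)


def full_mask(shape, name="ROI"):
    return StructureMask(np.ones(shape, dtype=bool), name=name)
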