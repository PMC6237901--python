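import numpy as np
import pytest

from lapsefit.psychometric import BlockData, PriorConfig, PsychometricParams, predict_prob
from lapsefit.simulate import SimConfig, simulate_cohort

STEPS = np.arange(1, 8)


@pytest.fixture(scope="session")
def fast_prior():
    """Reduced-resolution grid for test-speed fits (resolution is a config knob)."""
    return PriorConfig(asym_max=0.1, grid_points=25, grid_points_asym=13)


@pytest.fixture(scope="session")
def fast_prior_zero():
    return PriorConfig(asym_max=0.0, grid_points=25, grid_points_asym=13)


@pytest.fixture(scope="session")
def small_cohort():
    """12 virtual subjects under the default generative links."""
    return simulate_cohort(SimConfig(n_subjects=12, seed=11))


def make_block(counts, n_per_step=10, steps=STEPS, **meta):
    """Block from explicit per-step category-2 counts."""
    counts = np.asarray(counts)
    kwargs = dict(subject_id="S1", continuum="dynamic_ba_da", paradigm="abx", block_index=1)
    kwargs.update(meta)
    return BlockData(
        steps=np.asarray(steps), n_trials=np.full(len(counts), n_per_step),
        n_category2=counts, **kwargs,
    )


def sample_block(params: PsychometricParams, n_per_step: int, rng, **meta) -> BlockData:
    """Block sampled from a true psychometric."""
    psi = predict_prob(params, STEPS.astype(float))
    return make_block(rng.binomial(n_per_step, psi), n_per_step=n_per_step, **meta)
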