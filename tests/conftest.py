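import pytest

import flymotor as fm


@pytest.fixture(scope="session")
def clean_branch():
    """Noise-free intact branch (no gaps) with its ground truth."""
    params = fm.BranchSimParams(seed=2, gap_rate_per_um=0.0, snr=float("inf"))
    stack, truth = fm.generate_branch_image(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def gapped_branch():
    """Noise-free fragmented branch with known gap intervals."""
    params = fm.BranchSimParams(seed=1, gap_rate_per_um=0.1, snr=float("inf"))
    stack, truth = fm.generate_branch_image(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def muscle_field():
    """Noise-free muscle field with 40 perinuclear / 20 dispersed puncta."""
    params = fm.MuscleFieldSimParams(seed=3, snr=float("inf"))
    stack, truth = fm.generate_muscle_field(params)
    return params, stack, truth
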