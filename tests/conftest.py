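import numpy as np
import pytest

from lifespan_architect.synthetic_data import CohortSpec, SimConfig, simulate_syllable_cohort


@pytest.fixture(scope="session")
def staged_cohort():
    """15-animal, 3-stage cohort with well-separated stage templates."""
    cfg = SimConfig(n_syllables=20, n_bins_per_day=48, seed=0)
    spec = CohortSpec(
        n_stages=3, mean_dwell_days=60, min_dwell_days=20, template_separation=8.0
    )
    tensor, truth = simulate_syllable_cohort(15, spec, cfg)
    return cfg, spec, tensor, truth


def permutation_accuracy(est: np.ndarray, true: np.ndarray, k: int) -> float:
    """Best label agreement over all permutations of k estimated labels."""
    from itertools import permutations

    best = 0.0
    for perm in permutations(range(k)):
        mapped = np.array(perm)[est]
        best = max(best, float(np.mean(mapped == true)))
    return best
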