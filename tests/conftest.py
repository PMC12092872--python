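import numpy as np
import pytest

from petrad import (
    SyntheticSpec,
    extract_features,
    make_split_plan,
    reference_config,
    run_preliminary,
    simulate_feature_table,
    simulate_phantom,
)


@pytest.fixture(scope="session")
def phantom_features():
    """Full reference-profile extraction on a small noisy sphere phantom."""
    volume, mask = simulate_phantom(
        grid=(24, 24, 24),
        spacing=(2.73, 2.73, 3.27),
        lesion_radius_mm=10.0,
        contrast=5.0,
        noise_sd=0.2,
        seed=1,
    )
    return extract_features(volume, mask, reference_config())


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-patient, 60-feature table with 5 strong planted features."""
    spec = SyntheticSpec(
        n_patients=80, n_features=60, n_informative=5, effect_size=1.5, seed=3
    )
    return simulate_feature_table(spec)


@pytest.fixture(scope="session")
def small_run(small_cohort):
    """A short preliminary run (3 repetitions, budget 4) on the small table."""
    table, labels, truth = small_cohort
    plan = make_split_plan(labels, reps=3, test_frac=0.2, k=5, seed=7)
    result = run_preliminary(table, labels, plan, budget=4)
    return table, labels, truth, plan, result
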