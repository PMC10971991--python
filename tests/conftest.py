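import numpy as np
import pytest

from metaboselect import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def study_null_table():
    """46-subject, 3-group cohort with no planted signal (20 metabolites)."""
    return generate_cohort(SyntheticConfig(n_per_group=(31, 8, 7), n_metabolites=20, seed=11))


@pytest.fixture(scope="session")
def separable_table():
    """Cohort whose three groups are cleanly separated by two markers."""
    cfg = SyntheticConfig(
        n_per_group=(16, 8, 7),
        n_metabolites=10,
        noise_sigma=0.2,
        marker_spec=((2, (1.0, 8.0, 1.0)), (5, (1.0, 1.0, 8.0))),
        seed=3,
    )
    return generate_cohort(cfg)


def random_three_class(rng, n_min=12, n_max=26, p_max=4):
    """Small random labelled matrix with every class size >= 4."""
    n = int(rng.integers(n_min, n_max))
    p = int(rng.integers(1, p_max + 1))
    labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4 + list(rng.choice(["a", "b", "c"], n - 12))
    y = np.array(labels, dtype=object)
    X = rng.normal(size=(n, p)) + 0.8 * (y == "b")[:, None]
    return X, y
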