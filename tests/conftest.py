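import numpy as np
import pandas as pd
import pytest

from painfusion import GeneratorConfig, simulate_features


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A desk-scale cohort: 10 subjects x 2 days."""
    return GeneratorConfig(n_subjects=10, n_days=2, seed=7)


@pytest.fixture(scope="session")
def small_features(small_config) -> pd.DataFrame:
    return simulate_features(small_config)


@pytest.fixture(scope="session")
def separable_frame() -> pd.DataFrame:
    """Perfectly separable 3-class windows spread over 26 subjects.

    Class clouds are tight and far apart, identical across subjects, so
    any reasonable classifier reaches F1 = 1 under both CV schemes.
    """
    rng = np.random.default_rng(0)
    rows = []
    for s in range(26):
        for label, center in [("B", 0.0), ("LP", 20.0), ("HP", 40.0)]:
            for _ in range(4):
                x = center + rng.normal(0, 0.1, size=3)
                rows.append({
                    "subject": f"S{s:02d}", "label": label,
                    "sc.f0": x[0], "sc.f1": x[1], "sc.f2": x[2],
                })
    return pd.DataFrame(rows)
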