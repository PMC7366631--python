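import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fibrospec as fs

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort() -> fs.SpectrumSet:
    """A quick 12+12-subject triplicate cohort with the default class effect."""
    return fs.generate_spectra(fs.SyntheticConfig(n_per_class=12, seed=7))


@pytest.fixture(scope="session")
def tiny_labelled_set() -> fs.SpectrumSet:
    """20+20 single-replicate samples over a short axis, strongly separable."""
    rng = np.random.default_rng(11)
    axis = np.arange(900.0, 980.0, 4.0)
    n = 20
    base = np.exp(-0.5 * ((axis - 940.0) / 10.0) ** 2)
    effect = 0.5 * np.exp(-0.5 * ((axis - 920.0) / 6.0) ** 2)
    control = base + rng.normal(0, 0.05, size=(n, axis.size))
    case = base + effect + rng.normal(0, 0.05, size=(n, axis.size))
    return fs.SpectrumSet(
        axis=axis,
        absorbance=np.vstack([control, case]),
        sample_id=np.arange(1, 2 * n + 1),
        replicate=np.ones(2 * n, dtype=int),
        label=np.array([fs.CONTROL] * n + [fs.CASE] * n, dtype=object),
    )
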