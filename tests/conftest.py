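"""Shared fixtures: small seeded synthetic databases."""

import warnings

import pytest

from ch4meta.simulate import SyntheticConfig, generate_database

# the ether-extract digestibility summary admits no exactly-matching
# truncated normal; the generator warns once about the least-squares fallback
warnings.filterwarnings(
    "ignore", message="truncated-normal moment match imperfect"
)


@pytest.fixture(scope="session")
def small_db():
    """Noisy combined-database draw: 30 studies x 5 treatments."""
    cfg = SyntheticConfig(database="combined", n_studies=30, treatments_per_study=5, seed=42)
    return generate_database(cfg)


@pytest.fixture(scope="session")
def noiseless_db():
    """Combined draw with all noise off: CH4 sits exactly on the true equation."""
    cfg = SyntheticConfig(
        database="combined",
        n_studies=40,
        treatments_per_study=5,
        seed=7,
        study_intercept_sd=0.0,
        study_slope_sd=0.0,
        residual_sd=0.0,
    )
    return generate_database(cfg)
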