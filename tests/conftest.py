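import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from iltox import (
    DescriptorTable,
    IonDescriptors,
    TrueModel,
    gen_ions,
    gen_panel,
    gen_systems,
    published_model,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def published():
    return published_model()


@pytest.fixture
def zero_ions():
    """An all-zero descriptor pair (probes the intercept alone)."""
    return (
        IonDescriptors("c0", "cation", 0, 0, 0, 0, 0, 0),
        IonDescriptors("a0", "anion", 0, 0, 0, 0, 0, 0),
    )


@pytest.fixture
def small_ions():
    """Hand-built two-cation / two-anion descriptor table."""
    return DescriptorTable(
        [
            IonDescriptors("C1", "cation", 0.3, 1.2, 0.1, 0.2, 1.5, 0.9),
            IonDescriptors("C2", "cation", 0.8, 2.0, 0.4, 0.5, 2.4, 1.2),
            IonDescriptors("A1", "anion", -0.2, 0.8, 0.1, 0.6, 0.7, -0.4),
            IonDescriptors("A2", "anion", 0.1, 1.5, 0.3, 1.1, 1.6, 0.2),
        ]
    )


@pytest.fixture
def make_panel():
    """Factory: synthetic multi-system panel plus its ground truth."""

    def _make(
        seed=0,
        n_cations=60,
        n_anions=30,
        n_systems=8,
        n_per_system=100,
        noise_sd=0.45,
        alpha_range=(1.0, 1.0),
        beta_range=(0.0, 0.0),
        z_range=(-1.9, 2.8),
        coefficients=None,
    ):
        ions = gen_ions(n_cations, n_anions, seed=seed)
        systems = gen_systems(
            n_systems, seed=seed + 1, z_range=z_range,
            alpha_range=alpha_range, beta_range=beta_range,
        )
        kwargs = {"systems": systems, "noise_sd": noise_sd}
        if coefficients is not None:
            kwargs["coefficients"] = coefficients
        true = TrueModel(**kwargs)
        records = gen_panel(true, ions, n_per_system=n_per_system, seed=seed + 2)
        return ions, true, records

    return _make
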