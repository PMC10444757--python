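from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dermalight import (
    ChromatophoreMSP,
    GeneratorConfig,
    default_pigment_models,
    generate_scans,
)
from dermalight.msp import default_grid, transition_wavelength

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid() -> np.ndarray:
    return default_grid()


@pytest.fixture(scope="session")
def noiseless_config() -> GeneratorConfig:
    """Default study conditions with measurement noise and cell jitter off."""
    return GeneratorConfig(noise_cv=0.0, jitter_sigma=0.0,
                           n_fish=1, cells_per_fish_per_type=1, seed=0)


@pytest.fixture(scope="session")
def noiseless_results(noiseless_config):
    """Fit of the noiseless default synthetic pipeline (415-nm template)."""
    scans = generate_scans(noiseless_config)
    return ChromatophoreMSP(scans).fit()


@pytest.fixture(scope="session")
def noisy_transition_samples():
    """Per-seed transition estimates for the stepped types at default noise.

    50 independent seeds of the full default replication (3 fish x 20 cells
    per type) for erythrophores and xanthophores.
    """
    models = default_pigment_models()
    stepped = {k: v for k, v in models.items() if k != "melanophore"}
    out: dict[str, list[float]] = {k: [] for k in stepped}
    for seed in range(50):
        config = GeneratorConfig(seed=seed)
        scans = generate_scans(config, stepped)
        results = ChromatophoreMSP(scans).fit()
        for ctype in stepped:
            out[ctype].append(results[ctype].transition_nm)
    return {k: np.asarray(v, dtype=float) for k, v in out.items()}
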