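import numpy as np
import pytest

from esospec import (
    SensorGeometry,
    SimulationConfig,
    fixture_cohort,
    impedance_to_permittivity,
)


@pytest.fixture(scope="session")
def geometry():
    return SensorGeometry(surface=2.0e-4, separation=0.20)


@pytest.fixture(scope="session")
def reference_cohort():
    return fixture_cohort()


@pytest.fixture
def default_config():
    return SimulationConfig(n_subjects=4)


@pytest.fixture
def simulated_perm(reference_cohort, default_config):
    """A noiseless simulated water sweep converted to permittivity."""
    from esospec import simulate_spectrum
    from esospec.spectra import MeasurementState
    from esospec.synth import DEFAULT_LIQUIDS
    from dataclasses import replace

    cfg = replace(default_config, noise_sd_mult=0.0)
    subject = reference_cohort[0]
    sweep, truth = simulate_spectrum(
        subject, DEFAULT_LIQUIDS[MeasurementState.WATER], cfg, seed=7
    )
    perm = impedance_to_permittivity(
        sweep, SensorGeometry(cfg.electrode_surface, subject.electrode_distance)
    )
    return perm, truth


def random_impedance_spectrum(rng, n_bins=16):
    """A random valid impedance sweep (capacitive, lossy)."""
    from esospec import ImpedanceSpectrum

    f = np.logspace(1, 7, n_bins) * rng.uniform(0.5, 2.0)
    r = rng.uniform(1e2, 1e6, size=n_bins)
    x = -rng.uniform(1e2, 1e6, size=n_bins)
    return ImpedanceSpectrum(frequencies=f, resistance=r, reactance=x)
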