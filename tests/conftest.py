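"""Shared fixtures: noise-free spectra and simulated cohorts.

Session scope keeps the expensive spectrum synthesis to one pass per run.
"""

import numpy as np
import pytest

import milknmr as m


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free acquisition parameters."""
    return m.AcquisitionParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def organic_spectrum(quiet_params):
    """Noise-free spectrum of the organic composition preset."""
    return m.simulate_spectrum(m.FattyAcidProfile.organic(), quiet_params)


@pytest.fixture(scope="session")
def organic_integrals(organic_spectrum):
    return m.extract_integral_set(organic_spectrum)


@pytest.fixture(scope="session")
def p_cohort():
    """P-style design: 14 organic vs 16 conventional, mixed fat subgroups."""
    spec = m.CohortSpec(
        n_per_class={"organic": 14, "conventional": 16},
        lipid_scale={"organic": 1.0, "conventional": [2.0] * 8 + [1.0] * 8},
        seed=5)
    spectra, labels, profiles = m.simulate_cohort(spec)
    return spectra, labels, profiles


@pytest.fixture(scope="session")
def p_bucket_matrix(p_cohort):
    spectra, labels, _ = p_cohort
    return m.BucketMatrix.from_spectra(spectra, labels)


@pytest.fixture(scope="session")
def marker_cohort():
    """Balanced equal-fat cohort with the preset class differences planted."""
    spec = m.CohortSpec(n_per_class=20, seed=11)
    spectra, labels, profiles = m.simulate_cohort(spec)
    return spectra, labels, profiles


@pytest.fixture(scope="session")
def marker_bucket_matrix(marker_cohort):
    spectra, labels, _ = marker_cohort
    return m.BucketMatrix.from_spectra(spectra, labels)


@pytest.fixture(scope="session")
def null_matrix():
    """Exchangeable-label data: both classes drawn from the same preset."""
    preset = m.FattyAcidProfile.organic()
    spec = m.CohortSpec(
        n_per_class=7,
        class_presets={"a": preset, "b": preset},
        seed=29)
    spectra, labels, _ = m.simulate_cohort(spec)
    return m.BucketMatrix.from_spectra(spectra, labels)


def integral_set(**overrides) -> m.IntegralSet:
    """Convenience constructor for hand-built integral sets."""
    base = dict(i088=200.0, i095=100.0, d=50.0, c=200.0, i277=2.0, i281=1.0,
                i499=1.0, i580=1.0, i599=0.2, i628=0.5)
    base.update(overrides)
    return m.IntegralSet(**base)
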