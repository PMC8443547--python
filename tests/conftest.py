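"""Shared fixtures: synthetic datasets and fitted feature tables.

Everything is generated programmatically at test time; the default dataset
(46 spectra, 14/20/12 per ripeness class) and its fitted feature table are
session-scoped because the 4-Lorentzian fits dominate the suite's runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

import palmraman as pr
from palmraman import deconv, features, preprocess, synth


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic dataset: 46 labeled spectra + ground truth."""
    return synth.generate_dataset()


def fit_all(spectra):
    fits, labels = {}, {}
    for spec in spectra:
        segment = preprocess.preprocess_spectrum(spec)
        fits[spec.sample_id] = deconv.fit_nu1_band(segment)
        labels[spec.sample_id] = spec.label
    return fits, labels


@pytest.fixture(scope="session")
def fitted(default_dataset):
    """Fits for every sample of the default dataset."""
    spectra, truth = default_dataset
    fits, labels = fit_all(spectra)
    return fits, labels, truth


@pytest.fixture(scope="session")
def feature_table(fitted):
    """The 46x17 fitted feature table for the default dataset."""
    fits, labels, _ = fitted
    return features.build_feature_table(fits, labels)


@pytest.fixture()
def noiseless_config():
    """Generator config with no noise, no baseline, no offset."""
    return synth.GeneratorConfig(
        noise_sd=0.0,
        baseline_slope=0.0,
        baseline_intercept=0.0,
        baseline_gauss_amplitude=0.0,
        offset=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
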