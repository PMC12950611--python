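"""Shared fixtures.

The expensive fixtures are session-scoped: a small two-pass cohort carried
through deconvolution and labeling (used by most integration tests), and
the full default-protocol study (20 patients) used by the acceptance-level
validation tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flimcore.classify import prepare_dataset
from flimcore.deconvolve import extract_features
from flimcore.instrument import InstrumentConfig
from flimcore.labeling import build_labeled_dataset
from flimcore.laguerre import build_laguerre_basis
from flimcore.simulate import CohortConfig, sample_cohort

DEFAULT_ALPHA = 0.8
LAGUERRE_ORDER = 12


@pytest.fixture(scope="session")
def instrument():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def small_instrument():
    """Short-record instrument for fast unit tests (120 ns window)."""
    return InstrumentConfig(n_samples=300, irf_peak_ns=8.0)


@pytest.fixture(scope="session")
def small_basis(small_instrument):
    return build_laguerre_basis(
        DEFAULT_ALPHA, LAGUERRE_ORDER, small_instrument.n_samples
    )


def _build_labeled(config: CohortConfig, instrument: InstrumentConfig,
                   drop_scans: bool = False):
    cohort = sample_cohort(config, instrument)
    b = build_laguerre_basis(DEFAULT_ALPHA, LAGUERRE_ORDER, instrument.n_samples)
    ops: dict = {}
    feats = pd.concat(
        [extract_features(s, instrument, b, operators=ops) for s in cohort.scans],
        ignore_index=True,
    )
    tracks = {t.core_id: t for t in cohort.tracks}
    lengths = {l.core_id: l.fresh_length_mm for l in cohort.layouts}
    labeled = build_labeled_dataset(feats, tracks, lengths)
    if drop_scans:
        cohort.scans.clear()
    return cohort, labeled


@pytest.fixture(scope="session")
def default_study(instrument):
    """The full default-protocol study: 20-patient cohort, both passes
    deconvolved, labeled with transition exclusion.  This is the dataset
    the validation-protocol tests run on."""
    config = CohortConfig()  # the default study conditions
    cohort, labeled = _build_labeled(config, instrument, drop_scans=True)
    dataset = prepare_dataset(labeled)
    return {
        "cohort": cohort,
        "labeled": labeled,
        "dataset": dataset,
        "instrument": instrument,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
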