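import numpy as np
import pandas as pd
import pytest

from actirhythm.epochs import EpochSeries
from actirhythm.pipeline import RunConfig, analyze_subject, build_cohort_table
from actirhythm.simulate import GeneratorConfig, generate_cohort


def make_series(mets, epoch_seconds=60, start="2018-06-04 00:00:00", valid=None, subject_id="T"):
    mets = np.asarray(mets, dtype=float)
    if valid is None:
        valid = np.ones(mets.size, dtype=bool)
    return EpochSeries(subject_id, pd.Timestamp(start), epoch_seconds, mets, np.asarray(valid, bool))


def cosinor_series(mesor, components, n_days=1, epoch_seconds=60, noise=0.0, rng=None):
    """Noise-free (or Gaussian-noise) cosinor signal on a regular grid."""
    n = n_days * int(round(86400 / epoch_seconds))
    t = np.arange(n) * (epoch_seconds / 3600.0)
    y = np.full(n, float(mesor))
    for period, amp, theta in components:
        y += amp * np.cos(2 * np.pi / period * t - theta)
    if noise:
        y += noise * (rng or np.random.default_rng(0)).standard_normal(n)
    return make_series(y, epoch_seconds=epoch_seconds)


@pytest.fixture(scope="session")
def default_cohort():
    """The default calibrated synthetic cohort (n=34, 5 weekdays, fixed seed)."""
    return generate_cohort(GeneratorConfig())


@pytest.fixture(scope="session")
def default_cohort_table(default_cohort):
    """Full per-subject analysis merged with covariates for the default cohort."""
    cfg = RunConfig()
    rows = [analyze_subject(s, cfg) for s in default_cohort.series]
    return build_cohort_table(default_cohort.records, rows)
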