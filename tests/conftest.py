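import numpy as np
import pytest

from rpnsig.preprocess import RegionalTimeseries
from rpnsig.qst import ReferenceStats
from rpnsig.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12 subjects, 8 regions + global node, enough frames to survive QC."""
    cfg = SyntheticConfig(
        n_subjects=12, n_regions=8, n_frames=150,
        planted_edges=((0, 1), (2, 3)), seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_reference():
    cfg = SyntheticConfig()
    return ReferenceStats(
        hpt_mu=cfg.hpt_mu, hpt_sd=cfg.hpt_sd,
        cpt_mu=cfg.cpt_mu, cpt_sd=cfg.cpt_sd,
        mpt_mu=cfg.mpt_mu, mpt_sd=cfg.mpt_sd,
        source="test",
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_timeseries(data, tr=2.5, modules=None):
    data = np.asarray(data, dtype=float)
    labels = [f"n{i}" for i in range(data.shape[1])]
    return RegionalTimeseries(data=data, labels=labels, tr=tr, modules=modules)
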