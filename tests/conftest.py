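import numpy as np
import pandas as pd
import pytest

from oncoage.containers import SegmentProfile
from oncoage.genome import ArmModel
from oncoage.simulate import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def toy_arms() -> ArmModel:
    return ArmModel.toy()


@pytest.fixture(scope="session")
def hg19_arms() -> ArmModel:
    return ArmModel.hg19()


@pytest.fixture(scope="session")
def small_cohort(toy_arms):
    """One seeded endometrial-like cohort shared across read-only tests."""
    params = SimulationParams(n_samples=60, seed=11, n_genes=120, n_age_genes=12)
    return simulate_cohort(params, toy_arms)


def make_profile(rows, sample_id="T1", **kw) -> SegmentProfile:
    """Build a profile from (chrom, start, end, n_major, n_minor) tuples."""
    seg = pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "n_major", "n_minor"]
    )
    return SegmentProfile(sample_id=sample_id, segments=seg, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
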