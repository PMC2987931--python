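import numpy as np
import pandas as pd
import pytest

from trisomethyl.simulate import (
    CohortConfig,
    LocusEffectSpec,
    generate_cohort,
    table1_default_config,
)
from trisomethyl.types import BetaMatrix, ProbeAnnotation, SampleSheet


@pytest.fixture(scope="session")
def small_cohort():
    """A fast default-panel cohort: 29 DS / 20 controls, 100 null loci,
    beta matrix only."""
    cfg = table1_default_config(
        seed=101, n_null_loci=100,
        include_msnp=False, include_pyroseq=False, include_expression=False,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def full_cohort():
    """A small cohort with every assay layer generated."""
    cfg = table1_default_config(seed=202, n_ds=12, n_ctrl=10, n_null_loci=30)
    return generate_cohort(cfg)


@pytest.fixture
def tiny_annotation():
    return ProbeAnnotation(pd.DataFrame({
        "probe_id": ["p1", "p2", "p3", "px", "py"],
        "chrom": ["21", "2", "5", "X", "Y"],
        "position": [100, 200, 50, 10, 20],
        "gene": ["G1", "G2", "G3", "GX", "GY"],
        "cgi_flag": [True, False, False, False, False],
        "assay_class": ["infinium_cpg"] * 5,
    }))


def make_beta(values, probes=None, samples=None) -> BetaMatrix:
    arr = np.asarray(values, float)
    probes = probes or [f"p{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=pd.Index(probes, name="probe_id"),
                                   columns=samples))


def make_groups(n_ds, n_ctrl):
    ids = [f"s{j + 1}" for j in range(n_ds + n_ctrl)]
    return pd.Series(["DS"] * n_ds + ["control"] * n_ctrl, index=ids)
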