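import numpy as np
import pandas as pd
import pytest

from cfpanel.data_model import BetaMatrix, ProbeAnnotation
from cfpanel.simulate import SyntheticConfig, generate_study


def make_beta(values, groups, substrate="tissue", probe_ids=None,
              sample_ids=None) -> BetaMatrix:
    """Hand-rolled BetaMatrix from a nested list (samples x probes)."""
    arr = np.asarray(values, dtype=float)
    n, p = arr.shape
    probes = probe_ids or [f"cg{j:08d}" for j in range(p)]
    samples = sample_ids or [f"s{i}" for i in range(n)]
    df = pd.DataFrame(arr, index=pd.Index(samples, name="sample_id"),
                      columns=probes)
    return BetaMatrix(df,
                      pd.Series(list(groups), index=df.index, name="group"),
                      pd.Series(substrate, index=df.index, name="substrate"))


def make_annotation(probe_ids, chromosomes=None, features=None,
                    snp=None) -> ProbeAnnotation:
    p = len(probe_ids)
    return ProbeAnnotation(pd.DataFrame({
        "chromosome": chromosomes or ["chr1"] * p,
        "position": np.arange(1, p + 1) * 1000,
        "feature": features or ["promoter"] * p,
        "distance_to_tss": [0] * p,
        "snp_associated": snp or [False] * p,
    }, index=pd.Index(probe_ids, name="probe_id")))


@pytest.fixture(scope="session")
def small_study():
    """One small synthetic study shared by read-only tests."""
    cfg = SyntheticConfig(n_probes=400, n_hyper_markers=10, n_hypo_markers=10,
                          seed=7)
    bundles, truth = generate_study(cfg)
    return cfg, bundles, truth
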