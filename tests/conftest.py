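import numpy as np
import pandas as pd
import pytest

from cmapbench.synth import ConditionKey, CorpusSpec, generate_ground_truth, simulate_corpus
from cmapbench.de import DEProfile


@pytest.fixture(scope="session")
def small_spec():
    """A small but replicated corpus: 6 compounds, 1 cell line, 3 doses."""
    return CorpusSpec(
        n_genes=400,
        n_landmark=50,
        compounds=[f"cpd{i:02d}" for i in range(6)],
        concentrations=[0.1, 1.0, 10.0],
        cell_lines=["MCF7"],
        n_replicate_profiles=3,
        n_samples_per_group=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_spec():
    """Zero noise everywhere: DE recovers the planted signal exactly."""
    return CorpusSpec(
        n_genes=400,
        n_landmark=50,
        compounds=[f"cpd{i:02d}" for i in range(6)],
        concentrations=[1.0, 100.0],
        cell_lines=["MCF7"],
        n_replicate_profiles=2,
        n_samples_per_group=3,
        sample_noise_sd=0.0,
        platform_noise_sd=0.0,
        plate_effect_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    truth = generate_ground_truth(small_spec)
    return truth, simulate_corpus(truth, small_spec, "A")


@pytest.fixture(scope="session")
def noiseless_corpus(noiseless_spec):
    truth = generate_ground_truth(noiseless_spec)
    return truth, simulate_corpus(truth, noiseless_spec, "A")


def make_profile(values, kind="FC", n=4, compound="cpdX", conc=10.0, cell="MCF7",
                 replicate_id="r0", gene_prefix="G"):
    """Helper: wrap a plain value vector into a DEProfile."""
    vals = np.asarray(values, dtype=float)
    idx = pd.Index([f"{gene_prefix}{i:04d}" for i in range(vals.size)], name="gene_id")
    return DEProfile(
        condition=ConditionKey(compound, conc, cell, 6.0),
        kind=kind,
        values=pd.Series(vals, index=idx),
        n_contributing_replicates=n,
        replicate_id=replicate_id,
    )


@pytest.fixture
def profile_factory():
    return make_profile
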