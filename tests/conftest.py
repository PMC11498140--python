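import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dispersalshare import AsvTable, SampleRecord, SimulationConfig, generate_study
from dispersalshare.asv_tables import TaxonomyTable


@pytest.fixture
def toy_table():
    return AsvTable(
        sample_ids=["s1", "s2", "s3"],
        asv_ids=["a", "b", "c", "d"],
        counts=np.array(
            [
                [3, 0, 1, 0],
                [0, 2, 2, 0],
                [5, 5, 0, 1],
            ]
        ),
    )


@pytest.fixture
def toy_taxonomy():
    return TaxonomyTable(
        {
            "a": ("Bacteria", "Firmicutes", "Bacilli"),
            "b": ("Bacteria", "Cyanobacteria", "Chloroplast"),
            "c": ("Bacteria", "Proteobacteria", "Gammaproteobacteria"),
            "d": ("Eukaryota", "Fungi"),
        }
    )


@pytest.fixture
def small_study():
    cfg = SimulationConfig(n_subjects=8, seed=123, missing_fraction=0.0,
                           antibiotics_prevalence=0.0)
    return generate_study(cfg)


def make_glmm_data(
    rng,
    n_subjects=40,
    beta0=-1.5,
    beta_x=0.0,
    beta_tp=(0.0, 0.4),
    sigma=0.4,
    n_range=(80, 200),
    interaction=(0.0, 0.0),
    timepoints=("S", "A", "W"),
):
    """Simulate a (subject, timepoint) binomial panel for GLMM tests."""
    n_tp = len(timepoints)
    subj = np.repeat([f"s{i:03d}" for i in range(n_subjects)], n_tp)
    tp = np.tile(list(timepoints), n_subjects)
    x = np.repeat(rng.normal(size=n_subjects), n_tp)
    b = np.repeat(rng.normal(0.0, sigma, size=n_subjects), n_tp)
    eta = beta0 + beta_x * x + b
    for level, offset, inter in zip(("A", "W"), beta_tp, interaction):
        mask = tp == level
        eta = eta + mask * offset + mask * inter * x
    n = rng.integers(n_range[0], n_range[1] + 1, size=len(subj))
    k = rng.binomial(n, expit(eta))
    return pd.DataFrame(
        {"subject": subj, "timepoint": tp, "k": k, "n": n, "built": x}
    )


@pytest.fixture
def glmm_data():
    rng = np.random.default_rng(7)
    return make_glmm_data(rng, beta_x=0.8)


def records_for(ids, subject_type_tp):
    """Helper: build SampleRecords from (subject, type, timepoint) triples."""
    return [
        SampleRecord(sid, subj, stype, tp)
        for sid, (subj, stype, tp) in zip(ids, subject_type_tp)
    ]
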