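import numpy as np
import pandas as pd
import pytest

from noiseplast.chromatin import cre_score, normalize_profiles
from noiseplast.simulate import SyntheticConfig, generate_dataset
from noiseplast.variability import classify_variability


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: 2000 genes, 170 mutants, seed 1."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 400-gene dataset for structural (non-recovery) checks."""
    return generate_dataset(SyntheticConfig(n_genes=400, seed=3))


@pytest.fixture(scope="session")
def default_classes(default_dataset):
    return classify_variability(default_dataset.gene_table)


@pytest.fixture(scope="session")
def default_responsiveness(default_dataset):
    return normalize_profiles(default_dataset.compendium)


@pytest.fixture(scope="session")
def default_cre(default_responsiveness):
    return cre_score(default_responsiveness)


@pytest.fixture
def tiny_transcripts():
    """Hand-laid transcript set exercising every neighborhood geometry.

    chrA (+ focal g1 at 5000..6000):
      p1  - strand 4000..4800  -> divergent partner of g1, distance 200
      g2  + strand 7000..8000  -> parallel partner = g1 (TES 6000), distance 1000
    chrB (- focal g3 at tss 9000):
      p2  + strand 9300..9900  -> divergent partner of g3, distance 300
    """
    return pd.DataFrame({
        "transcript_id": ["g1", "p1", "g2", "g3", "p2"],
        "kind": ["ORF_T", "ORF_T", "ORF_T", "ORF_T", "ORF_T"],
        "chrom": ["chrA", "chrA", "chrA", "chrB", "chrB"],
        "strand": ["+", "-", "+", "-", "+"],
        "tss": [5000, 4800, 7000, 9000, 9300],
        "tes": [6000, 4000, 8000, 8500, 9900],
        "status": ["verified"] * 5,
        "bipromoter": [False, False, False, False, False],
    })
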