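import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from wseq.core import CountExperiment
from wseq.dimorphism import estimate_dispersions
from wseq.synthetic import SimConfig, simulate_counts

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study (seed 42): experiment + ground truth."""
    return simulate_counts(SimConfig())


@pytest.fixture(scope="session")
def default_experiment(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def default_truth(default_sim):
    return default_sim[1]


@pytest.fixture(scope="session")
def default_dispersions(default_experiment):
    return estimate_dispersions(default_experiment)


@pytest.fixture(scope="session")
def null_sim():
    """2000 autosomal genes with every effect switched off."""
    cfg = SimConfig(
        n_genes_per_class={"autosome": 2000},
        n_dimorphic_autosomal_per_tissue=0,
        n_tissue_de_genes=0,
        z_male_ratio=1.0,
        n_mhm_genes=0,
        seed=7,
    )
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def null_dispersions(null_sim):
    return estimate_dispersions(null_sim[0])


def make_experiment(counts: dict, tissues=None, sexes=None, lib=1e6):
    """Small hand-built experiment: counts maps gene -> 8 sample values.

    Sample order: blastoderm F1 F2 M1 M2, gonad F1 F2 M1 M2.
    """
    samples = [
        f"{t}_{x}_{r}"
        for t in ("blastoderm", "gonad")
        for x in ("F", "M")
        for r in (1, 2)
    ]
    design = pd.DataFrame(
        {
            "tissue": [s.split("_")[0] for s in samples],
            "sex": [s.split("_")[1] for s in samples],
            "replicate": [int(s.split("_")[2]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    counts_df = pd.DataFrame(counts, index=samples).T.astype(int)
    counts_df.index.name = "gene_id"
    ann = pd.DataFrame(
        {"chrom_class": "autosome", "length": 1000},
        index=counts_df.index,
    )
    return CountExperiment(
        counts=counts_df,
        design=design,
        library_sizes=pd.Series(float(lib), index=samples),
        annotation=ann,
    )
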