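import numpy as np
import pandas as pd
import pytest

from progcnv import CnvCallMatrix, SyntheticConfig, generate_bundle


def small_config(seed: int = 7, **overrides) -> SyntheticConfig:
    """A fast cohort: 60 genes x 150 samples, 4 planted drivers.

    Gain fraction 0.4 keeps the planted genes above the frequent-CNG
    sample cut-off (60 gained samples > 30) at this cohort size.
    """
    fields = dict(
        n_genes=60,
        n_samples=150,
        n_cohorts=2,
        n_reference_samples=25,
        planted_genes=["DRVA", "DRVB", "DRVC", "DRVD"],
        planted_gain_fraction=0.4,
        dosage_shift=3.0,
        background_gain_rate=0.03,
        background_loss_rate=0.03,
        n_gene_sets=6,
        planted_set_overlap=3,
        gene_set_size=12,
        seed=seed,
    )
    fields.update(overrides)
    return SyntheticConfig(**fields)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_bundle(small_config())


@pytest.fixture(scope="session")
def default_bundle():
    """The standard study conditions: 500 genes x 600 samples, seed 0."""
    return generate_bundle(SyntheticConfig(seed=0))


def random_cnv_matrix(rng: np.random.Generator, n_genes: int = 8,
                      n_samples: int = 12, n_cohorts: int = 2) -> CnvCallMatrix:
    calls = rng.choice(["GAIN", "LOSS", "NEUTRAL"], size=(n_genes, n_samples),
                       p=[0.25, 0.25, 0.5])
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{j}" for j in range(n_samples)]
    cohorts = pd.Series([f"c{j % n_cohorts}" for j in range(n_samples)],
                        index=samples)
    return CnvCallMatrix(
        calls=pd.DataFrame(calls, index=genes, columns=samples),
        cohorts=cohorts,
    )
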