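import numpy as np
import pandas as pd
import pytest

from rdnaclock import methylation, simdata


@pytest.fixture
def tiny_config():
    """Small, fast design: 3 cohorts, 20 loci, light coverage."""
    return simdata.SimulationConfig(
        n_loci=20,
        frac_informative=0.6,
        cohort_ages_months=[0.0, 12.0, 30.0],
        cohort_sizes=[8, 8, 8],
        batch2_cohorts=[],
        n_wild=4,
        coverage_mean=800.0,
        coverage_mean_batch2=800.0,
        sd_individual=1.0,
        seed=42,
    )


@pytest.fixture
def tiny_dataset(tiny_config):
    return simdata.simulate_dataset(tiny_config)


@pytest.fixture
def tiny_matrix(tiny_dataset):
    """QC'd matrix plus known-age vector for the tiny design."""
    panel, sheet, table, truth = tiny_dataset
    matrix, _ = methylation.apply_qc(table)
    known = sheet.index[sheet["age_months"].notna()]
    sub = methylation.MethylationMatrix(
        values=matrix.values.loc[known], loci=matrix.loci
    )
    ages = sheet.loc[known, "age_months"].astype(float)
    return sub, ages, sheet


def make_counts(records):
    """Shorthand: records = {(sample, locus): (meth, unmeth)}."""
    return methylation.MethylCountTable.from_records(records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
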