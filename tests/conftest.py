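"""Shared fixtures: small simulated populations and genotype builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clovergs.genotype_qc import MISSING, GenotypeData
from clovergs.synthetic_data import (
    SimConfig,
    simulate_gbs_reads,
    simulate_population,
    simulate_trial_phenotypes,
)


def make_genotypes(
    dosage: np.ndarray,
    depth: int = 30,
    sample_ids: list[str] | None = None,
) -> GenotypeData:
    """GenotypeData with read counts exactly consistent with the dosages.

    ``alt_reads = dosage * depth / 2`` so the fractional dosage estimate
    2*alt/depth reproduces the call exactly; missing calls get zero depth.
    """
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    obs = dosage != MISSING
    alt = np.where(obs, dosage.astype(np.int64) * depth // 2, 0)
    dp = np.where(obs, depth, 0)
    ref = dp - alt
    info = pd.DataFrame(
        {
            "id": [f"M{j + 1:04d}" for j in range(m)],
            "chrom": "chr1",
            "pos": np.arange(1, m + 1) * 10,
            "ref": "A",
            "alt": "C",
        }
    )
    return GenotypeData(
        dosage=dosage,
        ref_reads=ref,
        alt_reads=alt,
        marker_info=info,
        sample_ids=sample_ids or [f"S{i + 1:03d}" for i in range(n)],
        has_depth=True,
    )


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_families=60,
        seedlings_per_family=20,
        n_markers=600,
        n_qtl=60,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_pop(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def small_geno(small_pop):
    return simulate_gbs_reads(small_pop, mean_depth=10.0, depth_dispersion=2.0, seed=102)


@pytest.fixture(scope="session")
def small_pheno(small_pop, small_config):
    return simulate_trial_phenotypes(small_pop, small_config, seed=103)
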