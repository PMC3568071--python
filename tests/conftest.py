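import numpy as np
import pandas as pd
import pytest

from snpgsea.config import SimulationConfig
from snpgsea.datamodel import GeneAnnotation, GenotypeMatrix
from snpgsea.simulate import (
    simulate_annotation,
    simulate_case_control,
    simulate_snp_map,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_cases=60, n_controls=60, n_trios=40,
        n_chromosomes=2, genes_per_chromosome=25,
        gene_length_range=(20_000, 60_000),
        intergenic_gap_range=(5_000, 30_000),
        snp_spacing_range=(4_000, 12_000),
        maf_range=(0.1, 0.5), seed=11,
    )


@pytest.fixture(scope="session")
def small_annotation(small_config):
    return simulate_annotation(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config, small_annotation):
    return simulate_snp_map(small_config, small_annotation)


@pytest.fixture(scope="session")
def null_big():
    """Large null case-control simulation shared by calibration tests."""
    cfg = SimulationConfig(
        n_cases=150, n_controls=150, n_chromosomes=8,
        genes_per_chromosome=40, gene_length_range=(20_000, 60_000),
        intergenic_gap_range=(5_000, 30_000),
        snp_spacing_range=(4_000, 12_000), maf_range=(0.1, 0.5), seed=23,
    )
    ann = simulate_annotation(cfg)
    panel = simulate_snp_map(cfg, ann)
    matrix = simulate_case_control(cfg, ann, panel)
    return cfg, ann, panel, matrix


def toy_matrix(dosages, phenotype=None, chrom="1"):
    """Build a GenotypeMatrix from a plain dosage array for unit tests."""
    d = np.asarray(dosages, dtype=float)
    n_subj, n_snps = d.shape
    snps = pd.DataFrame({
        "snp": [f"s{j}" for j in range(n_snps)],
        "chrom": chrom,
        "pos": np.arange(1, n_snps + 1) * 1000,
        "allele1": "A", "allele2": "B",
    })
    subjects = pd.DataFrame({
        "family": [f"F{i}" for i in range(n_subj)],
        "individual": [f"I{i}" for i in range(n_subj)],
        "father": "0", "mother": "0", "sex": 0,
        "phenotype": (np.full(n_subj, np.nan) if phenotype is None
                      else np.asarray(phenotype, dtype=float)),
    })
    return GenotypeMatrix(d, snps, subjects)


def toy_annotation(rows):
    """rows: (gene, chrom, strand, tx_start, tx_end)."""
    return GeneAnnotation(pd.DataFrame(
        rows, columns=["gene", "chrom", "strand", "tx_start", "tx_end"]))
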