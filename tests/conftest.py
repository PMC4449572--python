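"""Shared fixtures: small simulated datasets with known ground truth."""
import numpy as np
import pytest

from trajgwas.data import PedigreeTable, TrajectoryRecordSet
from trajgwas.kinship import build_A
from trajgwas.rrmodel import VarianceComponents
from trajgwas.simulate import (
    SimulationConfig,
    simulate_genotypes,
    simulate_pedigree,
    simulate_phenotypes,
)

DEFAULT_GA = np.diag([4.0, 1.0, 0.25])
DEFAULT_PE = np.diag([2.0, 0.5, 0.1])
DEFAULT_SE2 = 4.0


@pytest.fixture
def default_vc():
    return VarianceComponents(DEFAULT_GA.copy(), DEFAULT_PE.copy(), DEFAULT_SE2)


def simulate_with_founder_freq(cfg: SimulationConfig):
    """Pedigree + genotypes + phenotypes with founder frequencies returned."""
    ped = simulate_pedigree(cfg)
    geno, maf = simulate_genotypes(ped, cfg)
    records, truth = simulate_phenotypes(ped, geno, cfg, founder_freq=maf)
    return ped, geno, records, truth, maf


def unrelated_panel(seed, qtl=(), genetic_cov=None, n=300, n_chrom=5,
                    n_snp_per_chrom=200):
    """Association panel of mutually unrelated genotyped animals.

    Simulates a pedigree whose founder cohort has size ``n`` and restricts
    genotypes and records to the founders, yielding an identity A.
    """
    cfg = SimulationConfig(
        n_founders=n,
        n_generations=1,
        n_chrom=n_chrom,
        n_snp_per_chrom=n_snp_per_chrom,
        seed=seed,
        qtl_spec=qtl,
        **({"genetic_cov": genetic_cov} if genetic_cov is not None else {}),
    )
    ped, geno, records, truth, maf = simulate_with_founder_freq(cfg)
    founders = ped.animal[ped.is_founder]
    sub = records.df[records.df["animal"].isin(founders)].reset_index(drop=True)
    pedf = PedigreeTable(
        founders,
        np.zeros(len(founders), dtype=np.int64),
        np.zeros(len(founders), dtype=np.int64),
    )
    genof = geno.subset(animal_keep=np.isin(geno.animal, founders))
    fmask = ped.is_founder
    truth_sub = truth
    return cfg, pedf, genof, TrajectoryRecordSet(sub), truth_sub, fmask


@pytest.fixture(scope="session")
def small_dataset():
    """90-animal, 3-generation dataset used by several module tests."""
    cfg = SimulationConfig(
        n_founders=30, n_generations=2, n_chrom=2, n_snp_per_chrom=60, seed=3
    )
    ped, geno, records, truth, maf = simulate_with_founder_freq(cfg)
    return {
        "cfg": cfg, "ped": ped, "geno": geno, "records": records,
        "truth": truth, "maf": maf, "A": build_A(ped),
    }
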