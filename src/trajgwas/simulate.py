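"""Synthetic pedigrees, genotypes and longitudinal phenotypes.

The generator reproduces the statistical structure the analysis assumes: a
multi-generation pedigree, gene-dropped biallelic genotypes, animal-specific
order-2 Legendre genetic and permanent-environment coefficient effects with
known 3x3 covariances, optional QTL effects attached to specific
coefficients, contemporary-group and parity fixed effects, homogeneous
residual noise, and per-animal on-test windows covering roughly ages
90-175 d.  Ground truth (coefficient breeding values, QTL effects, variance
components) is returned for parameter-recovery and power studies.

Polygenic coefficient breeding values follow a sequential gene-drop:
founders ~ N(0, G_a); offspring = (sire + dam)/2 + Mendelian sampling
~ N(0, G_a/2).  Inbreeding is ignored in the Mendelian-sampling variance;
validation against pedigree expectations uses the realized values, so
A-based oracles stay exact.  QTL effects are superimposed on the polygenic
variance: the total genetic variance exceeds ``genetic_cov`` unless the
caller compensates.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .basis import AgeStandardizer, legendre_matrix
from .data import GenotypeMatrix, PedigreeTable, TrajectoryRecordSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_dataset",
]


def _check_psd(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.shape != (3, 3) or not np.allclose(M, M.T):
        raise ValueError(f"{name} must be a symmetric 3x3 matrix")
    if np.linalg.eigvalsh(M).min() < -1e-10:
        raise ValueError(f"{name} must be positive semi-definite")
    return M


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic data generator.

    Defaults emulate a desk-scale version of a grow-finish boar test:
    a 3-generation pedigree, on-test windows of roughly 90-175 d of age,
    coefficient-scale genetic covariance diag(4, 1, 0.25), permanent
    environment diag(2, 0.5, 0.1) and residual variance 4.
    """

    n_founders: int = 40
    n_generations: int = 3
    n_snp_per_chrom: int = 100
    n_chrom: int = 5
    maf_range: tuple[float, float] = (0.1, 0.5)
    genetic_cov: np.ndarray = field(
        default_factory=lambda: np.diag([4.0, 1.0, 0.25])
    )
    pe_cov: np.ndarray = field(default_factory=lambda: np.diag([2.0, 0.5, 0.1]))
    resid_var: float = 4.0
    #: list of (chrom, snp_index_within_chrom, coefficient 0..2, effect size)
    qtl_spec: tuple = ()
    n_cg: int = 8
    cg_sd: float = 2.0
    parity_effects: tuple[float, float, float] = (0.0, 1.0, 1.5)
    mean: float = 70.0
    fixed_regression: tuple[float, float, float] = (0.0, 25.0, 3.0)
    #: ((onset mean, onset sd), (length mean, length sd)) in days
    age_window: tuple[tuple[float, float], tuple[float, float]] = (
        (90.0, 3.0),
        (80.0, 6.0),
    )
    obs_per_day: float = 0.7
    age_min: float = 80.0
    age_max: float = 185.0
    normalized_basis: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.genetic_cov = _check_psd(self.genetic_cov, "genetic_cov")
        self.pe_cov = _check_psd(self.pe_cov, "pe_cov")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders to mate")
        if self.n_generations < 1:
            raise ValueError("need at least one non-founder generation")
        if self.resid_var < 0:
            raise ValueError("resid_var must be non-negative")
        n_snp = self.n_snp_per_chrom
        for chrom, snp, coeff, _ in self.qtl_spec:
            if not (0 <= chrom < self.n_chrom and 0 <= snp < n_snp):
                raise ValueError(f"qtl_spec addresses missing SNP ({chrom},{snp})")
            if coeff not in (0, 1, 2):
                raise ValueError("qtl coefficient index must be 0, 1 or 2")

    @property
    def standardizer(self) -> AgeStandardizer:
        return AgeStandardizer(self.age_min, self.age_max)

    def _rng(self, stage: int) -> np.random.Generator:
        # per-stage stream so each generator is individually reproducible
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))


@dataclass
class GroundTruth:
    """Realized simulation truth for validation studies."""

    u_polygenic: np.ndarray  # (n_animals, 3)
    u_qtl: np.ndarray  # (n_animals, 3) marker contribution
    pe: np.ndarray  # (n_animals, 3)
    qtl_effects: tuple  # echo of qtl_spec
    qtl_snp_index: np.ndarray  # global SNP column per QTL
    genetic_cov: np.ndarray
    pe_cov: np.ndarray
    resid_var: float
    cg_effects: np.ndarray
    parity_effects: np.ndarray

    @property
    def u_total(self) -> np.ndarray:
        """Total genetic coefficient value = polygenic + QTL contribution."""
        return self.u_polygenic + self.u_qtl


def simulate_pedigree(cfg: SimulationConfig) -> PedigreeTable:
    """Random-mating pedigree: each generation the size of the founder cohort.

    Animals get consecutive integer ids starting at 1; sires are drawn from
    the first half of the previous generation, dams from the second half,
    so the table is topologically ordered by construction.
    """
    rng = cfg._rng(1)
    n = cfg.n_founders
    animal = list(range(1, n + 1))
    sire = [0] * n
    dam = [0] * n
    prev = np.arange(1, n + 1)
    next_id = n + 1
    for _ in range(cfg.n_generations):
        half = max(1, len(prev) // 2)
        males, females = prev[:half], prev[half:]
        if len(females) == 0:
            females = prev[-1:]
        cur = []
        for _ in range(n):
            animal.append(next_id)
            sire.append(int(rng.choice(males)))
            dam.append(int(rng.choice(females)))
            cur.append(next_id)
            next_id += 1
        prev = np.asarray(cur)
    return PedigreeTable(np.asarray(animal), np.asarray(sire), np.asarray(dam))


def simulate_genotypes(
    ped: PedigreeTable, cfg: SimulationConfig
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Gene-drop biallelic genotypes down the pedigree.

    Founder gametes are drawn from Hardy-Weinberg proportions at MAF
    ~ Uniform(maf_range); every non-founder inherits one allele per parent
    per locus, independently across loci (LD arises only through pedigree
    co-segregation).  Returns the matrix and the founder allele frequencies.
    """
    rng = cfg._rng(2)
    m = cfg.n_chrom * cfg.n_snp_per_chrom
    maf = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    n = len(ped)
    # paternal / maternal allele per animal per locus
    pat = np.empty((n, m), dtype=np.int8)
    mat = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        if si < 0:
            pat[i] = rng.random(m) < maf
        else:
            which = rng.integers(0, 2, size=m, dtype=np.int8)
            pat[i] = np.where(which, pat[si], mat[si])
        if di < 0:
            mat[i] = rng.random(m) < maf
        else:
            which = rng.integers(0, 2, size=m, dtype=np.int8)
            mat[i] = np.where(which, pat[di], mat[di])
    codes = (pat + mat).astype(np.int8)
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{c + 1}_{s + 1}"
                       for c in range(cfg.n_chrom)
                       for s in range(cfg.n_snp_per_chrom)],
            "chrom": np.repeat(np.arange(1, cfg.n_chrom + 1), cfg.n_snp_per_chrom),
            "pos": np.tile(
                (np.arange(cfg.n_snp_per_chrom) + 1) * 10_000, cfg.n_chrom
            ),
        }
    )
    return GenotypeMatrix(ped.animal, codes, snp_map), maf


def _polygenic_gene_drop(
    ped: PedigreeTable, cov: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    n = len(ped)
    u = np.empty((n, 3))
    # Cholesky with PSD fallback (zero or rank-deficient covariances allowed)
    L = _psd_chol(cov)
    founders_draw = rng.standard_normal((n, 3)) @ L.T
    mendelian = rng.standard_normal((n, 3)) @ (L.T / np.sqrt(2.0))
    for i in range(n):
        si, di = ped.sire_idx[i], ped.dam_idx[i]
        if si < 0 and di < 0:
            u[i] = founders_draw[i]
        else:
            parent_mean = np.zeros(3)
            if si >= 0:
                parent_mean += u[si]
            if di >= 0:
                parent_mean += u[di]
            u[i] = parent_mean / 2.0 + mendelian[i]
    return u


def _psd_chol(M: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(M)
        return V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_phenotypes(
    ped: PedigreeTable,
    geno: GenotypeMatrix,
    cfg: SimulationConfig,
    founder_freq: np.ndarray | None = None,
) -> tuple[TrajectoryRecordSet, GroundTruth]:
    """Generate longitudinal records from the random-regression model.

    Each record is mu + CG + parity + phi(t)'(beta + u_total + pe) + e with
    u_total the polygenic gene-drop plus the configured QTL contributions
    (centered gene content times effect size, so QTL genotype class means
    differ by twice the effect).
    """
    rng = cfg._rng(3)
    n = len(ped)
    u_poly = _polygenic_gene_drop(ped, cfg.genetic_cov, rng)
    pe = rng.standard_normal((n, 3)) @ _psd_chol(cfg.pe_cov).T

    u_qtl = np.zeros((n, 3))
    qtl_cols = []
    p_ref = founder_freq if founder_freq is not None else geno.allele_freq()
    for chrom, snp, coeff, effect in cfg.qtl_spec:
        col = chrom * cfg.n_snp_per_chrom + snp
        qtl_cols.append(col)
        z = geno.codes[:, col].astype(float) - 2.0 * p_ref[col]
        u_qtl[:, coeff] += z * effect

    cg_effects = rng.normal(0.0, cfg.cg_sd, size=cfg.n_cg)
    parity_effects = np.asarray(cfg.parity_effects, dtype=float)
    beta = np.asarray(cfg.fixed_regression, dtype=float)
    std = cfg.standardizer

    # CG by birth-batch round-robin over pedigree order; parity uniform 1..3
    cg = np.arange(n) * cfg.n_cg // n
    parity = rng.integers(1, 4, size=n)

    (on_mu, on_sd), (len_mu, len_sd) = cfg.age_window
    rows_animal, rows_age, rows_cg, rows_parity = [], [], [], []
    for i in range(n):
        onset = rng.normal(on_mu, on_sd)
        length = max(1.0, rng.normal(len_mu, len_sd))
        lo = int(np.clip(np.round(onset), cfg.age_min, cfg.age_max))
        hi = int(np.clip(np.round(onset + length), cfg.age_min, cfg.age_max))
        days = np.arange(lo, hi + 1)
        days = days[rng.random(len(days)) < cfg.obs_per_day]
        if len(days) == 0:
            days = np.asarray([lo])
        rows_animal.append(np.full(len(days), ped.animal[i]))
        rows_age.append(days)
        rows_cg.append(np.full(len(days), cg[i]))
        rows_parity.append(np.full(len(days), parity[i]))
    animal_col = np.concatenate(rows_animal)
    age_col = np.concatenate(rows_age).astype(float)
    cg_col = np.concatenate(rows_cg)
    parity_col = np.concatenate(rows_parity)

    phi = legendre_matrix(std.transform(age_col), normalized=cfg.normalized_basis)
    aidx = ped.index_of(animal_col)
    coef = beta + (u_poly + u_qtl + pe)[aidx]
    value = (
        cfg.mean
        + cg_effects[cg_col]
        + parity_effects[parity_col - 1]
        + np.einsum("ij,ij->i", phi, coef)
        + rng.normal(0.0, np.sqrt(cfg.resid_var), size=len(age_col))
    )
    records = TrajectoryRecordSet(
        pd.DataFrame(
            {
                "animal": animal_col,
                "age_days": age_col,
                "value": value,
                "cg": cg_col,
                "parity": parity_col,
            }
        )
    )
    truth = GroundTruth(
        u_polygenic=u_poly,
        u_qtl=u_qtl,
        pe=pe,
        qtl_effects=tuple(cfg.qtl_spec),
        qtl_snp_index=np.asarray(qtl_cols, dtype=np.int64),
        genetic_cov=cfg.genetic_cov,
        pe_cov=cfg.pe_cov,
        resid_var=cfg.resid_var,
        cg_effects=cg_effects,
        parity_effects=parity_effects,
    )
    return records, truth


def simulate_dataset(cfg: SimulationConfig):
    """Convenience: pedigree + genotypes + phenotypes in one call."""
    ped = simulate_pedigree(cfg)
    geno, maf = simulate_genotypes(ped, cfg)
    records, truth = simulate_phenotypes(ped, geno, cfg, founder_freq=maf)
    return ped, geno, records, truth
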