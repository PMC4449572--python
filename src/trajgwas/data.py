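"""Core data containers shared across the pipeline.

Three containers travel through every stage: a pedigree (ordered
animal/sire/dam triples), a genotype matrix (animals x SNP 0/1/2 codes with
a genome map) and a longitudinal record set (one row per animal-day with
fixed-effect levels).  They are thin wrappers around pandas/numpy with the
validation the downstream algebra relies on.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PedigreeTable", "GenotypeMatrix", "TrajectoryRecordSet"]

UNKNOWN_PARENT = 0


@dataclass
class PedigreeTable:
    """Topologically ordered pedigree; parents precede their offspring.

    ``animal``, ``sire`` and ``dam`` are integer id arrays; id 0 marks an
    unknown parent (founders have both parents unknown).
    """

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        if not (len(self.animal) == len(self.sire) == len(self.dam)):
            raise ValueError("animal/sire/dam length mismatch")
        if len(np.unique(self.animal)) != len(self.animal):
            raise ValueError("duplicate animal ids in pedigree")
        pos = {a: i for i, a in enumerate(self.animal)}
        self._pos = pos
        self.sire_idx = np.empty(len(self.animal), dtype=np.int64)
        self.dam_idx = np.empty(len(self.animal), dtype=np.int64)
        for i, (s, d) in enumerate(zip(self.sire, self.dam)):
            for parent, out in ((s, self.sire_idx), (d, self.dam_idx)):
                if parent == UNKNOWN_PARENT:
                    out[i] = -1
                else:
                    j = pos.get(parent)
                    if j is None:
                        raise ValueError(f"parent {parent} not in pedigree")
                    if j >= i:
                        raise ValueError(
                            f"parent {parent} appears at or after offspring "
                            f"{self.animal[i]}: pedigree not ordered"
                        )
                    out[i] = j

    def __len__(self) -> int:
        return len(self.animal)

    def index_of(self, animals) -> np.ndarray:
        return np.asarray([self._pos[a] for a in np.asarray(animals)], dtype=np.int64)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"animal": self.animal, "sire": self.sire, "dam": self.dam}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PedigreeTable":
        return cls(
            df["animal"].to_numpy(), df["sire"].to_numpy(), df["dam"].to_numpy()
        )


@dataclass
class GenotypeMatrix:
    """Animals x SNP gene-content matrix coded 0/1/2 (missing = -1).

    ``snp_map`` has one row per SNP with columns ``snp_id``, ``chrom``,
    ``pos`` (bp), in matrix column order, sorted by (chrom, pos) within
    chromosome.
    """

    animal: np.ndarray
    codes: np.ndarray
    snp_map: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.animal):
            raise ValueError("codes must be (n_animals, n_snp)")
        if len(self.snp_map) != self.codes.shape[1]:
            raise ValueError("snp_map length does not match SNP count")
        valid = np.isin(self.codes, (-1, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype codes must be in {0,1,2} (-1 missing)")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snp(self) -> int:
        return self.codes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Observed frequency of the counted allele per SNP (missing skipped)."""
        codes = np.ma.masked_equal(self.codes, -1)
        return np.asarray(codes.mean(axis=0) / 2.0)

    def subset(self, animal_keep=None, snp_keep=None) -> "GenotypeMatrix":
        a = slice(None) if animal_keep is None else np.asarray(animal_keep)
        s = slice(None) if snp_keep is None else np.asarray(snp_keep)
        return GenotypeMatrix(
            self.animal[a], self.codes[a][:, s], self.snp_map.iloc[s]
        )


@dataclass
class TrajectoryRecordSet:
    """Longitudinal phenotype rows: animal, age (days), value, CG, parity."""

    df: pd.DataFrame

    REQUIRED = ("animal", "age_days", "value", "cg", "parity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing record columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def animals(self) -> np.ndarray:
        return self.df["animal"].unique()

    def records_per_animal(self) -> pd.Series:
        return self.df.groupby("animal").size()
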