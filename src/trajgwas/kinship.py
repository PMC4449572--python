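"""Relationship matrices: pedigree A, genomic G, and the single-step blend.

The single-step analysis combines a pedigree numerator relationship matrix
A (tabular method, inbreeding accounted for) with a SNP-derived genomic
relationship matrix G = Z D Z', where Z holds gene content centered by
twice the allele frequency and D carries the reciprocal of the expected
marker variance 2 p q (scaled by the SNP count so mean diag(G) is near 1).
G is blended with the genotyped pedigree block A22 as

    G_b = w * G + (1 - w) * A22,      w = 0.995 by default,

and the inverse relationship matrix used by the mixed-model equations is

    H^-1 = A^-1 + [0 0; 0 G_b^-1 - A22^-1]

with the non-zero block on the genotyped animals.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import linalg

from .data import GenotypeMatrix, PedigreeTable

__all__ = [
    "RelationshipMatrix",
    "SparsePedigreeInverse",
    "MarkerScaling",
    "build_A",
    "build_A_inverse",
    "build_G",
    "blend_and_invert",
    "prune_pedigree",
]

DEFAULT_BLEND_WEIGHT = 0.995


@dataclass
class RelationshipMatrix:
    """Dense symmetric relationship matrix with its animal index."""

    animal: np.ndarray
    matrix: np.ndarray = field(repr=False)
    kind: str = "A"

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.animal)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match animal index")

    def save(self, path) -> None:
        """NPZ archive with the matrix, animal index and kind."""
        np.savez_compressed(
            path, animal=self.animal, matrix=self.matrix,
            kind=np.asarray(self.kind),
        )

    @classmethod
    def load(cls, path) -> "RelationshipMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls(z["animal"], z["matrix"], str(z["kind"]))

    def submatrix(self, animals) -> "RelationshipMatrix":
        pos = {a: i for i, a in enumerate(self.animal)}
        idx = np.asarray([pos[a] for a in np.asarray(animals)], dtype=np.int64)
        return RelationshipMatrix(
            np.asarray(animals), self.matrix[np.ix_(idx, idx)], self.kind + "_sub"
        )


@dataclass
class MarkerScaling:
    """Allele frequencies and diagonal marker-variance weights for G = ZDZ'."""

    freq: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any((self.freq <= 0) | (self.freq >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        if np.any(self.weights < 0):
            raise ValueError("marker weights must be non-negative")

    @classmethod
    def expected(cls, freq) -> "MarkerScaling":
        """Expected-marker-variance weights d_i = 1 / (m * 2 p_i q_i)."""
        freq = np.asarray(freq, dtype=float)
        m = len(freq)
        return cls(freq, 1.0 / (m * 2.0 * freq * (1.0 - freq)))


def build_A(ped: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular (Henderson) recursion.

    Inbreeding is accounted for: diag = 1 + F with F half the parents'
    relationship.  Requires a topologically ordered pedigree (enforced by
    ``PedigreeTable``).
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        diag = 1.0
        if si >= 0 and di >= 0:
            diag += 0.5 * A[si, di]
        A[i, i] = diag
    return RelationshipMatrix(ped.animal, A, "A")


@dataclass
class SparsePedigreeInverse:
    """Sparse A^-1 with its animal index and log|A|.

    Built directly by Henderson's rules, so the sparsity is exact; used by
    the sparse mixed-model path when no genomic information enters H.
    """

    animal: np.ndarray
    matrix: sp.csc_matrix = field(repr=False)
    logdet_A: float = 0.0

    def __post_init__(self) -> None:
        self.animal = np.asarray(self.animal, dtype=np.int64)
        self.matrix = sp.csc_matrix(self.matrix)


def build_A_inverse(ped: PedigreeTable) -> SparsePedigreeInverse:
    """Sparse inverse of the numerator relationship matrix (with inbreeding).

    Henderson's rules: each animal contributes 1/m_i to its own diagonal
    and the usual -1/2, 1/4 multiples to parent entries, where m_i is the
    Mendelian-sampling variance 0.5 - 0.25 (F_s + F_d) (adjusted for
    missing parents).  Inbreeding coefficients come from the tabular A,
    which is cheap at desk scale.  log|A| = sum log m_i falls out for free.
    """
    n = len(ped)
    F = build_A(ped).matrix.diagonal() - 1.0
    rows, cols, vals = [], [], []
    logdet = 0.0
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        parents = [p for p in (s, d) if p >= 0]
        m = 1.0 - sum(0.25 * (1.0 + F[p]) for p in parents)
        logdet += np.log(m)
        alpha = 1.0 / m
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in parents:
            rows.extend((i, p)); cols.extend((p, i)); vals.extend((-alpha / 2,) * 2)
        for p in parents:
            for q in parents:
                rows.append(p); cols.append(q); vals.append(alpha / 4)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return SparsePedigreeInverse(ped.animal, Ainv, float(logdet))


def prune_pedigree(
    ped: PedigreeTable, focal_animals, n_generations: int = 3
) -> PedigreeTable:
    """Restrict a pedigree to ``n_generations`` of ancestors of the focal set.

    Mirrors the common practice of building A from a fixed number of
    ancestral generations of the phenotyped animals.
    """
    keep = set(ped.index_of(np.asarray(focal_animals)))
    frontier = set(keep)
    for _ in range(n_generations):
        nxt = set()
        for i in frontier:
            for p in (ped.sire_idx[i], ped.dam_idx[i]):
                if p >= 0 and p not in keep:
                    nxt.add(p)
        keep |= nxt
        frontier = nxt
        if not frontier:
            break
    idx = np.asarray(sorted(keep), dtype=np.int64)
    sel = np.zeros(len(ped), dtype=bool)
    sel[idx] = True
    # parents dropped by the truncation become unknown
    sire = ped.sire.copy()
    dam = ped.dam.copy()
    for i in idx:
        if ped.sire_idx[i] >= 0 and not sel[ped.sire_idx[i]]:
            sire[i] = 0
        if ped.dam_idx[i] >= 0 and not sel[ped.dam_idx[i]]:
            dam[i] = 0
    return PedigreeTable(ped.animal[idx], sire[idx], dam[idx])


def center_genotypes(geno: GenotypeMatrix, freq=None) -> tuple[np.ndarray, np.ndarray]:
    """Gene-content matrix Z = M - 2p and the frequencies used to center it."""
    if np.any(geno.codes < 0):
        raise ValueError("missing genotypes present; run QC/imputation first")
    p = geno.allele_freq() if freq is None else np.asarray(freq, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("monomorphic SNP present; QC them out before building G")
    Z = geno.codes.astype(float) - 2.0 * p
    return Z, p


def build_G(
    geno: GenotypeMatrix, scaling: MarkerScaling | None = None
) -> tuple[RelationshipMatrix, MarkerScaling]:
    """Genomic relationship matrix G = Z D Z' with expected-variance weights.

    Frequencies default to the observed frequencies of the genotyped set.
    Returns the matrix together with the scaling actually used, which the
    GWAS back-solving step must reuse.
    """
    if scaling is None:
        _, p = center_genotypes(geno)
        scaling = MarkerScaling.expected(p)
    Z, _ = center_genotypes(geno, scaling.freq)
    G = (Z * scaling.weights) @ Z.T
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(geno.animal, G, "G"), scaling


def blend_and_invert(
    A: RelationshipMatrix,
    G: RelationshipMatrix,
    w: float = DEFAULT_BLEND_WEIGHT,
) -> tuple[RelationshipMatrix, RelationshipMatrix]:
    """Blend G with A22 and assemble H^-1 over the full pedigree index.

    Returns ``(H_inverse, G_blended)``.  Genotyped animals are located in
    the pedigree index by id; with zero genotyped animals H^-1 = A^-1.
    """
    n = len(A.animal)
    Ainv = _sym_inv(A.matrix)
    Hinv = Ainv
    pos = {a: i for i, a in enumerate(A.animal)}
    gidx = np.asarray([pos[a] for a in G.animal], dtype=np.int64)
    if len(gidx) == 0:
        return RelationshipMatrix(A.animal, Hinv, "H_inverse"), G
    A22 = A.matrix[np.ix_(gidx, gidx)]
    Gb = w * G.matrix + (1.0 - w) * A22
    Gb = 0.5 * (Gb + Gb.T)
    block = _sym_inv(Gb) - _sym_inv(A22)
    Hinv = Ainv.copy()
    Hinv[np.ix_(gidx, gidx)] += block
    Hinv = 0.5 * (Hinv + Hinv.T)
    return (
        RelationshipMatrix(A.animal, Hinv, "H_inverse"),
        RelationshipMatrix(G.animal, Gb, "G_blended"),
    )


def _sym_inv(M: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via Cholesky."""
    try:
        c, low = linalg.cho_factor(M, lower=True, check_finite=False)
    except linalg.LinAlgError as err:
        raise linalg.LinAlgError(
            f"relationship matrix of order {M.shape[0]} is not positive "
            "definite; blend with the pedigree block or check QC"
        ) from err
    inv = linalg.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)
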