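"""Random-regression mixed model: Henderson equations and EM-REML.

The observation model for a record of animal m at age t (standardized) is

    y = CG_i + Parity_j + sum_k phi_k(t) beta_k
        + sum_k phi_k(t) u_mk + sum_k phi_k(t) pe_mk + e,

with u ~ N(0, H x G_a) over all pedigree animals (Kronecker, animal-major),
pe ~ N(0, I x P_pe) over phenotyped animals, and homogeneous residual
variance sigma_e^2.  The overall mean is absorbed into the contemporary
groups (first CG level is the reference intercept together with the fixed
regression); parity level 1 is the reference.

The mixed-model equations are assembled in precision form

    C = W'W + sigma_e^2 * blockdiag(0, H^-1 x G_a^-1, I x P_pe^-1),
    C theta = W'y,

so that sigma_e^2 * C^-1 is the posterior (prediction-error) covariance.
The permanent-environment block is block-diagonal per animal and is
absorbed exactly (Schur complement) before factorization; EM-REML therefore
factors only the fixed + genetic system each iteration.  EM updates are the
classical ones: coefficient covariances from conditional second moments,
residual variance from y'y - theta'W'y over n - rank(X).  The REML
log-likelihood is evaluated every iteration and must be monotone
non-decreasing, a property the implementation asserts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import linalg

from . import _spchol
from .basis import AgeStandardizer, legendre_matrix
from .data import TrajectoryRecordSet
from .kinship import RelationshipMatrix, SparsePedigreeInverse

__all__ = [
    "VarianceComponents",
    "RRModelFit",
    "MMESystem",
    "assemble_mme",
    "solve_mme",
    "em_reml",
    "trajectory_h2_rg",
    "phase_summary",
    "PHASES",
]

#: trajectory phases in days of age used for heritability / r_g summaries
PHASES = ((90, 118), (119, 146), (147, 175))


@dataclass
class VarianceComponents:
    """Genetic and permanent-environment 3x3 covariances plus residual."""

    G_a: np.ndarray
    P_pe: np.ndarray
    sigma_e2: float

    def __post_init__(self) -> None:
        self.G_a = np.asarray(self.G_a, dtype=float)
        self.P_pe = np.asarray(self.P_pe, dtype=float)
        for name, M in (("G_a", self.G_a), ("P_pe", self.P_pe)):
            if M.shape != (3, 3) or not np.allclose(M, M.T, atol=1e-8):
                raise ValueError(f"{name} must be symmetric 3x3")
            if np.linalg.eigvalsh(M).min() < -1e-8:
                raise ValueError(f"{name} must be positive semi-definite")
        if not self.sigma_e2 > 0:
            raise ValueError("sigma_e2 must be positive")

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(self.G_a.copy(), self.P_pe.copy(), self.sigma_e2)


@dataclass
class RRModelFit:
    """Solutions of the mixed-model equations plus everything needed downstream."""

    fixed_names: list
    b: np.ndarray
    u_animals: np.ndarray  # Hinv index order
    u: np.ndarray  # (N, 3) genetic coefficient solutions (GEBV coefficients)
    pe_animals: np.ndarray
    pe: np.ndarray  # (Np, 3)
    vc: VarianceComponents
    standardizer: AgeStandardizer
    normalized_basis: bool
    #: per training record: fixed part, genetic part, PE part of the fitted value
    fixed_part: np.ndarray = field(repr=False, default=None)
    genetic_part: np.ndarray = field(repr=False, default=None)
    pe_part: np.ndarray = field(repr=False, default=None)
    loglik: float = np.nan

    def gebv(self, animals) -> np.ndarray:
        """Genetic coefficient solutions for a subset of animals (in order)."""
        pos = {a: i for i, a in enumerate(self.u_animals)}
        idx = np.asarray([pos[a] for a in np.asarray(animals)])
        return self.u[idx]

    def save(self, path) -> None:
        """Single NPZ archive: solutions, components and the standardizer."""
        np.savez_compressed(
            path,
            fixed_names=np.asarray(self.fixed_names),
            b=self.b, u_animals=self.u_animals, u=self.u,
            pe_animals=self.pe_animals, pe=self.pe,
            G_a=self.vc.G_a, P_pe=self.vc.P_pe,
            sigma_e2=np.asarray(self.vc.sigma_e2),
            age_range=np.asarray(
                [self.standardizer.age_min, self.standardizer.age_max]
            ),
            normalized_basis=np.asarray(self.normalized_basis),
            fixed_part=self.fixed_part, genetic_part=self.genetic_part,
            pe_part=self.pe_part, loglik=np.asarray(self.loglik),
        )

    @classmethod
    def load(cls, path) -> "RRModelFit":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                fixed_names=[str(n) for n in z["fixed_names"]],
                b=z["b"], u_animals=z["u_animals"], u=z["u"],
                pe_animals=z["pe_animals"], pe=z["pe"],
                vc=VarianceComponents(
                    z["G_a"], z["P_pe"], float(z["sigma_e2"])
                ),
                standardizer=AgeStandardizer(*z["age_range"]),
                normalized_basis=bool(z["normalized_basis"]),
                fixed_part=z["fixed_part"], genetic_part=z["genetic_part"],
                pe_part=z["pe_part"], loglik=float(z["loglik"]),
            )

    @property
    def fitted_values(self) -> np.ndarray:
        return self.fixed_part + self.genetic_part + self.pe_part


def _clamped_inv(M: np.ndarray, floor_rel: float = 1e-10):
    """Inverse of a symmetric PSD 3x3 with eigenvalue clamping; also logdet."""
    w, V = np.linalg.eigh(M)
    floor = floor_rel * max(1.0, float(w.max(initial=1.0)))
    w = np.clip(w, floor, None)
    return (V / w) @ V.T, float(np.log(w).sum())


class MMESystem:
    """Assembled design moments for the random-regression MME.

    Construction precomputes everything that does not depend on the
    variance components or the phenotype vector, so EM-REML iterations
    (variance components change) and bootstrap replicates (phenotypes
    change) pay only for what actually varies.
    """

    def __init__(
        self,
        records: TrajectoryRecordSet,
        hinv: RelationshipMatrix,
        standardizer: AgeStandardizer | None = None,
        normalized_basis: bool = True,
    ):
        df = records.df
        self.records = records
        self.standardizer = standardizer or AgeStandardizer.from_ages(
            df["age_days"].to_numpy()
        )
        self.normalized_basis = normalized_basis
        self.hinv = hinv
        self.n_rec = len(df)

        pos = {a: i for i, a in enumerate(hinv.animal)}
        try:
            self.rec_uidx = np.asarray(
                [pos[a] for a in df["animal"].to_numpy()], dtype=np.int64
            )
        except KeyError as err:
            raise ValueError(
                f"record animal {err.args[0]} missing from the relationship index"
            ) from None
        self.n_animals = len(hinv.animal)

        # phenotyped animals, ordered by their position in the Hinv index
        pheno_uidx = np.unique(self.rec_uidx)
        self.pheno_uidx = pheno_uidx
        self.n_pheno = len(pheno_uidx)
        remap = -np.ones(self.n_animals, dtype=np.int64)
        remap[pheno_uidx] = np.arange(self.n_pheno)
        self.rec_pidx = remap[self.rec_uidx]

        t = self.standardizer.transform(df["age_days"].to_numpy())
        self.phi = legendre_matrix(t, normalized=normalized_basis)

        # fixed design: Legendre fixed regression + CG dummies (ref = first
        # level) + parity dummies (ref = first level)
        cols = [self.phi]
        names = ["beta0", "beta1", "beta2"]
        for factor, ref_tag in (("cg", "cg"), ("parity", "parity")):
            levels = np.sort(df[factor].unique())
            for lev in levels[1:]:
                cols.append((df[factor].to_numpy() == lev).astype(float)[:, None])
                names.append(f"{ref_tag}:{lev}")
        self.X = np.hstack(cols)
        self.fixed_names = names
        self.nf = self.X.shape[1]
        self.rank_X = int(np.linalg.matrix_rank(self.X.T @ self.X))

        # y-independent moments
        self.XtX = self.X.T @ self.X
        self.F = np.zeros((self.n_pheno, 3, 3))  # Phi_m' Phi_m
        np.add.at(
            self.F, self.rec_pidx, self.phi[:, :, None] * self.phi[:, None, :]
        )
        self.XtPhi = np.zeros((self.n_pheno, self.nf, 3))  # X_m' Phi_m
        np.add.at(
            self.XtPhi, self.rec_pidx, self.X[:, :, None] * self.phi[:, None, :]
        )
        self.sparse = isinstance(hinv, SparsePedigreeInverse)
        if self.sparse:
            self.logdet_H = hinv.logdet_A
            self._build_sparse_structures()
        else:
            sign, self.logdet_H = np.linalg.slogdet(hinv.matrix)
            if sign <= 0:
                raise linalg.LinAlgError("H^-1 must be positive definite")
            self.logdet_H = -self.logdet_H  # log|H| = -log|H^-1|

    def _build_sparse_structures(self) -> None:
        """Symbolic analysis for the sparse (pedigree-only) MME path.

        A fill-reducing symmetric ordering of the animal graph is obtained
        once, the scalar (3 equations per animal) sparsity pattern is
        expanded from it, and the LDL' factor pattern is computed once;
        numeric factorizations reuse it every iteration.
        """
        N = self.n_animals
        Ainv = self.hinv.matrix.tocsc()
        pattern = sp.csc_matrix(
            (np.ones(Ainv.nnz), Ainv.indices, Ainv.indptr), shape=(N, N)
        ) + sp.eye(N)
        aperm = _min_degree_order(pattern.tocsr())
        self._aperm = aperm
        inv = np.empty(N, dtype=np.int64)
        inv[aperm] = np.arange(N)
        self._ainv_perm = inv
        Aperm = Ainv[aperm, :][:, aperm].tocsc()
        Aperm.sort_indices()
        self._Ap = Aperm.indptr.astype(np.int64)
        self._Ai = Aperm.indices.astype(np.int64)
        self._Av = Aperm.data.astype(float)
        # scalar pattern: 3x3 block per animal entry, row/col-major in (m,a)
        counts = np.diff(self._Ap)
        Cp = np.zeros(3 * N + 1, dtype=np.int64)
        Cp[1:] = np.repeat(3 * counts, 3).cumsum()
        Ci = np.empty(Cp[-1], dtype=np.int64)
        pos = 0
        for ncol in range(N):
            R = self._Ai[self._Ap[ncol] : self._Ap[ncol + 1]]
            rows3 = (3 * R[:, None] + np.arange(3)).ravel()
            for _ in range(3):
                Ci[pos : pos + len(rows3)] = rows3
                pos += len(rows3)
        self._Cp, self._Ci = Cp, Ci
        self._Lp, self._Li, self._etree_parent = _spchol.symbolic(3 * N, Cp, Ci)

    def with_hinv(self, hinv: RelationshipMatrix) -> "MMESystem":
        """Clone with a new (dense) H^-1 over the same animal index.

        Reuses all record-design moments; used by the GWAS reweighting
        chain, where only the genomic part of H changes between rounds.
        """
        import copy

        if self.sparse:
            raise NotImplementedError("with_hinv applies to the dense path")
        if not np.array_equal(hinv.animal, self.hinv.animal):
            raise ValueError("animal index mismatch")
        new = copy.copy(self)
        new.hinv = hinv
        sign, ld = np.linalg.slogdet(hinv.matrix)
        if sign <= 0:
            raise linalg.LinAlgError("H^-1 must be positive definite")
        new.logdet_H = -ld
        return new

    # -- phenotype moments -------------------------------------------------
    def moments(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_rec,):
            raise ValueError("phenotype vector length mismatch")
        Xty = self.X.T @ y
        Phity = np.zeros((self.n_pheno, 3))
        np.add.at(Phity, self.rec_pidx, self.phi * y[:, None])
        return Xty, Phity, float(y @ y)

    def factor(self, vc: VarianceComponents, want_inverse: bool = False):
        if self.sparse:
            return SparseMMEFactor(self, vc, want_inverse=want_inverse)
        return MMEFactor(self, vc, want_inverse=want_inverse)


def _min_degree_order(pattern_csr: sp.csr_matrix) -> np.ndarray:
    """Greedy minimum-degree elimination ordering of a symmetric pattern.

    Plain heap-based variant; quadratic worst case but the pedigree graphs
    this path is used for are small and very sparse.
    """
    import heapq

    n = pattern_csr.shape[0]
    adj = [
        set(pattern_csr.indices[pattern_csr.indptr[i] : pattern_csr.indptr[i + 1]])
        - {i}
        for i in range(n)
    ]
    alive = np.ones(n, dtype=bool)
    heap = [(len(adj[i]), i) for i in range(n)]
    heapq.heapify(heap)
    order = []
    while heap:
        deg, i = heapq.heappop(heap)
        if not alive[i] or deg != len(adj[i]):
            continue
        order.append(i)
        alive[i] = False
        nb = [j for j in adj[i] if alive[j]]
        for j in nb:
            adj[j].discard(i)
            adj[j].update(k for k in nb if k != j)
            heapq.heappush(heap, (len(adj[j]), j))
        adj[i] = set()
    return np.asarray(order, dtype=np.int64)


class _Absorption:
    """Shared PE-absorption pieces used by both MME factorizations."""

    def __init__(self, sys: "MMESystem", vc: VarianceComponents):
        se2 = vc.sigma_e2
        self.Ga_inv, self.logdet_Ga = _clamped_inv(vc.G_a)
        P_inv, self.logdet_P = _clamped_inv(vc.P_pe)
        S = sys.F + se2 * P_inv
        self.S_inv = np.linalg.inv(S)
        sign, logdet_S = np.linalg.slogdet(S)
        self.logdet_S_total = float(logdet_S.sum())
        self.FS = np.einsum("mij,mjk->mik", sys.XtPhi, self.S_inv)  # X'Phi S^-1
        self.Cbb = sys.XtX - np.einsum("mik,mjk->ij", self.FS, sys.XtPhi)
        self.Cbu = sys.XtPhi - np.einsum("mik,mkl->mil", self.FS, sys.F)
        self.Fabs = sys.F - np.einsum(
            "mij,mjk,mkl->mil", sys.F, self.S_inv, sys.F
        )


class MMEFactor:
    """Dense Cholesky factorization of the PE-absorbed MME."""

    def __init__(self, system: MMESystem, vc: VarianceComponents, want_inverse=False):
        self.system = sys = system
        self.vc = vc
        se2 = vc.sigma_e2
        ab = _Absorption(sys, vc)
        Ga_inv, logdet_Ga = ab.Ga_inv, ab.logdet_Ga
        logdet_P = ab.logdet_P
        self.S_inv = ab.S_inv
        self.logdet_S_total = ab.logdet_S_total

        nf, N, Np = sys.nf, sys.n_animals, sys.n_pheno
        q = nf + 3 * N
        C = np.zeros((q, q))
        C[:nf, :nf] = ab.Cbb
        for j, m in enumerate(sys.pheno_uidx):
            C[:nf, nf + 3 * m : nf + 3 * m + 3] = ab.Cbu[j]
        C[nf:, :nf] = C[:nf, nf:].T
        for j, m in enumerate(sys.pheno_uidx):
            C[nf + 3 * m : nf + 3 * m + 3, nf + 3 * m : nf + 3 * m + 3] += ab.Fabs[j]
        # genetic prior sigma_e2 * (H^-1 x G_a^-1)
        Hinv = sys.hinv.matrix
        prior = (
            Hinv[:, None, :, None] * (se2 * Ga_inv)[None, :, None, :]
        ).reshape(3 * N, 3 * N)
        C[nf:, nf:] += prior

        try:
            self.chol = linalg.cho_factor(C, lower=True, check_finite=False)
        except linalg.LinAlgError as err:
            raise linalg.LinAlgError(
                "MME coefficient matrix not positive definite; check variance "
                "components and fixed-effect constraints"
            ) from err
        self.logdet_Cabs = 2.0 * float(
            np.log(np.diag(self.chol[0])).sum()
        )
        self.logdet_Ga = logdet_Ga
        self.logdet_P = logdet_P
        self.C_inv = None
        if want_inverse:
            inv, info = linalg.lapack.dpotri(self.chol[0], lower=True)
            if info != 0:
                raise linalg.LinAlgError("dpotri failed on the MME factor")
            # dpotri fills one triangle only
            self.C_inv = np.tril(inv) + np.tril(inv, -1).T

    def solve(self, y: np.ndarray):
        """Solve the MME for phenotype vector ``y``.

        Returns ``(b, u, pe)`` with u over all pedigree animals (N x 3) and
        pe over phenotyped animals (Np x 3).
        """
        sys = self.system
        Xty, Phity, yty = sys.moments(y)
        nf, N = sys.nf, sys.n_animals
        rhs = np.zeros(nf + 3 * N)
        SinvPhity = np.einsum("mij,mj->mi", self.S_inv, Phity)
        rhs[:nf] = Xty - np.einsum("mik,mk->i", sys.XtPhi, SinvPhity)
        r_u = Phity - np.einsum("mij,mj->mi", sys.F, SinvPhity)
        for j, m in enumerate(sys.pheno_uidx):
            rhs[nf + 3 * m : nf + 3 * m + 3] = r_u[j]
        theta = linalg.cho_solve(self.chol, rhs, check_finite=False)
        b = theta[:nf]
        u = theta[nf:].reshape(N, 3)
        # back-substitute the absorbed PE block
        u_ph = u[sys.pheno_uidx]
        resid_m = (
            Phity
            - np.einsum("mik,i->mk", sys.XtPhi, b)
            - np.einsum("mij,mj->mi", sys.F, u_ph)
        )
        pe = np.einsum("mij,mj->mi", self.S_inv, resid_m)
        self._last = (Xty, Phity, yty, b, u, pe)
        return b, u, pe

    # -- REML pieces -------------------------------------------------------
    def reml_loglik(self) -> float:
        """-2 x restricted log-likelihood / -2 (up to a constant), maximized."""
        sys = self.system
        Xty, Phity, yty, b, u, pe = self._last
        se2 = self.vc.sigma_e2
        u_ph = u[sys.pheno_uidx]
        quad = yty - b @ Xty - np.einsum("mi,mi->", u_ph, Phity) - np.einsum(
            "mi,mi->", pe, Phity
        )
        yPy = quad / se2
        q = sys.nf + 3 * sys.n_animals + 3 * sys.n_pheno
        logdet_C = self.logdet_Cabs + self.logdet_S_total - q * np.log(se2)
        m2ll = (
            sys.n_rec * np.log(se2)
            + 3.0 * sys.logdet_H
            + sys.n_animals * self.logdet_Ga
            + sys.n_pheno * self.logdet_P
            + logdet_C
            + yPy
        )
        return -0.5 * m2ll

    def em_update(self) -> VarianceComponents:
        """One EM-REML step from the current solutions (needs the inverse)."""
        if self.C_inv is None:
            raise RuntimeError("factor with want_inverse=True for EM updates")
        sys = self.system
        Xty, Phity, yty, b, u, pe = self._last
        se2 = self.vc.sigma_e2
        nf, N, Np = sys.nf, sys.n_animals, sys.n_pheno
        Hinv = sys.hinv.matrix

        Cuu = self.C_inv[nf:, nf:].reshape(N, 3, N, 3)
        trace_u = np.einsum("mn,manb->ab", Hinv, Cuu)
        Ga_new = (u.T @ Hinv @ u + se2 * trace_u) / N
        Ga_new = 0.5 * (Ga_new + Ga_new.T)

        # PE conditional covariance via the absorption identity:
        # Cov(pe_m) = se2 [S_m^-1 + S_m^-1 J_m C^-1 J_m' S_m^-1],
        # J_m = [Phi'X_m | F_m] on the fixed and own-genetic columns.
        P_acc = pe.T @ pe
        Cbb = self.C_inv[:nf, :nf]
        for j, m in enumerate(sys.pheno_uidx):
            sl = slice(nf + 3 * m, nf + 3 * m + 3)
            K = np.empty((nf + 3, nf + 3))
            K[:nf, :nf] = Cbb
            K[:nf, nf:] = self.C_inv[:nf, sl]
            K[nf:, :nf] = K[:nf, nf:].T
            K[nf:, nf:] = self.C_inv[sl, sl]
            J = np.hstack([sys.XtPhi[j].T, sys.F[j]])  # 3 x (nf+3)
            SJ = self.S_inv[j] @ J
            P_acc += se2 * (self.S_inv[j] + SJ @ K @ SJ.T)
        P_new = P_acc / Np
        P_new = 0.5 * (P_new + P_new.T)

        u_ph = u[sys.pheno_uidx]
        quad = yty - b @ Xty - np.einsum("mi,mi->", u_ph, Phity) - np.einsum(
            "mi,mi->", pe, Phity
        )
        se2_new = quad / (sys.n_rec - sys.rank_X)
        return VarianceComponents(Ga_new, P_new, float(se2_new))


class SparseMMEFactor:
    """Sparse LDL' factorization of the PE-absorbed MME (pedigree-only H).

    The genetic block blockdiag(F_abs) + se2 (A^-1 x G_a^-1) is factored
    with the numba sparse kernel on a fill-reducing ordering; the dense
    fixed-effect equations form a trailing Schur-complement border.  EM
    trace terms come from the Takahashi selected inverse plus the low-rank
    border correction, so a full EM-REML iteration costs a small multiple
    of the factor's nonzero count instead of a dense inversion.
    """

    def __init__(self, system: MMESystem, vc: VarianceComponents, want_inverse=False):
        self.system = sys = system
        self.vc = vc
        se2 = vc.sigma_e2
        ab = self._ab = _Absorption(sys, vc)
        self.S_inv = ab.S_inv
        self.logdet_S_total = ab.logdet_S_total
        self.logdet_Ga, self.logdet_P = ab.logdet_Ga, ab.logdet_P

        nf, N = sys.nf, sys.n_animals
        Fdiag = np.zeros((N, 3, 3))
        pperm = sys._ainv_perm[sys.pheno_uidx]
        Fdiag[pperm] = ab.Fabs
        Cx = _spchol.assemble_block_values(
            sys._Ap, sys._Ai, sys._Av, ab.Ga_inv, se2, Fdiag
        )
        try:
            self._Lx, self._d = _spchol.numeric_ldl(
                3 * N, sys._Cp, sys._Ci, Cx, sys._Lp, sys._Li, sys._etree_parent
            )
        except Exception as err:  # numba raises a bare LinAlgError
            raise linalg.LinAlgError(
                "sparse MME coefficient matrix not positive definite"
            ) from err

        B = np.zeros((3 * N, nf))
        for j, pm in enumerate(pperm):
            B[3 * pm : 3 * pm + 3, :] = ab.Cbu[j].T
        self._B = B
        self._W = _spchol.ldl_solve_multi(sys._Lp, sys._Li, self._Lx, self._d, B)
        S_bb = ab.Cbb - B.T @ self._W
        self._Sbb_chol = linalg.cho_factor(S_bb, lower=True, check_finite=False)
        logdet_Sbb = 2.0 * float(np.log(np.diag(self._Sbb_chol[0])).sum())
        self.logdet_Cabs = float(np.log(self._d).sum()) + logdet_Sbb
        # Q Q' is the dense-border correction to the genetic-block inverse
        self._Q = linalg.solve_triangular(
            self._Sbb_chol[0], self._W.T, lower=True, check_finite=False
        ).T
        self._Z = None
        if want_inverse:
            self._Z = _spchol.takahashi(
                3 * N, sys._Lp, sys._Li, self._Lx, self._d
            )

    def solve(self, y: np.ndarray):
        sys = self.system
        Xty, Phity, yty = sys.moments(y)
        nf, N = sys.nf, sys.n_animals
        SinvPhity = np.einsum("mij,mj->mi", self.S_inv, Phity)
        r_b = Xty - np.einsum("mik,mk->i", sys.XtPhi, SinvPhity)
        r_u = Phity - np.einsum("mij,mj->mi", sys.F, SinvPhity)
        ru_s = np.zeros(3 * N)
        pperm = sys._ainv_perm[sys.pheno_uidx]
        for j, pm in enumerate(pperm):
            ru_s[3 * pm : 3 * pm + 3] = r_u[j]
        t = _spchol.ldl_solve(sys._Lp, sys._Li, self._Lx, self._d, ru_s)
        b = linalg.cho_solve(
            self._Sbb_chol, r_b - self._B.T @ t, check_finite=False
        )
        u_perm = (t - self._W @ b).reshape(N, 3)
        u = np.empty((N, 3))
        u[sys._aperm] = u_perm
        u_ph = u[sys.pheno_uidx]
        resid_m = (
            Phity
            - np.einsum("mik,i->mk", sys.XtPhi, b)
            - np.einsum("mij,mj->mi", sys.F, u_ph)
        )
        pe = np.einsum("mij,mj->mi", self.S_inv, resid_m)
        self._last = (Xty, Phity, yty, b, u, pe)
        return b, u, pe

    reml_loglik = MMEFactor.reml_loglik

    def em_update(self) -> VarianceComponents:
        if self._Z is None:
            raise RuntimeError("factor with want_inverse=True for EM updates")
        sys = self.system
        Xty, Phity, yty, b, u, pe = self._last
        se2 = self.vc.sigma_e2
        nf, N, Np = sys.nf, sys.n_animals, sys.n_pheno
        Zx, Zd = self._Z

        trace_u = _spchol.weighted_block_trace(
            sys._Ap, sys._Ai, sys._Av, sys._Lp, sys._Li, Zx, Zd, self._Q
        )
        Hu = sys.hinv.matrix @ u
        Ga_new = (u.T @ Hu + se2 * trace_u) / N
        Ga_new = 0.5 * (Ga_new + Ga_new.T)

        pperm = sys._ainv_perm[sys.pheno_uidx]
        Zblocks = _spchol.diag_blocks(pperm, sys._Lp, sys._Li, Zx, Zd)
        Sbb_inv = linalg.cho_solve(
            self._Sbb_chol, np.eye(nf), check_finite=False
        )
        P_acc = pe.T @ pe
        ab = self._ab
        for j, pm in enumerate(pperm):
            Wm = self._W[3 * pm : 3 * pm + 3, :]  # 3 x nf
            Qm = self._Q[3 * pm : 3 * pm + 3, :]
            K = np.empty((nf + 3, nf + 3))
            K[:nf, :nf] = Sbb_inv
            K[:nf, nf:] = -(Sbb_inv @ Wm.T)
            K[nf:, :nf] = K[:nf, nf:].T
            K[nf:, nf:] = Zblocks[j] + Qm @ Qm.T
            J = np.hstack([sys.XtPhi[j].T, sys.F[j]])
            SJ = self.S_inv[j] @ J
            P_acc += se2 * (self.S_inv[j] + SJ @ K @ SJ.T)
        P_new = P_acc / Np
        P_new = 0.5 * (P_new + P_new.T)

        u_ph = u[sys.pheno_uidx]
        quad = yty - b @ Xty - np.einsum("mi,mi->", u_ph, Phity) - np.einsum(
            "mi,mi->", pe, Phity
        )
        se2_new = quad / (sys.n_rec - sys.rank_X)
        return VarianceComponents(Ga_new, P_new, float(se2_new))


def assemble_mme(
    records: TrajectoryRecordSet,
    hinv: RelationshipMatrix,
    vc: VarianceComponents,
    standardizer: AgeStandardizer | None = None,
    normalized_basis: bool = True,
) -> MMEFactor:
    """Assemble and factor the mixed-model equations (PE absorbed)."""
    system = MMESystem(
        records, hinv, standardizer=standardizer, normalized_basis=normalized_basis
    )
    return system.factor(vc)


def solve_mme(factor: MMEFactor, y: np.ndarray | None = None) -> RRModelFit:
    """Solve the factored MME and package the solutions."""
    sys = factor.system
    if y is None:
        y = sys.records.df["value"].to_numpy(dtype=float)
    b, u, pe = factor.solve(y)
    fixed_part = sys.X @ b
    genetic_part = np.einsum("ij,ij->i", sys.phi, u[sys.rec_uidx])
    pe_part = np.einsum("ij,ij->i", sys.phi, pe[sys.rec_pidx])
    return RRModelFit(
        fixed_names=sys.fixed_names,
        b=b,
        u_animals=sys.hinv.animal,
        u=u,
        pe_animals=sys.hinv.animal[sys.pheno_uidx],
        pe=pe,
        vc=factor.vc,
        standardizer=sys.standardizer,
        normalized_basis=sys.normalized_basis,
        fixed_part=fixed_part,
        genetic_part=genetic_part,
        pe_part=pe_part,
        loglik=factor.reml_loglik(),
    )


def _psd_project(M: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    return (V * np.clip(w, floor * max(1.0, abs(w).max()), None)) @ V.T


def moment_start_values(
    records: TrajectoryRecordSet,
    standardizer: AgeStandardizer | None = None,
    normalized_basis: bool = True,
    pedigree=None,
) -> VarianceComponents:
    """Moment-based starting values for EM-REML.

    Fits each animal's records by OLS on its Legendre basis (animals with
    fewer than 5 records are skipped) and pools the within-animal residual
    variance as the residual start.  The between-animal coefficient
    covariance, corrected for its average sampling covariance, estimates
    the genetic-plus-PE total; when a pedigree is supplied the genetic
    share is anchored by twice the parent-offspring coefficient covariance
    (permanent environment does not transmit), otherwise the total is split
    equally.  Purely a warm start; EM-REML owns the estimation.
    """
    df = records.df
    std = standardizer or AgeStandardizer.from_ages(df["age_days"].to_numpy())
    phi = legendre_matrix(
        std.transform(df["age_days"].to_numpy()), normalized=normalized_basis
    )
    y = df["value"].to_numpy(dtype=float)
    coefs, sampling, animals, sse, dof = [], [], [], 0.0, 0
    for animal, idx in df.groupby("animal").indices.items():
        if len(idx) < 5:
            continue
        P, yy = phi[idx], y[idx]
        FtF = P.T @ P
        try:
            FtF_inv = np.linalg.inv(FtF)
        except np.linalg.LinAlgError:
            continue
        c = FtF_inv @ (P.T @ yy)
        r = yy - P @ c
        coefs.append(c)
        sampling.append(FtF_inv)
        animals.append(animal)
        sse += float(r @ r)
        dof += len(idx) - 3
    if len(coefs) < 3 or dof < 1:
        return VarianceComponents(np.eye(3), np.eye(3), 1.0)
    se2 = max(1e-6, sse / dof)
    coefs = np.asarray(coefs)
    # residualize on animal-level CG/parity so fixed-effect variance (and the
    # negative correlation between deviations of distinct factor levels) does
    # not leak into the coefficient covariances
    lev = df.groupby("animal")[["cg", "parity"]].first().loc[animals]
    D = [np.ones(len(coefs))]
    for col in ("cg", "parity"):
        vals = lev[col].to_numpy()
        for v in np.unique(vals)[1:]:
            D.append((vals == v).astype(float))
    D = np.column_stack(D)
    dev = coefs - D @ np.linalg.lstsq(D, coefs, rcond=None)[0]
    C_total = _psd_project(
        (dev.T @ dev) / (len(dev) - 1) - se2 * np.mean(sampling, axis=0)
    )
    Ga0 = 0.5 * C_total
    if pedigree is not None:
        pos = {a: i for i, a in enumerate(animals)}
        acc = np.zeros((3, 3))
        n_pairs = 0
        ppos = {a: i for i, a in enumerate(pedigree.animal)}
        for a in animals:
            i = ppos[a]
            for par_idx in (pedigree.sire_idx[i], pedigree.dam_idx[i]):
                if par_idx < 0:
                    continue
                j = pos.get(pedigree.animal[par_idx])
                if j is None:
                    continue
                acc += np.outer(dev[pos[a]], dev[j])
                n_pairs += 1
        if n_pairs >= 30:
            # cov(offspring, parent) = G_a / 2; symmetrize and keep PSD
            Ga0 = _psd_project(2.0 * acc / n_pairs)
    # keep the start strictly inside the parameter space: a zero variance is
    # an absorbing state for EM
    floor = 0.05 * max(np.linalg.eigvalsh(C_total).max(), 1e-6)
    Ga0 = _psd_project(Ga0) + floor * np.eye(3)
    P0 = _psd_project(C_total - Ga0) + floor * np.eye(3)
    return VarianceComponents(Ga0, P0, se2)


@dataclass
class EMLog:
    iterations: int
    loglik: list
    converged: bool


def _vc_line(base: VarianceComponents, step: VarianceComponents, alpha: float):
    """base + alpha * (step - base), or None when it leaves the PD cone."""
    Ga = base.G_a + alpha * (step.G_a - base.G_a)
    P = base.P_pe + alpha * (step.P_pe - base.P_pe)
    se2 = base.sigma_e2 + alpha * (step.sigma_e2 - base.sigma_e2)
    if se2 <= 0:
        return None
    if np.linalg.eigvalsh(Ga).min() <= 0 or np.linalg.eigvalsh(P).min() <= 0:
        return None
    return VarianceComponents(Ga, P, float(se2))


def em_reml(
    records: TrajectoryRecordSet,
    hinv: RelationshipMatrix,
    init: VarianceComponents,
    tol: float = 1e-6,
    max_iter: int = 500,
    standardizer: AgeStandardizer | None = None,
    normalized_basis: bool = True,
    monotone_jitter: float = 1e-6,
    accelerate: bool = True,
) -> tuple[VarianceComponents, EMLog]:
    """EM-REML estimation of G_a, P_pe and sigma_e^2.

    The REML log-likelihood is computed every iteration and must not
    decrease by more than ``monotone_jitter`` (relative); a larger decrease
    aborts with diagnostics since it signals an assembly error.  Stops when
    the largest relative parameter change falls below ``tol``.

    With ``accelerate`` the EM step direction is over-relaxed (step length
    adapts upward while the likelihood keeps increasing, falling back to
    the plain EM step otherwise); every accepted point is explicitly
    checked against the previous likelihood, so the monotonicity guarantee
    of EM is preserved while the long near-linear tail of the EM path is
    traversed in far fewer factorizations.
    """
    system = MMESystem(
        records, hinv, standardizer=standardizer, normalized_basis=normalized_basis
    )
    y = records.df["value"].to_numpy(dtype=float)
    vc = init.copy()
    logliks: list[float] = []
    converged = False
    alpha = 1.0
    fac = None
    for _ in range(max_iter):
        if fac is None:
            fac = system.factor(vc, want_inverse=True)
            fac.solve(y)
        ll = fac.reml_loglik()
        if logliks and ll < logliks[-1] - monotone_jitter * (1.0 + abs(logliks[-1])):
            raise RuntimeError(
                f"EM-REML log-likelihood decreased: {logliks[-1]:.6f} -> {ll:.6f}"
            )
        logliks.append(ll)
        em_step = fac.em_update()
        candidate = _vc_line(vc, em_step, alpha) if (accelerate and alpha > 1.0) else None
        accepted = None
        if candidate is not None:
            try:
                fac_c = system.factor(candidate, want_inverse=True)
                fac_c.solve(y)
                if fac_c.reml_loglik() >= ll:
                    accepted, fac = candidate, fac_c
                    alpha = min(alpha * 1.5, 16.0)
                else:
                    alpha = 1.0
            except linalg.LinAlgError:
                alpha = 1.0
        if accepted is None:
            # plain EM step: monotone by construction, no extra check needed
            accepted, fac = em_step, None
            if accelerate and alpha == 1.0:
                alpha = 2.0
        delta = max(
            np.abs(accepted.G_a - vc.G_a).max() / max(1e-12, np.abs(vc.G_a).max()),
            np.abs(accepted.P_pe - vc.P_pe).max() / max(1e-12, np.abs(vc.P_pe).max()),
            abs(accepted.sigma_e2 - vc.sigma_e2) / vc.sigma_e2,
        )
        vc = accepted
        if delta < tol:
            converged = True
            break
    return vc, EMLog(iterations=len(logliks), loglik=logliks, converged=converged)


# -- trajectory summaries --------------------------------------------------

def trajectory_h2_rg(
    vc: VarianceComponents,
    ages,
    standardizer: AgeStandardizer,
    normalized_basis: bool = True,
):
    """Heritability along the trajectory and the genetic correlation surface.

    h2(t) = phi' G_a phi / (phi' G_a phi + phi' P_pe phi + sigma_e^2);
    r_g(t, s) = phi_t' G_a phi_s / sqrt(phi_t' G_a phi_t * phi_s' G_a phi_s).
    Ages with zero genetic variance yield NaN in the correlation surface.
    """
    ages = np.asarray(ages, dtype=float)
    phi = legendre_matrix(standardizer.transform(ages), normalized=normalized_basis)
    gv = np.einsum("ij,jk,ik->i", phi, vc.G_a, phi)
    pv = np.einsum("ij,jk,ik->i", phi, vc.P_pe, phi)
    h2 = gv / (gv + pv + vc.sigma_e2)
    cov = phi @ vc.G_a @ phi.T
    sd = np.sqrt(np.clip(gv, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        rg = cov / np.outer(sd, sd)
    rg[:, sd == 0] = np.nan
    rg[sd == 0, :] = np.nan
    return h2, rg


def phase_summary(
    vc: VarianceComponents,
    standardizer: AgeStandardizer,
    normalized_basis: bool = True,
    phases=PHASES,
):
    """Phase-mean heritabilities and between-phase mean genetic correlations."""
    ages = np.arange(phases[0][0], phases[-1][1] + 1, dtype=float)
    h2, rg = trajectory_h2_rg(vc, ages, standardizer, normalized_basis)
    nph = len(phases)
    h2_phase = np.empty(nph)
    rg_phase = np.empty((nph, nph))
    masks = [(ages >= lo) & (ages <= hi) for lo, hi in phases]
    for i, mi in enumerate(masks):
        h2_phase[i] = h2[mi].mean()
        for j, mj in enumerate(masks):
            rg_phase[i, j] = np.nanmean(rg[np.ix_(mi, mj)])
    return h2_phase, rg_phase
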