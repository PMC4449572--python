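"""Single-step GWAS: SNP-effect back-solving and iterative reweighting.

Marker effects are obtained from the genomic breeding values of the
genotyped animals by the linear back-transformation

    u_hat = D Z' G_b^{-1} a_g,

where Z is centered gene content, D the diagonal SNP-variance weights used
to build G = Z D Z', G_b the blended matrix actually employed in the
mixed-model equations, and a_g the per-coefficient GEBV solutions.  In the
first round D carries the expected marker variance (1 / (m 2 p q)); in
subsequent rounds each SNP's weight is replaced by its realized variance
2 p q u_hat^2 (renormalized to constant trace and floored away from zero),
G is rebuilt, the mixed model re-solved, and effects back-solved again.
Two reweighting rounds are the pipeline default.  Each polynomial
coefficient is treated independently (its own weight sequence).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg

from .data import GenotypeMatrix, TrajectoryRecordSet
from .kinship import (
    DEFAULT_BLEND_WEIGHT,
    MarkerScaling,
    RelationshipMatrix,
    blend_and_invert,
    build_G,
    center_genotypes,
)
from .rrmodel import MMESystem, VarianceComponents, solve_mme

__all__ = [
    "SnpEffectSet",
    "backsolve_snp_effects",
    "reweight",
    "SsgwasEngine",
    "N_REWEIGHTS",
    "WEIGHT_FLOOR_REL",
]

#: reweighting rounds after the expected-variance round
N_REWEIGHTS = 2
#: weight floor, relative to the mean weight
WEIGHT_FLOOR_REL = 1e-8


@dataclass
class SnpEffectSet:
    """Per-coefficient SNP effects with the weights that produced them."""

    snp_map: pd.DataFrame = field(repr=False)
    freq: np.ndarray = field(repr=False)
    effects: np.ndarray = field(repr=False)  # (3, m)
    weights: np.ndarray = field(repr=False)  # (3, m) D diagonal per coefficient
    iteration: int = 0

    def __post_init__(self) -> None:
        m = len(self.snp_map)
        if self.effects.shape != (3, m) or self.weights.shape != (3, m):
            raise ValueError("effects/weights must be (3, n_snp)")
        if np.any(self.weights <= 0):
            raise ValueError("weights must stay above the floor (> 0)")

    def to_frame(self) -> pd.DataFrame:
        df = self.snp_map.copy()
        for k in range(3):
            df[f"effect_c{k}"] = self.effects[k]
            df[f"weight_c{k}"] = self.weights[k]
        df["iteration"] = self.iteration
        return df


def backsolve_snp_effects(
    Z: np.ndarray,
    weights: np.ndarray,
    G_blended: np.ndarray,
    gebv: np.ndarray,
) -> np.ndarray:
    """u_hat = D Z' G_b^{-1} a for one coefficient.

    ``Z`` is the centered gene content of the genotyped animals (same rows
    as ``gebv``), ``weights`` the D diagonal used to build the G inside
    ``G_blended``.
    """
    if Z.shape[0] != len(gebv):
        raise ValueError("GEBV vector does not match genotype rows")
    sol = linalg.solve(G_blended, gebv, assume_a="pos")
    return weights * (Z.T @ sol)


def reweight(effects: SnpEffectSet, floor_rel: float = WEIGHT_FLOOR_REL) -> SnpEffectSet:
    """Realized-variance reweighting d_i <- 2 p q u_hat^2, per coefficient.

    Weights are renormalized so sum(d 2 p q) is preserved (constant trace
    of G across rounds) and floored at ``floor_rel`` times the mean weight
    so no SNP is ever excluded outright.  An all-zero effect vector resets
    that coefficient to uniform expected weights with a warning.
    """
    p = effects.freq
    het = 2.0 * p * (1.0 - p)
    new_w = np.empty_like(effects.weights)
    for k in range(3):
        target = float(np.sum(effects.weights[k] * het))
        d = het * effects.effects[k] ** 2
        total = float(np.sum(d * het))
        if total <= 0:
            import warnings

            warnings.warn(
                f"all SNP effects zero for coefficient {k}; uniform weights restored"
            )
            new_w[k] = effects.weights[k]
            continue
        d *= target / total
        floor = floor_rel * float(d.mean())
        new_w[k] = np.maximum(d, floor)
    return replace(
        effects, weights=new_w, effects=effects.effects.copy(),
        iteration=effects.iteration + 1,
    )


class SsgwasEngine:
    """Runs the MME -> back-solve -> reweight chain for one trait.

    Holds everything that is constant across reweighting rounds and
    bootstrap replicates: the record design, the pedigree A and its
    genotyped block, centered gene content, and the variance components
    (fixed at their full-data estimates).
    """

    def __init__(
        self,
        records: TrajectoryRecordSet,
        A: RelationshipMatrix,
        geno: GenotypeMatrix,
        vc: VarianceComponents,
        standardizer=None,
        normalized_basis: bool = True,
        blend_weight: float = DEFAULT_BLEND_WEIGHT,
        freq: np.ndarray | None = None,
    ):
        self.records = records
        self.A = A
        self.geno = geno
        self.vc = vc
        self.blend_weight = blend_weight
        # observed frequencies by default; supplying base-population (e.g.
        # founder) frequencies keeps G non-singular when no blending is used
        self.Z, self.freq = center_genotypes(geno, freq)
        self.scaling = MarkerScaling.expected(self.freq)
        pos = {a: i for i, a in enumerate(A.animal)}
        self.gidx = np.asarray([pos[a] for a in geno.animal], dtype=np.int64)
        self.A22 = A.matrix[np.ix_(self.gidx, self.gidx)]
        self._round0 = None
        self._base_system = None
        self._Ainv_cache = None
        self._A22inv_cache = None
        self.standardizer = standardizer
        self.normalized_basis = normalized_basis

    # -- plumbing ----------------------------------------------------------
    def _hinv_for(self, weights: np.ndarray) -> tuple[RelationshipMatrix, np.ndarray]:
        """H^-1 and the blended G for a given D diagonal.

        A^-1 and A22^-1 never change across reweighting rounds or bootstrap
        replicates and are cached.
        """
        from .kinship import _sym_inv

        if self._Ainv_cache is None:
            self._Ainv_cache = _sym_inv(self.A.matrix)
            self._A22inv_cache = _sym_inv(self.A22)
        G = (self.Z * weights) @ self.Z.T
        Gb = self.blend_weight * G + (1.0 - self.blend_weight) * self.A22
        Gb = 0.5 * (Gb + Gb.T)
        Hinv = self._Ainv_cache.copy()
        Hinv[np.ix_(self.gidx, self.gidx)] += _sym_inv(Gb) - self._A22inv_cache
        return (
            RelationshipMatrix(self.A.animal, Hinv, "H_inverse"),
            Gb,
        )

    def _system(self, hinv: RelationshipMatrix) -> MMESystem:
        if self._base_system is None:
            self._base_system = MMESystem(
                self.records,
                hinv,
                standardizer=self.standardizer,
                normalized_basis=self.normalized_basis,
            )
            return self._base_system
        return self._base_system.with_hinv(hinv)

    def solve_gebv(self, weights: np.ndarray, y: np.ndarray | None = None):
        """Solve the MME under G(D) and return (fit, G_blended).

        The expected-variance round is cached: its coefficient matrix is
        identical for every coefficient chain and bootstrap replicate.
        """
        if self._round0 is not None and np.array_equal(
            weights, self.scaling.weights
        ):
            factor, gb = self._round0
        else:
            hinv, gb = self._hinv_for(weights)
            system = self._system(hinv)
            factor = system.factor(self.vc)
            if np.array_equal(weights, self.scaling.weights):
                self._round0 = (factor, gb)
        fit = solve_mme(factor, y=y)
        return fit, gb

    # -- the public chain --------------------------------------------------
    def run(
        self,
        n_reweights: int = N_REWEIGHTS,
        y: np.ndarray | None = None,
        coefficients=(0, 1, 2),
        initial_weights: np.ndarray | None = None,
    ) -> tuple[SnpEffectSet, dict]:
        """Expected-variance round plus ``n_reweights`` realized rounds.

        ``initial_weights`` overrides the expected-variance D of the first
        round (used e.g. to exclude a window's SNPs from G by near-zero
        weight).  Returns the final effect set and the last-round fit per
        coefficient requested.
        """
        m = self.geno.n_snp
        w0 = (
            self.scaling.weights if initial_weights is None else
            np.asarray(initial_weights, dtype=float)
        )
        eff = SnpEffectSet(
            snp_map=self.geno.snp_map,
            freq=self.freq,
            effects=np.zeros((3, m)),
            weights=np.tile(w0, (3, 1)),
            iteration=0,
        )
        fits = {}
        for k in coefficients:
            w = w0.copy()
            for it in range(n_reweights + 1):
                fit, gb = self.solve_gebv(w, y=y)
                a_g = fit.u[self.gidx, k]
                u_hat = backsolve_snp_effects(self.Z, w, gb, a_g)
                eff.effects[k] = u_hat
                eff.weights[k] = w
                if it < n_reweights:
                    single = SnpEffectSet(
                        snp_map=self.geno.snp_map,
                        freq=self.freq,
                        effects=np.tile(u_hat, (3, 1)),
                        weights=np.tile(w, (3, 1)),
                        iteration=it,
                    )
                    w = reweight(single).weights[0]
            fits[k] = fit
        eff.iteration = n_reweights
        return eff, fits
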