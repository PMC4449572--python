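"""Mixed-model equations, EM-REML and trajectory summaries."""
import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from trajgwas.basis import AgeStandardizer, legendre_matrix
from trajgwas.data import GenotypeMatrix, PedigreeTable, TrajectoryRecordSet
from trajgwas.kinship import (
    MarkerScaling,
    RelationshipMatrix,
    blend_and_invert,
    build_A,
    build_A_inverse,
    build_G,
)
from trajgwas.rrmodel import (
    MMESystem,
    VarianceComponents,
    assemble_mme,
    em_reml,
    moment_start_values,
    phase_summary,
    solve_mme,
    trajectory_h2_rg,
)
from trajgwas.simulate import SimulationConfig, simulate_pedigree, simulate_genotypes, simulate_phenotypes

STD = AgeStandardizer(90.0, 175.0)


def five_animal_toy(seed=0):
    """Hand-assembled 5-animal pedigree, 3 genotyped, with records."""
    rng = np.random.default_rng(seed)
    ped = PedigreeTable([1, 2, 3, 4, 5], [0, 0, 1, 1, 3], [0, 0, 2, 2, 4])
    codes = rng.integers(0, 3, size=(3, 20)).astype(np.int8)
    snp_map = pd.DataFrame(
        {"snp_id": [f"s{i}" for i in range(20)], "chrom": 1,
         "pos": 1000 * (np.arange(20) + 1)}
    )
    geno = GenotypeMatrix([3, 4, 5], codes, snp_map)
    A = build_A(ped)
    G, _ = build_G(geno, MarkerScaling.expected(np.full(20, 0.4)))
    hinv, _ = blend_and_invert(A, G, w=0.95)
    rows = []
    for animal in ped.animal:
        ages = np.sort(rng.choice(np.arange(90, 176), size=8, replace=False))
        for age in ages:
            rows.append(
                {"animal": animal, "age_days": float(age),
                 "value": rng.normal(50, 5), "cg": int(animal % 2),
                 "parity": int(1 + animal % 3)}
            )
    return ped, hinv, TrajectoryRecordSet(pd.DataFrame(rows))


class TestMMEAgainstGLS:
    def test_solutions_match_direct_gls(self):
        """MME solutions equal textbook GLS/BLUP computed from the joint
        covariance matrix on the 5-animal toy."""
        ped, hinv, records = five_animal_toy()
        vc = VarianceComponents(
            np.diag([3.0, 1.0, 0.4]), np.diag([1.0, 0.5, 0.2]), 2.0
        )
        factor = assemble_mme(records, hinv, vc, standardizer=STD)
        fit = solve_mme(factor)
        sys = factor.system
        n_rec, N = sys.n_rec, sys.n_animals
        H = linalg.inv(hinv.matrix)
        Gu = np.kron(H, vc.G_a)
        Wu = np.zeros((n_rec, 3 * N))
        Wpe = np.zeros((n_rec, 3 * sys.n_pheno))
        for r in range(n_rec):
            m = sys.rec_uidx[r]
            Wu[r, 3 * m : 3 * m + 3] = sys.phi[r]
            p = sys.rec_pidx[r]
            Wpe[r, 3 * p : 3 * p + 3] = sys.phi[r]
        Gpe = np.kron(np.eye(sys.n_pheno), vc.P_pe)
        V = Wu @ Gu @ Wu.T + Wpe @ Gpe @ Wpe.T + vc.sigma_e2 * np.eye(n_rec)
        X = sys.X
        y = records.df["value"].to_numpy()
        Vi = linalg.inv(V)
        b = linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        resid = y - X @ b
        u = (Gu @ Wu.T @ Vi @ resid).reshape(N, 3)
        pe = (Gpe @ Wpe.T @ Vi @ resid).reshape(sys.n_pheno, 3)
        assert np.allclose(fit.b, b, atol=1e-10)
        assert np.allclose(fit.u, u, atol=1e-10)
        assert np.allclose(fit.pe, pe, atol=1e-10)


class TestSolveProperties:
    @pytest.fixture()
    def toy(self):
        ped, hinv, records = five_animal_toy(3)
        vc = VarianceComponents(
            np.diag([3.0, 1.0, 0.4]), np.diag([1.0, 0.5, 0.2]), 2.0
        )
        return ped, hinv, records, vc

    def test_zero_phenotypes_zero_solutions(self, toy):
        _, hinv, records, vc = toy
        factor = assemble_mme(records, hinv, vc, standardizer=STD)
        fit = solve_mme(factor, y=np.zeros(len(records)))
        assert np.allclose(fit.u, 0) and np.allclose(fit.pe, 0)

    def test_record_order_invariance(self, toy):
        _, hinv, records, vc = toy
        fit1 = solve_mme(assemble_mme(records, hinv, vc, standardizer=STD))
        perm = np.random.default_rng(0).permutation(len(records))
        shuffled = TrajectoryRecordSet(records.df.iloc[perm])
        fit2 = solve_mme(assemble_mme(shuffled, hinv, vc, standardizer=STD))
        assert np.allclose(fit1.u, fit2.u, atol=1e-9)
        assert np.allclose(fit1.b, fit2.b, atol=1e-9)

    def test_duplicated_records_halved_residual(self, toy):
        """Duplicating every record is equivalent to halving the residual
        variance: solutions coincide."""
        _, hinv, records, vc = toy
        vc_half = VarianceComponents(vc.G_a, vc.P_pe, vc.sigma_e2 / 2)
        fit1 = solve_mme(assemble_mme(records, hinv, vc_half, standardizer=STD))
        doubled = TrajectoryRecordSet(
            pd.concat([records.df, records.df], ignore_index=True)
        )
        fit2 = solve_mme(assemble_mme(doubled, hinv, vc, standardizer=STD))
        assert np.allclose(fit1.u, fit2.u, atol=1e-8)
        assert np.allclose(fit1.b, fit2.b, atol=1e-8)

    def test_infinite_shrinkage_limit(self, toy):
        _, hinv, records, vc = toy
        tiny = VarianceComponents(1e-10 * np.eye(3), vc.P_pe, vc.sigma_e2)
        fit = solve_mme(assemble_mme(records, hinv, tiny, standardizer=STD))
        assert np.abs(fit.u).max() < 1e-4


class TestSparseDenseAgreement:
    def test_factor_solve_loglik_and_em_agree(self):
        cfg = SimulationConfig(n_founders=25, n_generations=2, n_chrom=1,
                               n_snp_per_chrom=2, seed=5)
        ped = simulate_pedigree(cfg)
        geno, maf = simulate_genotypes(ped, cfg)
        rec, _ = simulate_phenotypes(ped, geno, cfg, founder_freq=maf)
        vc = VarianceComponents(np.diag([3.0, 1.0, 0.3]),
                                np.diag([1.5, 0.4, 0.1]), 3.0)
        y = rec.df["value"].to_numpy()
        hd = RelationshipMatrix(
            ped.animal, linalg.inv(build_A(ped).matrix), "H_inverse"
        )
        hs = build_A_inverse(ped)
        fd = MMESystem(rec, hd, standardizer=cfg.standardizer).factor(
            vc, want_inverse=True
        )
        fs = MMESystem(rec, hs, standardizer=cfg.standardizer).factor(
            vc, want_inverse=True
        )
        bd, ud, ped_d = fd.solve(y)
        bs, us, pes = fs.solve(y)
        assert np.allclose(bd, bs, atol=1e-9)
        assert np.allclose(ud, us, atol=1e-9)
        assert np.allclose(ped_d, pes, atol=1e-9)
        assert fd.reml_loglik() == pytest.approx(fs.reml_loglik(), abs=1e-6)
        nd, ns = fd.em_update(), fs.em_update()
        assert np.allclose(nd.G_a, ns.G_a, atol=1e-10)
        assert np.allclose(nd.P_pe, ns.P_pe, atol=1e-10)
        assert nd.sigma_e2 == pytest.approx(ns.sigma_e2, rel=1e-10)


class TestEMReml:
    def test_loglik_monotone_and_improves(self):
        cfg = SimulationConfig(n_founders=40, n_generations=2, n_chrom=1,
                               n_snp_per_chrom=2, seed=2)
        ped = simulate_pedigree(cfg)
        geno, maf = simulate_genotypes(ped, cfg)
        rec, _ = simulate_phenotypes(ped, geno, cfg, founder_freq=maf)
        hinv = build_A_inverse(ped)
        init = VarianceComponents(np.eye(3), np.eye(3), 1.0)
        vc, log = em_reml(rec, hinv, init, tol=1e-4, max_iter=40,
                          standardizer=cfg.standardizer)
        lls = log.loglik
        assert all(b >= a - 1e-6 * (1 + abs(a)) for a, b in zip(lls, lls[1:]))
        assert lls[-1] > lls[0]

    def test_zero_pe_boundary_recovery(self):
        """Data generated without permanent environment: the PE estimate
        collapses toward zero relative to the genetic covariance."""
        cfg = SimulationConfig(n_founders=100, n_generations=2, n_chrom=1,
                               n_snp_per_chrom=2, seed=13,
                               pe_cov=np.zeros((3, 3)))
        ped = simulate_pedigree(cfg)
        geno, maf = simulate_genotypes(ped, cfg)
        rec, _ = simulate_phenotypes(ped, geno, cfg, founder_freq=maf)
        hinv = build_A_inverse(ped)
        init = moment_start_values(rec, cfg.standardizer, pedigree=ped)
        vc, log = em_reml(rec, hinv, init, tol=1e-4, max_iter=120,
                          standardizer=cfg.standardizer)
        assert np.trace(vc.P_pe) < 0.15 * np.trace(vc.G_a)

    def test_near_stationarity_at_truth(self):
        """One EM step from the generating values barely moves them on a
        large dataset."""
        cfg = SimulationConfig(n_founders=300, n_generations=3, n_chrom=1,
                               n_snp_per_chrom=2, seed=21)
        ped = simulate_pedigree(cfg)
        geno, maf = simulate_genotypes(ped, cfg)
        rec, _ = simulate_phenotypes(ped, geno, cfg, founder_freq=maf)
        hinv = build_A_inverse(ped)
        truth = VarianceComponents(cfg.genetic_cov, cfg.pe_cov, cfg.resid_var)
        system = MMESystem(rec, hinv, standardizer=cfg.standardizer)
        fac = system.factor(truth, want_inverse=True)
        fac.solve(rec.df["value"].to_numpy())
        new = fac.em_update()
        assert np.abs(np.diag(new.G_a) - np.diag(truth.G_a)).max() < 0.15 * 4
        assert abs(new.sigma_e2 - truth.sigma_e2) / truth.sigma_e2 < 0.05


class TestTrajectorySummaries:
    def test_h2_is_one_without_noise_sources(self):
        vc = VarianceComponents(np.diag([4.0, 1.0, 0.25]),
                                np.zeros((3, 3)), 1e-12)
        h2, rg = trajectory_h2_rg(vc, np.arange(90, 176), STD)
        assert np.allclose(h2, 1.0, atol=1e-9)

    def test_rank_one_covariance_perfect_correlation(self):
        v = np.array([1.0, 0.4, -0.2])
        vc = VarianceComponents(np.outer(v, v) * 2, np.eye(3), 1.0)
        _, rg = trajectory_h2_rg(vc, np.arange(90, 176), STD)
        assert np.allclose(np.abs(rg), 1.0, atol=1e-9)

    def test_two_route_equality_with_covariance_function(self):
        vc = VarianceComponents(np.diag([1.0, 1.0, 1.0]),
                                np.diag([0.5, 0.2, 0.1]), 1.0)
        ages = np.array([90.0, 120.0, 175.0])
        _, rg = trajectory_h2_rg(vc, ages, STD)
        phi = legendre_matrix(STD.transform(ages))
        C = phi @ vc.G_a @ phi.T
        expected = C / np.sqrt(np.outer(np.diag(C), np.diag(C)))
        assert np.allclose(rg, expected, atol=1e-12)
        assert rg[0, 0] == pytest.approx(1.0)

    def test_h2_invariant_to_basis_normalization(self):
        """The same fit expressed in raw vs normalized coefficients gives
        identical h2(t): transform the covariances with the change of
        basis T (phi_norm = T phi_raw)."""
        rng = np.random.default_rng(5)
        L = rng.standard_normal((3, 3))
        Ga = L @ L.T
        P = np.diag([0.5, 0.2, 0.1])
        T = np.diag(np.sqrt((2 * np.arange(3) + 1) / 2.0))
        vc_norm = VarianceComponents(Ga, P, 2.0)
        vc_raw = VarianceComponents(T @ Ga @ T, T @ P @ T, 2.0)
        ages = np.arange(90, 176, dtype=float)
        h2n, _ = trajectory_h2_rg(vc_norm, ages, STD, normalized_basis=True)
        h2r, _ = trajectory_h2_rg(vc_raw, ages, STD, normalized_basis=False)
        assert np.allclose(h2n, h2r, atol=1e-10)

    def test_phase_summary_shapes(self):
        vc = VarianceComponents(np.diag([4.0, 1.0, 0.25]),
                                np.diag([2.0, 0.5, 0.1]), 4.0)
        h2p, rgp = phase_summary(vc, STD)
        assert h2p.shape == (3,) and rgp.shape == (3, 3)
        assert np.allclose(np.diag(rgp), 1.0, atol=0.05)
        assert np.all((h2p > 0) & (h2p < 1))
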