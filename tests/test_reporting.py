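"""Variance-explained accounting, correlation tables, annotation, pipeline."""
import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from trajgwas.reporting import (
    annotate_regions,
    gebv_correlation_table,
    run_pipeline,
    variance_explained,
)
from trajgwas.windows import WindowScanResult


def region_frame(rows):
    df = pd.DataFrame(rows)
    if "region_id" not in df:
        df["region_id"] = np.arange(len(df))
    return df


class TestVarianceExplained:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.Z = rng.standard_normal((50, 40))
        self.eff = rng.standard_normal((3, 40))

    def test_whole_genome_region_is_100_percent(self):
        regions = region_frame(
            [{"coefficient": k, "start_idx": 0, "end_idx": 40}
             for k in range(3)]
        )
        out = variance_explained(self.Z, self.eff, regions)
        for k in range(3):
            assert out["per_coefficient"][k]["cumulative_pct"] == pytest.approx(
                100.0
            )
        assert out["whole_trajectory_pct"] == pytest.approx(100.0)

    def test_empty_region_set_zero_percent(self):
        out = variance_explained(self.Z, self.eff, region_frame([]).assign())
        assert out["whole_trajectory_pct"] == 0.0
        for k in range(3):
            assert out["per_coefficient"][k]["cumulative_pct"] == 0.0

    def test_denominator_equals_total_genomic_variance(self):
        regions = region_frame(
            [{"coefficient": 0, "start_idx": 5, "end_idx": 15}]
        )
        out = variance_explained(self.Z, self.eff, regions)
        for k in range(3):
            assert out["per_coefficient"][k][
                "denominator_variance"
            ] == pytest.approx(np.var(self.Z @ self.eff[k], ddof=1), abs=1e-10)

    def test_additivity_for_orthogonal_genotype_blocks(self):
        """Disjoint regions with independent genotype columns contribute
        additively."""
        rng = np.random.default_rng(1)
        n = 4000
        Z = rng.standard_normal((n, 20))
        eff = np.vstack([np.ones(20), np.ones(20), np.ones(20)])
        regions = region_frame(
            [
                {"coefficient": 0, "start_idx": 0, "end_idx": 5},
                {"coefficient": 0, "start_idx": 10, "end_idx": 15},
            ]
        )
        out = variance_explained(Z, eff, regions)
        parts = [r["pct"] for r in out["per_coefficient"][0]["regions"]]
        assert out["per_coefficient"][0]["cumulative_pct"] == pytest.approx(
            sum(parts)
        )
        assert sum(parts) == pytest.approx(50.0, abs=3.0)


class TestCorrelationTable:
    def test_structure_and_diagonal(self, small_dataset, default_vc):
        rng = np.random.default_rng(2)
        gebv = rng.standard_normal((30, 3))

        class FakeFit:
            vc = default_vc

        scan = WindowScanResult(
            windows=pd.DataFrame(
                {
                    "window_id": [0, 1], "chrom": 1,
                    "start_idx": [0, 1], "end_idx": [10, 11],
                    "start_pos": [1, 2], "end_pos": [10, 11],
                    "var_c0": [1.0, 2.0], "var_c1": [1.0, 2.0],
                    "var_c2": [1.0, 2.0],
                    "cov_c01": [1.0, 2.0], "cov_c02": [0.5, 1.0],
                    "cov_c12": [1.0, 2.0],
                }
            )
        )
        table = gebv_correlation_table(
            {"trait": (FakeFit(), gebv)}, {"trait": scan}
        )
        vc = default_vc
        for k in range(3):
            expected = vc.G_a[k, k] / (
                vc.G_a[k, k] + vc.P_pe[k, k] + vc.sigma_e2
            )
            assert table.iloc[k, k] == pytest.approx(expected)
        # upper triangle: GEBV correlations of the random vectors
        assert abs(table.iloc[0, 1]) < 0.5

    def test_constant_gebv_reported_missing(self, default_vc):
        gebv = np.zeros((10, 3))
        gebv[:, 1] = np.arange(10)
        gebv[:, 2] = np.arange(10) * 2

        class FakeFit:
            vc = default_vc

        scan = WindowScanResult(
            windows=pd.DataFrame(
                {
                    "window_id": [0], "chrom": 1, "start_idx": [0],
                    "end_idx": [10], "start_pos": [1], "end_pos": [10],
                    "var_c0": [0.0], "var_c1": [1.0], "var_c2": [1.0],
                    "cov_c01": [0.0], "cov_c02": [0.0], "cov_c12": [1.0],
                }
            )
        )
        table = gebv_correlation_table(
            {"t": (FakeFit(), gebv)}, {"t": scan}
        )
        assert np.isnan(table.iloc[0, 1])  # zero-variance GEBV vector
        assert table.iloc[1, 2] == pytest.approx(1.0)  # corr of 1:2 scaling


class TestAnnotateRegions:
    def _regions(self):
        return region_frame(
            [
                {"coefficient": 0, "chrom": "1", "start_idx": 0,
                 "end_idx": 10, "start_pos": 1000, "end_pos": 5000},
                {"coefficient": 0, "chrom": "1", "start_idx": 20,
                 "end_idx": 30, "start_pos": 20_000, "end_pos": 30_000},
            ]
        )

    def _annotation(self):
        # three genes constructed on paper: one containing region 1, one
        # ending exactly at region 1's half-open start, one inside region 2
        return pd.DataFrame(
            {
                "chrom": ["1", "1", "1"],
                "start": [500, 0, 22_000],
                "end": [6000, 999, 25_000],
                "gene_id": ["g1", "g2", "g3"],
                "gene_name": ["G1", "G2", "G3"],
            }
        )

    def test_hand_enumerated_overlaps(self):
        ann = annotate_regions(self._regions(), self._annotation())
        assert ann.loc[0, "genes"] == "G1"  # G2 ends 1 bp before the span
        assert ann.loc[1, "genes"] == "G3"

    def test_boundary_half_open(self):
        regions = region_frame(
            [{"coefficient": 0, "chrom": "1", "start_idx": 0, "end_idx": 10,
              "start_pos": 1000, "end_pos": 2000}]
        )
        ann = pd.DataFrame(
            {"chrom": ["1"], "start": [0], "end": [999],
             "gene_id": ["gx"], "gene_name": ["GX"]}
        )
        out = annotate_regions(regions, ann)
        assert out.loc[0, "n_genes"] == 0


class TestPipeline:
    CONFIG = {
        "simulation": {
            "n_founders": 40, "n_generations": 2, "n_chrom": 2,
            "n_snp_per_chrom": 60, "seed": 5,
            "qtl_spec": [[0, 30, 0, 2.5]],
        },
        "reml": {"tol": 1e-3, "max_iter": 40},
        "bootstrap": {"n_reps": 0},
    }

    def test_zero_replicates_skips_bootstrap(self, tmp_path):
        result = run_pipeline(self.CONFIG, outdir=tmp_path / "out")
        assert result.bootstrap == []
        assert (tmp_path / "out" / "summary.json").exists()
        assert (tmp_path / "out" / "regions.bed").exists()

    def test_rerun_same_seed_identical_archive(self, tmp_path):
        h = []
        for d in ("a", "b"):
            run_pipeline(self.CONFIG, outdir=tmp_path / d)
            digest = hashlib.sha256()
            for f in sorted((tmp_path / d).iterdir()):
                digest.update(f.name.encode())
                digest.update(f.read_bytes())
            h.append(digest.hexdigest())
        assert h[0] == h[1]
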