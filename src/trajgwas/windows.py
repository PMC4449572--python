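"""Sliding-window GEBV variance scan and two-stage putative-QTL selection.

For each 10-SNP window w (step 1, never spanning chromosomes) and animal a
the window GEBV is

    WGEBV[a, w] = sum over SNP i in w of z_ai * u_hat_i

with centered gene content z; the scan statistic is the across-animal
variance of WGEBV, computed per polynomial coefficient.  Selection is
two-stage, per coefficient: stage 1 keeps the top 5 % of windows by
variance; stage 2 merges surviving windows that share at least one SNP
into regions, ranks regions by their maximum member variance and tags the
top 10 % (ceiling) as putative QTL.  Windows are indexed 0-based half-open
internally; reported coordinates are 1-based inclusive.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WindowScanResult",
    "window_gebv",
    "window_scan",
    "select_putative_qtl",
    "window_covariance",
    "WINDOW_SIZE",
]

log = logging.getLogger(__name__)

WINDOW_SIZE = 10
TOP_WINDOW_FRAC = 0.05
TOP_REGION_FRAC = 0.10


@dataclass
class WindowScanResult:
    """Window table plus (optionally) per-animal window GEBV arrays."""

    windows: pd.DataFrame = field(repr=False)
    wgebv: dict = field(default_factory=dict, repr=False)  # coeff -> (n, n_win)

    def __len__(self) -> int:
        return len(self.windows)


def _window_starts(snp_map: pd.DataFrame, window_size: int, step: int):
    """(chrom, global start index) pairs; windows never span chromosomes."""
    out = []
    for chrom, sub in snp_map.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        if np.any(np.diff(idx) != 1):
            raise ValueError("snp_map must be contiguous within chromosome")
        m = len(idx)
        if m < window_size:
            log.info("chromosome %s has %d SNP (< %d): no windows", chrom, m,
                     window_size)
            continue
        for s in range(0, m - window_size + 1, step):
            out.append((chrom, idx[0] + s))
    return out


def window_gebv(
    Z: np.ndarray,
    effects: np.ndarray,
    snp_map: pd.DataFrame,
    window_size: int = WINDOW_SIZE,
    step: int = 1,
) -> tuple[np.ndarray, list]:
    """Per-animal sliding-window GEBV for one coefficient.

    Returns ``(values, starts)`` where values is (n_animals, n_windows)
    and starts the list of (chrom, global SNP start index).
    """
    contrib = Z * effects  # (n, m)
    csum = np.concatenate(
        [np.zeros((Z.shape[0], 1)), np.cumsum(contrib, axis=1)], axis=1
    )
    starts = _window_starts(snp_map, window_size, step)
    vals = np.empty((Z.shape[0], len(starts)))
    for j, (_, s) in enumerate(starts):
        vals[:, j] = csum[:, s + window_size] - csum[:, s]
    return vals, starts


def window_scan(
    Z: np.ndarray,
    effects_by_coeff: np.ndarray,
    snp_map: pd.DataFrame,
    window_size: int = WINDOW_SIZE,
    step: int = 1,
    keep_wgebv: bool = False,
) -> WindowScanResult:
    """Window variances for all three coefficients plus cross-coefficient
    covariances (sample moments across animals)."""
    rows = None
    wg = {}
    per_coeff = {}
    for k in range(effects_by_coeff.shape[0]):
        vals, starts = window_gebv(Z, effects_by_coeff[k], snp_map,
                                   window_size, step)
        per_coeff[k] = vals
        if keep_wgebv:
            wg[k] = vals
        if rows is None:
            rows = pd.DataFrame(
                {
                    "chrom": [c for c, _ in starts],
                    "start_idx": [s for _, s in starts],
                }
            )
            rows["end_idx"] = rows["start_idx"] + window_size
            rows["start_pos"] = snp_map["pos"].to_numpy()[rows["start_idx"]]
            rows["end_pos"] = snp_map["pos"].to_numpy()[rows["end_idx"] - 1]
        rows[f"var_c{k}"] = vals.var(axis=0, ddof=1)
    # cross-coefficient covariance per window
    for a in range(effects_by_coeff.shape[0]):
        for b in range(a + 1, effects_by_coeff.shape[0]):
            va, vb = per_coeff[a], per_coeff[b]
            ca = va - va.mean(axis=0)
            cb = vb - vb.mean(axis=0)
            rows[f"cov_c{a}{b}"] = (ca * cb).sum(axis=0) / (len(va) - 1)
    rows.insert(0, "window_id", np.arange(len(rows)))
    return WindowScanResult(windows=rows, wgebv=wg)


def select_putative_qtl(
    scan: WindowScanResult,
    coefficient: int,
    top_window_frac: float = TOP_WINDOW_FRAC,
    top_region_frac: float = TOP_REGION_FRAC,
    window_size: int = WINDOW_SIZE,
) -> pd.DataFrame:
    """Two-stage selection for one coefficient.

    Returns the region table (one row per aggregated region) with 1-based
    inclusive SNP coordinates, the member window ids, the maximum member
    WGEBV variance, region rank and the putative-QTL flag.
    """
    df = scan.windows
    if len(df) == 0:
        raise ValueError("no windows to select from")
    var = df[f"var_c{coefficient}"].to_numpy()
    n_keep = math.ceil(top_window_frac * len(df))
    order = np.argsort(var)[::-1]
    kept = df.iloc[np.sort(order[:n_keep])]

    regions = []
    cur = None
    for _, w in kept.sort_values(["chrom", "start_idx"]).iterrows():
        if (
            cur is not None
            and w["chrom"] == cur["chrom"]
            and w["start_idx"] < cur["end_idx"]  # shares >= 1 SNP index
        ):
            cur["end_idx"] = max(cur["end_idx"], w["end_idx"])
            cur["end_pos"] = max(cur["end_pos"], w["end_pos"])
            cur["max_var"] = max(cur["max_var"], w[f"var_c{coefficient}"])
            cur["members"].append(int(w["window_id"]))
        else:
            if cur is not None:
                regions.append(cur)
            cur = {
                "chrom": w["chrom"],
                "start_idx": int(w["start_idx"]),
                "end_idx": int(w["end_idx"]),
                "start_pos": w["start_pos"],
                "end_pos": w["end_pos"],
                "max_var": w[f"var_c{coefficient}"],
                "members": [int(w["window_id"])],
            }
    if cur is not None:
        regions.append(cur)
    reg = pd.DataFrame(regions)
    reg["n_windows"] = reg["members"].apply(len)
    reg = reg.sort_values("max_var", ascending=False).reset_index(drop=True)
    reg.insert(0, "region_id", np.arange(len(reg)))
    reg["rank"] = np.arange(1, len(reg) + 1)
    n_flag = math.ceil(top_region_frac * len(reg))
    reg["putative"] = reg["rank"] <= n_flag
    reg["coefficient"] = coefficient
    # 1-based inclusive coordinates for reporting
    reg["start_snp_1based"] = reg["start_idx"] + 1
    reg["end_snp_1based"] = reg["end_idx"]
    return reg


def window_covariance(scan: WindowScanResult) -> pd.DataFrame:
    """Genome-averaged WGEBV correlations per coefficient pair.

    A window pair with zero variance in either member contributes a
    missing correlation.
    """
    df = scan.windows
    ks = sorted(
        int(c[len("var_c"):]) for c in df.columns if c.startswith("var_c")
    )
    rows = []
    for a in ks:
        for b in ks:
            if a >= b:
                continue
            va = df[f"var_c{a}"].to_numpy()
            vb = df[f"var_c{b}"].to_numpy()
            cov = df[f"cov_c{a}{b}"].to_numpy()
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = cov / np.sqrt(va * vb)
            corr[(va <= 0) | (vb <= 0)] = np.nan
            rows.append(
                {
                    "coeff_a": a,
                    "coeff_b": b,
                    "mean_correlation": float(np.nanmean(corr)),
                    "n_windows": int(np.isfinite(corr).sum()),
                }
            )
    return pd.DataFrame(rows)
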