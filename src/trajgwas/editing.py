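"""Phenotype cleaning and genotype quality control.

Two longitudinal traits feed the analysis: daily feed intake and body
weight.  Feed intake follows a four-step visit-error procedure: flag
erroneous feeder visits with a configurable rule registry, sum error-free
intake within animal-day, estimate the intake lost to error visits with a
linear mixed model (error counts, contemporary group, body weight and
average daily gain as covariates, animal as a random effect), and add the
estimated loss back to each affected day.  Animals with fewer than 20
adjusted daily records are removed.

Body weight is cleaned per animal by iteratively reweighted robust
regression (Tukey bisquare, tuning constant 4.685) of weight on a
quadratic in on-test day and a linear term in on-test age; records with
robust weight below 0.5 are outliers, animals whose weight-on-age slope
(on-test ADG) falls outside [0.4, 2.0] kg/d are dropped, and surviving
same-day weights are averaged.

Genotype QC removes animals and SNP with call rate <= 0.90, SNP with minor
allele frequency <= 0.02 and SNP failing a Hardy-Weinberg chi-square test
(p < 1e-4), in the order animal call rate -> SNP call rate -> MAF -> HWE;
a stricter MAF < 0.002 filter is re-applied on the analysis subset.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .data import GenotypeMatrix, TrajectoryRecordSet

__all__ = [
    "VisitRuleRegistry",
    "DEFAULT_VISIT_RULES",
    "EditReport",
    "adjust_daily_feed_intake",
    "edit_body_weight",
    "qc_genotypes",
]

log = logging.getLogger(__name__)

BISQUARE_C = 4.685
ROBUST_WEIGHT_CUTOFF = 0.5
ADG_BOUNDS = (0.4, 2.0)
MIN_DAILY_RECORDS = 20


@dataclass
class EditReport:
    """Record accounting per editing rule; input = output + removals."""

    records_in: int = 0
    records_out: int = 0
    removals: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)

    def check(self) -> None:
        if self.records_in != self.records_out + sum(self.removals.values()):
            raise AssertionError("edit report does not reconcile")


class VisitRuleRegistry:
    """Named visit-error rules; each maps a visit frame to a boolean mask.

    The per-visit error profile is the vector of triggered-rule indicators;
    summed within animal-day these become the error-count covariates of the
    adjustment model.
    """

    def __init__(self):
        self._rules: dict = {}

    def register(self, name: str, fn) -> None:
        self._rules[name] = fn

    def names(self) -> list:
        return list(self._rules)

    def apply(self, visits: pd.DataFrame) -> pd.DataFrame:
        flags = pd.DataFrame(index=visits.index)
        for name, fn in self._rules.items():
            flags[name] = np.asarray(fn(visits), dtype=bool)
        return flags


def _default_registry() -> VisitRuleRegistry:
    reg = VisitRuleRegistry()
    reg.register("negative_intake", lambda v: v["intake"] < 0)
    reg.register("huge_intake", lambda v: v["intake"] > 3.0)
    if_has = lambda col, fn: (
        lambda v: fn(v) if col in v.columns else np.zeros(len(v), dtype=bool)
    )
    reg.register(
        "long_occupancy",
        if_has("duration_s", lambda v: v["duration_s"] > 3600.0),
    )
    reg.register(
        "nonpositive_occupancy",
        if_has("duration_s", lambda v: v["duration_s"] <= 0.0),
    )
    reg.register(
        "intake_rate",
        if_has(
            "duration_s",
            lambda v: (v["intake"] / v["duration_s"].clip(lower=1.0)) > 0.01,
        ),
    )
    return reg


DEFAULT_VISIT_RULES = _default_registry()


def adjust_daily_feed_intake(
    visits: pd.DataFrame,
    rules: VisitRuleRegistry = DEFAULT_VISIT_RULES,
    covariates: pd.DataFrame | None = None,
    min_daily_records: int = MIN_DAILY_RECORDS,
) -> tuple[TrajectoryRecordSet, EditReport]:
    """Visit-error adjusted daily feed intake.

    ``visits`` has one row per feeder visit with columns ``animal``,
    ``age_days``, ``intake`` (kg), ``cg``, ``parity`` and any columns the
    rule registry consumes.  ``covariates`` optionally supplies per
    animal-day ``body_weight`` and per-animal ``adg`` used in the
    adjustment model.  Error-flagged visits are excluded from the daily
    sum; the estimated intake lost to error visits (never negative) is
    added back to each animal-day; animals with fewer than
    ``min_daily_records`` adjusted days are removed.
    """
    if visits["animal"].nunique() < 2:
        raise ValueError("need at least two animals to fit the adjustment model")
    flags = rules.apply(visits)
    any_flag = flags.any(axis=1)
    rule_names = rules.names()

    keyed = visits[["animal", "age_days", "intake", "cg", "parity"]].copy()
    clean_sum = (
        keyed[~any_flag.to_numpy()]
        .groupby(["animal", "age_days"], as_index=False)
        .agg(value=("intake", "sum"), cg=("cg", "first"), parity=("parity", "first"))
    )
    counts = (
        flags.assign(animal=visits["animal"], age_days=visits["age_days"])
        .groupby(["animal", "age_days"], as_index=False)[rule_names]
        .sum()
    )
    day = clean_sum.merge(counts, on=["animal", "age_days"], how="left").fillna(0)

    if covariates is not None:
        day = day.merge(covariates, on=["animal", "age_days"], how="left")

    # adjustment model: error-free daily intake on error counts (+ CG, body
    # weight, ADG where available), animal as random effect
    terms = [c for c in rule_names if day[c].to_numpy().std() > 0]
    exog_cols = list(terms)
    for extra in ("body_weight", "adg"):
        if extra in day.columns and day[extra].notna().all():
            exog_cols.append(extra)
    X = pd.get_dummies(day["cg"].astype("category"), prefix="cg", drop_first=True)
    X = pd.concat([day[exog_cols], X], axis=1).astype(float)
    X = sm.add_constant(X)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular fixed-effect design in the adjustment model")
    coef = {}
    coef_se = {}
    if terms:
        model = sm.MixedLM(
            day["value"].to_numpy(dtype=float), X, groups=day["animal"].to_numpy()
        )
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
        coef = {
            c: float(np.asarray(fit.fe_params)[X.columns.get_loc(c)])
            for c in terms
        }
        coef_se = {
            c: float(np.asarray(fit.bse_fe)[X.columns.get_loc(c)])
            for c in terms
        }

    lost = np.zeros(len(day))
    for c, beta in coef.items():
        # a negative coefficient means intake lost per error visit; the
        # adjustment adds it back and never decreases the daily value
        lost += day[c].to_numpy(dtype=float) * max(0.0, -beta)
    day["value"] = day["value"].to_numpy(dtype=float) + lost

    n_days = day.groupby("animal")["value"].transform("size")
    kept = day[n_days >= min_daily_records]
    report = EditReport(
        records_in=len(day),
        records_out=len(kept),
        removals={"min_daily_records": int(len(day) - len(kept))},
        details={
            "visits_flagged": int(any_flag.sum()),
            "per_rule_visit_flags": {c: int(flags[c].sum()) for c in rule_names},
            "adjustment_coefficients": coef,
            "adjustment_coefficient_se": coef_se,
        },
    )
    report.check()
    out = kept[["animal", "age_days", "value", "cg", "parity"]].reset_index(drop=True)
    return TrajectoryRecordSet(out), report


def edit_body_weight(
    records: TrajectoryRecordSet,
    adg_bounds: tuple[float, float] = ADG_BOUNDS,
    weight_cutoff: float = ROBUST_WEIGHT_CUTOFF,
) -> tuple[TrajectoryRecordSet, EditReport]:
    """Robust-regression weight cleaning and daily averaging.

    Per animal, weight is fitted by iteratively reweighted least squares
    with the Tukey bisquare weight function on a quadratic in on-test day
    and a linear term in age; records with robust weight < ``weight_cutoff``
    are removed.  On-test ADG is then the OLS slope of weight on age, and
    animals outside ``adg_bounds`` (kg/d) are removed.  Surviving same-day
    weights are averaged.
    """
    df = records.df
    kept_parts = []
    n_outliers = 0
    n_adg_removed = 0
    n_too_few = 0
    robust_weights = {}
    for animal, sub in df.groupby("animal"):
        sub = sub.sort_values("age_days")
        if len(sub) < 3:
            n_too_few += len(sub)
            continue
        d = sub["age_days"].to_numpy(dtype=float)
        d_on = d - d[0]
        X = np.column_stack([np.ones_like(d), d_on, d_on**2, d])
        # quadratic on-test day + linear age are collinear up to a shift;
        # drop the redundant column for the robust fit
        X = X[:, :3]
        y = sub["value"].to_numpy(dtype=float)
        rlm = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
        res = rlm.fit(conv="weights", maxiter=50)
        w = np.asarray(res.weights)
        robust_weights[animal] = w
        ok = w >= weight_cutoff
        n_outliers += int((~ok).sum())
        sub = sub[ok]
        if len(sub) < 2:
            n_too_few += len(sub)
            continue
        d2 = sub["age_days"].to_numpy(dtype=float)
        y2 = sub["value"].to_numpy(dtype=float)
        slope = np.polyfit(d2, y2, 1)[0] if len(np.unique(d2)) > 1 else np.nan
        if not (adg_bounds[0] <= slope <= adg_bounds[1]):
            n_adg_removed += len(sub)
            log.info("animal %s removed: on-test ADG %.3f kg/d", animal, slope)
            continue
        kept_parts.append(sub)
    if kept_parts:
        kept = pd.concat(kept_parts)
        out = (
            kept.groupby(["animal", "age_days"], as_index=False)
            .agg(value=("value", "mean"), cg=("cg", "first"),
                 parity=("parity", "first"))
        )
    else:
        out = df.iloc[:0]
    report = EditReport(
        records_in=len(df),
        records_out=int(
            sum(len(p) for p in kept_parts)
        ),
        removals={
            "bisquare_outlier": n_outliers,
            "adg_bounds": n_adg_removed,
            "too_few_records": n_too_few,
        },
        details={"robust_weights": robust_weights},
    )
    report.check()
    return TrajectoryRecordSet(out.reset_index(drop=True)), report


def qc_genotypes(
    geno: GenotypeMatrix,
    call_rate: float = 0.90,
    maf: float = 0.02,
    hwe_alpha: float = 1e-4,
    analysis_maf: float = 0.002,
) -> tuple[GenotypeMatrix, EditReport]:
    """Genotype quality control with the fixed filter order.

    Order: animal call rate -> SNP call rate -> MAF -> HWE, then the
    analysis-subset MAF re-check.  The order is a documented choice; the
    thresholds keep entities with call rate strictly above ``call_rate``
    and MAF strictly above ``maf``.
    """
    codes = geno.codes
    n0, m0 = codes.shape
    animal_cr = (codes >= 0).mean(axis=1)
    keep_animals = animal_cr > call_rate
    codes = codes[keep_animals]
    if codes.shape[0] == 0:
        raise ValueError("genotype QC removed every animal (call rate)")
    log.info("genotype QC order: animal call rate -> SNP call rate -> MAF -> HWE")

    snp_cr = (codes >= 0).mean(axis=0)
    keep_cr = snp_cr > call_rate

    with np.errstate(invalid="ignore"):
        masked = np.ma.masked_equal(codes, -1)
        p = np.asarray(masked.mean(axis=0) / 2.0)
    freq = np.minimum(p, 1.0 - p)
    keep_maf = keep_cr & (freq > maf)

    keep_hwe = keep_maf.copy()
    for j in np.flatnonzero(keep_maf):
        col = codes[:, j]
        col = col[col >= 0]
        n = len(col)
        counts = np.array([(col == 0).sum(), (col == 1).sum(), (col == 2).sum()])
        pj = (counts[1] + 2 * counts[2]) / (2 * n)
        exp = n * np.array([(1 - pj) ** 2, 2 * pj * (1 - pj), pj**2])
        if np.any(exp <= 0):
            continue
        chi2 = float(((counts - exp) ** 2 / exp).sum())
        if stats.chi2.sf(chi2, df=1) < hwe_alpha:
            keep_hwe[j] = False

    out = GenotypeMatrix(
        geno.animal[keep_animals], codes[:, keep_hwe], geno.snp_map.iloc[keep_hwe]
    )
    # analysis-subset re-check with the relaxed threshold
    p2 = out.allele_freq()
    freq2 = np.minimum(p2, 1.0 - p2)
    keep2 = freq2 >= analysis_maf
    out = out.subset(snp_keep=np.flatnonzero(keep2))
    if out.n_animals == 0 or out.n_snp == 0:
        raise ValueError("genotype QC removed everything; check thresholds")

    report = EditReport(
        records_in=m0,
        records_out=out.n_snp,
        removals={
            "snp_call_rate": int((~keep_cr).sum()),
            "maf": int((keep_cr & ~(freq > maf)).sum()),
            "hwe": int((keep_maf & ~keep_hwe).sum()),
            "analysis_maf": int((~keep2).sum()),
        },
        details={"animals_removed_call_rate": int((~keep_animals).sum())},
    )
    report.check()
    return out, report
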