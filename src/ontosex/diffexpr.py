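"""Normalization, the three-rule gene screen, and per-stage sex-bias calls.

The screening cascade applied to the replicated log2(male/female) ratio
matrix:

1. *Replicate rule* — keep genes observed in at least 66% of all
   biological replicate slots (inclusive).
2. *ANOVA rule* — among those, keep genes whose stage means differ from
   zero at P <= alpha under a one-way ANOVA whose error variance is a
   cross-gene pooled within-stage replicate variance (a variance-
   stabilised test suitable for 3-replicate designs).
3. *Recovery rule* — genes failing 1 or 2 are recovered if at some
   stage the replicate mean exceeds 0.6 log2 units in magnitude
   (strictly) and at least 66% of that stage's replicates share the
   mean's sign.

A gene is then called male-biased at a stage when its mean ratio is
strictly above +0.8 log2 units (about 1.74-fold), female-biased below
-0.8, unbiased in between, and undetermined where no value exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from ontosex.core_io import (
    FEMALE,
    LARVAL_STAGES,
    MALE,
    STAGES,
    UNBIASED,
    UNDETERMINED,
    BiasProfile,
    ExpressionMatrix,
)

ALPHA_DEFAULT = 0.05
BIAS_THRESHOLD = 0.8
RECOVERY_THRESHOLD = 0.6
MIN_REPLICATE_FRACTION = 0.66
TIERS_DEFAULT = (0.8, 1.6)


@dataclass
class ScreenResult:
    """Outcome of the three-rule screen for one gene."""

    gene: str
    passed_replicate_rule: bool
    anova_p: float  # NaN when not computable
    recovered: bool
    admitted: bool


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def lowess_normalize(
    male: np.ndarray,
    female: np.ndarray,
    span: float = 0.3,
    iterations: int = 2,
) -> np.ndarray:
    """Intensity-dependent (MA-plot) lowess normalization of two-colour spots.

    Returns ``M - fit(A)`` where ``M = log2(male/female)`` and
    ``A = (log2 male + log2 female)/2``; the fit is a locally weighted
    linear regression of M on A with the given span and robustness
    iterations.  Spots with a nonpositive intensity come back as NaN.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    male = np.asarray(male, dtype=float)
    female = np.asarray(female, dtype=float)
    if male.shape != female.shape:
        raise ValueError("intensity vectors must have equal length")
    ok = (male > 0) & (female > 0)
    out = np.full(male.shape, np.nan)
    if ok.sum() == 0:
        return out
    m = np.log2(male[ok]) - np.log2(female[ok])
    a = 0.5 * (np.log2(male[ok]) + np.log2(female[ok]))
    fit = _sm_lowess(m, a, frac=span, it=iterations, return_sorted=False)
    out[ok] = m - fit
    return out


# ---------------------------------------------------------------------------
# Screening cascade
# ---------------------------------------------------------------------------


def filter_replicates(
    matrix: ExpressionMatrix,
    min_fraction: float = MIN_REPLICATE_FRACTION,
    per_stage: bool = False,
) -> set[str]:
    """Genes observed in >= ``min_fraction`` of replicate slots (inclusive).

    By default the fraction is computed jointly over all stage x
    replicate slots; ``per_stage=True`` instead requires the fraction at
    every stage separately.
    """
    vals = matrix.data.to_numpy(dtype=float)
    observed = ~np.isnan(vals)
    if not per_stage:
        frac = observed.mean(axis=1)
        keep = frac >= min_fraction
    else:
        stages = matrix.data.columns.get_level_values(0)
        keep = np.ones(len(matrix.genes), dtype=bool)
        for s in matrix.stages:
            cols = stages == s
            keep &= observed[:, cols].mean(axis=1) >= min_fraction
    return {g for g, k in zip(matrix.genes, keep) if k}


def _pooled_error_variance(matrix: ExpressionMatrix) -> tuple[float, int]:
    """Cross-gene pooled within-stage replicate variance and its df.

    Pools squared deviations from the per-gene per-stage replicate mean
    across every gene and stage with >= 2 observations; this borrowed
    error term stabilises the 3-replicate ANOVA.
    """
    ss = 0.0
    df = 0
    stages = matrix.data.columns.get_level_values(0)
    vals = matrix.data.to_numpy(dtype=float)
    for s in matrix.stages:
        block = vals[:, stages == s]
        n = (~np.isnan(block)).sum(axis=1)
        total = np.nansum(block, axis=1)
        mean = np.divide(total, n, out=np.full(n.shape, np.nan), where=n > 0)
        dev = block - mean[:, None]
        ss += np.nansum(dev * dev)
        df += int(np.maximum(n - 1, 0).sum())
    return ss, df


def cross_gene_anova(
    matrix: ExpressionMatrix, genes: set[str] | None = None
) -> pd.Series:
    """Per-gene p-value that all stage-mean log-ratios are zero.

    One-way ANOVA with the cross-gene pooled within-stage variance as the
    error term: F = (sum_s n_s * mean_s^2 / S) / s2_pool on (S, df_pool)
    degrees of freedom, S the number of observed stages.  Genes with
    fewer than 2 values in total get a missing p-value.
    """
    ss_pool, df_pool = _pooled_error_variance(matrix)
    s2_pool = ss_pool / df_pool if df_pool > 0 else np.nan
    stages = matrix.data.columns.get_level_values(0)
    vals = matrix.data.to_numpy(dtype=float)
    target = matrix.genes if genes is None else [g for g in matrix.genes if g in genes]
    gene_idx = {g: i for i, g in enumerate(matrix.genes)}

    pvals = {}
    for g in target:
        row = vals[gene_idx[g]]
        if (~np.isnan(row)).sum() < 2:
            pvals[g] = np.nan
            continue
        ss_num = 0.0
        n_stages = 0
        for s in matrix.stages:
            x = row[stages == s]
            x = x[~np.isnan(x)]
            if x.size == 0:
                continue
            ss_num += x.size * float(np.mean(x)) ** 2
            n_stages += 1
        if ss_num == 0.0:
            pvals[g] = 1.0
        elif not np.isfinite(s2_pool) or s2_pool == 0.0:
            pvals[g] = 0.0
        else:
            f = (ss_num / n_stages) / s2_pool
            pvals[g] = float(stats.f.sf(f, n_stages, df_pool))
    return pd.Series(pvals, name="anova_p")


def recover_marginal(
    matrix: ExpressionMatrix,
    failed: set[str],
    ratio_threshold: float = RECOVERY_THRESHOLD,
    direction_fraction: float = MIN_REPLICATE_FRACTION,
) -> set[str]:
    """Recover screen-failing genes with a strong, consistent stage effect.

    A gene is recovered iff at some stage the mean of its non-missing
    replicates strictly exceeds ``ratio_threshold`` in magnitude and at
    least ``direction_fraction`` of those replicates share the mean's
    sign.
    """
    recovered = set()
    for g in failed:
        for s in matrix.stages:
            x = matrix.stage_values(g, s)
            x = x[~np.isnan(x)]
            if x.size == 0:
                continue
            m = float(np.mean(x))
            if abs(m) <= ratio_threshold:
                continue
            same = (x > 0).sum() if m > 0 else (x < 0).sum()
            if same / x.size >= direction_fraction:
                recovered.add(g)
                break
    return recovered


def screen_genes(
    matrix: ExpressionMatrix,
    alpha: float = ALPHA_DEFAULT,
    min_fraction: float = MIN_REPLICATE_FRACTION,
    recovery_threshold: float = RECOVERY_THRESHOLD,
) -> list[ScreenResult]:
    """Run the full three-rule cascade; admitted = (rule1 & rule2) | recovery."""
    passed_rep = filter_replicates(matrix, min_fraction)
    pvals = cross_gene_anova(matrix, passed_rep)
    significant = {g for g in passed_rep if pvals.get(g, np.nan) <= alpha}
    failed = set(matrix.genes) - significant
    recovered = recover_marginal(matrix, failed, recovery_threshold, min_fraction)
    results = []
    for g in matrix.genes:
        results.append(
            ScreenResult(
                gene=g,
                passed_replicate_rule=g in passed_rep,
                anova_p=float(pvals.get(g, np.nan)),
                recovered=g in recovered,
                admitted=g in significant or g in recovered,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Bias classification and summaries
# ---------------------------------------------------------------------------


def classify_stage_bias(mean_ratio: float, threshold: float = BIAS_THRESHOLD) -> str:
    """male above +threshold (strict), female below -threshold, else unbiased;
    undetermined for a missing ratio."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if mean_ratio is None or (isinstance(mean_ratio, float) and math.isnan(mean_ratio)):
        return UNDETERMINED
    if mean_ratio > threshold:
        return MALE
    if mean_ratio < -threshold:
        return FEMALE
    return UNBIASED


def build_bias_profiles(
    matrix: ExpressionMatrix,
    admitted: set[str],
    threshold: float = BIAS_THRESHOLD,
) -> list[BiasProfile]:
    """Stage means over non-missing replicates + bias calls, admitted genes only."""
    profiles = []
    for g in matrix.genes:
        if g not in admitted:
            continue
        mean_ratio: dict[str, float] = {}
        call: dict[str, str] = {}
        for s in matrix.stages:
            x = matrix.stage_values(g, s)
            x = x[~np.isnan(x)]
            m = float(np.mean(x)) if x.size else float("nan")
            mean_ratio[s] = m
            call[s] = classify_stage_bias(m, threshold)
        profiles.append(BiasProfile(g, mean_ratio, call))
    return profiles


def percentage(k: int, n: int, decimals: int = 1) -> float:
    """100*k/n rounded to ``decimals`` places, half away from zero.

    ``decimals=0`` returns an integer-valued float (the summary style
    used for cross-species proportions).  Undefined (n == 0) raises.
    """
    if n == 0:
        raise ZeroDivisionError("percentage undefined for n = 0")
    x = 100.0 * k / n
    scale = 10 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def stage_summary(
    profiles: list[BiasProfile],
    tiers: tuple[float, ...] = TIERS_DEFAULT,
) -> pd.DataFrame:
    """Per-stage, per-tier sex-biased gene counts with derived percentages.

    One row per (stage, tier): counts of genes with mean ratio strictly
    above +tier (male) or below -tier (female), the number of genes
    with a determined call at the stage, and percentages to one decimal.
    Also reports, per stage, the fraction of tier-1 biased genes above
    2-fold (|log2| > 1).
    """
    if not profiles:
        raise ValueError("no profiles to summarise")
    rows = []
    for s in STAGES:
        means = np.array(
            [p.mean_ratio.get(s, np.nan) for p in profiles], dtype=float
        )
        determined = ~np.isnan(means)
        n_det = int(determined.sum())
        base = min(tiers)
        biased = np.abs(means) > base
        over2 = int((np.abs(means[determined]) > 1.0).sum())
        n_biased = int(np.nansum(biased))
        for tier in sorted(tiers):
            n_male = int(np.nansum(means > tier))
            n_female = int(np.nansum(means < -tier))
            rows.append(
                {
                    "stage": s,
                    "tier": tier,
                    "n_male_biased": n_male,
                    "n_female_biased": n_female,
                    "n_total_admitted": n_det,
                    "pct_male": percentage(n_male, n_det) if n_det else np.nan,
                    "pct_female": percentage(n_female, n_det) if n_det else np.nan,
                    "frac_biased_over_2fold": (
                        percentage(over2, n_biased) / 100.0 if n_biased else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows)


def maintained_bias(profiles: list[BiasProfile]) -> dict[frozenset[str], set[str]]:
    """Venn partition of sex-biased genes over pooled {larvae, pupae, adult}.

    A gene is larvae-biased if biased (either sex) at any of L1/L2-3/L4.
    Returns a mapping from the nonempty subset of pools to the genes in
    exactly that subset; the classes partition the sex-biased set.
    """
    partition: dict[frozenset[str], set[str]] = {}
    for p in profiles:
        pools = set()
        for s in p.biased_stages():
            if s in LARVAL_STAGES:
                pools.add("larvae")
            elif s == "P":
                pools.add("pupae")
            else:
                pools.add("adult")
        if pools:
            partition.setdefault(frozenset(pools), set()).add(p.gene)
    return partition


def variance_profile(profiles: list[BiasProfile]) -> pd.DataFrame:
    """Per gene: mean and sample SD (ddof=1) of the non-missing stage means.

    Genes with fewer than two observed stages get a missing SD.
    """
    rows = []
    for p in profiles:
        v = p.vector()
        v = v[~np.isnan(v)]
        rows.append(
            {
                "gene": p.gene,
                "mean_ratio": float(np.mean(v)) if v.size else np.nan,
                "sd_ratio": float(np.std(v, ddof=1)) if v.size >= 2 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def spearman_validation(
    ratios_a: np.ndarray, ratios_b: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties), two-sided p.

    Used to validate one expression platform against another over the
    shared gene set; requires at least 3 pairs.
    """
    a = np.asarray(ratios_a, dtype=float)
    b = np.asarray(ratios_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("at least 3 pairs required")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
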