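"""Group-comparison battery validating the severity benchmarks.

One-way ANOVA with eta-squared (computable from exact group summaries,
since (n, mean, SD) are sufficient), Tukey-Kramer post hoc comparisons,
orthogonal polynomial linear contrasts, one-way MANOVA via Wilks' lambda
with Rao's F approximation, Pearson chi-square with Cramer's V, and
Cohen's d from summary statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .benchmarks import (
    CLASS_ORDER,
    POOLED_CLASS_ORDER,
    SeverityBenchmarks,
    SeverityClass,
    classify_scores,
)
from .core import CovariateFrame, ValidationError, log


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics (n, mean, SD) of one variable in one group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"group {self.label!r} must have n >= 1")
        if self.sd < 0:
            raise ValidationError("SD must be non-negative")


@dataclass(frozen=True)
class ComparisonResult:
    method: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float
    effect_label: str


def _as_summaries(groups: Sequence) -> list[GroupSummary]:
    """Accept GroupSummary objects or raw arrays; reduce raw to summaries."""
    out = []
    for g, item in enumerate(groups):
        if isinstance(item, GroupSummary):
            out.append(item)
        else:
            arr = np.asarray(item, dtype=float)
            out.append(
                GroupSummary(
                    label=f"group{g + 1}",
                    n=len(arr),
                    mean=float(arr.mean()),
                    sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                )
            )
    return out


def _sums_of_squares(summaries: list[GroupSummary]) -> tuple[float, float, float]:
    n = np.array([g.n for g in summaries], dtype=float)
    m = np.array([g.mean for g in summaries])
    s = np.array([g.sd for g in summaries])
    grand = float(np.sum(n * m) / n.sum())
    ssb = float(np.sum(n * (m - grand) ** 2))
    ssw = float(np.sum((n - 1) * s**2))
    return ssb, ssw, n.sum()


def anova_oneway(groups: Sequence) -> ComparisonResult:
    """One-way ANOVA from raw columns or exact (n, mean, SD) summaries.

    F and eta-squared are identical in the two modes because the summaries
    are sufficient for the between/within sums of squares.
    """
    summaries = _as_summaries(groups)
    if len(summaries) < 2:
        raise ValidationError("ANOVA requires at least two groups")
    if any(g.n < 2 for g in summaries):
        raise ValidationError("every group needs n >= 2 (within-group variance undefined)")
    ssb, ssw, n_total = _sums_of_squares(summaries)
    df_b = len(summaries) - 1
    df_w = n_total - len(summaries)
    msb = ssb / df_b
    msw = ssw / df_w
    if msw == 0:
        f = 0.0 if ssb == 0 else np.inf
    else:
        f = msb / msw
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    eta_sq = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    return ComparisonResult(
        method="one-way ANOVA", statistic=float(f), df=(df_b, df_w),
        p_value=p, effect_size=float(eta_sq), effect_label="eta_sq",
    )


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    mean_diff: float
    q: float
    p_adjusted: float


def tukey_posthoc(groups: Sequence) -> list[PairwiseComparison]:
    """Tukey-Kramer pairwise comparisons (studentized-range reference).

    Uses MSW from the omnibus ANOVA and the Kramer unequal-n standard error
    SE = sqrt(MSW/2 * (1/n_i + 1/n_j)).
    """
    summaries = _as_summaries(groups)
    if len(summaries) < 2:
        raise ValidationError("post hoc comparisons need at least two groups")
    if any(g.n < 2 for g in summaries):
        raise ValidationError("every group needs n >= 2")
    _, ssw, n_total = _sums_of_squares(summaries)
    k = len(summaries)
    df_w = n_total - k
    msw = ssw / df_w
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = summaries[i], summaries[j]
            diff = gi.mean - gj.mean
            se = np.sqrt(msw / 2.0 * (1.0 / gi.n + 1.0 / gj.n))
            q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
            p = float(stats.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            out.append(
                PairwiseComparison(
                    group_a=gi.label, group_b=gj.label,
                    mean_diff=float(diff), q=float(q), p_adjusted=min(p, 1.0),
                )
            )
    return out


def _linear_coefficients(k: int) -> np.ndarray:
    """Unscaled integer orthogonal linear polynomial coefficients."""
    ranks = np.arange(1, k + 1, dtype=float)
    c = ranks - ranks.mean()
    # scale to the classical integer form (e.g. -3,-1,1,3 for k = 4)
    scale = 2.0 if k % 2 == 0 else 1.0
    return c * scale


def linear_contrast(groups: Sequence) -> ComparisonResult:
    """Linear polynomial contrast across ordered groups.

    t = sum(c m) / sqrt(MSW sum(c^2 / n)), df = N - g; effect size reported
    as the contrast estimate itself.
    """
    summaries = _as_summaries(groups)
    k = len(summaries)
    if k < 3:
        raise ValidationError("a linear contrast needs at least three ordered groups")
    if any(g.n < 2 for g in summaries):
        raise ValidationError("every group needs n >= 2")
    c = _linear_coefficients(k)
    _, ssw, n_total = _sums_of_squares(summaries)
    df_w = n_total - k
    msw = ssw / df_w
    m = np.array([g.mean for g in summaries])
    n = np.array([g.n for g in summaries], dtype=float)
    estimate = float(np.sum(c * m))
    se = float(np.sqrt(msw * np.sum(c**2 / n)))
    t = estimate / se if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(t), df_w)) if np.isfinite(t) else 0.0
    return ComparisonResult(
        method="linear contrast", statistic=float(t), df=(df_w,),
        p_value=p, effect_size=estimate, effect_label="contrast",
    )


def manova_wilks(groups: Sequence[np.ndarray]) -> ComparisonResult:
    """One-way MANOVA: Wilks' lambda with Rao's F approximation.

    Requires raw multivariate data per group (n_g x p arrays); the
    between/within cross-product matrices are not recoverable from
    univariate summaries.
    """
    mats = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    if len(mats) < 2:
        raise ValidationError("MANOVA requires at least two groups")
    p = mats[0].shape[1]
    if any(m.shape[1] != p for m in mats):
        raise ValidationError("all groups must share the same variables")
    all_data = np.vstack(mats)
    n_total = all_data.shape[0]
    g = len(mats)
    grand = all_data.mean(axis=0)
    w = np.zeros((p, p))
    b = np.zeros((p, p))
    for m in mats:
        centred = m - m.mean(axis=0)
        w += centred.T @ centred
        dev = (m.mean(axis=0) - grand)[:, None]
        b += m.shape[0] * (dev @ dev.T)
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0 or sign_t <= 0:
        raise ValidationError("singular within-group cross-product matrix")
    lam = float(np.exp(logdet_w - logdet_t))
    # Rao's F approximation
    nu_h = g - 1
    nu_e = n_total - g
    t_ = np.sqrt(
        (p**2 * nu_h**2 - 4) / (p**2 + nu_h**2 - 5)
    ) if (p**2 + nu_h**2 - 5) > 0 else 1.0
    df1 = p * nu_h
    df2 = t_ * (nu_e - (p - nu_h + 1) / 2.0) - (p * nu_h - 2) / 2.0
    lam_t = lam ** (1.0 / t_)
    f = (1.0 - lam_t) / lam_t * df2 / df1
    p_val = float(stats.f.sf(f, df1, df2))
    return ComparisonResult(
        method="MANOVA (Wilks)", statistic=float(f), df=(df1, float(df2)),
        p_value=p_val, effect_size=lam, effect_label="wilks_lambda",
    )


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValidationError("contingency table must be at least 2x2")
        if (counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValidationError("contingency table must have a positive total")
        object.__setattr__(self, "counts", counts.astype(float))


def chi_square(table: ContingencyTable) -> ComparisonResult:
    """Pearson chi-square (no continuity correction) with Cramer's V."""
    counts = table.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValidationError("zero row or column margin")
    chi2, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    n = counts.sum()
    k = min(counts.shape[0] - 1, counts.shape[1] - 1)
    v = float(np.sqrt(chi2 / (n * k)))
    return ComparisonResult(
        method="Pearson chi-square", statistic=float(chi2), df=(float(dof),),
        p_value=float(p), effect_size=v, effect_label="cramers_v",
    )


def cohens_d_summary(
    m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int
) -> tuple[float, ComparisonResult]:
    """Cohen's d from group summaries, with the pooled-SD two-sample t test."""
    if n1 < 2 or n2 < 2:
        raise ValidationError("both samples need n >= 2")
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
    pooled_sd = float(np.sqrt(pooled_var))
    if pooled_sd == 0:
        if m1 != m2:
            raise ValidationError("zero pooled SD with unequal means: d undefined")
        d = 0.0
        t = 0.0
    else:
        d = abs(m1 - m2) / pooled_sd
        t = (m1 - m2) / (pooled_sd * np.sqrt(1.0 / n1 + 1.0 / n2))
    df = n1 + n2 - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(d), ComparisonResult(
        method="two-sample t (pooled)", statistic=float(t), df=(float(df),),
        p_value=p, effect_size=float(d), effect_label="cohens_d",
    )


# ---------------------------------------------------------------------------
# Assembling the validation battery for a classified cohort


@dataclass(frozen=True)
class GroupComparisonBundle:
    """Per-group descriptives plus the omnibus tests for one cohort."""

    group_order: tuple[SeverityClass, ...]
    group_sizes: dict
    continuous_summaries: dict
    continuous_tests: dict
    contingency_tables: dict
    categorical_tests: dict
    warnings: tuple[str, ...]

    def continuous_table(self) -> pd.DataFrame:
        rows = []
        for var, by_group in self.continuous_summaries.items():
            row: dict = {"variable": var}
            for cls in self.group_order:
                g = by_group.get(cls)
                row[f"{cls.value}_M"] = g.mean if g else np.nan
                row[f"{cls.value}_SD"] = g.sd if g else np.nan
            test = self.continuous_tests.get(var)
            row["F"] = test.statistic if test else np.nan
            row["eta_sq"] = test.effect_size if test else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    def categorical_table(self) -> pd.DataFrame:
        rows = []
        for var, table in self.contingency_tables.items():
            row: dict = {"variable": var}
            yes = table.counts[0]
            totals = table.counts.sum(axis=0)
            for cls, y, tot in zip(self.group_order, yes, totals):
                row[f"{cls.value}_n"] = int(y)
                row[f"{cls.value}_pct"] = 100.0 * y / tot if tot else np.nan
            test = self.categorical_tests.get(var)
            row["chi_sq"] = test.statistic if test else np.nan
            row["cramers_v"] = test.effect_size if test else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def build_group_table(
    scores: np.ndarray,
    covariates: CovariateFrame,
    benchmarks: SeverityBenchmarks,
    pool_extreme: bool = True,
) -> GroupComparisonBundle:
    """Classify a cohort and compute the full Table-4-style battery.

    Empty severity groups are kept in the descriptives with n = 0 but
    excluded from the tests, with a logged warning.
    """
    scores = np.asarray(scores)
    if len(scores) != covariates.n:
        raise ValidationError("scores and covariates must align row-wise")
    order = POOLED_CLASS_ORDER if pool_extreme else CLASS_ORDER
    labels = classify_scores(scores, benchmarks, pool_extreme=pool_extreme)
    labels = np.asarray([c.value for c in labels])
    sizes = {cls: int((labels == cls.value).sum()) for cls in order}
    warnings: list[str] = []
    nonempty = [cls for cls in order if sizes[cls] >= 2]
    for cls in order:
        if sizes[cls] < 2:
            msg = f"severity group {cls.value!r} has n={sizes[cls]}; excluded from tests"
            warnings.append(msg)
            log.warning(msg)

    df = covariates.data.reset_index(drop=True)
    cont_summ: dict = {}
    cont_tests: dict = {}
    for var in covariates.continuous():
        by_group = {}
        for cls in order:
            mask = labels == cls.value
            if mask.sum() >= 1:
                vals = df.loc[mask, var].to_numpy(dtype=float)
                by_group[cls] = GroupSummary(
                    label=cls.value, n=int(mask.sum()), mean=float(vals.mean()),
                    sd=float(vals.std(ddof=1)) if mask.sum() > 1 else 0.0,
                )
        cont_summ[var] = by_group
        usable = [by_group[cls] for cls in nonempty if cls in by_group]
        if len(usable) >= 2:
            cont_tests[var] = anova_oneway(usable)
        else:
            warnings.append(f"comparison skipped for {var!r}: fewer than two usable groups")
    cont_tables: dict = {}
    cat_tests: dict = {}
    for var in covariates.binary():
        counts = np.zeros((2, len(order)))
        for j, cls in enumerate(order):
            mask = labels == cls.value
            yes = int(df.loc[mask, var].sum())
            counts[0, j] = yes
            counts[1, j] = int(mask.sum()) - yes
        table = ContingencyTable(
            counts=counts, row_labels=("yes", "no"),
            col_labels=tuple(cls.value for cls in order),
        )
        cont_tables[var] = table
        usable_cols = [j for j, cls in enumerate(order) if sizes[cls] >= 2]
        sub = counts[:, usable_cols]
        if sub.shape[1] >= 2 and (sub.sum(axis=1) > 0).all():
            cat_tests[var] = chi_square(
                ContingencyTable(
                    counts=sub, row_labels=("yes", "no"),
                    col_labels=tuple(order[j].value for j in usable_cols),
                )
            )
        else:
            warnings.append(f"chi-square skipped for {var!r}: degenerate table")
    return GroupComparisonBundle(
        group_order=tuple(order),
        group_sizes=sizes,
        continuous_summaries=cont_summ,
        continuous_tests=cont_tests,
        contingency_tables=cont_tables,
        categorical_tests=cat_tests,
        warnings=tuple(warnings),
    )
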