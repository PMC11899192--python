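"""Cohort statistics: group comparisons, correlations, noise propagation.

The analysis battery mirrors a cross-sectional morphometry study design:
pooled-variance two-sample t-tests between groups (sex within age group,
adjacent muscle-fat-infiltration classes within sex), Pearson correlations
of morphometry against covariates with the two-sided t transform of r, a
coefficient-of-variation summary of repeated segmentations, and a
noise-propagation analysis that re-runs correlations after multiplicative
Gaussian perturbation of the measurements at segmentation-repeatability
scale, asking whether significance classifications survive.

No multiple-testing correction is applied by default: every test is reported
at its raw two-sided p-value against a fixed alpha (0.05). Holm correction
can be applied post hoc via :func:`holm_adjust`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateSampleError,
    ImplausibleNoiseError,
    UndefinedCorrelationError,
    UndefinedCVError,
)

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "NoiseRobustnessResult",
    "two_sample_ttest",
    "pearson_correlation",
    "mfi_group_analysis",
    "sex_comparisons_by_age_group",
    "correlations_by_sex",
    "age_window_refit",
    "reproducibility_stats",
    "noise_perturbation_analysis",
    "holm_adjust",
    "comparisons_to_frame",
    "correlations_to_frame",
]

MFI_ORDER = ("normal", "mild", "moderate")


@dataclass
class GroupComparison:
    """A pooled-variance two-sample t-test between two groups."""

    variable: str
    group_labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    t_statistic: float
    df: int
    p_value: float
    significant: bool
    alpha: float = 0.05


@dataclass
class CorrelationResult:
    """Pearson correlation with its least-squares display line."""

    x_name: str
    y_name: str
    n: int
    r: float
    p_value: float
    slope: float
    intercept: float
    significant: bool
    alpha: float = 0.05


@dataclass
class NoiseRobustnessResult:
    """Correlation significance under repeated multiplicative noise."""

    variable_pair: tuple[str, str]
    noise_fraction: float
    n_executions: int
    p_values: list[float]
    mean_p: float
    baseline_p: float
    significance_preserved: bool
    alpha: float = 0.05
    executions_significant: int = 0


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise DegenerateSampleError(f"sample {name!r} must be non-empty and finite")
    return arr


def two_sample_ttest(
    a,
    b,
    variable: str = "value",
    group_labels: tuple[str, str] = ("A", "B"),
    alpha: float = 0.05,
    equal_var: bool = True,
) -> GroupComparison:
    """Two-sample t-test, pooled variance by default (Student's t).

    Degenerate samples (zero pooled variance) yield p = 1 when the means are
    equal — no evidence either way — and raise otherwise, since the test
    statistic is unbounded.
    """
    a = _as_sample(a, group_labels[0])
    b = _as_sample(b, group_labels[1])
    if a.size < 2 or b.size < 2:
        raise DegenerateSampleError("each sample needs n >= 2")
    df = a.size + b.size - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            t_stat, p = 0.0, 1.0
        else:
            raise DegenerateSampleError(
                "zero pooled variance with unequal means: t is unbounded"
            )
    else:
        res = sps.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = res.statistic, res.pvalue
        df = int(res.df)
    return GroupComparison(
        variable=variable,
        group_labels=group_labels,
        n=(int(a.size), int(b.size)),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(np.std(a, ddof=1)), float(np.std(b, ddof=1))),
        t_statistic=float(t_stat),
        df=int(df),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=alpha,
    )


def pearson_correlation(
    x,
    y,
    x_name: str = "x",
    y_name: str = "y",
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided p (t transform,
    n - 2 df) and the least-squares line for display."""
    x = _as_sample(x, x_name)
    y = _as_sample(y, y_name)
    if x.size != y.size:
        raise DegenerateSampleError("x and y must have the same length")
    if x.size < 3:
        raise DegenerateSampleError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"correlation of {x_name!r} and {y_name!r} undefined: constant input"
        )
    res = sps.pearsonr(x, y)
    lin = sps.linregress(x, y)
    return CorrelationResult(
        x_name=x_name,
        y_name=y_name,
        n=int(x.size),
        r=float(res.statistic),
        p_value=float(res.pvalue),
        slope=float(lin.slope),
        intercept=float(lin.intercept),
        significant=bool(res.pvalue < alpha),
        alpha=alpha,
    )


def _cell(df: pd.DataFrame, **conditions) -> pd.DataFrame:
    out = df
    for col, val in conditions.items():
        out = out[out[col] == val]
    return out


def mfi_group_analysis(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = ("BT", "BA", "g", "MPI"),
    alpha: float = 0.05,
    min_n: int = 2,
) -> list[GroupComparison]:
    """Muscle-fat-infiltration contrasts for each morphometric variable.

    Within each sex: t-tests between adjacent MFI classes (normal vs mild,
    mild vs moderate); within each MFI class: the between-sex t-test.
    Contrasts whose cells have fewer than ``min_n`` subjects are skipped.
    """
    results: list[GroupComparison] = []
    classes = [c for c in MFI_ORDER if c in set(cohort["mfi_class"])]
    sexes = [s for s in ("F", "M") if s in set(cohort["sex"])]
    for var in variables:
        if var not in cohort.columns:
            continue
        for sex in sexes:
            for c1, c2 in zip(classes, classes[1:]):
                a = _cell(cohort, sex=sex, mfi_class=c1)[var]
                b = _cell(cohort, sex=sex, mfi_class=c2)[var]
                if len(a) < min_n or len(b) < min_n:
                    continue
                results.append(
                    two_sample_ttest(
                        a, b, variable=var,
                        group_labels=(f"{sex}/{c1}", f"{sex}/{c2}"), alpha=alpha,
                    )
                )
        if len(sexes) == 2:
            for cls in classes:
                a = _cell(cohort, sex="F", mfi_class=cls)[var]
                b = _cell(cohort, sex="M", mfi_class=cls)[var]
                if len(a) < min_n or len(b) < min_n:
                    continue
                results.append(
                    two_sample_ttest(
                        a, b, variable=var,
                        group_labels=(f"F/{cls}", f"M/{cls}"), alpha=alpha,
                    )
                )
    return results


def sex_comparisons_by_age_group(
    cohort: pd.DataFrame,
    variables: tuple[str, ...] = ("BT", "BA", "g", "MPI"),
    age_split: float = 50.0,
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Female-vs-male t-tests within the two age groups (split inclusive:
    the younger group is age <= split)."""
    results = []
    young = cohort[cohort["age"] <= age_split]
    old = cohort[cohort["age"] > age_split]
    for label, sub in ((f"age<={age_split:g}", young), (f"age>{age_split:g}", old)):
        f = sub[sub["sex"] == "F"]
        m = sub[sub["sex"] == "M"]
        if len(f) < 2 or len(m) < 2:
            continue
        for var in variables:
            if var not in cohort.columns:
                continue
            results.append(
                two_sample_ttest(
                    f[var], m[var], variable=var,
                    group_labels=(f"F/{label}", f"M/{label}"), alpha=alpha,
                )
            )
    return results


def correlations_by_sex(
    cohort: pd.DataFrame,
    x: str,
    variables: tuple[str, ...] = ("BT", "BA", "g", "MPI"),
    alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Per-sex Pearson correlations of each variable against covariate x."""
    results = []
    for sex in ("F", "M"):
        sub = cohort[cohort["sex"] == sex]
        if len(sub) < 3:
            continue
        for var in variables:
            if var not in cohort.columns or x not in cohort.columns:
                continue
            try:
                res = pearson_correlation(
                    sub[x], sub[var], x_name=f"{x}({sex})", y_name=var, alpha=alpha
                )
            except UndefinedCorrelationError:
                continue
            results.append(res)
    return results


def age_window_refit(
    cohort: pd.DataFrame,
    variable: str,
    covariate: str = "age",
    window: tuple[float, float] = (15.0, 78.0),
    sex: str | None = None,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Re-fit a correlation after restricting the covariate to a window —
    the sensitivity check for unequal covariate ranges between groups."""
    sub = cohort
    if sex is not None:
        sub = sub[sub["sex"] == sex]
    sub = sub[(sub[covariate] >= window[0]) & (sub[covariate] <= window[1])]
    return pearson_correlation(
        sub[covariate], sub[variable],
        x_name=f"{covariate}[{window[0]:g},{window[1]:g}]", y_name=variable,
        alpha=alpha,
    )


def reproducibility_stats(repeated_measurements: dict[str, list[float]]) -> dict[str, float]:
    """Coefficient of variation (sample sd / mean) per quantity, as a fraction."""
    out = {}
    for name, values in repeated_measurements.items():
        arr = _as_sample(values, name)
        if arr.size < 2:
            raise DegenerateSampleError(f"{name}: CV needs >= 2 repetitions")
        mean = arr.mean()
        if mean == 0:
            raise UndefinedCVError(f"{name}: CV undefined at zero mean")
        out[name] = float(np.std(arr, ddof=1) / mean)
    return out


def noise_perturbation_analysis(
    cohort: pd.DataFrame,
    target_vars: tuple[str, ...],
    covariate: str,
    noise_fraction: float,
    n_executions: int = 10,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[NoiseRobustnessResult]:
    """Propagate segmentation-scale noise into correlation p-values.

    Each execution multiplies every target value by ``(1 + eps)`` with
    ``eps ~ Normal(0, noise_fraction)``, recomputes the Pearson p against the
    covariate, and records it. ``significance_preserved`` is true when every
    execution classifies significance at ``alpha`` the same way as the
    noise-free baseline.
    """
    if noise_fraction < 0:
        raise ImplausibleNoiseError("noise_fraction must be >= 0")
    if noise_fraction > 0.5:
        raise ImplausibleNoiseError(
            f"noise_fraction {noise_fraction} exceeds the plausible range (> 0.5)"
        )
    if n_executions < 2:
        raise DegenerateSampleError("n_executions must be >= 2")
    rng = np.random.default_rng(seed)
    results = []
    for var in target_vars:
        baseline = pearson_correlation(
            cohort[covariate], cohort[var], x_name=covariate, y_name=var, alpha=alpha
        )
        p_values = []
        for _ in range(n_executions):
            noisy = cohort[var].to_numpy() * (
                1.0 + rng.normal(0.0, noise_fraction, size=len(cohort))
            )
            res = pearson_correlation(
                cohort[covariate], noisy, x_name=covariate, y_name=var, alpha=alpha
            )
            p_values.append(res.p_value)
        n_sig = sum(p < alpha for p in p_values)
        preserved = all((p < alpha) == baseline.significant for p in p_values)
        results.append(
            NoiseRobustnessResult(
                variable_pair=(var, covariate),
                noise_fraction=noise_fraction,
                n_executions=n_executions,
                p_values=p_values,
                mean_p=float(np.mean(p_values)),
                baseline_p=baseline.p_value,
                significance_preserved=preserved,
                alpha=alpha,
                executions_significant=n_sig,
            )
        )
    return results


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (optional; off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def comparisons_to_frame(results: list[GroupComparison]) -> pd.DataFrame:
    """Tidy one-row-per-test table of group comparisons."""
    return pd.DataFrame(
        [
            dict(
                variable=r.variable,
                group_a=r.group_labels[0],
                group_b=r.group_labels[1],
                n_a=r.n[0],
                n_b=r.n[1],
                mean_a=r.means[0],
                mean_b=r.means[1],
                sd_a=r.sds[0],
                sd_b=r.sds[1],
                t=r.t_statistic,
                df=r.df,
                p=r.p_value,
                significant=r.significant,
            )
            for r in results
        ]
    )


def correlations_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    """Tidy one-row-per-test table of correlations."""
    return pd.DataFrame(
        [
            dict(
                x=r.x_name,
                y=r.y_name,
                n=r.n,
                r=r.r,
                p=r.p_value,
                slope=r.slope,
                intercept=r.intercept,
                significant=r.significant,
            )
            for r in results
        ]
    )
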