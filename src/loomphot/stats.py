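"""Statistical layer of the looming-assay analysis.

Thin, validated wrappers around the standard tests the assay uses: Pearson
product-moment correlation (two-sided p from the t transform), pooled-variance
unpaired and paired t tests, one- and two-way repeated-measures ANOVA with
Bonferroni-corrected pairwise comparisons against a baseline condition, and
the uncorrected Pearson chi-squared test on 2x2 escape-count tables.

Conventions follow the assay's reporting: sphericity-assumed ANOVA df, no
Yates continuity correction, Bonferroni multiplier equal to the number of
comparisons actually performed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsError",
    "ConstantInputError",
    "ZeroVarianceError",
    "CorrelationResult",
    "TTestResult",
    "PairwiseComparison",
    "EffectResult",
    "RmAnovaResult",
    "ContingencyResult",
    "pearson",
    "t_test",
    "bonferroni",
    "one_way_rm_anova",
    "two_way_rm_anova",
    "chi_squared_gof",
]


class StatsError(ValueError):
    pass


class ConstantInputError(StatsError):
    """Correlation undefined: at least one input has zero variance."""


class ZeroVarianceError(StatsError):
    """t statistic undefined: zero (pooled or difference) variance."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    p: float
    n: int


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p: float
    paired: bool


@dataclass(frozen=True)
class PairwiseComparison:
    label: str
    statistic: float
    p_raw: float
    p_corrected: float


@dataclass(frozen=True)
class EffectResult:
    name: str
    F: float
    df1: float
    df2: float
    p: float


@dataclass(frozen=True)
class RmAnovaResult:
    effects: tuple          # of EffectResult
    pairwise: tuple         # of PairwiseComparison
    n_subjects: int

    def effect(self, name: str) -> EffectResult:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass(frozen=True)
class ContingencyResult:
    chi2: float
    df: int
    p: float
    observed: tuple
    expected: tuple


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided p (t transform,
    n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("x and y must have equal length")
    if x.size < 3:
        raise StatsError("need at least 3 paired observations")
    if float(x.std()) == 0.0 or float(y.std()) == 0.0:
        raise ConstantInputError("correlation undefined for constant input")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, p=float(res.pvalue), n=int(x.size))


def t_test(a, b, paired: bool) -> TTestResult:
    """Two-sided t test: paired (on differences, n-1 df) or pooled-variance
    unpaired (n1 + n2 - 2 df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if paired:
        if a.size != b.size:
            raise StatsError("paired samples must have equal length")
        if a.size < 2:
            raise StatsError("need at least 2 pairs")
        d = a - b
        if float(d.std(ddof=1)) == 0.0 and float(d.mean()) != 0.0:
            raise ZeroVarianceError("constant nonzero paired difference: t undefined")
        if float(d.std(ddof=1)) == 0.0:
            return TTestResult(statistic=0.0, df=float(a.size - 1), p=1.0, paired=True)
        res = sps.ttest_rel(a, b)
        return TTestResult(statistic=float(res.statistic), df=float(a.size - 1),
                           p=float(res.pvalue), paired=True)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least 2 observations")
    sp2 = (((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
           / (a.size + b.size - 2))
    if sp2 == 0.0:
        if float(a.mean()) == float(b.mean()):
            return TTestResult(statistic=0.0, df=float(a.size + b.size - 2),
                               p=1.0, paired=False)
        raise ZeroVarianceError("zero pooled variance: t undefined")
    res = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(statistic=float(res.statistic),
                       df=float(a.size + b.size - 2),
                       p=float(res.pvalue), paired=False)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p for ``m`` comparisons, capped at 1."""
    if m < 1:
        raise StatsError("comparison count must be >= 1")
    return min(1.0, p * m)


def _check_matrix(data: np.ndarray, min_levels: int = 2) -> None:
    if data.ndim < 2:
        raise StatsError("expected a subject x condition matrix")
    if not np.isfinite(data).all():
        raise StatsError("matrix is incomplete (non-finite cells)")
    if data.shape[0] < 2:
        raise StatsError("need at least 2 subjects")
    if any(s < min_levels for s in data.shape[1:]):
        raise StatsError("need at least 2 levels per within-subject factor")


def one_way_rm_anova(data, condition_labels=None, baseline_index: int = 0,
                     factor_name: str = "condition") -> RmAnovaResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix,
    with Bonferroni-corrected paired comparisons of every condition against
    the ``baseline_index`` column.

    df are the sphericity-assumed (k-1, (k-1)(n-1)).  A matrix in which every
    subject is constant across conditions has no effect and no error variance;
    it is reported as F = 0, p = 1.
    """
    data = np.asarray(data, dtype=float)
    _check_matrix(data)
    n, k = data.shape
    labels = list(condition_labels) if condition_labels is not None else [
        f"level{j}" for j in range(k)]
    if len(labels) != k:
        raise StatsError("condition_labels length must match the column count")
    df1, df2 = float(k - 1), float((k - 1) * (n - 1))

    cell = data - data.mean(axis=1, keepdims=True)  # remove subject means
    ss_cond = float(n * ((data.mean(axis=0) - data.mean()) ** 2).sum())
    ss_err = float((cell ** 2).sum()) - ss_cond
    scale = max(1.0, float(np.abs(data).max()) ** 2)
    if ss_cond < 1e-12 * scale and ss_err < 1e-12 * scale:
        effects = (EffectResult(factor_name, 0.0, df1, df2, 1.0),)
        pairwise = tuple(
            PairwiseComparison(f"{labels[j]} vs {labels[baseline_index]}", 0.0, 1.0, 1.0)
            for j in range(k) if j != baseline_index)
        return RmAnovaResult(effects=effects, pairwise=pairwise, n_subjects=n)
    if ss_err < 1e-12 * scale:
        raise StatsError("singular error term: no within-subject residual variance")

    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        factor_name: np.tile(np.arange(k), n),
        "dv": data.ravel(),
    })
    import pingouin as pg
    aov = pg.rm_anova(data=long, dv="dv", within=factor_name, subject="subject",
                      detailed=True)
    row = aov.loc[aov["Source"] == factor_name].iloc[0]
    err = aov.loc[aov["Source"] == "Error"].iloc[0]
    effects = (EffectResult(factor_name, float(row["F"]), float(row["DF"]),
                            float(err["DF"]), float(row["p_unc"])),)
    m = k - 1
    pairwise = []
    for j in range(k):
        if j == baseline_index:
            continue
        tt = t_test(data[:, j], data[:, baseline_index], paired=True)
        pairwise.append(PairwiseComparison(
            label=f"{labels[j]} vs {labels[baseline_index]}",
            statistic=tt.statistic, p_raw=tt.p, p_corrected=bonferroni(tt.p, m)))
    return RmAnovaResult(effects=effects, pairwise=tuple(pairwise), n_subjects=n)


def two_way_rm_anova(data, factor_names=("A", "B"), level_labels=None) -> RmAnovaResult:
    """Two-way fully within-subject ANOVA on a subjects x levelsA x levelsB
    array: main effects and the interaction, each tested against its own
    subject-interaction error term (sphericity-assumed df).

    When factor A has exactly two levels, Bonferroni-corrected paired
    comparisons of the two A levels at each B level are reported.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 3:
        raise StatsError("expected a subjects x levelsA x levelsB array")
    _check_matrix(data)
    n, a, b = data.shape
    fa, fb = factor_names
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), a * b),
        fa: np.tile(np.repeat(np.arange(a), b), n),
        fb: np.tile(np.arange(b), n * a),
        "dv": data.ravel(),
    })
    import pingouin as pg
    aov = pg.rm_anova(data=long, dv="dv", within=[fa, fb], subject="subject")
    effects = []
    for name in (fa, fb, f"{fa} * {fb}"):
        row = aov.loc[aov["Source"] == name].iloc[0]
        effects.append(EffectResult(name, float(row["F"]), float(row["ddof1"]),
                                    float(row["ddof2"]), float(row["p_unc"])))
    pairwise = []
    if a == 2:
        if level_labels is None:
            level_labels = [f"{fb}{j}" for j in range(b)]
        for j in range(b):
            tt = t_test(data[:, 0, j], data[:, 1, j], paired=True)
            pairwise.append(PairwiseComparison(
                label=f"{fa} at {level_labels[j]}",
                statistic=tt.statistic, p_raw=tt.p,
                p_corrected=bonferroni(tt.p, b)))
    return RmAnovaResult(effects=tuple(effects), pairwise=tuple(pairwise),
                         n_subjects=n)


def chi_squared_gof(observed) -> ContingencyResult:
    """Uncorrected Pearson chi-squared test on a 2x2 count table.

    Expected counts come from the margin products; no Yates continuity
    correction is applied (the convention under which the assay's escape
    counts [[8, 2], [1, 7]] give chi2 = 8.10, df = 1).
    """
    obs = np.asarray(observed)
    if obs.shape != (2, 2):
        raise StatsError("observed must be a 2x2 table")
    if np.any(obs < 0) or not np.allclose(obs, np.round(obs)):
        raise StatsError("observed counts must be nonnegative integers")
    obs = obs.astype(float)
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise StatsError("all table margins must be positive")
    res = sps.chi2_contingency(obs, correction=False)
    return ContingencyResult(
        chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue),
        observed=tuple(map(tuple, obs)),
        expected=tuple(map(tuple, res.expected_freq)))
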