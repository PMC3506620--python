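"""Cohort statistics: ANOVA, ANCOVA with adjusted means, Bonferroni, Fisher.

The battery applied to a per-eye cohort table: one-way ANOVA compares a
parameter (density, diameter, thickness, age) across the clinical groups;
ANCOVA refits the comparison adjusting either for choroidal thickness
("model 1") or for age and gender ("model 2"), reporting adjusted group means
evaluated at the covariate grand means; pairwise Bonferroni-adjusted p-values
are reported only when the omnibus test is significant at 0.05; and an exact
Fisher r x c test (exhaustive enumeration over tables with the observed
margins) handles the choriocapillaris-visibility contingency counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
import statsmodels.api as sm

__all__ = [
    "GroupComparison",
    "anova_oneway",
    "ancova",
    "bonferroni_pairwise",
    "fisher_exact_rxc",
    "anova_type1_rate",
    "MODEL_COVARIATES",
]

#: Covariate sets of the two named adjustment models.
MODEL_COVARIATES = {
    "thickness": ["thickness_um"],
    "age_gender": ["age", "gender"],
}

OMNIBUS_ALPHA = 0.05


@dataclass
class GroupComparison:
    """Result of an omnibus group comparison.

    ``adjusted_means`` maps group label to ``(mean, standard_error)`` — raw
    means for ANOVA, covariate-adjusted means (at the covariate grand means)
    for ANCOVA.  ``pairwise`` lists ``(group_a, group_b, bonferroni_p)`` and is
    populated only when the omnibus p-value is below 0.05.
    """

    statistic: float
    p_value: float
    df: tuple[float, float]
    adjusted_means: dict[str, tuple[float, float]]
    pairwise: list[tuple[str, str, float]] = field(default_factory=list)
    kind: str = "anova"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")


def _group_arrays(values, groups) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    out: dict[str, np.ndarray] = {}
    for g in pd.unique(groups):
        out[str(g)] = values[groups == g]
    return out


def anova_oneway(values, groups) -> GroupComparison:
    """Classical one-way ANOVA F test across groups.

    Requires at least two groups with at least two observations each.  When
    the between-group sum of squares is exactly zero (all group means equal),
    F = 0 and p = 1 by convention.
    """
    by_group = _group_arrays(values, groups)
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    for g, arr in by_group.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than two observations")
    arrays = list(by_group.values())
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = n_total - len(arrays)
    if ss_between <= 1e-12 * max(ss_within, 1.0):
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat, p_value = sps.f_oneway(*arrays)
        f_stat, p_value = float(f_stat), float(p_value)
    mse = ss_within / df_w if df_w > 0 else np.nan
    means = {
        g: (float(a.mean()), float(np.sqrt(mse / a.size)))
        for g, a in by_group.items()
    }
    comparison = GroupComparison(
        statistic=f_stat,
        p_value=p_value,
        df=(float(df_b), float(df_w)),
        adjusted_means=means,
        kind="anova",
    )
    if p_value < OMNIBUS_ALPHA:
        pairs = []
        for (ga, a), (gb, b) in itertools.combinations(by_group.items(), 2):
            se = np.sqrt(mse * (1 / a.size + 1 / b.size))
            t = (a.mean() - b.mean()) / se
            p = 2 * sps.t.sf(abs(t), df_w)
            pairs.append((ga, gb, float(p)))
        adj = bonferroni_pairwise([p for *_, p in pairs])
        comparison.pairwise = [(ga, gb, p) for (ga, gb, _), p in zip(pairs, adj)]
    return comparison


def _check_full_rank(exog: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        # identify a minimal set of offending columns by greedy elimination
        keep: list[int] = []
        for idx in range(exog.shape[1]):
            trial = keep + [idx]
            if np.linalg.matrix_rank(exog[:, trial]) == len(trial):
                keep.append(idx)
        dropped = [names[i] for i in range(exog.shape[1]) if i not in keep]
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} of {exog.shape[1]}); "
            f"collinear columns: {dropped}"
        )


def ancova(
    values,
    groups,
    covariates: pd.DataFrame | None = None,
    model: str | None = None,
) -> GroupComparison:
    """Linear-model group comparison adjusting for covariates.

    The outcome is regressed on group indicators plus the covariates (numeric
    columns enter linearly, non-numeric ones as indicator sets); the omnibus
    statistic is the partial F test for the group factor.  Adjusted group
    means are model predictions at the covariate grand means (indicator
    covariates at their observed proportions) with model-based standard
    errors.  ``model`` may name one of the two standard covariate sets
    ("thickness" / "age_gender") to select columns from ``covariates``; with
    no covariates the fit reduces exactly to the one-way ANOVA.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(str)
    if model is not None:
        if model not in MODEL_COVARIATES:
            raise ValueError(f"model must be one of {sorted(MODEL_COVARIATES)}")
        if covariates is None:
            raise ValueError(f"model {model!r} requires covariates")
        covariates = covariates[MODEL_COVARIATES[model]]
    if covariates is None:
        covariates = pd.DataFrame(index=np.arange(values.size))
    if len(covariates) != values.size:
        raise ValueError("covariates must have one row per observation")
    if covariates.isna().any().any():
        raise ValueError("covariates must be complete (no missing values)")

    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")

    # design: intercept + treatment-coded group dummies + covariate columns
    names = ["intercept"]
    cols = [np.ones(values.size)]
    for level in levels[1:]:
        cols.append((groups == level).astype(float))
        names.append(f"group[{level}]")
    cov_cols: list[str] = []
    for col in covariates.columns:
        series = covariates[col]
        if pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(dtype=float))
            names.append(str(col))
            cov_cols.append(str(col))
        else:
            cats = list(pd.unique(series.astype(str)))
            for cat in cats[1:]:
                cols.append((series.astype(str) == cat).to_numpy(dtype=float))
                names.append(f"{col}[{cat}]")
                cov_cols.append(f"{col}[{cat}]")
    exog = np.column_stack(cols)
    _check_full_rank(exog, names)

    fit = sm.OLS(values, exog).fit()
    # partial F for the group factor
    k_group = len(levels) - 1
    restriction = np.zeros((k_group, exog.shape[1]))
    for r in range(k_group):
        restriction[r, 1 + r] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ftest = fit.f_test(restriction)
    f_stat = float(np.squeeze(ftest.fvalue))
    p_value = float(ftest.pvalue)

    grand = exog.mean(axis=0)
    means: dict[str, tuple[float, float]] = {}
    rows: dict[str, np.ndarray] = {}
    for level in levels:
        x = grand.copy()
        x[0] = 1.0
        for r, other in enumerate(levels[1:]):
            x[1 + r] = 1.0 if other == level else 0.0
        rows[level] = x
        mean = float(x @ fit.params)
        se = float(np.sqrt(x @ fit.cov_params() @ x))
        means[level] = (mean, se)

    comparison = GroupComparison(
        statistic=f_stat,
        p_value=p_value,
        df=(float(k_group), float(fit.df_resid)),
        adjusted_means=means,
        kind="ancova",
    )
    if p_value < OMNIBUS_ALPHA:
        pairs = []
        for ga, gb in itertools.combinations(levels, 2):
            contrast = rows[ga] - rows[gb]
            tt = fit.t_test(contrast)
            pairs.append((ga, gb, float(tt.pvalue)))
        adj = bonferroni_pairwise([p for *_, p in pairs])
        comparison.pairwise = [(ga, gb, p) for (ga, gb, _), p in zip(pairs, adj)]
    return comparison


def bonferroni_pairwise(p_values, n_pairs: int | None = None) -> list[float]:
    """Bonferroni adjustment: each p multiplied by the number of pairs, capped at 1."""
    p_values = [float(p) for p in p_values]
    n = len(p_values) if n_pairs is None else int(n_pairs)
    return [min(1.0, p * n) for p in p_values]


def _log_table_probability(table: np.ndarray, row_sums, col_sums, total) -> float:
    return float(
        gammaln(row_sums + 1).sum()
        + gammaln(col_sums + 1).sum()
        - gammaln(total + 1)
        - gammaln(table + 1).sum()
    )


def enumerate_margin_tables(row_sums, col_sums):
    """Yield every nonnegative integer table with the given margins."""
    row_sums = list(row_sums)
    col_sums = list(col_sums)

    def fill(row_idx: int, remaining_cols: list[int], current: list[list[int]]):
        if row_idx == len(row_sums) - 1:
            if all(v >= 0 for v in remaining_cols) and sum(remaining_cols) == row_sums[-1]:
                yield np.array(current + [remaining_cols], dtype=np.int64)
            return
        target = row_sums[row_idx]

        def fill_row(col_idx: int, left: int, row: list[int]):
            if col_idx == len(col_sums) - 1:
                if 0 <= left <= remaining_cols[col_idx]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                yield from fill_row(col_idx + 1, left - v, row + [v])

        for row in fill_row(0, target, []):
            yield from fill(
                row_idx + 1,
                [rc - v for rc, v in zip(remaining_cols, row)],
                current + [row],
            )

    yield from fill(0, col_sums, [])


def fisher_exact_rxc(table) -> float:
    """Exact two-sided Fisher test for an r x c contingency table.

    The p-value is the total probability, under the multivariate hypergeometric
    distribution with the observed margins, of all tables no more probable
    than the observed one (probability ordering, the conventional two-sided
    definition).  Computed by exhaustive enumeration — exact for the small
    count tables this pipeline produces.  A table with a zero row or column
    margin is degenerate: p = 1 by convention (a warning is emitted).
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (table < 0).any():
        raise ValueError("counts must be non-negative integers")
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        warnings.warn(
            "contingency table has a zero margin; Fisher p = 1 by convention",
            stacklevel=2,
        )
        return 1.0
    total = table.sum()
    log_p_obs = _log_table_probability(table, row_sums, col_sums, total)
    p = 0.0
    for candidate in enumerate_margin_tables(row_sums, col_sums):
        log_p = _log_table_probability(candidate, row_sums, col_sums, total)
        if log_p <= log_p_obs + 1e-9:
            p += np.exp(log_p)
    return float(min(p, 1.0))


def anova_type1_rate(
    n_per_group=(14, 11, 23, 10),
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the one-way ANOVA on null cohorts.

    Simulates ``n_reps`` cohorts with the given group sizes, all observations
    drawn from one normal distribution (no group effect), and returns the
    fraction of omnibus p-values below ``alpha`` — a calibration check that
    should sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    labels = np.concatenate(
        [np.full(n, i) for i, n in enumerate(n_per_group)]
    )
    hits = 0
    for _ in range(n_reps):
        values = rng.standard_normal(labels.size)
        arrays = [values[labels == i] for i in range(len(n_per_group))]
        _, p = sps.f_oneway(*arrays)
        if p < alpha:
            hits += 1
    return hits / n_reps
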