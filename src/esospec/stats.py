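"""Cohort statistics: one-way ANOVA, Fisher LSD intervals, dummy coding,
and the multiple-regression predictor.

The group-comparison stage mirrors the study design: liquid states and
binary health flags are compared by classical one-way ANOVA, and group
means are reported with unprotected Fisher least-significant-difference
(LSD) intervals,

    half_width(g) = t(1 − α/2, df_within) · √(MSE / n_g),

whose non-overlap (for equal group sizes) indicates a pairwise-significant
difference.  LSD is computed regardless of the omnibus F and without
multiple-testing correction; a Bonferroni option exists but is off by
default.  The predictor is ordinary least squares with intercept
(statsmodels under the hood), with a documented default of regressing the
reflux flag on body fat, visceral fat and smoking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .cohort import Cohort, FLAG_FIELDS, TABLE1, bin_counts

__all__ = [
    "AnovaResult",
    "LsdSummary",
    "PredictorFit",
    "CohortSummary",
    "StatsError",
    "one_way_anova",
    "lsd_intervals",
    "dummy_code",
    "fit_predictor",
    "summarize_cohort",
]

#: default predictor specification (response, features)
DEFAULT_PREDICTOR_RESPONSE = "reflux"
DEFAULT_PREDICTOR_FEATURES = ("body_fat_pct", "visceral_fat_pct", "smoker")


class StatsError(ValueError):
    """Invalid input to a statistical routine."""


class InsufficientReplicationError(StatsError):
    """A group has fewer than two observations."""


class CollinearityError(StatsError):
    """Rank-deficient regression design."""

    def __init__(self, columns: list[str]):
        self.columns = columns
        super().__init__(f"collinear design columns: {columns}")


@dataclass(frozen=True)
class AnovaResult:
    """Classical one-way ANOVA decomposition."""

    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    group_means: dict
    mse_within: float


@dataclass(frozen=True)
class LsdSummary:
    """Group means with Fisher LSD interval half-widths."""

    groups: tuple
    means: np.ndarray
    half_widths: np.ndarray
    pairwise_significant: np.ndarray
    alpha_level: float

    def all_pairs_separated(self) -> bool:
        off = ~np.eye(len(self.groups), dtype=bool)
        return bool(np.all(self.pairwise_significant[off]))


def _group_arrays(values, group_labels) -> tuple[list, list[np.ndarray]]:
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if values.shape != labels.shape:
        raise StatsError("values and group_labels must have equal length")
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    arrays = [values[labels == g] for g in groups]
    for g, arr in zip(groups, arrays):
        if arr.size < 2:
            raise InsufficientReplicationError(
                f"group {g!r} has {arr.size} observation(s); need >= 2"
            )
    return groups, arrays


def one_way_anova(values, group_labels) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    The p-value comes from the F(df_between, df_within) distribution.
    """
    groups, arrays = _group_arrays(values, group_labels)
    all_values = np.concatenate(arrays)
    grand_mean = all_values.mean()
    n_total = all_values.size
    k = len(groups)

    ss_between = sum(a.size * (a.mean() - grand_mean) ** 2 for a in arrays)
    ss_within = sum(np.sum((a - a.mean()) ** 2) for a in arrays)
    df_between = k - 1
    df_within = n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        f_stat = 0.0 if ms_between == 0.0 else np.inf
    else:
        f_stat = ms_between / ms_within
    p = float(sps.f.sf(f_stat, df_between, df_within)) if np.isfinite(f_stat) else 0.0
    return AnovaResult(
        f_statistic=float(f_stat),
        p_value=p,
        df_between=df_between,
        df_within=df_within,
        group_means={g: float(a.mean()) for g, a in zip(groups, arrays)},
        mse_within=float(ms_within),
    )


def lsd_intervals(values, group_labels, alpha_level: float = 0.05,
                  bonferroni: bool = False) -> LsdSummary:
    """Fisher LSD interval half-widths and the pairwise-significance matrix.

    ``half_width(g) = t(1−α/2, df_within)·√(MSE/n_g)``; pair (g, h) is
    significant when ``|mean_g − mean_h| > t·√(MSE·(1/n_g + 1/n_h))``.
    With ``bonferroni=True`` α is divided by the number of pairs first
    (off by default — unprotected LSD is the reference procedure here).
    """
    groups, arrays = _group_arrays(values, group_labels)
    anova = one_way_anova(values, group_labels)
    k = len(groups)
    alpha = alpha_level / (k * (k - 1) / 2) if bonferroni else alpha_level
    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, anova.df_within))
    ns = np.array([a.size for a in arrays], dtype=float)
    means = np.array([a.mean() for a in arrays])
    half_widths = t_crit * np.sqrt(anova.mse_within / ns)

    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            lsd = t_crit * np.sqrt(anova.mse_within * (1.0 / ns[i] + 1.0 / ns[j]))
            sig[i, j] = sig[j, i] = abs(means[i] - means[j]) > lsd
    return LsdSummary(
        groups=tuple(groups),
        means=means,
        half_widths=half_widths,
        pairwise_significant=sig,
        alpha_level=alpha,
    )


def dummy_code(cohort) -> pd.DataFrame:
    """Binary indicator table (smoker / reflux / gastric_issue), 1 = present."""
    if isinstance(cohort, Cohort):
        df = cohort.to_dataframe()
    else:
        df = pd.DataFrame(cohort)
    missing = [f for f in FLAG_FIELDS if f not in df.columns]
    if missing:
        raise StatsError(f"missing flag column(s): {missing}")
    out = df[list(FLAG_FIELDS)].astype(int)
    bad = ~out.isin([0, 1]).all(axis=None)
    if bad:
        raise StatsError("flag columns must contain only 0/1 values")
    return out


@dataclass
class PredictorFit:
    """OLS multiple-regression fit with intercept."""

    feature_names: tuple
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    r_squared: float
    n_obs: int

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        x = sm.add_constant(features[list(self.feature_names)], has_constant="add")
        return np.asarray(x @ self.coefficients.reindex(x.columns))


def fit_predictor(features: pd.DataFrame, response) -> PredictorFit:
    """Ordinary least squares with intercept.

    *features* is a per-subject numeric table; *response* a numeric or
    binary outcome of the same length.  Raises :class:`CollinearityError`
    (naming the offending columns) on a rank-deficient design, and refuses
    constant features.
    """
    features = pd.DataFrame(features)
    y = np.asarray(response, dtype=float)
    if len(features) != y.size:
        raise StatsError("features and response must have equal length")
    if len(features) <= features.shape[1] + 1:
        raise StatsError("need n_subjects > n_features + 1")
    constant_cols = [c for c in features.columns if features[c].nunique() <= 1]
    if constant_cols:
        raise CollinearityError(constant_cols)

    x = sm.add_constant(features.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # greedily identify columns that do not extend the column space
        offenders = []
        kept = x[["const"]].to_numpy()
        for c in features.columns:
            cand = np.column_stack([kept, features[c].to_numpy(dtype=float)])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                offenders.append(str(c))
            else:
                kept = cand
        raise CollinearityError(offenders)

    model = sm.OLS(y, x).fit()
    return PredictorFit(
        feature_names=tuple(features.columns),
        coefficients=model.params,
        std_errors=model.bse,
        p_values=model.pvalues,
        r_squared=float(model.rsquared),
        n_obs=int(model.nobs),
    )


@dataclass(frozen=True)
class CohortSummary:
    """Cohort layout in the published-table structure."""

    n_subjects: int
    counts: dict       # param → sex → list of bin counts
    means: dict        # param → sex → mean
    ranges: dict       # param → sex → (min, max)
    flag_totals: dict  # flag → total


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Counts per published bin by sex, per-sex mean/[min–max], flag totals."""
    counts: dict = {}
    means: dict = {}
    ranges: dict = {}
    for param in TABLE1:
        counts[param] = {}
        means[param] = {}
        ranges[param] = {}
        for sex in ("M", "W"):
            counts[param][sex] = bin_counts(cohort, param, sex)
            vals = [getattr(s, param) for s in cohort if s.sex == sex]
            if vals:
                means[param][sex] = float(np.mean(vals))
                ranges[param][sex] = (float(min(vals)), float(max(vals)))
            else:
                means[param][sex] = float("nan")
                ranges[param][sex] = (float("nan"), float("nan"))
    flags = {f: (cohort.flag_total(f) if len(cohort) else 0) for f in FLAG_FIELDS}
    return CohortSummary(
        n_subjects=len(cohort),
        counts=counts,
        means=means,
        ranges=ranges,
        flag_totals=flags,
    )
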