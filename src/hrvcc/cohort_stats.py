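"""Cohort-level statistics: HR adjustment, group comparisons, moderated regressions.

The analysis surface mirrors a standard sex-differences HRV study design:

* **Heart-rate adjustment.** Many HRV and complexity indices carry a purely
  mathematical dependence on mean heart rate. Each measure is adjusted by
  the subject's average HR according to the sign of its cross-subject
  correlation with HR: divided by HR when the correlation is negative,
  multiplied when positive. Both raw and adjusted values are retained and
  analysed.

* **Group comparisons.** Per-measure one-way F tests between the two sex
  groups (df 1, N-2; equivalent to the squared pooled-variance t), Cohen's d
  effect sizes (absolute, pooled SD), and Bonferroni-corrected alpha levels
  applied per measure family (time domain, frequency domain, fractal,
  entropy).

* **Hierarchical (moderated) regressions.** For each internalizing-symptom
  subscale and each cardiac measure: step 1 regresses the subscale total on
  sex (coded 1 = boys, 2 = girls) and the z-scored measure; step 2 adds
  their interaction. Standardized coefficients and per-step R-squared
  increments are reported. Rows with missing values are dropped listwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "MEASURE_FAMILIES",
    "AdjustmentReport",
    "RegressionStep",
    "RegressionResult",
    "hr_adjust",
    "cohens_d",
    "bonferroni_alpha",
    "compare_groups",
    "hierarchical_regression",
    "regression_table",
    "normality_screen",
]

# Bonferroni families: measures tested together share a corrected alpha.
MEASURE_FAMILIES: Dict[str, tuple[str, ...]] = {
    "time_domain": ("hr_bpm", "rmssd_ms"),
    "frequency_domain": ("lf_ms2", "ln_hf"),
    "fractal": ("dfa_alpha1", "dfa_alpha2", "fd"),
    "entropy": ("mse_s1", "mse_s5", "mse_s10", "mse_s15", "mse_s20"),
}


@dataclass(frozen=True)
class AdjustmentReport:
    """Per-measure record of the HR-adjustment rule applied."""

    correlations: Mapping[str, float]
    operations: Mapping[str, str]  # divided_by_hr | multiplied_by_hr | unadjusted


def hr_adjust(
    cohort: pd.DataFrame,
    measures: Sequence[str] | None = None,
    hr_col: str = "hr_bpm",
) -> tuple[pd.DataFrame, AdjustmentReport]:
    """Adjust cardiac measures by each subject's average HR.

    For each measure, its Pearson correlation with HR across subjects sets
    the operation: divide by HR when negative, multiply when positive. A
    zero or undefined correlation leaves the measure unadjusted with a
    warning. Adjusted values appear as new ``<measure>_adj`` columns; raw
    columns are retained.
    """
    if len(cohort) < 3:
        raise ValueError("need at least 3 subjects to estimate correlations")
    if hr_col not in cohort:
        raise ValueError(f"missing HR column {hr_col!r}")
    if measures is None:
        measures = [c for fam in MEASURE_FAMILIES.values() for c in fam if c != hr_col and c in cohort]
    out = cohort.copy()
    corrs: Dict[str, float] = {}
    ops: Dict[str, str] = {}
    hr = cohort[hr_col].to_numpy(dtype=float)
    for m in measures:
        x = cohort[m].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"measure {m!r} has zero variance; left unadjusted")
            corrs[m], ops[m] = float("nan"), "unadjusted"
            continue
        r = float(np.corrcoef(x, hr)[0, 1])
        corrs[m] = r
        if r > 0:
            out[m + "_adj"] = out[m] * out[hr_col]
            ops[m] = "multiplied_by_hr"
        elif r < 0:
            out[m + "_adj"] = out[m] / out[hr_col]
            ops[m] = "divided_by_hr"
        else:
            warnings.warn(f"measure {m!r} uncorrelated with HR; left unadjusted")
            ops[m] = "unadjusted"
    return out, AdjustmentReport(correlations=corrs, operations=ops)


def cohens_d(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Absolute standardized mean difference with pooled SD."""
    if sd1 < 0 or sd2 < 0:
        raise ValueError("SDs must be non-negative")
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("pooled SD is zero; d undefined")
    return float(abs(mean1 - mean2) / pooled)


def bonferroni_alpha(base_alpha: float, family_size: int) -> float:
    """Per-test alpha after Bonferroni correction within a family."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    return base_alpha / family_size


def compare_groups(
    cohort: pd.DataFrame,
    measures: Sequence[str],
    family_alpha: float = 0.05,
    group_col: str = "sex_code",
) -> pd.DataFrame:
    """Two-group univariate F tests with Cohen's d for each measure.

    Returns a tidy frame with group means/SDs, F (df 1, N-2), p, d and a
    significance flag at ``family_alpha``. F is computed as the squared
    pooled-variance t statistic.
    """
    groups = sorted(cohort[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    g1 = cohort[cohort[group_col] == groups[0]]
    g2 = cohort[cohort[group_col] == groups[1]]
    rows = []
    for m in measures:
        x1 = g1[m].dropna().to_numpy(dtype=float)
        x2 = g2[m].dropna().to_numpy(dtype=float)
        if x1.size < 2 or x2.size < 2:
            raise ValueError(f"measure {m!r}: need n >= 2 per group")
        t, _ = stats.ttest_ind(x1, x2, equal_var=True)
        f = float(t**2)
        df2 = x1.size + x2.size - 2
        p = float(stats.f.sf(f, 1, df2))
        d = cohens_d(x1.mean(), x1.std(ddof=1), x1.size, x2.mean(), x2.std(ddof=1), x2.size)
        rows.append(
            {
                "measure": m,
                "mean_1": x1.mean(),
                "sd_1": x1.std(ddof=1),
                "n_1": x1.size,
                "mean_2": x2.mean(),
                "sd_2": x2.std(ddof=1),
                "n_2": x2.size,
                "F": f,
                "df1": 1,
                "df2": df2,
                "p": p,
                "cohens_d": d,
                "family_alpha": family_alpha,
                "significant": p < family_alpha,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionStep:
    r2: float
    delta_r2: float
    beta: Mapping[str, float]  # standardized coefficients
    pvalues: Mapping[str, float]


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    measure: str
    n: int
    step1: RegressionStep
    step2: RegressionStep


def _standardized_betas(model, res, y_sd: float) -> Dict[str, float]:
    out = {}
    X = model.exog
    params = np.asarray(res.params)
    for i, name in enumerate(model.exog_names):
        if name == "const":
            continue
        out[name] = float(params[i] * X[:, i].std(ddof=0) / y_sd)
    return out


def hierarchical_regression(
    cohort: pd.DataFrame,
    outcome: str,
    measure: str,
    sex_col: str = "sex_code",
) -> RegressionResult:
    """Two-step moderated regression of a symptom subscale on sex and a measure.

    Step 1: ``outcome ~ sex + z(measure)``; step 2 adds ``sex * z(measure)``
    (sex kept on its raw 1/2 coding, the measure z-scored across the
    analysed subjects). Coefficients are reported as standardized betas
    (slope times predictor SD over outcome SD); the interaction's
    contribution is the step-2 R-squared increment.
    """
    data = cohort[[outcome, measure, sex_col]].dropna()
    if len(data) < 10:
        raise ValueError(f"fewer than 10 complete cases for {outcome} ~ {measure}")
    y = data[outcome].to_numpy(dtype=float)
    sex = data[sex_col].to_numpy(dtype=float)
    z = data[measure].to_numpy(dtype=float)
    if z.std(ddof=0) == 0:
        raise ValueError(f"collinear/degenerate column: {measure} has zero variance")
    if sex.std(ddof=0) == 0:
        raise ValueError(f"collinear/degenerate column: {sex_col} has zero variance")
    z = (z - z.mean()) / z.std(ddof=0)
    y_sd = y.std(ddof=0)
    if y_sd == 0:
        raise ValueError(f"outcome {outcome} has zero variance")

    X1 = pd.DataFrame({sex_col: sex, measure: z})
    X2 = X1.assign(**{f"{sex_col}_x_{measure}": sex * z})
    results = []
    prev_r2 = 0.0
    for X in (X1, X2):
        exog = sm.add_constant(X)
        if np.linalg.matrix_rank(exog.to_numpy()) < exog.shape[1]:
            raise ValueError(f"rank-deficient design: columns {list(exog.columns)}")
        model = sm.OLS(y, exog)
        res = model.fit()
        betas = _standardized_betas(model, res, y_sd)
        pvals = {k: float(res.pvalues[k]) for k in X.columns}
        results.append(
            RegressionStep(
                r2=float(res.rsquared),
                delta_r2=float(res.rsquared) - prev_r2,
                beta=betas,
                pvalues=pvals,
            )
        )
        prev_r2 = float(res.rsquared)
    return RegressionResult(
        outcome=outcome, measure=measure, n=len(data), step1=results[0], step2=results[1]
    )


def regression_table(
    cohort: pd.DataFrame,
    outcomes: Sequence[str],
    measures: Sequence[str],
    sex_col: str = "sex_code",
) -> pd.DataFrame:
    """Tidy frame of hierarchical regressions over outcome x measure pairs."""
    rows = []
    for outcome in outcomes:
        for measure in measures:
            r = hierarchical_regression(cohort, outcome, measure, sex_col=sex_col)
            interaction = f"{sex_col}_x_{measure}"
            rows.append(
                {
                    "outcome": outcome,
                    "measure": measure,
                    "n": r.n,
                    "step1_delta_r2": r.step1.delta_r2,
                    "beta_sex": r.step1.beta[sex_col],
                    "p_sex": r.step1.pvalues[sex_col],
                    "beta_measure": r.step1.beta[measure],
                    "p_measure": r.step1.pvalues[measure],
                    "step2_delta_r2": r.step2.delta_r2,
                    "beta_interaction": r.step2.beta[interaction],
                    "p_interaction": r.step2.pvalues[interaction],
                }
            )
    return pd.DataFrame(rows)


def normality_screen(values: Sequence[float]) -> Dict[str, float]:
    """Shapiro-Wilk W and p plus sample skewness/kurtosis (excess)."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    w, p = stats.shapiro(x)
    return {
        "W": float(w),
        "p": float(p),
        "skewness": float(stats.skew(x)),
        "kurtosis": float(stats.kurtosis(x)),
    }
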