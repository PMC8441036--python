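"""Reliability and inferential statistics over derived participant variables.

Three pieces:

* :func:`icc_two_way_random` — intraclass correlation for a complete
  items × raters matrix under the two-way random-effects,
  absolute-agreement model, in the McGraw-Wong mean-squares
  formulation: ICC(A,1) for a single rater and ICC(A,k) for the
  average of k raters (equivalently Shrout-Fleiss ICC(2,1)/(2,k)).
  Absolute agreement penalizes systematic rater shifts, so a constant
  offset between raters lowers the coefficient.

* :func:`correlation_matrix` — pairwise Pearson correlations with
  two-sided p-values, pairwise-complete over missing cells.

* :func:`hierarchical_regression` — blockwise OLS on standardized
  variables, reporting per block the cumulative R², the increment
  ΔR² with its F test, and per predictor the standardized β, its SE,
  p-value, and the part (semipartial) correlation — the signed square
  root of the R² lost when that predictor alone is dropped from its
  model, whose square is the predictor's unique variance contribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

OUTCOME_VARIABLES = ("ps_ts2", "wp_ts2", "wp_wasw")
PREDICTOR_BLOCKS = (("wp_tw4",), ("ps_tw4",))
COVARIATE_BLOCK = ("vineland_composite",)


class IncompleteMatrixError(ValueError):
    """The ratings matrix has missing cells."""


class InsufficientDataError(ValueError):
    """Too few complete cases for the requested analysis."""


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IccResult:
    """ICC(A,1) and ICC(A,k) with the underlying ANOVA mean squares.

    ``defined`` is False when the matrix has no variance at all, in
    which case both coefficients are NaN.
    """

    icc_single: float
    icc_average: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n_items: int
    k_raters: int
    model: str = "two-way random, absolute agreement"
    defined: bool = True


def icc_two_way_random(matrix) -> IccResult:
    """Two-way random-effects absolute-agreement ICC for items × raters scores.

    Parameters
    ----------
    matrix
        Array-like of shape (n_items, k_raters); complete (no NaN),
        n_items >= 2, k_raters >= 2.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings matrix must be 2-dimensional")
    n, k = x.shape
    if n < 2 or k < 2:
        raise InsufficientDataError("need at least 2 items and 2 raters")
    if np.isnan(x).any():
        raise IncompleteMatrixError("ratings matrix contains missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    # clamp tiny negative rounding so perfect agreement yields exactly 1.0
    ss_error = max(ss_total - ss_rows - ss_cols, 0.0)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))

    if ss_total == 0.0:
        return IccResult(np.nan, np.nan, msr, msc, mse, n, k, defined=False)

    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    denom_average = msr + (msc - mse) / n
    icc_single = (msr - mse) / denom_single if denom_single != 0 else np.nan
    icc_average = (msr - mse) / denom_average if denom_average != 0 else np.nan
    return IccResult(icc_single, icc_average, msr, msc, mse, n, k,
                     defined=not (np.isnan(icc_single) or np.isnan(icc_average)))


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def correlation_matrix(
    variables: pd.DataFrame, min_n: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r and two-sided p-value matrices.

    Raises :class:`InsufficientDataError` when any pair has fewer than
    ``min_n`` complete cases.
    """
    cols = list(variables.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            pair = variables[[a, b]].dropna()
            if len(pair) < min_n:
                raise InsufficientDataError(
                    f"pair ({a}, {b}) has only {len(pair)} complete cases"
                )
            res = sps.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


# ---------------------------------------------------------------------------
# hierarchical regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictorStats:
    """Standardized coefficient, its SE and p, and the part correlation."""

    name: str
    beta: float
    se: float
    p: float
    part: float


@dataclass(frozen=True)
class BlockResult:
    """Cumulative model after adding one block of predictors."""

    block: int
    predictors: tuple[PredictorStats, ...]
    r2: float
    delta_r2: float
    delta_f: float
    df_num: int
    df_den: int
    delta_f_p: float


@dataclass(frozen=True)
class RegressionReport:
    """Blockwise OLS summary for one outcome."""

    outcome: str
    n: int
    blocks: tuple[BlockResult, ...]

    @property
    def final_r2(self) -> float:
        return self.blocks[-1].r2


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    if sd == 0:
        raise InsufficientDataError("a variable has zero variance")
    return (values - values.mean()) / sd


def _r2(y: np.ndarray, x_cols: list[np.ndarray]) -> float:
    if not x_cols:
        return 0.0
    X = sm.add_constant(np.column_stack(x_cols))
    return float(sm.OLS(y, X).fit().rsquared)


def hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    blocks: Sequence[Sequence[str]],
) -> RegressionReport:
    """Fit nested OLS models, one per cumulative predictor block.

    All variables are z-scored before fitting, so coefficients are
    standardized βs.  Rows with a missing value in the outcome or any
    predictor are dropped listwise.  The increment test for block b is
    ΔF = (ΔR²/p_added) / ((1−R²_b)/(n−k_b−1)) on (p_added, n−k_b−1)
    degrees of freedom.
    """
    all_predictors = [p for block in blocks for p in block]
    if len(set(all_predictors)) != len(all_predictors):
        raise ValueError("a predictor appears in more than one block")
    frame = data[[outcome, *all_predictors]].dropna()
    n = len(frame)
    if n <= len(all_predictors) + 1:
        raise InsufficientDataError(
            f"n={n} too small for {len(all_predictors)} predictors"
        )
    z = {c: _standardize(frame[c].to_numpy(dtype=float)) for c in frame.columns}
    y = z[outcome]

    results: list[BlockResult] = []
    cumulative: list[str] = []
    prev_r2 = 0.0
    for b, block in enumerate(blocks, start=1):
        cumulative = cumulative + list(block)
        X = sm.add_constant(np.column_stack([z[p] for p in cumulative]))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise np.linalg.LinAlgError("design matrix is rank deficient")
        fit = sm.OLS(y, X).fit()
        r2 = float(fit.rsquared)
        k_full = len(cumulative)
        p_added = len(block)
        df_den = n - k_full - 1
        delta_r2 = r2 - prev_r2
        denom = (1.0 - r2) / df_den
        delta_f = (delta_r2 / p_added) / denom if denom > 0 else np.inf
        delta_f_p = float(sps.f.sf(delta_f, p_added, df_den)) if np.isfinite(delta_f) else 0.0

        predictors = []
        for idx, name in enumerate(cumulative, start=1):
            beta = float(fit.params[idx])
            reduced = [p for p in cumulative if p != name]
            r2_reduced = _r2(y, [z[p] for p in reduced])
            unique = max(r2 - r2_reduced, 0.0)
            part = float(np.sign(beta) * np.sqrt(unique)) if beta != 0 else float(np.sqrt(unique))
            predictors.append(PredictorStats(
                name=name,
                beta=beta,
                se=float(fit.bse[idx]),
                p=float(fit.pvalues[idx]),
                part=part,
            ))
        results.append(BlockResult(
            block=b,
            predictors=tuple(predictors),
            r2=r2,
            delta_r2=delta_r2,
            delta_f=float(delta_f),
            df_num=p_added,
            df_den=df_den,
            delta_f_p=delta_f_p,
        ))
        prev_r2 = r2
    return RegressionReport(outcome=outcome, n=n, blocks=tuple(results))


# ---------------------------------------------------------------------------
# full analysis report
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.10:
        return "^"
    return ""


@dataclass(frozen=True)
class AnalysisReport:
    """Descriptives, the correlation matrix, and the three regressions."""

    descriptives: pd.DataFrame
    correlations_r: pd.DataFrame
    correlations_p: pd.DataFrame
    regressions: tuple[RegressionReport, ...]
    with_covariate: bool

    def to_text(self) -> str:
        lines = ["Descriptive statistics", "----------------------"]
        lines.append(self.descriptives.round(3).to_string())
        lines += ["", "Pearson correlations (stars: two-sided p)", "-" * 41]
        starred = self.correlations_r.round(3).astype(str)
        for a in self.correlations_r.index:
            for b in self.correlations_r.columns:
                if a != b:
                    starred.loc[a, b] += significance_stars(self.correlations_p.loc[a, b])
        lines.append(starred.to_string())
        for report in self.regressions:
            lines += ["", f"Hierarchical regression — DV: {report.outcome} (n={report.n})",
                      "-" * 60]
            for blk in report.blocks:
                stars = significance_stars(blk.delta_f_p)
                lines.append(
                    f"  Model {blk.block}: R2={blk.r2:.3f}  dR2={blk.delta_r2:.3f}  "
                    f"dF={blk.delta_f:.2f}{stars} ({blk.df_num},{blk.df_den})"
                )
                for pr in blk.predictors:
                    lines.append(
                        f"    {pr.name:<22} beta={pr.beta: .3f}  SE={pr.se:.3f}  "
                        f"p={pr.p:.3f}{significance_stars(pr.p)}  part={pr.part: .3f}"
                    )
        lines.append("")
        lines.append("*** p<.001  ** p<.01  * p<.05  ^ p<.10")
        return "\n".join(lines)


def analysis_report(
    derived: pd.DataFrame, with_covariate: bool = False
) -> AnalysisReport:
    """Run the standard analysis battery over a derived-variable table.

    For each outcome (``ps_ts2``, ``wp_ts2``, ``wp_wasw``) fits the
    hierarchical regression with week-4 words passed per trial in one
    block and week-4 phonemic score per trial added in the next;
    ``with_covariate=True`` prepends the Vineland composite as block 1.
    """
    from .probes import descriptives as _desc

    desc = _desc(derived)
    corr_cols = ["ps_tw4", "wp_tw4", "ps_ts2", "wp_ts2", "wp_wasw"]
    if with_covariate and "vineland_composite" in derived.columns:
        corr_cols.append("vineland_composite")
    r, p = correlation_matrix(derived[corr_cols].dropna(how="all"))
    blocks: tuple = PREDICTOR_BLOCKS
    if with_covariate:
        blocks = (COVARIATE_BLOCK,) + PREDICTOR_BLOCKS
    regressions = tuple(
        hierarchical_regression(derived, outcome, blocks)
        for outcome in OUTCOME_VARIABLES
    )
    return AnalysisReport(desc, r, p, regressions, with_covariate)
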