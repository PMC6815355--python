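"""Trial statistics: per-protocol filter, change scores, ANCOVA, Spearman, ICC.

The primary analysis contract: change from baseline at follow-up is the
dependent variable of an ordinary-least-squares ANCOVA with the outcome's own
baseline value, treatment group, and gender as covariates (gender because
randomisation was stratified by it). The treatment-group coefficient is the
ET - CG adjusted mean difference; covariate-adjusted (least-squares) means
fix all other covariates at their pooled sample means. A sensitivity variant
additionally adjusts for age and weight (gender is already a covariate, so
only those two are added).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "MIN_ADHERENT_SESSIONS",
    "filter_per_protocol",
    "compute_changes",
    "change_table",
    "AncovaResult",
    "ChangeScoreAncova",
    "fit_ancova",
    "ancova_table",
    "SpearmanMatrix",
    "spearman_matrix",
    "IccResult",
    "AgreementIcc",
    "icc_agreement",
]

#: Protocol adherence: at least 24 of 36 exercise sessions attended
#: (equivalently, 12 or fewer non-attendances).
MIN_ADHERENT_SESSIONS = 24
TOTAL_SESSIONS = 36


def filter_per_protocol(
    table: pd.DataFrame, min_sessions: int = MIN_ADHERENT_SESSIONS
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Restrict to the per-protocol population with complete imaging data.

    Keeps ET rows with ``attendance >= min_sessions`` (boundary inclusive),
    CG rows with ``exercised_outside == False``, and only rows with
    ``complete_dce == True``. Row order is preserved. Returns the filtered
    table and a flow log of exclusion counts (each row counted once, by the
    first rule it fails: adherence/exercise before missing imaging).
    """
    et = table["arm"] == "ET"
    nonadherent = et & ~(table["attendance"] >= min_sessions)
    exercised = (~et) & table["exercised_outside"].astype(bool)
    incomplete = ~nonadherent & ~exercised & ~table["complete_dce"].astype(bool)
    keep = ~(nonadherent | exercised | incomplete)
    flow = {
        "input": int(len(table)),
        "et_nonadherent": int(nonadherent.sum()),
        "cg_exercised_outside": int(exercised.sum()),
        "incomplete_dce": int(incomplete.sum()),
        "retained": int(keep.sum()),
    }
    if flow["retained"] == 0:
        warnings.warn("per-protocol filter retained no participants", stacklevel=2)
    logger.info("per-protocol flow: %s", flow)
    return table.loc[keep].copy(), flow


def compute_changes(table: pd.DataFrame, outcome: str) -> pd.Series:
    """Follow-up minus baseline for one outcome; incomplete rows are dropped.

    Raises ``KeyError`` when the ``<outcome>_baseline/_followup`` columns are
    absent.
    """
    b, f = f"{outcome}_baseline", f"{outcome}_followup"
    if b not in table.columns or f not in table.columns:
        raise KeyError(f"unknown outcome {outcome!r}: expected columns {b!r} and {f!r}")
    change = table[f] - table[b]
    n_missing = int(change.isna().sum())
    if n_missing:
        logger.info("outcome %s: dropped %d rows with a missing timepoint", outcome, n_missing)
    return change.dropna()


def change_table(table: pd.DataFrame, outcomes: list[str]) -> pd.DataFrame:
    """Change scores for several outcomes, aligned on participants (NaN where missing)."""
    return pd.DataFrame(
        {name: table[f"{name}_followup"] - table[f"{name}_baseline"] for name in outcomes},
        index=table.index,
    )


@dataclass
class AncovaResult:
    """Baseline-adjusted group comparison for one outcome."""

    outcome: str
    adjusted_mean_et: float
    adjusted_mean_cg: float
    se_et: float
    se_cg: float
    mean_difference: float
    se_difference: float
    ci95: tuple[float, float]
    p_value: float
    n_used: int
    covariates: tuple[str, ...]


def _encode_gender(g: pd.Series) -> pd.Series:
    if g.dtype == object or isinstance(g.dtype, pd.CategoricalDtype):
        return g.map({"F": 1.0, "M": 0.0})
    return g.astype(float)


class ChangeScoreAncova(BaseEstimator):
    """OLS ANCOVA of a change score on baseline, treatment arm, and gender.

    Coding: arm ET=1 (so the arm coefficient is the ET-CG difference),
    gender female=1. ``extra_covariates`` (e.g. ``("age", "weight")``) enables
    the sensitivity variant. Fitted attributes mirror
    :class:`AncovaResult` (``mean_difference_``, ``adjusted_mean_et_``,
    ``ci95_``, ``p_value_``, ...); ``model_`` holds the statsmodels results.
    """

    def __init__(self, outcome: str = "koos_pain", extra_covariates: tuple[str, ...] = ()):
        self.outcome = outcome
        self.extra_covariates = tuple(extra_covariates)

    def fit(self, table: pd.DataFrame, y=None):
        change = compute_changes(table, self.outcome)
        df = table.loc[change.index]
        design = pd.DataFrame(
            {
                "baseline": df[f"{self.outcome}_baseline"].astype(float),
                "arm_et": (df["arm"] == "ET").astype(float),
                "female": _encode_gender(df["gender"]),
            },
            index=df.index,
        )
        for cov in self.extra_covariates:
            design[cov] = df[cov].astype(float)
        ok = design.notna().all(axis=1)
        design, change = design[ok], change[ok]
        n_et = int(design["arm_et"].sum())
        if n_et < 2 or len(design) - n_et < 2:
            raise ValueError("fit_ancova requires at least 2 participants in each arm")
        X = sm.add_constant(design, has_constant="add")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            offender = _find_collinear(X)
            raise ValueError(f"rank-deficient ANCOVA design; offending covariate: {offender}")
        res = sm.OLS(change.to_numpy(), X.to_numpy()).fit()
        cols = list(X.columns)
        i_arm = cols.index("arm_et")
        beta = res.params
        cov_beta = res.cov_params()

        # least-squares means: arm indicator at 1/0, every other covariate at
        # its pooled sample mean
        x_base = X.to_numpy().mean(axis=0)
        preds, ses = [], []
        for arm_value in (1.0, 0.0):
            xv = x_base.copy()
            xv[i_arm] = arm_value
            preds.append(float(xv @ beta))
            ses.append(float(np.sqrt(xv @ cov_beta @ xv)))

        ci = res.conf_int()[i_arm]
        self.model_ = res
        self.design_columns_ = cols
        self.n_used_ = int(len(design))
        self.covariates_ = tuple(c for c in cols if c not in ("const", "arm_et"))
        self.adjusted_mean_et_, self.adjusted_mean_cg_ = preds
        self.se_et_, self.se_cg_ = ses
        self.mean_difference_ = float(beta[i_arm])
        self.se_difference_ = float(res.bse[i_arm])
        self.ci95_ = (float(ci[0]), float(ci[1]))
        self.p_value_ = float(res.pvalues[i_arm])
        return self

    @property
    def result_(self) -> AncovaResult:
        return AncovaResult(
            outcome=self.outcome,
            adjusted_mean_et=self.adjusted_mean_et_,
            adjusted_mean_cg=self.adjusted_mean_cg_,
            se_et=self.se_et_,
            se_cg=self.se_cg_,
            mean_difference=self.mean_difference_,
            se_difference=self.se_difference_,
            ci95=self.ci95_,
            p_value=self.p_value_,
            n_used=self.n_used_,
            covariates=self.covariates_,
        )


def _find_collinear(X: pd.DataFrame) -> str:
    """Name a column whose removal restores full rank (best effort)."""
    arr = X.to_numpy()
    full = np.linalg.matrix_rank(arr)
    for j, name in enumerate(X.columns):
        if name == "const":
            continue
        sub = np.delete(arr, j, axis=1)
        if np.linalg.matrix_rank(sub) == full:
            return str(name)
    return "<unidentified>"


def fit_ancova(
    table: pd.DataFrame, outcome: str, extra_covariates: tuple[str, ...] = ()
) -> AncovaResult:
    """Functional wrapper around :class:`ChangeScoreAncova`."""
    return ChangeScoreAncova(outcome=outcome, extra_covariates=extra_covariates).fit(table).result_


def ancova_table(
    table: pd.DataFrame, outcomes: list[str], extra_covariates: tuple[str, ...] = ()
) -> pd.DataFrame:
    """One ANCOVA row per outcome (adjusted means, difference, 95% CI, p)."""
    rows = []
    for outcome in outcomes:
        r = fit_ancova(table, outcome, extra_covariates)
        rows.append(
            {
                "outcome": r.outcome,
                "adjusted_mean_et": r.adjusted_mean_et,
                "se_et": r.se_et,
                "adjusted_mean_cg": r.adjusted_mean_cg,
                "se_cg": r.se_cg,
                "mean_difference": r.mean_difference,
                "ci95_low": r.ci95[0],
                "ci95_high": r.ci95[1],
                "p_value": r.p_value,
                "n_used": r.n_used,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SpearmanMatrix:
    """Pairwise Spearman correlations of change scores."""

    rho: pd.DataFrame
    p_value: pd.DataFrame
    n: pd.DataFrame


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p-value (feasible for n <= 9)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def spearman_matrix(
    changes: pd.DataFrame, min_n: int = 4, method: str = "t"
) -> SpearmanMatrix:
    """Spearman rank correlation of every pair of change columns.

    Pairwise-complete observations; ties get average ranks. p-values use the
    two-sided t approximation with n-2 df (``method="t"``), or an exact
    permutation null for n <= 9 (``method="exact"``). Pairs with fewer than
    ``min_n`` complete observations are flagged absent (NaN).
    """
    cols = list(changes.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    nobs = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            pair = changes[[cols[i], cols[j]]].dropna()
            n = len(pair)
            nobs[i, j] = nobs[j, i] = n
            if i == j:
                rho[i, j] = 1.0
                pval[i, j] = 0.0 if n >= min_n else np.nan
                continue
            if n < min_n:
                continue
            x = pair.iloc[:, 0].to_numpy()
            y = pair.iloc[:, 1].to_numpy()
            r, p = stats.spearmanr(x, y)
            if method == "exact":
                if n > 9:
                    raise ValueError("exact permutation p-values supported only for n <= 9")
                p = _exact_spearman_p(x, y, r)
            rho[i, j] = rho[j, i] = float(r)
            pval[i, j] = pval[j, i] = float(p)
    as_df = lambda a: pd.DataFrame(a, index=cols, columns=cols)
    return SpearmanMatrix(rho=as_df(rho), p_value=as_df(pval), n=as_df(nobs))


@dataclass
class IccResult:
    """Two-way random-effects, absolute-agreement, single-measurement ICC."""

    icc: float
    ci95: tuple[float, float]
    msr: float
    msc: float
    mse: float
    n_subjects: int
    n_sessions: int


class AgreementIcc(BaseEstimator):
    """ICC(A,1) for repeated measurements (e.g. two segmentation sessions).

    Computed from the two-way mean-squares decomposition (subjects x
    sessions); the 95% CI uses the F-distribution method of McGraw & Wong.
    Fit with a ``(n_subjects, n_sessions)`` array; fitted attributes:
    ``icc_``, ``ci95_``.
    """

    def __init__(self, ci_level: float = 0.95):
        self.ci_level = ci_level

    def fit(self, ratings, y=None):
        R = np.asarray(ratings, dtype=float)
        if R.ndim != 2 or R.shape[0] < 3 or R.shape[1] < 2:
            raise ValueError("ratings must be (n_subjects >= 3, n_sessions >= 2)")
        if np.isnan(R).any():
            raise ValueError("ratings must be complete")
        n, k = R.shape
        grand = R.mean()
        row_means = R.mean(axis=1)
        col_means = R.mean(axis=0)
        ssr = k * np.sum((row_means - grand) ** 2)
        ssc = n * np.sum((col_means - grand) ** 2)
        sse = np.sum((R - row_means[:, None] - col_means[None, :] + grand) ** 2)
        msr = ssr / (n - 1)
        msc = ssc / (k - 1)
        mse = sse / ((n - 1) * (k - 1))
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        if denom <= 0 or msr <= mse:
            if msr <= mse:
                warnings.warn(
                    "no between-subject variance beyond error; ICC reported as 0",
                    stacklevel=2,
                )
            icc = 0.0
        else:
            icc = (msr - mse) / denom

        alpha = 1.0 - self.ci_level
        # McGraw & Wong (1996) absolute-agreement single-rater interval
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if not np.isfinite(a):  # perfect agreement
            lower = upper = 1.0
        elif (a * msc + b * mse) > 0:
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            )
            f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
            f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
            lower = n * (msr - f_l * mse) / (
                f_l * (k * msc + (k * n - k - n) * mse) + n * msr
            )
            upper = n * (f_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_u * msr
            )
        else:  # no variance anywhere: interval undefined
            lower = upper = float("nan")
        self.icc_ = float(icc)
        self.ci95_ = (float(np.clip(lower, -1.0, 1.0)), float(np.clip(upper, -1.0, 1.0)))
        self.msr_, self.msc_, self.mse_ = float(msr), float(msc), float(mse)
        self.n_subjects_, self.n_sessions_ = n, k
        return self

    @property
    def result_(self) -> IccResult:
        return IccResult(
            icc=self.icc_,
            ci95=self.ci95_,
            msr=self.msr_,
            msc=self.msc_,
            mse=self.mse_,
            n_subjects=self.n_subjects_,
            n_sessions=self.n_sessions_,
        )


def icc_agreement(ratings, ci_level: float = 0.95) -> IccResult:
    """Functional wrapper around :class:`AgreementIcc`."""
    return AgreementIcc(ci_level=ci_level).fit(ratings).result_
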