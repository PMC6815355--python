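"""Model-based causal mediation with nonparametric bootstrap.

Decomposes the treatment effect on a change-score outcome (KOOS pain change)
into the part transmitted through a mediator (a muscle-perfusion change
score) and the direct remainder, under two linear structural models fitted by
ordinary least squares:

    mediator model:  dM = alpha0 + a * T + covariates
    outcome model:   dY = beta0 + c' * T + b * dM + covariates

With no treatment x mediator interaction the average causal mediation effect
(ACME) is the product ``a * b``, the average direct effect (ADE) is ``c'``,
and the total effect is exactly ``ACME + ADE`` (the product-of-coefficients
and difference-of-coefficients decompositions coincide). Uncertainty comes
from a seeded nonparametric bootstrap that case-resamples participants,
refits both models, and takes percentile intervals; bootstrap p-values are
``2 * min(Pr*(stat <= 0), Pr*(stat >= 0))``.

Both models adjust for the same covariates as the primary trial analysis
(baseline outcome value and gender) by default; the mediator model's
covariate set can be overridden (e.g. to use the mediator's own baseline).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .trialstats import _encode_gender

logger = logging.getLogger(__name__)

__all__ = ["MediationResult", "CausalMediation", "fit_mediation", "mediate_all"]

_TOTAL_EPS = 1e-8


@dataclass
class MediationResult:
    """Mediation estimands with bootstrap percentile CIs and p-values."""

    outcome: str
    mediator: str
    acme: float
    ade: float
    total_effect: float
    proportion_mediated: float
    ci95: dict[str, tuple[float, float]]
    p_value: dict[str, float]
    n_used: int
    n_boot_effective: int
    n_redrawn: int
    n_prop_dropped: int


def _design(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(float) for c in columns])
    return X


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design in mediation model")
    return beta


class CausalMediation(BaseEstimator):
    """Fit the two structural models and bootstrap the mediation estimands.

    Parameters
    ----------
    outcome, mediator
        Change-score column names present in the fitted table (the mediator
        must differ from the outcome).
    covariates
        Covariate columns of the outcome model (default: baseline outcome
        and gender, as in the primary analysis).
    mediator_covariates
        Covariates of the mediator model; ``None`` reuses ``covariates``.
    n_boot, ci_level, random_state
        Bootstrap settings. Resamples that lose an arm or leave the mediator
        constant are redrawn (counted in ``n_redrawn_``); resamples with
        ``|total| < 1e-8`` are dropped from the proportion-mediated ratio
        distribution (counted in ``n_prop_dropped_``).

    Fitted attributes: ``acme_``, ``ade_``, ``total_effect_``,
    ``proportion_mediated_``, ``ci95_`` (dict per quantity), ``p_value_``,
    ``n_boot_effective_``.
    """

    def __init__(
        self,
        outcome: str = "koos_pain_change",
        mediator: str = "perfusion_index_change",
        covariates: tuple[str, ...] = ("koos_pain_baseline", "female"),
        mediator_covariates: tuple[str, ...] | None = None,
        n_boot: int = 1000,
        ci_level: float = 0.95,
        random_state: int | None = 0,
    ):
        self.outcome = outcome
        self.mediator = mediator
        self.covariates = tuple(covariates)
        self.mediator_covariates = (
            None if mediator_covariates is None else tuple(mediator_covariates)
        )
        self.n_boot = n_boot
        self.ci_level = ci_level
        self.random_state = random_state

    # ---- internals ----------------------------------------------------

    def _prepare(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.mediator == self.outcome:
            raise ValueError("mediator must differ from outcome")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        df = table.copy()
        if "female" not in df.columns and "gender" in df.columns:
            df["female"] = _encode_gender(df["gender"])
        df["treat"] = (df["arm"] == "ET").astype(float)
        med_covs = self.covariates if self.mediator_covariates is None else self.mediator_covariates
        cols = ["treat", self.outcome, self.mediator, *self.covariates, *med_covs]
        missing = [c for c in dict.fromkeys(cols) if c not in df.columns]
        if missing:
            raise KeyError(f"columns absent from table: {missing}")
        df = df.dropna(subset=list(dict.fromkeys(cols)))
        if df["treat"].nunique() < 2:
            raise ValueError("both arms must be present")
        if np.ptp(df[self.mediator].to_numpy(float)) == 0:
            raise ValueError(f"mediator {self.mediator!r} is constant")
        return df

    @staticmethod
    def _point(Xm, m, Xy, y) -> tuple[float, float, float]:
        """(a, b, c') from the two OLS fits; T is column 1, M the last Xy column-but-covariates."""
        bm = _ols(Xm, m)
        by = _ols(Xy, y)
        a = float(bm[1])
        c_prime = float(by[1])
        b = float(by[2])
        return a, b, c_prime

    def fit(self, table: pd.DataFrame, y=None):
        df = self._prepare(table)
        med_covs = list(
            self.covariates if self.mediator_covariates is None else self.mediator_covariates
        )
        out_covs = list(self.covariates)
        m = df[self.mediator].to_numpy(float)
        yv = df[self.outcome].to_numpy(float)
        treat = df["treat"].to_numpy(float)
        Cm = np.column_stack([df[c].to_numpy(float) for c in med_covs]) if med_covs else np.empty((len(df), 0))
        Cy = np.column_stack([df[c].to_numpy(float) for c in out_covs]) if out_covs else np.empty((len(df), 0))
        ones = np.ones(len(df))
        Xm = np.column_stack([ones, treat, Cm])
        Xy = np.column_stack([ones, treat, m, Cy])

        a, b, c_prime = self._point(Xm, m, Xy, yv)
        self.acme_ = a * b
        self.ade_ = c_prime
        self.total_effect_ = self.acme_ + self.ade_
        if abs(self.total_effect_) < 1e-12:
            warnings.warn(
                "total effect is numerically zero; proportion mediated undefined",
                stacklevel=2,
            )
            self.proportion_mediated_ = np.nan
        else:
            self.proportion_mediated_ = self.acme_ / self.total_effect_

        rng = np.random.default_rng(self.random_state)
        n = len(df)
        boots = {"acme": [], "ade": [], "total": [], "prop": []}
        n_redrawn = 0
        n_prop_dropped = 0
        draws = 0
        max_draws = 50 * self.n_boot
        while len(boots["acme"]) < self.n_boot and draws < max_draws:
            draws += 1
            idx = rng.integers(0, n, n)
            t_b = treat[idx]
            m_b = m[idx]
            if t_b.min() == t_b.max() or np.ptp(m_b) == 0:
                n_redrawn += 1
                continue
            Xm_b = np.column_stack([ones, t_b, Cm[idx]])
            Xy_b = np.column_stack([ones, t_b, m_b, Cy[idx]])
            try:
                a_b, b_b, c_b = self._point(Xm_b, m_b, Xy_b, yv[idx])
            except (ValueError, np.linalg.LinAlgError):
                n_redrawn += 1
                continue
            acme = a_b * b_b
            total = acme + c_b
            boots["acme"].append(acme)
            boots["ade"].append(c_b)
            boots["total"].append(total)
            if abs(total) < _TOTAL_EPS:
                n_prop_dropped += 1
            else:
                boots["prop"].append(acme / total)
        if len(boots["acme"]) < self.n_boot:
            raise RuntimeError("bootstrap failed: too many degenerate resamples")

        lo = 100 * (1.0 - self.ci_level) / 2.0
        hi = 100 - lo
        self.ci95_ = {}
        self.p_value_ = {}
        for key in ("acme", "ade", "total", "prop"):
            samples = np.asarray(boots[key])
            if samples.size == 0:
                self.ci95_[key] = (np.nan, np.nan)
                self.p_value_[key] = np.nan
                continue
            self.ci95_[key] = (
                float(np.percentile(samples, lo)),
                float(np.percentile(samples, hi)),
            )
            p = 2.0 * min(float(np.mean(samples <= 0)), float(np.mean(samples >= 0)))
            self.p_value_[key] = min(p, 1.0)
        self.n_used_ = n
        self.n_boot_effective_ = len(boots["acme"])
        self.n_redrawn_ = n_redrawn
        self.n_prop_dropped_ = n_prop_dropped
        return self

    @property
    def result_(self) -> MediationResult:
        return MediationResult(
            outcome=self.outcome,
            mediator=self.mediator,
            acme=self.acme_,
            ade=self.ade_,
            total_effect=self.total_effect_,
            proportion_mediated=self.proportion_mediated_,
            ci95=self.ci95_,
            p_value=self.p_value_,
            n_used=self.n_used_,
            n_boot_effective=self.n_boot_effective_,
            n_redrawn=self.n_redrawn_,
            n_prop_dropped=self.n_prop_dropped_,
        )


def fit_mediation(
    table: pd.DataFrame,
    outcome: str,
    mediator: str,
    covariates: tuple[str, ...] = ("koos_pain_baseline", "female"),
    mediator_covariates: tuple[str, ...] | None = None,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    random_state: int | None = 0,
) -> MediationResult:
    """Functional wrapper around :class:`CausalMediation`."""
    est = CausalMediation(
        outcome=outcome,
        mediator=mediator,
        covariates=covariates,
        mediator_covariates=mediator_covariates,
        n_boot=n_boot,
        ci_level=ci_level,
        random_state=random_state,
    )
    return est.fit(table).result_


def mediate_all(
    table: pd.DataFrame,
    mediators: list[str],
    outcome: str,
    covariates: tuple[str, ...] = ("koos_pain_baseline", "female"),
    n_boot: int = 1000,
    ci_level: float = 0.95,
    random_state: int = 0,
) -> pd.DataFrame:
    """One bootstrap mediation fit per mediator; errors are isolated per row.

    Each mediator is analysed with seed ``random_state + index of its first
    occurrence`` so any row can be reproduced in isolation and a duplicated
    mediator yields identical rows. Returns a tidy frame with one row per
    mediator (ACME, CI, p, proportion mediated, CI, total effect, error).
    """
    rows = []
    for mediator in mediators:
        row: dict = {"mediator": mediator}
        try:
            r = fit_mediation(
                table,
                outcome=outcome,
                mediator=mediator,
                covariates=covariates,
                n_boot=n_boot,
                ci_level=ci_level,
                random_state=random_state + mediators.index(mediator),
            )
            row.update(
                acme=r.acme,
                acme_ci_low=r.ci95["acme"][0],
                acme_ci_high=r.ci95["acme"][1],
                acme_p=r.p_value["acme"],
                ade=r.ade,
                total_effect=r.total_effect,
                proportion_mediated=r.proportion_mediated,
                prop_ci_low=r.ci95["prop"][0],
                prop_ci_high=r.ci95["prop"][1],
                error="",
            )
        except Exception as exc:  # noqa: BLE001 - per-mediator isolation is the contract
            logger.warning("mediator %s failed: %s", mediator, exc)
            row.update(
                acme=np.nan, acme_ci_low=np.nan, acme_ci_high=np.nan, acme_p=np.nan,
                ade=np.nan, total_effect=np.nan, proportion_mediated=np.nan,
                prop_ci_low=np.nan, prop_ci_high=np.nan, error=str(exc),
            )
        rows.append(row)
    return pd.DataFrame(rows)
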