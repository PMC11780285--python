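"""Monotone sequential-regression multiple imputation and Rubin pooling.

Missing post-baseline weight losses are imputed one time point at a time,
in chronological order.  At each point a normal linear regression of that
point's loss on the demographic covariates plus all earlier-point losses
is fit to the rows observed there; the residual variance is drawn from
its scaled inverse chi-square distribution, the coefficients from their
estimated multivariate-normal sampling distribution, and each missing
value is filled with a predictive draw.  Later points condition on the
filled earlier values, so the scheme degenerates to textbook monotone MI
when the missingness pattern is monotone, while non-monotone rows keep
every observed value untouched.

Estimates from the ``m`` completed datasets are pooled with Rubin's
rules: pooled point estimate = mean of the per-dataset estimates; total
variance ``T = W + (1 + 1/m) B`` where ``W`` is the mean within-dataset
variance and ``B`` the between-dataset variance of the estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._grid import POST_BASELINE
from .cohort import Cohort

__all__ = ["ImputationSpec", "PooledEstimate", "EstimationError",
           "impute", "pool_mean", "pool_proportion", "estimate_all"]

DEFAULT_COVARIATES = ("age_group", "sex", "state", "start_weight_kg",
                      "start_bmi", "seifa_quintile")
_CATEGORICAL = {"age_group", "sex", "state", "seifa_quintile"}


class EstimationError(RuntimeError):
    """An imputation regression could not be estimated."""


@dataclass(frozen=True)
class ImputationSpec:
    """Configuration of the monotone imputation model."""

    m: int = 20
    seed: int = 0
    response_order: tuple[str, ...] = POST_BASELINE
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    #: pool proportions on the logit scale instead of the proportion scale
    logit_proportions: bool = False

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("at least 2 imputations are required")
        order = [POST_BASELINE.index(t) for t in self.response_order]
        if order != sorted(order) or len(set(order)) != len(order):
            raise ValueError("response_order must be strictly chronological")


@dataclass(frozen=True)
class PooledEstimate:
    """A Rubin's-rules pooled estimand."""

    label: str
    q_bar: float
    W: float
    B: float
    m: int
    T: float = field(init=False)
    se: float = field(init=False)

    def __post_init__(self):
        if self.W < 0 or self.B < 0:
            raise ValueError("variance components must be nonnegative")
        object.__setattr__(self, "T", self.W + (1.0 + 1.0 / self.m) * self.B)
        object.__setattr__(self, "se", float(np.sqrt(self.T)))


def _design(members: pd.DataFrame, covariates) -> np.ndarray:
    """Reference-coded design matrix (with intercept) for the covariates."""
    members = members.reset_index(drop=True)
    cols = [pd.Series(np.ones(len(members)), name="intercept")]
    for cov in covariates:
        s = members[cov]
        if cov in _CATEGORICAL:
            dummies = pd.get_dummies(s.astype(str), prefix=cov, drop_first=True)
            if dummies.shape[1] == 0:
                warnings.warn(f"covariate {cov!r} has a single level; dropped",
                              stacklevel=3)
                continue
            cols.append(dummies.astype(float))
        else:
            cols.append(s.astype(float))
    X = pd.concat(cols, axis=1).to_numpy(float)
    return X


def impute(cohort: Cohort, spec: ImputationSpec) -> list[pd.DataFrame]:
    """Produce ``m`` completed wide weights tables.

    Requires complete baseline weights and covariates.  Deterministic
    given ``spec.seed``; a cohort with no missing values returns ``m``
    copies identical to the input.
    """
    w = cohort.weights
    members = cohort.members.set_index("member_id").reindex(w.index)
    if w["baseline"].isna().any():
        raise EstimationError("imputation requires complete baseline weights")
    baseline = w["baseline"].to_numpy(float)
    loss_obs = {tp: baseline - w[tp].to_numpy(float) for tp in spec.response_order}
    miss = {tp: np.isnan(loss_obs[tp]) for tp in spec.response_order}
    X_cov = _design(members, spec.covariates)

    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(spec.seed).spawn(spec.m)]
    completed = []
    for rng in rngs:
        loss = {tp: loss_obs[tp].copy() for tp in spec.response_order}
        earlier: list[str] = []
        for tp in spec.response_order:
            mis = miss[tp]
            if mis.any():
                X = (np.column_stack([X_cov] + [loss[e] for e in earlier])
                     if earlier else X_cov)
                obs = ~miss[tp]
                n_obs, p = int(obs.sum()), X.shape[1]
                if n_obs <= p:
                    raise EstimationError(
                        f"time point {tp!r}: {n_obs} observed rows for {p} predictors")
                Xo, yo = X[obs], loss_obs[tp][obs]
                beta_hat, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
                resid = yo - Xo @ beta_hat
                sse = float(resid @ resid)
                df = n_obs - p
                sigma2 = sse / rng.chisquare(df)
                xtx_inv = np.linalg.pinv(Xo.T @ Xo)
                cov = 0.5 * (xtx_inv + xtx_inv.T) * sigma2
                beta = rng.multivariate_normal(beta_hat, cov, method="svd")
                loss[tp][mis] = (X[mis] @ beta
                                 + rng.normal(0.0, np.sqrt(sigma2), size=int(mis.sum())))
            earlier.append(tp)
        filled = w.copy()
        for tp in spec.response_order:
            # only overwrite cells that were actually missing
            filled[tp] = np.where(miss[tp], baseline - loss[tp],
                                  filled[tp].to_numpy(float))
        completed.append(filled)
    return completed


def pool_mean(estimates) -> PooledEstimate:
    """Pool per-dataset (estimate, se) pairs with Rubin's rules."""
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValueError("pooling requires at least 2 completed datasets")
    q = np.array([e[0] for e in estimates], dtype=float)
    se = np.array([e[1] for e in estimates], dtype=float)
    m = len(q)
    # identical estimates have exactly zero between-imputation variance
    B = 0.0 if np.ptp(q) == 0.0 else float(np.var(q, ddof=1))
    return PooledEstimate(label="mean", q_bar=float(q.mean()),
                          W=float(np.mean(se ** 2)), B=B, m=m)


def pool_proportion(estimates, logit: bool = False) -> PooledEstimate:
    """Pool per-dataset (p, n) pairs; per-dataset se is binomial.

    With ``logit=True`` pooling happens on the logit scale and the result
    is transformed back (delta-method se); the default pools proportions
    directly.
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        raise ValueError("pooling requires at least 2 completed datasets")
    p = np.array([e[0] for e in estimates], dtype=float)
    n = np.array([e[1] for e in estimates], dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    se = np.sqrt(p * (1.0 - p) / n)
    if not logit:
        est = pool_mean(zip(p, se))
        return PooledEstimate(label="proportion", q_bar=est.q_bar,
                              W=est.W, B=est.B, m=est.m)
    eps = 0.5 / n  # continuity guard for degenerate datasets
    p_adj = np.clip(p, eps, 1.0 - eps)
    eta = np.log(p_adj / (1.0 - p_adj))
    se_eta = se / (p_adj * (1.0 - p_adj))
    pooled = pool_mean(zip(eta, se_eta))
    back = 1.0 / (1.0 + np.exp(-pooled.q_bar))
    deriv = back * (1.0 - back)
    return PooledEstimate(label="proportion", q_bar=float(back),
                          W=float(pooled.W * deriv ** 2),
                          B=float(pooled.B * deriv ** 2), m=pooled.m)


def _dataset_stats(weights: pd.DataFrame, members: pd.DataFrame, tp: str):
    """Per-dataset (mean kg, se), (mean pct, se), (p>=5, n), (p>=10, n)."""
    loss = (weights["baseline"] - weights[tp]).to_numpy(float)
    pct = 100.0 * loss / weights["baseline"].to_numpy(float)
    n = len(loss)
    mk = (loss.mean(), loss.std(ddof=1) / np.sqrt(n))
    mp = (pct.mean(), pct.std(ddof=1) / np.sqrt(n))
    p5 = (float(np.mean(pct >= 5.0)), n)
    p10 = (float(np.mean(pct >= 10.0)), n)
    return mk, mp, p5, p10


def estimate_all(cohort: Cohort, spec: ImputationSpec,
                 completed: list[pd.DataFrame] | None = None) -> pd.DataFrame:
    """Pooled outcome table over time points, estimands and sex strata.

    Rows: 4 time points x 4 estimands (mean loss kg, mean loss %,
    proportion >=5% TBW, proportion >=10% TBW) x strata (each observed sex
    plus 'total').  An absent sex stratum is omitted with a warning.
    """
    if completed is None:
        completed = impute(cohort, spec)
    members = cohort.members.set_index("member_id").reindex(cohort.weights.index)
    strata: dict[str, np.ndarray] = {"total": np.ones(len(members), dtype=bool)}
    for sex in ("female", "male"):
        mask = (members["sex"] == sex).to_numpy()
        if mask.any():
            strata[sex] = mask
        else:
            warnings.warn(f"sex stratum {sex!r} is empty; omitted", stacklevel=2)

    rows = []
    for stratum, mask in strata.items():
        for tp in spec.response_order:
            per = [_dataset_stats(d.loc[mask], members.loc[mask], tp)
                   for d in completed]
            pooled = {
                "mean_loss_kg": pool_mean(s[0] for s in per),
                "mean_loss_pct": pool_mean(s[1] for s in per),
                "prop_ge5": pool_proportion((s[2] for s in per),
                                            logit=spec.logit_proportions),
                "prop_ge10": pool_proportion((s[3] for s in per),
                                             logit=spec.logit_proportions),
            }
            for estimand, est in pooled.items():
                rows.append({"estimand": estimand, "stratum": stratum,
                             "time_point": tp, "n": int(mask.sum()),
                             "q_bar": est.q_bar, "W": est.W, "B": est.B,
                             "T": est.T, "se": est.se, "m": est.m})
    return pd.DataFrame(rows)
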