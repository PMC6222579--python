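"""Cox proportional-hazards screening of clinical covariates.

Maximizes the Breslow-ties partial likelihood by Newton-Raphson and reports
hazard ratios, Wald confidence intervals and p-values - the machinery used
to pick the fixed-effect baseline (in the motivating cohort: age at
diagnosis and temozolomide). Kaplan-Meier curves go through lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import Cohort, design_matrix

__all__ = ["CoxPH", "CoxFit", "fit_cox", "screen_covariates", "kaplan_meier",
           "breslow_partial_loglik", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    pass


def _risk_set_sums(times, Xb_exp, X):
    """Breslow building blocks S0/S1/S2 over risk sets {j: t_j >= t_i}.

    Rows must be sorted by descending time; returns cumulative sums so that
    index i holds the sum over all rows with time >= times[i] (ties share
    the same value).
    """
    n, q = X.shape
    s0 = np.cumsum(Xb_exp)
    s1 = np.cumsum(X * Xb_exp[:, None], axis=0)
    s2 = np.cumsum(X[:, :, None] * X[:, None, :] * Xb_exp[:, None, None], axis=0)
    # ties: every row of a tied time block must see the block's last cumsum
    # (nearest block end at or after each row)
    last_of_block = np.r_[times[1:] != times[:-1], True]
    idx = np.minimum.accumulate(np.where(last_of_block, np.arange(n), n)[::-1])[::-1]
    return s0[idx], s1[idx], s2[idx]


def breslow_partial_loglik(beta, times, events, X):
    """Breslow-ties partial log likelihood (direct evaluation; also the
    grid-search oracle target)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    order = np.argsort(-np.asarray(times, dtype=float), kind="stable")
    t, d, Xs = np.asarray(times, float)[order], np.asarray(events, float)[order], \
        np.asarray(X, float)[order]
    xb = Xs @ beta
    s0 = np.cumsum(np.exp(xb))
    n = len(t)
    last_of_block = np.r_[t[1:] != t[:-1], True]
    idx = np.minimum.accumulate(np.where(last_of_block, np.arange(n), n)[::-1])[::-1]
    ev = d == 1
    return float(np.sum(xb[ev] - np.log(s0[idx][ev])))


class CoxPH(BaseEstimator):
    """Cox proportional hazards with Breslow ties, Newton-Raphson fitting.

    ``fit(X, y)`` takes a numeric design matrix and ``y`` of shape (n, 2)
    with columns ``[time, censor]`` (censor = 1 means right censored, so the
    event indicator is ``1 - censor``). Convergence: sup-norm of the score
    below ``tol`` within ``max_iter`` iterations.
    """

    def __init__(self, max_iter: int = 50, tol: float = 1e-8, alpha: float = 0.05):
        self.max_iter = max_iter
        self.tol = tol
        self.alpha = alpha

    def fit(self, X, y, feature_names=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        times, censor = y[:, 0], y[:, 1]
        events = 1.0 - censor
        n, q = X.shape
        if events.sum() < 2:
            raise ValueError("need at least 2 observed events")
        Xc = X - X.mean(axis=0)
        if np.linalg.matrix_rank(Xc) < q:
            raise np.linalg.LinAlgError("collinear (rank-deficient) covariate design")
        names = list(feature_names) if feature_names is not None else [f"x{j}" for j in range(q)]

        order = np.argsort(-times, kind="stable")
        t, Xs, ev = times[order], Xc[order], (events[order] == 1)

        beta = np.zeros(q)
        ll = breslow_partial_loglik(beta, times, events, Xc)
        for _ in range(self.max_iter):
            xb = Xs @ beta
            w = np.exp(xb)
            s0, s1, s2 = _risk_set_sums(t, w, Xs)
            mu = s1 / s0[:, None]
            score = (Xs[ev] - mu[ev]).sum(axis=0)
            info = (s2[ev] / s0[ev, None, None]
                    - mu[ev, :, None] * mu[ev, None, :]).sum(axis=0)
            if np.max(np.abs(score)) < self.tol:
                break
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            # step-halving to keep the likelihood ascending (tolerance relative
            # to the loglik magnitude, or float noise stalls the iteration)
            new_beta, new_ll = beta + step, None
            for _ in range(30):
                new_ll = breslow_partial_loglik(new_beta, times, events, Xc)
                if new_ll >= ll - 1e-10 * (1.0 + abs(ll)):
                    break
                new_beta = (beta + new_beta) / 2.0
            beta, ll = new_beta, new_ll
            # |beta| * sd(x) > 5 means a hazard ratio above e^5 per SD of the
            # covariate: the likelihood is effectively monotone (separation)
            scale = np.abs(beta) * (Xc.std(axis=0) + 1e-12)
            if np.max(scale) > 5:
                j = int(np.argmax(scale))
                raise ConvergenceError(
                    f"monotone likelihood (separation) for covariate {names[j]!r}")

        xb = Xs @ beta
        s0, s1, s2 = _risk_set_sums(t, np.exp(xb), Xs)
        mu = s1 / s0[:, None]
        info = (s2[ev] / s0[ev, None, None] - mu[ev, :, None] * mu[ev, None, :]).sum(axis=0)
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        z = beta / se
        zcrit = stats.norm.ppf(1 - self.alpha / 2)
        self.coef_ = beta
        self.se_ = se
        self.hazard_ratios_ = np.exp(beta)
        self.wald_z_ = z
        self.p_values_ = 2 * stats.norm.sf(np.abs(z))
        self.ci_95_ = np.exp(np.column_stack([beta - zcrit * se, beta + zcrit * se]))
        self.loglik_ = ll
        self.n_ = n
        self.n_events_ = int(events.sum())
        self.feature_names_ = names
        return self


@dataclass
class CoxFit:
    """Per-covariate hazard-ratio table from a joint Cox fit."""

    table: pd.DataFrame        # index: encoded covariate; HR, CI, z, p
    loglik: float
    n: int
    n_events: int
    origin: dict               # encoded column -> original covariate name

    @property
    def coefficients(self) -> pd.Series:
        return self.table["coef"]


def fit_cox(cohort: Cohort, covariate_names) -> CoxFit:
    """Joint Cox regression of survival on the named covariates."""
    if not cohort.has_outcomes():
        raise ValueError("cohort has no outcomes")
    X, colnames, origin = design_matrix(cohort, covariate_names)
    y = np.column_stack([cohort.time, cohort.censor])
    est = CoxPH().fit(X, y, feature_names=colnames)
    table = pd.DataFrame({
        "coef": est.coef_,
        "hazard_ratio": est.hazard_ratios_,
        "se": est.se_,
        "wald_z": est.wald_z_,
        "p_value": est.p_values_,
        "ci_low": est.ci_95_[:, 0],
        "ci_high": est.ci_95_[:, 1],
    }, index=colnames)
    return CoxFit(table=table, loglik=est.loglik_, n=est.n_, n_events=est.n_events_,
                  origin=dict(zip(colnames, origin)))


def screen_covariates(cohort: Cohort, candidate_names, alpha: float = 0.05,
                      joint: bool = True) -> list[str]:
    """Covariates with Wald p < alpha; joint model by default, with a
    per-covariate univariate option."""
    selected: list[str] = []
    if joint:
        fitres = fit_cox(cohort, candidate_names)
        for name in candidate_names:
            cols = [c for c, o in fitres.origin.items() if o == name]
            if any(fitres.table.loc[c, "p_value"] < alpha for c in cols):
                selected.append(name)
    else:
        for name in candidate_names:
            fitres = fit_cox(cohort, [name])
            if (fitres.table["p_value"] < alpha).any():
                selected.append(name)
    return selected


def kaplan_meier(cohort: Cohort, group_by: str | None = None,
                 groups=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves, one per level of ``group_by``.

    Returns ``{group_label: DataFrame(time, survival)}``; the pooled curve
    when ``group_by`` is None. Each curve starts at S(0) = 1 and is
    nonincreasing.
    """
    from lifelines import KaplanMeierFitter

    if not cohort.has_outcomes():
        raise ValueError("cohort has no outcomes")
    if group_by is None:
        members = {"all": np.ones(cohort.n, dtype=bool)}
    else:
        col = cohort.data[group_by]
        levels = groups if groups is not None else sorted(pd.unique(col.dropna()))
        members = {}
        for g in levels:
            m = np.asarray(col == g)
            if not m.any():
                raise ValueError(f"unknown or empty group label {g!r} in {group_by!r}")
            members[str(g)] = m
    out = {}
    for label, m in members.items():
        kmf = KaplanMeierFitter()
        kmf.fit(cohort.time[m], event_observed=cohort.event[m])
        sf = kmf.survival_function_
        out[label] = pd.DataFrame({
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        })
    return out
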