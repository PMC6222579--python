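"""Bayesian censored log-normal regression with multiple kernel random effects.

The model for patient i with log survival time y_i is

    y_i = mu + sum_j x_ij alpha_j + sum_k u_ki + eps_i,   eps_i ~ N(0, sigma2_e)

with flat priors on the fixed effects alpha, u_k ~ N(0, K_k sigma2_k) for
each omic kernel K_k, and independent scaled-inverse-chi-square priors on
every variance. Right-censored rows contribute the survival probability
1 - Phi((log t_i - eta_i)/sigma_e) to the likelihood; the sampler handles
them by data augmentation, drawing the latent log time from a truncated
normal each sweep. Working in each kernel's eigenbasis (u_k = Gamma_k
delta_k, delta_kj ~ N(0, lambda_kj sigma2_k)) makes every full conditional
scalar or low-dimensional, so a sweep costs O(n * rank) per kernel.

Prediction for held-out subjects uses the "set the outcome to missing"
idiom: test subjects are included in the kernels with their outcome masked
(latent drawn unconstrained), and the prediction is the posterior mean of
their linear predictor. The algebraically equivalent cross-kernel
projection is available as :meth:`BayesKernelSurvival.predict_out_of_sample`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import log_ndtr, ndtri_exp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_random_state

from .containers import Cohort, KernelMatrix, design_matrix

__all__ = [
    "BayesKernelSurvival", "PosteriorChains", "PosteriorSummary",
    "sample_truncated_normal", "fit", "summarize", "dic", "predict", "deviance",
]


# ---------------------------------------------------------------------------
# truncated normal sampling
# ---------------------------------------------------------------------------

_TAIL_SWITCH = 8.0  # standardized lower bound beyond which rejection sampling takes over


def _rejection_tail(a: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Exponential-proposal rejection sampler for z ~ N(0,1) | z > a, a large."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    todo = np.ones(a.shape, dtype=bool)
    alpha = (a + np.sqrt(a * a + 4.0)) / 2.0
    while todo.any():
        m = int(todo.sum())
        z = a[todo] + rng.exponential(1.0, size=m) / alpha[todo]
        accept = rng.random(m) <= np.exp(-0.5 * (z - alpha[todo]) ** 2)
        idx = np.flatnonzero(todo)
        hit = idx[accept]
        out[hit] = z[accept]
        todo[hit] = False
    return out


def sample_truncated_normal(mean, sd, lower, rng=None, size=None) -> np.ndarray | float:
    """Draw from N(mean, sd^2) conditioned on exceeding ``lower``.

    Uses the inverse-CDF in log-space (``ndtri_exp``/``log_ndtr``), which is
    stable for standardized bounds well beyond +/-8; for extreme lower tails
    an exponential-proposal rejection sampler takes over. ``lower`` may be
    ``-inf`` (plain normal). Inputs broadcast; scalar inputs give a scalar.
    """
    rng = np.random.default_rng() if rng is None else rng
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd <= 0):
        raise ValueError("sd must be positive")
    lower = np.asarray(lower, dtype=float)
    shape = np.broadcast_shapes(mean.shape, sd.shape, lower.shape) if size is None else (size,)
    mean, sd, lower = (np.broadcast_to(x, shape) for x in (mean, sd, lower))
    a = (lower - mean) / sd
    u = rng.random(shape)
    with np.errstate(divide="ignore"):
        # upper-tail mass beyond a is exp(log_ndtr(-a)); thin it by u
        log_tail = np.log(u) + log_ndtr(-a)
    z = -ndtri_exp(log_tail)
    far = a > _TAIL_SWITCH
    if far.any():
        z = np.where(far, np.nan, z)
        z[far] = _rejection_tail(a[far], rng)
    out = mean + sd * z
    return float(out) if out.shape == () else out


# ---------------------------------------------------------------------------
# chains / summaries
# ---------------------------------------------------------------------------

@dataclass
class PosteriorChains:
    """Thinned post-burn-in draws plus everything needed to evaluate them."""

    alpha: np.ndarray            # (S, q) fixed effects, first column = intercept
    sigma2: dict                 # kernel name -> (S,) variance draws
    sigma2_e: np.ndarray         # (S,)
    u: dict                      # kernel name -> (S, n) random-effect draws
    eta: np.ndarray              # (S, n) linear predictor
    ylat: np.ndarray             # (S, n) latent/observed log outcomes
    sample_ids: list
    log_time: np.ndarray         # (n,) log follow-up (NaN where masked)
    censor: np.ndarray           # (n,) 1 = censored
    mask: np.ndarray             # (n,) True = outcome hidden at fit time
    fixed_names: list = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return self.eta.shape[0]

    @property
    def n(self) -> int:
        return self.eta.shape[1]

    def posterior_mean_eta(self) -> np.ndarray:
        return self.eta.mean(axis=0)


@dataclass
class PosteriorSummary:
    variance_table: pd.DataFrame   # rows: kernels + residual; mean/sd/mc_error/proportion/flag
    fixed_effects: pd.DataFrame    # per fixed effect: mean, sd
    dic: float | None = None

    @property
    def converged(self) -> bool:
        """True when every variance parameter's MC error is below 1% of its mean."""
        return bool((~self.variance_table["mc_error_flag"]).all())


def batch_means_mcse(x: np.ndarray, n_batches: int = 20) -> float:
    """Monte-Carlo standard error of the chain mean by non-overlapping batch means."""
    x = np.asarray(x, dtype=float)
    S = len(x)
    if S < 2 * n_batches:
        n_batches = max(2, S // 2)
    b = S // n_batches
    bm = x[: b * n_batches].reshape(n_batches, b).mean(axis=1)
    return float(bm.std(ddof=1) / math.sqrt(n_batches))


def _scaled_inv_chi2(rng, df: float, scale: float) -> float:
    """Draw sigma2 ~ scaled-inv-chi2(df, S): sigma2 = S / chi2_df (mean S/(df-2))."""
    return scale / rng.chisquare(df)


# ---------------------------------------------------------------------------
# the estimator
# ---------------------------------------------------------------------------

class BayesKernelSurvival(BaseEstimator):
    """Gibbs sampler for the censored log-normal multi-kernel regression.

    Parameters
    ----------
    n_iter, burn_in, thin : int
        MCMC settings. Defaults (30000/5000/5) are conservative; recovery
        simulations in the test suite run shorter chains.
    prior_df : float
        Degrees of freedom of every scaled-inverse-chi-square variance prior.
    prior_scales : dict or None
        Optional explicit scales keyed by kernel name and ``"residual"``.
        When absent, scales are set so each prior mode equals an equal share
        of half the sample variance of the observed log times (kernels) and
        half for the residual - a weakly informative default.
    fixed_variances : dict or None
        Map of kernel name (or ``"residual"``) to a fixed value; those
        variance updates are skipped. Intended for oracle checks.
    random_state : int, Generator or None
        Seed for the sampler.
    """

    def __init__(self, n_iter: int = 30000, burn_in: int = 5000, thin: int = 5,
                 prior_df: float = 5.0, prior_scales: dict | None = None,
                 fixed_variances: dict | None = None, random_state=None):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thin = thin
        self.prior_df = prior_df
        self.prior_scales = prior_scales
        self.fixed_variances = fixed_variances
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _validate_y(y):
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be (n, 2): columns [time_months, censor_flag]")
        times, censor = y[:, 0], y[:, 1]
        if not set(np.unique(censor[np.isfinite(censor)])) <= {0.0, 1.0}:
            raise ValueError("censor flag must be 0 or 1")
        return times, censor

    def _prepare_kernels(self, kernels, n):
        prepared = {}
        for name, k in (kernels or {}).items():
            if not isinstance(k, KernelMatrix):
                k = KernelMatrix.from_matrix(np.asarray(k, dtype=float), list(range(n)))
            if k.n != n:
                raise ValueError(f"kernel {name!r} has {k.n} samples, expected {n}")
            if k.rank == 0:
                raise ValueError(f"kernel {name!r} has zero retained rank")
            prepared[name] = k
        return prepared

    # -- API ---------------------------------------------------------------
    def fit(self, X, y, kernels: dict | None = None, mask=None):
        """Run the Gibbs sampler.

        ``X`` is the (n, q) fixed-effect design without intercept (``None``
        for intercept-only), ``y`` is (n, 2) ``[time_months, censor]``,
        ``kernels`` maps names to :class:`KernelMatrix` (or raw PSD arrays)
        over the same n samples, and ``mask`` marks rows whose outcome is
        hidden (their time may be NaN; predictions are read off them).
        """
        times, censor = self._validate_y(y)
        n = len(times)
        mask = np.zeros(n, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        with np.errstate(invalid="ignore", divide="ignore"):
            logt = np.where(mask, np.nan, np.log(times))
        if np.any(~mask & ~np.isfinite(logt)):
            raise ValueError("non-finite follow-up time in unmasked rows")
        censor = np.where(mask, 0.0, censor)
        if not np.any(~mask & (censor == 0)):
            raise ValueError("at least one uncensored observation is required")

        if X is None:
            Xf = np.ones((n, 1))
            self.fixed_names_ = ["intercept"]
        else:
            X = np.asarray(X, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            Xf = np.hstack([np.ones((n, 1)), X])
            self.fixed_names_ = ["intercept"] + [f"x{j}" for j in range(X.shape[1])]
        if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")

        kernels = self._prepare_kernels(kernels, n)
        rng = self._rng()
        chains = self._gibbs(Xf, logt, censor.astype(bool), mask, kernels, rng)
        self.chains_ = chains
        self.kernels_ = kernels
        self.n_features_in_ = Xf.shape[1] - 1
        return self

    def _rng(self) -> np.random.Generator:
        rs = self.random_state
        if isinstance(rs, np.random.Generator):
            return rs
        if rs is None:
            return np.random.default_rng()
        return np.random.default_rng(check_random_state(rs).randint(2**31))

    def _prior(self, name: str, var_y: float, n_kernels: int) -> tuple[float, float]:
        """(scale S, df) for one variance parameter.

        Default: prior mode S/(df+2) equals an equal split of half of
        var(log t) across kernels, and half for the residual.
        """
        df = float(self.prior_df)
        if self.prior_scales and name in self.prior_scales:
            return float(self.prior_scales[name]), df
        share = 0.5 * var_y if name == "residual" else 0.5 * var_y / max(n_kernels, 1)
        return max(share, 1e-6) * (df + 2.0), df

    # -- the sampler -------------------------------------------------------
    def _gibbs(self, X, logt, censored, mask, kernels, rng) -> PosteriorChains:
        n, q = X.shape
        names = list(kernels)
        Gam = {k: kernels[k].eigenvectors for k in names}
        lam = {k: kernels[k].eigenvalues for k in names}
        obs = ~mask & ~censored
        var_y = float(np.var(logt[obs], ddof=1)) if obs.sum() > 1 else 1.0

        fixed = dict(self.fixed_variances or {})
        S_e, df_e = self._prior("residual", var_y, len(names))
        priors = {k: self._prior(k, var_y, len(names)) for k in names}

        XtX = X.T @ X
        cho = cho_factor(XtX)
        R = np.linalg.cholesky(XtX).T  # upper triangular: XtX = R'R

        # initial state
        ylat = np.where(np.isfinite(logt), logt, 0.0)
        ylat[mask] = np.nanmean(logt[obs]) if obs.any() else 0.0
        ylat[censored] = logt[censored] + 0.5
        sig2_e = float(fixed.get("residual", var_y / 2.0 if var_y > 0 else 1.0))
        sig2 = {k: float(fixed.get(k, var_y / (2.0 * max(len(names), 1)))) for k in names}
        alpha = cho_solve(cho, X.T @ ylat)
        u = {k: np.zeros(n) for k in names}
        delta = {k: np.zeros(len(lam[k])) for k in names}
        usum = np.zeros(n)
        xb = X @ alpha
        eta = xb + usum

        n_keep = (self.n_iter - self.burn_in) // self.thin
        if n_keep <= 0:
            raise ValueError("n_iter, burn_in and thin leave no retained draws")
        out_alpha = np.empty((n_keep, q))
        out_s2e = np.empty(n_keep)
        out_s2 = {k: np.empty(n_keep) for k in names}
        out_u = {k: np.empty((n_keep, n)) for k in names}
        out_eta = np.empty((n_keep, n))
        out_ylat = np.empty((n_keep, n))

        cens_idx = np.flatnonzero(censored)
        mask_idx = np.flatnonzero(mask)
        kept = 0
        for it in range(self.n_iter):
            se = math.sqrt(sig2_e)
            # (1) latent outcomes
            if cens_idx.size:
                ylat[cens_idx] = sample_truncated_normal(
                    eta[cens_idx], se, logt[cens_idx], rng=rng)
            if mask_idx.size:
                ylat[mask_idx] = eta[mask_idx] + se * rng.standard_normal(mask_idx.size)
            # (2) fixed effects: flat prior => Gaussian centered at GLS solution
            resid = ylat - usum
            ahat = cho_solve(cho, X.T @ resid)
            alpha = ahat + se * solve_triangular(R, rng.standard_normal(q))
            xb = X @ alpha
            # (3) kernel random effects in the eigenbasis
            for k in names:
                e = ylat - xb - (usum - u[k])
                r = Gam[k].T @ e
                prec = 1.0 / sig2_e + 1.0 / (lam[k] * sig2[k])
                mu = r / (sig2_e * prec)
                d = mu + rng.standard_normal(len(mu)) / np.sqrt(prec)
                new_u = Gam[k] @ d
                usum += new_u - u[k]
                u[k] = new_u
                delta[k] = d
                # (4) kernel variance
                if k not in fixed:
                    S_k, df_k = priors[k]
                    ss = float(np.sum(d * d / lam[k]))
                    sig2[k] = _scaled_inv_chi2(rng, df_k + len(d), S_k + ss)
            eta = xb + usum
            # (5) residual variance
            if "residual" not in fixed:
                ss = float(np.sum((ylat - eta) ** 2))
                sig2_e = _scaled_inv_chi2(rng, df_e + n, S_e + ss)
            if not np.isfinite(sig2_e) or sig2_e <= 0:
                raise FloatingPointError(f"non-finite residual variance at iteration {it}")
            # store
            if it >= self.burn_in and (it - self.burn_in) % self.thin == 0 and kept < n_keep:
                out_alpha[kept] = alpha
                out_s2e[kept] = sig2_e
                for k in names:
                    out_s2[k][kept] = sig2[k]
                    out_u[k][kept] = u[k]
                out_eta[kept] = eta
                out_ylat[kept] = ylat
                kept += 1

        return PosteriorChains(
            alpha=out_alpha[:kept], sigma2={k: v[:kept] for k, v in out_s2.items()},
            sigma2_e=out_s2e[:kept], u={k: v[:kept] for k, v in out_u.items()},
            eta=out_eta[:kept], ylat=out_ylat[:kept],
            sample_ids=list(range(n)), log_time=logt, censor=censored.astype(float),
            mask=mask, fixed_names=list(self.fixed_names_),
        )

    # -- post-fit API ------------------------------------------------------
    def predict(self, indices=None) -> np.ndarray:
        """Posterior mean linear predictor (log survival time).

        With no argument, returns predictions for the masked rows if any
        were masked at fit time, else for all rows.
        """
        eta = self.chains_.posterior_mean_eta()
        if indices is None:
            return eta[self.chains_.mask] if self.chains_.mask.any() else eta
        return eta[np.asarray(indices)]

    def predict_out_of_sample(self, X_new, cross_kernels: dict) -> np.ndarray:
        """Project posterior-mean random effects onto new subjects.

        ``cross_kernels[name]`` is the (m, n_train) block K_new,train of the
        same kernel used at fit time; the new-subject effect is
        K_new,train K_train^- u_bar (the conditional prior mean given the
        training effects).
        """
        ch = self.chains_
        m = None
        for name, Kc in cross_kernels.items():
            Kc = np.asarray(Kc, dtype=float)
            m = Kc.shape[0] if m is None else m
        if X_new is None:
            Xf = np.ones((m, 1))
        else:
            X_new = np.asarray(X_new, dtype=float)
            if X_new.ndim == 1:
                X_new = X_new[:, None]
            Xf = np.hstack([np.ones((m, 1)), X_new])
        eta_new = Xf @ ch.alpha.mean(axis=0)
        for name, Kc in cross_kernels.items():
            km = self.kernels_[name]
            u_bar = ch.u[name].mean(axis=0)
            # K_train^- u through the retained eigenbasis
            coef = km.eigenvectors @ ((km.eigenvectors.T @ u_bar) / km.eigenvalues)
            eta_new = eta_new + np.asarray(Kc, dtype=float) @ coef
        return eta_new

    def summary(self) -> PosteriorSummary:
        s = summarize(self.chains_)
        s.dic = self.dic()
        return s

    def dic(self) -> float:
        return dic(self.chains_)


# ---------------------------------------------------------------------------
# summaries, deviance, DIC - module-level surface
# ---------------------------------------------------------------------------

def summarize(chains: PosteriorChains, min_draws: int = 100) -> PosteriorSummary:
    """Posterior means/SDs, batch-means MC errors and the variance table.

    A variance parameter is flagged when its MC error exceeds 1% of its
    posterior mean (the convergence rule used for all reported fits).
    """
    if chains.n_draws < min_draws:
        raise ValueError(f"need at least {min_draws} retained draws, have {chains.n_draws}")
    rows = []
    total = np.zeros(chains.n_draws)
    for name, draws in chains.sigma2.items():
        total = total + draws
    total = total + chains.sigma2_e
    for name, draws in list(chains.sigma2.items()) + [("residual", chains.sigma2_e)]:
        mean = float(draws.mean())
        mcse = batch_means_mcse(draws)
        rows.append({
            "component": name,
            "mean": mean,
            "sd": float(draws.std(ddof=1)),
            "mc_error": mcse,
            "proportion": float((draws / total).mean()),
            "mc_error_flag": bool(mcse > 0.01 * abs(mean)),
        })
    vt = pd.DataFrame(rows).set_index("component")
    # normalise mean proportions to sum exactly to one
    vt["proportion"] = vt["proportion"] / vt["proportion"].sum()
    fe = pd.DataFrame({
        "mean": chains.alpha.mean(axis=0),
        "sd": chains.alpha.std(axis=0, ddof=1),
    }, index=chains.fixed_names)
    return PosteriorSummary(variance_table=vt, fixed_effects=fe)


def deviance(log_time: np.ndarray, censor: np.ndarray, eta: np.ndarray,
             sigma2_e: float) -> float:
    """-2 log likelihood of the censored log-normal model at fixed parameters.

    Observed rows contribute log N(y_i | eta_i, sigma2_e); censored rows the
    log survival probability log(1 - Phi((log t_i - eta_i)/sigma_e)),
    computed with ``log_ndtr`` so extreme tails never underflow to -inf.
    """
    se = math.sqrt(sigma2_e)
    z = (log_time - eta) / se
    obs = censor == 0
    ll = float(np.sum(-0.5 * math.log(2 * math.pi * sigma2_e) - 0.5 * z[obs] ** 2))
    ll += float(np.sum(log_ndtr(-z[~obs])))
    return -2.0 * ll


def dic(chains: PosteriorChains) -> float:
    """Deviance information criterion: mean deviance + effective parameters.

    p_D = mean(D) - D(posterior mean of eta, posterior mean of sigma2_e);
    masked rows carry no data and are excluded.
    """
    keep = ~chains.mask
    logt = chains.log_time[keep]
    cens = chains.censor[keep]
    devs = np.array([
        deviance(logt, cens, chains.eta[s][keep], chains.sigma2_e[s])
        for s in range(chains.n_draws)
    ])
    d_bar = float(devs.mean())
    d_hat = deviance(logt, cens, chains.posterior_mean_eta()[keep],
                     float(chains.sigma2_e.mean()))
    return d_bar + (d_bar - d_hat)


# ---------------------------------------------------------------------------
# thin functional wrappers over the estimator
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """A named model: which covariates enter as fixed effects and which
    kernels as random effects, plus the MCMC settings."""

    fixed: list = field(default_factory=list)
    kernels: list = field(default_factory=list)
    n_iter: int = 30000
    burn_in: int = 5000
    thin: int = 5
    prior_df: float = 5.0
    prior_scales: dict | None = None


def _estimator(spec: ModelSpec, random_state=None) -> BayesKernelSurvival:
    return BayesKernelSurvival(
        n_iter=spec.n_iter, burn_in=spec.burn_in, thin=spec.thin,
        prior_df=spec.prior_df, prior_scales=spec.prior_scales,
        random_state=random_state)


def fit(spec: ModelSpec, cohort: Cohort, kernels: dict, mask=None,
        random_state=None) -> BayesKernelSurvival:
    """Fit ``spec`` to a cohort using pre-built kernels; returns the fitted
    estimator (chains under ``.chains_``)."""
    X, _, _ = design_matrix(cohort, spec.fixed) if spec.fixed else (None, [], [])
    y = np.column_stack([cohort.time, cohort.censor])
    ks = {name: kernels[name] for name in spec.kernels}
    est = _estimator(spec, random_state)
    est.fit(X if spec.fixed else None, y, kernels=ks, mask=mask)
    if spec.fixed:
        est.chains_.fixed_names = ["intercept"] + design_matrix(cohort, spec.fixed)[1]
    est.chains_.sample_ids = cohort.sample_ids
    return est


def predict(est: BayesKernelSurvival, target_rows=None) -> np.ndarray:
    """Posterior-mean log survival for the requested rows (see
    :meth:`BayesKernelSurvival.predict`)."""
    if target_rows is not None:
        ids = pd.Index(est.chains_.sample_ids)
        pos = ids.get_indexer(list(target_rows))
        if (pos < 0).any():
            raise KeyError("unknown sample id in target_rows")
        return est.predict(pos)
    return est.predict()
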