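"""Repeated k-fold cross-validation with month-wise AUC of survival predictions.

Predictive ability is scored by the AUC for classifying alive-vs-dead status
at each month after diagnosis from the model's predicted log survival time,
using only the patients whose status at that month is known: a patient
censored at or before the month is excluded, since their status is genuinely
unknown. Per-repeat mean AUC averages over the months where both classes are
present, and pairwise win proportions count the repeats in which one model's
mean AUC exceeds another's (ties at 1/2).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import Cohort
from .gibbs import ModelSpec
from .gibbs import fit as fit_model

__all__ = ["CVPlan", "CVResult", "make_cv_folds", "monthly_labels", "roc_auc",
           "run_cv", "pairwise_win_proportions"]


@dataclass
class CVPlan:
    n: int
    n_folds: int
    n_repeats: int
    seed: int
    assignments: np.ndarray  # (n_repeats, n) fold id per sample

    def folds(self, repeat: int):
        for f in range(self.n_folds):
            yield f, np.flatnonzero(self.assignments[repeat] == f)


def make_cv_folds(n: int, n_folds: int = 5, n_repeats: int = 20, seed: int = 0) -> CVPlan:
    """Seeded uniform random partition into folds of near-equal size."""
    if n < n_folds:
        raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignments = np.empty((n_repeats, n), dtype=int)
    base = np.arange(n) % n_folds  # sizes differ by at most 1
    for r in range(n_repeats):
        assignments[r] = base[rng.permutation(n)]
    return CVPlan(n, n_folds, n_repeats, seed, assignments)


def monthly_labels(cohort: Cohort, month: int):
    """Alive-status labels at a given month plus the evaluable-sample mask.

    Label 1: known alive beyond the month (any patient with time > month);
    label 0: died at or before the month; masked out: censored at or before
    the month (status unknown).
    """
    if month < 1:
        raise ValueError("month must be >= 1")
    t = cohort.time
    c = cohort.censor
    alive = t > month
    died = (~alive) & (c == 0)
    evaluable = alive | died
    labels = np.where(alive, 1, 0)
    return labels, evaluable


def roc_auc(labels, scores) -> float:
    """AUC as the tie-adjusted Mann-Whitney statistic.

    Equals the trapezoidal area under the empirical ROC, with tied scores
    contributing 1/2; exact (no approximation), matching the O(n^2)
    pairwise concordance count.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class CVResult:
    plan: CVPlan
    predictions: np.ndarray          # (n_repeats, n) held-out predicted log time
    auc_by_month: pd.DataFrame       # rows repeats, columns months (NaN = skipped)
    mean_auc_by_repeat: np.ndarray   # (n_repeats,)
    skipped_months: list = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.mean_auc_by_repeat))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.mean_auc_by_repeat, ddof=1))


def auc_curve(cohort: Cohort, predictions: np.ndarray, months=None, fold_ids=None):
    """Month-wise AUC of one prediction vector; undefined months -> NaN.

    With ``fold_ids`` given, the AUC for each month is computed within each
    held-out fold and averaged over the folds where both classes are
    present. Scores from different folds come from different training runs
    and are not on a common scale, so pooling them into one ROC is biased
    (pessimistically so for weak models); fold-averaging avoids comparing
    scores across folds. ``fold_ids=None`` pools all samples (the biased
    but simpler variant, kept for comparison).
    """
    if months is None:
        months = range(1, int(np.floor(np.nanmax(cohort.time))) + 1)
    groups = [np.arange(cohort.n)] if fold_ids is None else [
        np.flatnonzero(fold_ids == f) for f in np.unique(fold_ids)]
    out = {}
    for month in months:
        labels, ok = monthly_labels(cohort, month)
        vals = []
        for g in groups:
            sub = g[ok[g]]
            if len(sub) < 2 or len(np.unique(labels[sub])) < 2:
                continue
            vals.append(roc_auc(labels[sub], predictions[sub]))
        out[month] = float(np.mean(vals)) if vals else np.nan
    return out


def run_cv(model_specs: dict[str, ModelSpec], cohort: Cohort, kernels: dict,
           plan: CVPlan, score_fn=None, pool_folds: bool = False) -> dict[str, CVResult]:
    """Repeated k-fold CV of each model; identical folds for all models.

    Per repeat and fold the model is refit with the held-out fold's outcomes
    masked (test subjects stay inside the kernels), and the posterior-mean
    linear predictor scores the held-out patients. Month-wise AUCs are
    fold-averaged by default (see :func:`auc_curve`); ``pool_folds=True``
    pools all predictions of a repeat into one ROC instead.
    ``score_fn(cohort, train_mask, rng)`` may replace the model fit for
    oracle runs: it must return a full-length score vector.
    """
    if not cohort.has_outcomes():
        raise ValueError("cohort has no outcomes")
    n = cohort.n
    if plan.n != n:
        raise ValueError("CV plan was built for a different sample size")
    months = list(range(1, int(np.floor(np.nanmax(cohort.time))) + 1))
    root = np.random.SeedSequence(plan.seed)
    results = {}
    for name, spec in model_specs.items():
        preds = np.full((plan.n_repeats, n), np.nan)
        auc_rows = []
        for rep in range(plan.n_repeats):
            for fold, test_idx in plan.folds(rep):
                seed = np.random.SeedSequence(
                    entropy=plan.seed,
                    spawn_key=(zlib.crc32(name.encode()) % (2**20), rep, fold))
                mask = np.zeros(n, dtype=bool)
                mask[test_idx] = True
                try:
                    if score_fn is not None:
                        scores = score_fn(cohort, ~mask, np.random.default_rng(seed))
                    else:
                        est = fit_model(spec, cohort, kernels, mask=mask,
                                        random_state=np.random.default_rng(seed))
                        scores = est.chains_.posterior_mean_eta()
                except Exception as exc:
                    raise RuntimeError(
                        f"model {name!r} failed at repeat {rep}, fold {fold}: {exc}") from exc
                preds[rep, test_idx] = scores[test_idx]
            auc_rows.append(auc_curve(
                cohort, preds[rep], months,
                fold_ids=None if pool_folds else plan.assignments[rep]))
        auc = pd.DataFrame(auc_rows, index=range(plan.n_repeats))
        mean_by_rep = np.asarray(auc.mean(axis=1, skipna=True))
        skipped = [m for m in months if auc[m].isna().all()]
        results[name] = CVResult(plan, preds, auc, mean_by_rep, skipped)
    return results


def pairwise_win_proportions(results: dict[str, CVResult]) -> pd.DataFrame:
    """Entry (A, B): fraction of repeats where A's mean AUC beat B's (ties 1/2)."""
    names = list(results)
    reps = {results[n].plan.n_repeats for n in names}
    seeds = {results[n].plan.seed for n in names}
    if len(reps) > 1 or len(seeds) > 1:
        raise ValueError("all results must share the same CV plan")
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            xa = results[a].mean_auc_by_repeat
            xb = results[b].mean_auc_by_repeat
            mat.loc[a, b] = float(np.mean((xa > xb) + 0.5 * (xa == xb)))
    return mat
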