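"""Associations between omic principal components and demographics, and
gene-set enrichment of age-associated differential methylation.

The PC analyses regress each of the first 10 principal-component scores of
an omic layer on a clinical covariate (R-squared and F test per component);
this flags structure such as ancestry on the leading SNP component or an age
signal on a mid-rank methylation component. The methylation-age analysis
fits a per-probe linear model of M-values on age, aggregates probes to
genes, applies Benjamini-Hochberg FDR, and tests candidate gene sets for an
excess of extreme t-statistics via a rank-sum test and quartile overlap
counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Cohort, OmicMatrix

__all__ = [
    "pca_scores", "pc_covariate_regression", "PCAssociation",
    "diff_methylation_age", "bh_fdr", "gene_level_aggregate",
    "quartile_overlap", "gene_set_rank_test", "EnrichmentResult",
]


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------

def pca_scores(m: OmicMatrix, n_components: int = 10):
    """PC scores and variance shares via SVD of the centered matrix.

    Scores are left singular vectors scaled by singular values; variance
    shares are relative to the total variance. If the matrix rank is below
    ``n_components`` the available components are returned.
    """
    X = m.to_array()
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite values; preprocess first")
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size else np.zeros(0, dtype=bool)
    U, s = U[:, keep], s[keep]
    k = min(n_components, len(s))
    scores = pd.DataFrame(
        U[:, :k] * s[:k], index=m.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)])
    shares = (s**2 / (s**2).sum())[:k]
    return scores, shares


@dataclass
class PCAssociation:
    omic_kind: str
    covariate: str
    table: pd.DataFrame      # per PC: variance_share, r2, p_value, significant
    summed_significant_r2: float


def pc_covariate_regression(scores: pd.DataFrame, covariate, variance_shares=None,
                            alpha: float = 0.05, omic_kind: str = "",
                            name: str = "covariate") -> PCAssociation:
    """OLS of each PC score on the covariate; R-squared and F-test p-value.

    Categorical covariates are dummy-encoded (F test on all levels jointly).
    """
    import statsmodels.api as sm

    cov = pd.Series(covariate, index=scores.index) if not isinstance(covariate, pd.Series) \
        else covariate.loc[scores.index]
    if pd.api.types.is_numeric_dtype(cov):
        Z = np.asarray(cov, dtype=float)[:, None]
    else:
        Z = np.asarray(pd.get_dummies(cov, drop_first=True), dtype=float)
    if Z.shape[1] == 0 or np.allclose(Z.std(axis=0), 0):
        raise ValueError(f"covariate {name!r} is constant")
    design = sm.add_constant(Z)
    rows = []
    shares = variance_shares if variance_shares is not None else [np.nan] * scores.shape[1]
    for j, pc in enumerate(scores.columns):
        res = sm.OLS(np.asarray(scores[pc], dtype=float), design).fit()
        rows.append({"pc": pc, "variance_share": float(shares[j]),
                     "r2": float(res.rsquared), "p_value": float(res.f_pvalue)})
    table = pd.DataFrame(rows).set_index("pc")
    table["significant"] = table["p_value"] < alpha
    summed = float(table.loc[table["significant"], "r2"].sum())
    return PCAssociation(omic_kind, name, table, summed)


# ---------------------------------------------------------------------------
# differential methylation vs age
# ---------------------------------------------------------------------------

def beta_to_m(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Convert methylation beta values to M-values, M = log2(beta/(1-beta))."""
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def diff_methylation_age(meth: OmicMatrix, age, input_scale: str = "m") -> pd.DataFrame:
    """Per-probe simple linear regression of methylation on age.

    Returns a DataFrame indexed by probe with ``slope``, ``t`` (n-2 df) and
    two-sided ``p``. Vectorized closed-form OLS across probes.
    """
    age = np.asarray(age, dtype=float)
    if age.std() == 0:
        raise ValueError("age has zero variance")
    Y = meth.to_array()
    if input_scale == "beta":
        Y = beta_to_m(Y)
    elif input_scale != "m":
        raise ValueError("input_scale must be 'm' or 'beta'")
    n = len(age)
    xc = age - age.mean()
    sxx = float(np.sum(xc**2))
    Yc = Y - Y.mean(axis=0)
    slope = (xc @ Yc) / sxx
    resid = Yc - np.outer(xc, slope)
    dof = n - 2
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(sigma2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, slope / se, np.sign(slope) * np.inf)
    p = 2 * stats.t.sf(np.abs(t), dof)
    return pd.DataFrame({"slope": slope, "t": t, "p": p}, index=meth.feature_ids)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def gene_level_aggregate(probe_stats: pd.DataFrame, probe_to_gene: pd.Series,
                         method: str = "max_abs_t", fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate per-probe statistics to genes and apply gene-level BH-FDR.

    ``max_abs_t`` (default): gene t is the probe t of largest magnitude, with
    that probe's p. ``mean``: average t across probes, p from the normal
    approximation. ``stouffer``: combine probe z-scores.
    Probes without a gene mapping are dropped.
    """
    mapped = probe_stats.join(probe_to_gene.rename("gene"), how="inner").dropna(subset=["gene"])
    if mapped.empty:
        raise ValueError("no probes could be mapped to genes")
    rows = []
    for gene, grp in mapped.groupby("gene", sort=True):
        if method == "max_abs_t":
            i = grp["t"].abs().idxmax()
            t, p = float(grp.loc[i, "t"]), float(grp.loc[i, "p"])
        elif method == "mean":
            t = float(grp["t"].mean() * np.sqrt(len(grp)))
            p = float(2 * stats.norm.sf(abs(t)))
        elif method == "stouffer":
            z = stats.norm.isf(grp["p"] / 2) * np.sign(grp["t"])
            t = float(z.sum() / np.sqrt(len(grp)))
            p = float(2 * stats.norm.sf(abs(t)))
        else:
            raise ValueError(f"unknown aggregation method {method!r}")
        rows.append({"gene": gene, "t": t, "p": p, "n_probes": len(grp)})
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr_alpha
    return out


# ---------------------------------------------------------------------------
# gene-set enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_name: str
    quartile_counts: np.ndarray   # set members per t-value quartile (Q1..Q4)
    rank_test_p: float
    direction: str
    n_tested: int
    n_dropped: int


def quartile_overlap(gene_stats: pd.DataFrame, gene_set) -> np.ndarray:
    """Counts of set members in each empirical quartile of the t-statistics.

    Quartile boundaries come from all tested genes; ties on a boundary fall
    into the lower quartile. Counts sum to the number of set genes present
    among the tested genes.
    """
    genes = gene_stats.index
    members = [g for g in gene_set if g in genes]
    if not members:
        raise ValueError("gene set has no overlap with the tested genes")
    t_all = gene_stats["t"].to_numpy(dtype=float)
    qs = np.quantile(t_all, [0.25, 0.5, 0.75])
    t_set = gene_stats.loc[members, "t"].to_numpy(dtype=float)
    bins = np.searchsorted(qs, t_set, side="left")
    return np.bincount(bins, minlength=4)


def gene_set_rank_test(gene_stats: pd.DataFrame, gene_set,
                       direction: str = "greater") -> float:
    """Wilcoxon rank-sum test of set-member t-statistics vs the rest.

    ``direction='greater'`` tests for over-representation of high t-values
    (hyper-methylation with age); also supports ``'less'`` and
    ``'two-sided'``.
    """
    if direction not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown direction {direction!r}")
    in_set = gene_stats.index.isin(set(gene_set))
    t_in = gene_stats.loc[in_set, "t"].to_numpy(dtype=float)
    t_out = gene_stats.loc[~in_set, "t"].to_numpy(dtype=float)
    if len(t_in) < 2 or len(t_out) < 2:
        raise ValueError("need at least 2 genes inside and outside the set")
    res = stats.mannwhitneyu(t_in, t_out, alternative=direction)
    return float(res.pvalue)


def enrich(gene_stats: pd.DataFrame, gene_set, set_name: str = "set",
           direction: str = "greater") -> EnrichmentResult:
    """Quartile overlap plus rank-sum enrichment p for one gene set."""
    members = [g for g in gene_set if g in gene_stats.index]
    counts = quartile_overlap(gene_stats, members)
    p = gene_set_rank_test(gene_stats, members, direction)
    return EnrichmentResult(set_name, counts, p, direction,
                            n_tested=len(members), n_dropped=len(gene_set) - len(members))


def methylation_age_enrichment(meth: OmicMatrix, cohort: Cohort, gene_sets: dict,
                               input_scale: str = "m", method: str = "max_abs_t",
                               direction: str = "greater"):
    """End-to-end: probe regressions -> gene aggregation -> per-set enrichment."""
    if meth.feature_meta is None:
        raise ValueError("methylation matrix has no probe-to-gene metadata")
    probe_stats = diff_methylation_age(meth, cohort.data["age"], input_scale=input_scale)
    gene_stats = gene_level_aggregate(probe_stats, meth.feature_meta, method=method)
    results = {name: enrich(gene_stats, genes, name, direction)
               for name, genes in gene_sets.items()}
    return gene_stats, results
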