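"""Synthetic multi-omic survival cohorts with known ground truth.

The generator mirrors the statistical structure of a GBM-like cohort: ~500
patients, right censoring around 25%, an age-coupled latent factor in
methylation, race-differentiated SNP allele frequencies, a sex-coupled
expression factor, and log-normal survival whose variance is partitioned
across omic kernels with known components. Because it generates from the
same additive-kernel log-normal model the sampler fits, parameter recovery
is a well-posed test for every downstream stage.

Scales are desk-sized by default (SNP 5000, methylation 2000, expression
1000, CNV 500 features) - far below array scale but preserving p >> n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import Cohort, OmicMatrix
from .preprocessing import build_kernels

DEFAULT_FEATURES = {"snp": 5000, "methylation": 2000, "expression": 1000, "cnv": 500}

#: latent-factor score scales per structured omic layer. Feature noise has SD
#: 1; each layer carries a handful of separated leading factors (so leading
#: PCs have a few percent of the variance each and covariate couplings land on
#: an identifiable PC) plus a broad bank of weak factors, mimicking the long
#: eigenvalue tails of real array kernels and keeping the implied kernel at a
#: high effective rank so variance components are as identifiable as the data
#: allow
_FACTOR_SCALES = {
    "methylation": (0.60, 0.52, 0.46, 0.40, 0.36) + (0.24,) * 50,
    "expression": (0.55, 0.48, 0.42, 0.36) + (0.22,) * 40,
    "cnv": (0.50, 0.42, 0.34) + (0.20,) * 20,
}
#: which latent factor carries the covariate coupling (0-based)
_AGE_FACTOR = 3     # 4th methylation factor, echoing an age signal on a mid-rank PC
_SEX_FACTOR = 2     # 3rd expression factor


class InvalidConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the generative model.

    Defaults follow the demographics of a de-novo GBM cohort: age truncated
    normal (mean 58.2, sd 14.06, on [18, 95]), 61% male, 93.6% in the
    majority race group, 59.4% treated with temozolomide, and a 24.9%
    target right-censoring fraction. Fixed effects act on centered
    covariates, on the log-survival (months) scale.
    """

    n_patients: int = 500
    features_per_omic: dict | None = None
    true_variance_components: dict | None = None
    residual_variance: float = 0.4
    fixed_effects: dict = field(default_factory=lambda: {"age": -0.02, "temozolomide": 0.35})
    coupling_strengths: dict = field(
        default_factory=lambda: {"age_meth": 0.4, "race_snp": 0.9, "sex_ge": 0.3})
    target_censoring_fraction: float = 0.249
    intercept: float = 2.3  # log-months; exp(2.3) ~ 10 months median survival
    age_mean: float = 58.2
    age_sd: float = 14.06
    age_bounds: tuple = (18.0, 95.0)
    p_male: float = 0.61
    p_race_major: float = 0.936
    p_temozolomide: float = 0.594
    probes_per_gene: int = 5
    missing_fraction: dict = field(default_factory=dict)  # omic kind -> fraction of samples absent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.features_per_omic is None:
            self.features_per_omic = dict(DEFAULT_FEATURES)
        if self.true_variance_components is None:
            # default partition, restricted to the layers actually simulated
            self.true_variance_components = {
                k: v for k, v in {"methylation": 0.5, "expression": 0.3}.items()
                if k in self.features_per_omic}
        if self.n_patients <= 0:
            raise InvalidConfigError("n_patients must be positive")
        if any(v <= 0 for v in self.features_per_omic.values()):
            raise InvalidConfigError("feature counts must be positive")
        if any(v < 0 for v in self.true_variance_components.values()):
            raise InvalidConfigError("variance components must be nonnegative")
        if self.residual_variance <= 0:
            raise InvalidConfigError("residual_variance must be positive")
        if not 0.0 < self.target_censoring_fraction < 1.0:
            raise InvalidConfigError("target_censoring_fraction must lie strictly in (0,1)")
        for key, v in self.coupling_strengths.items():
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"coupling strength {key} must lie in [0,1]")
        orphans = [k for k, v in self.true_variance_components.items()
                   if v > 0 and k not in self.features_per_omic]
        if orphans:
            raise InvalidConfigError(
                f"variance components for omic layers not simulated: {orphans}")

    def coupling(self, key: str) -> float:
        return float(self.coupling_strengths.get(key, 0.0))


@dataclass
class SimTruth:
    """Ground truth recorded by the generator for recovery tests."""

    true_log_times: np.ndarray
    true_u: dict
    true_sigma2: dict
    causal_feature_ids: dict
    enriched_gene_set: list = field(default_factory=list)


@dataclass
class GeneSetTruth:
    sets: dict            # set name -> list of gene ids
    labels: dict          # set name -> True if truly enriched
    probe_slopes: pd.Series  # probe id -> additive slope per SD of age


@dataclass
class SimulatedDataset:
    config: SimConfig
    cohort: Cohort
    omics: dict
    truth: SimTruth
    gene_sets: GeneSetTruth | None = None


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) % (2**31), salt]))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def simulate_cohort(config: SimConfig) -> Cohort:
    """Draw demographics and treatment flags; outcomes stay empty until
    :func:`simulate_survival` fills them."""
    rng = _rng(config, 1)
    n = config.n_patients
    lo, hi = config.age_bounds
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                              size=n, random_state=rng)
    sex = (rng.random(n) < config.p_male).astype(int)          # 1 = male
    race = (rng.random(n) < config.p_race_major).astype(int)   # 1 = majority group
    tmz = (rng.random(n) < config.p_temozolomide).astype(int)  # temozolomide given
    ids = [f"P{i:05d}" for i in range(n)]
    df = pd.DataFrame({"age": age, "sex": sex, "race": race, "temozolomide": tmz,
                       "time": np.nan, "censor": np.nan}, index=ids)
    return Cohort(df)


# ---------------------------------------------------------------------------
# omics
# ---------------------------------------------------------------------------

def methylation_feature_map(config: SimConfig) -> pd.Series:
    """Deterministic probe -> gene map: consecutive probes share a gene."""
    p = config.features_per_omic.get("methylation", DEFAULT_FEATURES["methylation"])
    probes = [f"cg{i:06d}" for i in range(p)]
    genes = [f"GENE{i // config.probes_per_gene:04d}" for i in range(p)]
    return pd.Series(genes, index=probes, name="gene")


def _lowrank_layer(rng, n, p, scales, coupled_factor=None, coupled_score=None,
                   coupling=0.0, extra_slopes=None, z_age=None):
    """Shared factory for low-rank factor layers (methylation/expression/CNV).

    Each latent factor has unit-variance scores and N(0,1) loadings, scaled
    by ``scales``; one factor may be a convex mix of a covariate score and
    noise (strength ``coupling``). Feature noise has SD 1.
    """
    L = len(scales)
    F = rng.standard_normal((n, L))
    if coupled_factor is not None and coupling > 0:
        F[:, coupled_factor] = (coupling * coupled_score
                                + math.sqrt(1.0 - coupling**2) * F[:, coupled_factor])
    load = rng.standard_normal((L, p))
    base = rng.normal(0.0, 1.0, size=p)
    M = base + (F * np.asarray(scales)) @ load + rng.standard_normal((n, p))
    if extra_slopes is not None:
        M = M + np.outer(z_age, extra_slopes)
    return M


def simulate_omics(cohort: Cohort, config: SimConfig,
                   meth_age_slopes: pd.Series | None = None) -> dict[str, OmicMatrix]:
    """Generate every configured omic layer, coupled to the cohort covariates.

    ``meth_age_slopes`` (probe id -> slope per SD of age) injects additional
    age-dependent methylation into designated probes; see
    :func:`make_gene_sets`.
    """
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    n = cohort.n
    ids = cohort.sample_ids
    age = np.asarray(cohort.data["age"], dtype=float)
    z_age = _zscore(age)
    omics: dict[str, OmicMatrix] = {}
    for kind, p in config.features_per_omic.items():
        rng = _rng(config, 100 + _salt_for(kind))
        if kind == "snp":
            c = config.coupling("race_snp")
            base = rng.uniform(0.1, 0.9, size=p)
            delta = c * rng.normal(0.0, 0.25, size=p)
            p_major = np.clip(base + delta / 2.0, 0.02, 0.98)
            p_minor = np.clip(base - delta / 2.0, 0.02, 0.98)
            race = np.asarray(cohort.data["race"], dtype=int)
            freqs = np.where(race[:, None] == 1, p_major[None, :], p_minor[None, :])
            M = rng.binomial(2, freqs).astype(float)
            cols = [f"rs{i:06d}" for i in range(p)]
            meta = None
        elif kind == "methylation":
            meta = methylation_feature_map(config)
            cols = list(meta.index)
            slopes = None
            if meth_age_slopes is not None:
                slopes = meth_age_slopes.reindex(cols).fillna(0.0).to_numpy()
            M = _lowrank_layer(rng, n, p, _FACTOR_SCALES["methylation"],
                               coupled_factor=_AGE_FACTOR, coupled_score=z_age,
                               coupling=config.coupling("age_meth"),
                               extra_slopes=slopes, z_age=z_age)
        elif kind == "expression":
            sex = _zscore(np.asarray(cohort.data["sex"], dtype=float))
            M = _lowrank_layer(rng, n, p, _FACTOR_SCALES["expression"],
                               coupled_factor=_SEX_FACTOR, coupled_score=sex,
                               coupling=config.coupling("sex_ge"))
            cols = [f"ge{i:05d}" for i in range(p)]
            meta = None
        elif kind == "cnv":
            M = _lowrank_layer(rng, n, p, _FACTOR_SCALES["cnv"])
            cols = [f"cnv{i:05d}" for i in range(p)]
            meta = None
        else:
            raise ValueError(f"unknown omic kind {kind!r}")
        df = pd.DataFrame(M, index=ids, columns=cols)
        frac_missing = float(config.missing_fraction.get(kind, 0.0))
        if frac_missing > 0:
            n_drop = int(round(frac_missing * n))
            drop = rng.choice(n, size=n_drop, replace=False)
            df = df.drop(index=[ids[i] for i in drop])
        omics[kind] = OmicMatrix(df, kind, meta)
    return omics


def _salt_for(kind: str) -> int:
    return {"snp": 1, "methylation": 2, "expression": 3, "cnv": 4}[kind]


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def make_gene_sets(feature_meta: pd.Series, n_enriched: int = 111, n_null: int = 273,
                   shift: float = 1.0, config: SimConfig | None = None,
                   seed: int | None = None) -> GeneSetTruth:
    """Designate a truly age-shifted gene set and a disjoint null set.

    The enriched set's probes receive an additive slope of ``shift`` (in
    feature-noise SD units per SD of age) inside the methylation generator;
    default sizes echo published brain-aging (111 genes) and GBM
    hyper-methylation (273 genes) sets. Returns the sets, truth labels and
    the per-probe slope vector to pass to :func:`simulate_omics`.
    """
    genes = pd.unique(feature_meta)
    if n_enriched + n_null > len(genes):
        raise ValueError(
            f"requested set sizes ({n_enriched}+{n_null}) exceed the gene universe ({len(genes)})")
    if seed is None:
        seed = 0 if config is None else config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 500]))
    perm = rng.permutation(len(genes))
    enriched = sorted(genes[perm[:n_enriched]])
    null = sorted(genes[perm[n_enriched:n_enriched + n_null]])
    in_set = feature_meta.isin(enriched)
    slopes = pd.Series(np.where(in_set, float(shift), 0.0), index=feature_meta.index)
    return GeneSetTruth(
        sets={"age_shifted": list(enriched), "null": list(null)},
        labels={"age_shifted": shift != 0.0, "null": False},
        probe_slopes=slopes,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def _fixed_effect_part(cohort: Cohort, config: SimConfig) -> np.ndarray:
    out = np.zeros(cohort.n)
    for name, beta in config.fixed_effects.items():
        if name not in cohort.data.columns:
            raise ValueError(f"fixed effect on unknown covariate {name!r}")
        x = np.asarray(cohort.data[name], dtype=float)
        out += beta * (x - x.mean())  # centered so the intercept stays the mean log-time
    return out


def _calibrate_horizon_location(y_star: np.ndarray, scale: float, target: float) -> float:
    """Bisection on the horizon log-location so E[censoring fraction] = target.

    The horizon is log-normal with the given log-scale; the expected realized
    fraction is mean_i Phi((y*_i - m)/scale), decreasing in m.
    """
    lo = y_star.min() - 10 * scale
    hi = y_star.max() + 10 * scale
    for _ in range(200):
        mid = (lo + hi) / 2.0
        frac = stats.norm.cdf((y_star - mid) / scale).mean()
        if frac > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def simulate_survival(cohort: Cohort, omics: dict[str, OmicMatrix], config: SimConfig):
    """Draw log-normal survival from the additive-kernel model and censor it.

    For each omic named in ``true_variance_components`` a GBLUP kernel is
    built and a random effect u_k ~ N(0, K_k sigma2_k) drawn; the latent log
    time is y* = mu + sum_j x_ij alpha_j + sum_k u_ki + eps. An independent
    log-normal follow-up horizon, its location calibrated by bisection,
    produces administrative right censoring near the target fraction.
    Returns ``(cohort_with_outcomes, SimTruth)``.
    """
    ids = cohort.sample_ids
    used = {k: v for k, v in config.true_variance_components.items() if v > 0}
    for name in used:
        if name not in omics:
            raise ValueError(f"variance component for missing omic layer {name!r}")
        if omics[name].sample_ids != ids:
            raise ValueError(f"omic layer {name!r} is not sample-aligned with the cohort")
    rng = _rng(config, 900)
    n = cohort.n
    kernels = build_kernels({k: omics[k] for k in used}) if used else {}
    true_u: dict[str, np.ndarray] = {}
    u_sum = np.zeros(n)
    for name, sig2 in used.items():
        km = kernels[name]
        z = rng.standard_normal(km.rank)
        u = km.eigenvectors @ (np.sqrt(np.maximum(km.eigenvalues, 0.0) * sig2) * z)
        true_u[name] = u
        u_sum += u
    eps = rng.normal(0.0, math.sqrt(config.residual_variance), size=n)
    y_star = config.intercept + _fixed_effect_part(cohort, config) + u_sum + eps

    scale = max(y_star.std(), 0.25)
    loc = _calibrate_horizon_location(y_star, scale, config.target_censoring_fraction)
    log_horizon = rng.normal(loc, scale, size=n)
    censored = (log_horizon < y_star).astype(float)
    obs_time = np.exp(np.minimum(y_star, log_horizon))

    out = cohort.with_outcomes(obs_time, censored)
    sigma2 = dict(used)
    sigma2["residual"] = config.residual_variance
    truth = SimTruth(
        true_log_times=y_star,
        true_u=true_u,
        true_sigma2=sigma2,
        causal_feature_ids={k: omics[k].feature_ids for k in used},
    )
    return out, truth


# ---------------------------------------------------------------------------
# orchestration + disk round trip
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig, gene_set_sizes: tuple[int, int] | None = None,
                     gene_set_shift: float = 1.0) -> SimulatedDataset:
    """Full generative pipeline: cohort, omics (with an age-shifted gene set
    when methylation is simulated), survival outcomes and ground truth.

    ``gene_set_sizes`` defaults to (111, 273) - the published brain-aging and
    GBM hyper-methylation set sizes - shrunk proportionally when the gene
    universe is too small to hold both disjointly.
    """
    cohort = simulate_cohort(config)
    gene_sets = None
    slopes = None
    if "methylation" in config.features_per_omic:
        meta = methylation_feature_map(config)
        if gene_set_sizes is None:
            universe = len(pd.unique(meta))
            n_enr, n_null = 111, 273
            if n_enr + n_null > universe:
                n_enr = max(2, int(universe * 111 / 384))
                n_null = max(2, universe - n_enr - 1)
            gene_set_sizes = (n_enr, n_null)
        gene_sets = make_gene_sets(meta, *gene_set_sizes, shift=gene_set_shift, config=config)
        slopes = gene_sets.probe_slopes
    omics = simulate_omics(cohort, config, meth_age_slopes=slopes)
    causal = {}
    for name, sig2 in config.true_variance_components.items():
        if sig2 <= 0:
            continue
        m = omics.get(name)
        if m is None:
            raise ValueError(f"variance component for omic layer {name!r} not simulated")
        if not set(cohort.sample_ids) <= set(m.sample_ids):
            raise ValueError(
                f"causal omic layer {name!r} has missing samples; cannot generate survival")
        causal[name] = m if m.sample_ids == cohort.sample_ids else m.subset(cohort.sample_ids)
    cohort_out, truth = simulate_survival(cohort, causal, config)
    if gene_sets is not None:
        truth.enriched_gene_set = gene_sets.sets["age_shifted"]
    return SimulatedDataset(config, cohort_out, omics, truth, gene_sets)


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the dataset in the same delimited formats the pipeline reads."""
    from pathlib import Path

    from .io import write_clinical, write_gene_sets, write_json, write_omic_matrix

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_clinical(ds.cohort, outdir / "clinical.csv")
    for kind, m in ds.omics.items():
        write_omic_matrix(m, outdir / f"{kind}.tsv")
    if ds.gene_sets is not None:
        write_gene_sets(ds.gene_sets.sets, outdir / "gene_sets.gmt")
    write_json(
        {
            "true_sigma2": ds.truth.true_sigma2,
            "true_log_times": ds.truth.true_log_times,
            "true_u": {k: v for k, v in ds.truth.true_u.items()},
            "enriched_gene_set": ds.truth.enriched_gene_set,
        },
        outdir / "truth.json",
    )
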