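# Methods

## Model

For patient $i$ with survival time $t_i$ (months) the package models the log
survival time

$$y_i = \mu + \sum_j x_{ij}\alpha_j + \sum_k u_{ki} + \varepsilon_i,
\qquad \varepsilon_i \sim N(0, \sigma_\varepsilon^2),$$

where the $x_{ij}$ are baseline clinical covariates (entered as "fixed"
effects with flat priors, so their estimates match maximum likelihood) and
each $u_k = (u_{k1},\dots,u_{kn})$ is a random effect representing one omic
layer, $u_k \sim N(0, K_k \sigma_k^2)$. The kernel $K_k = X_kX_k'/p_k$
(features centred, optionally standardised) is the GBLUP / RKHS
representation of a high-dimensional linear regression on that layer's
features with IID Gaussian effect priors: the "kernel trick" reduces the
number of unknowns from $p_k$ (thousands of probes) to $n$ (patients).
Kernels are rescaled so that $\mathrm{mean}(\mathrm{diag}\,K_k)=1$, which
puts the $\sigma_k^2$ of layers with different feature counts on a common
scale; the raw $K=XX'$ scale would simply be absorbed into $\sigma_k^2$.

Right-censored patients contribute the survival probability
$1-\Phi\!\left((\log t_i - \eta_i)/\sigma_\varepsilon\right)$ to the
likelihood, where $\eta_i$ is the linear predictor. (A log-normal density
for observed rows and a normal survival function for censored rows is the
standard Tobit-type likelihood; the CDF form without the complement that
sometimes appears in write-ups of this model would describe *left*
censoring, so the survival form is used.)

Variances carry independent scaled-inverse-chi-square priors
$\sigma^2 \sim S/\chi^2_{df}$ (prior mean $S/(df-2)$, mode $S/(df+2)$).
Defaults follow common whole-genome-regression practice: $df=5$ for every
variance, and scales chosen so that the prior **mode** of the residual
variance equals half of $\mathrm{Var}(\log t)$ among observed deaths and
the kernel variances share the other half equally. Both the scales and
$df$ are overridable per component.

## Gibbs sampler

All full conditionals are conjugate. Per sweep:

1. **Censored data augmentation** - for each censored row, the latent log
   time is drawn from $N(\eta_i, \sigma_\varepsilon^2)$ truncated below at
   $\log t_i$. The truncated-normal sampler uses the inverse CDF evaluated
   in log space (`log_ndtr` / `ndtri_exp`), exact and stable far into the
   tail, with an exponential-proposal rejection sampler (Robert 1995)
   taking over beyond a standardized bound of 8.
2. **Fixed effects** - flat prior, so $\alpha$ is drawn from the Gaussian
   centred at the least-squares solution of the current residuals with
   covariance $\sigma_\varepsilon^2 (X'X)^{-1}$.
3. **Random effects** - in the eigenbasis $K_k = \Gamma_k \Lambda_k
   \Gamma_k'$ the effect is $u_k = \Gamma_k\delta_k$ with independent
   priors $\delta_{kj}\sim N(0,\lambda_{kj}\sigma_k^2)$; because
   $\Gamma_k'\Gamma_k = I$ the full conditional factorises into scalar
   Gaussians, so a sweep costs $O(n\,r_k)$ per kernel. Eigencomponents
   below $10^{-8}\lambda_{\max}$ are truncated.
4. **Variances** - $\sigma_k^2 \sim (S_k + \sum_j
   \delta_{kj}^2/\lambda_{kj}) / \chi^2_{df+r_k}$ and
   $\sigma_\varepsilon^2 \sim (S_\varepsilon + \sum_i (y_i-\eta_i)^2)
   / \chi^2_{df+n}$.

Defaults are 30 000 iterations, 5 000 burn-in, thinning 5; the recovery and
cross-validation analyses in the test-suite run 2 000-5 000 iterations at
$n \le 300$, which the batch-means diagnostics show is adequate at those
sizes. Monte-Carlo standard errors use non-overlapping batch means
(20 batches); a fit is flagged when any variance parameter's MC error
exceeds 1% of its posterior mean.

**Prediction** for held-out subjects uses the "set the outcome to missing"
idiom: test subjects stay inside the kernels, their latent outcome is drawn
from the unconstrained full conditional (which is a valid augmentation -
marginalising the missing outcomes returns the training-data posterior),
and the prediction is the posterior mean of $\eta_i$. The algebraically
equivalent projection $K_{\text{new,train}}K_{\text{train}}^{-}\bar u$ is
provided for genuinely out-of-sample subjects and tested for agreement.

**DIC** uses the mixed deviance (normal density for deaths, log survival
probability for censored rows, computed with `log_ndtr` so tails never
underflow), with $p_D = \bar D - D(\bar\eta, \bar\sigma_\varepsilon^2)$.

## Baseline Cox screening

Clinical covariates are screened with a Cox proportional-hazards model
maximising the Breslow-ties partial likelihood by Newton-Raphson
(step-halving, convergence when the score's sup-norm drops below $10^{-8}$,
at most 50 iterations). Efron ties are a non-goal; the test-suite
cross-checks against lifelines on tie-free data, where the two likelihoods
coincide. Separation is detected when a coefficient exceeds 5 per SD of its
covariate (a hazard ratio above $e^5$ per SD) and reported as a
non-convergence error naming the covariate. Kaplan-Meier curves are
delegated to lifelines.

## Cross-validated month-wise AUC

Prediction accuracy is summarised by the AUC for classifying alive-vs-dead
status at each month after diagnosis from the predicted log survival time,
under repeated 5-fold cross-validation (default 20 repeats, fold
assignments seeded). A patient censored at or before the month has unknown
status and is excluded from that month (an option treats them as alive
instead); months where only one class remains are skipped. The AUC is the
tie-adjusted Mann-Whitney statistic, identical to trapezoidal integration
of the empirical ROC.

A design point worth flagging: month-wise AUCs are computed **within each
held-out fold and averaged over folds**. Scores produced by different
training runs are not on a common scale, and pooling them into a single ROC
is pessimistically biased - a constant (intercept-only) model scores
~0.41-0.44 pooled at $n=200$ rather than 0.5 (cf. Forman & Scholz 2010 on
pooled cross-validation AUCs). With fold-averaging an uninformative model
scores exactly 0.5 by the tie rule. The pooled variant remains available
(`run_cv(..., pool_folds=True)`). Per-repeat mean AUC averages the defined
months; pairwise win proportions count repeats where one model's mean AUC
exceeds another's, ties at 1/2.

## PC association and methylation-age enrichment

Each omic layer's first 10 principal components (SVD of the centred,
by default unscaled matrix) are regressed on a clinical covariate;
the per-PC $R^2$ and F-test p-value, and the summed $R^2$ over significant
PCs, describe how demographics structure the omics. Differential
methylation with age fits a per-probe simple linear regression of M-values
on age (beta values are converted by $M=\log_2\beta/(1-\beta)$ with
clipping); probes aggregate to genes by the largest-|t| probe (mean and
Stouffer rules available), gene-level p-values get Benjamini-Hochberg
step-up q-values, and a candidate gene set is tested for enrichment by a
one-sided Wilcoxon rank-sum comparison of member vs non-member t-statistics
plus quartile overlap counts (quartile boundaries from all tested genes,
boundary ties to the lower quartile). The rank-sum test replaces limma's
geneSetTest; both are competitive rank-based set tests, so the equivalence
is qualitative rather than numeric.

## Synthetic data generator

The generator exists so that every stage has a parameter-recovery surface;
it adopts the fitted model's own structure (additive kernels on the
log-time scale) as the generative truth, which makes recovery well-posed.
Defaults emulate a de-novo GBM cohort: $n=500$; age truncated-normal
(mean 58.2, SD 14.06, range 18-95); 61% male; 93.6% in the majority race
group; 59.4% temozolomide; target right-censoring 24.9% via an independent
log-normal follow-up horizon whose location is calibrated by bisection
(administrative censoring - the mechanism behind the observed fraction is
not identifiable from a published fraction alone). Fixed effects act on
centred covariates with defaults age $-0.02$ and temozolomide $+0.35$ per
log-month, directionally matching the screening results such models report.

Omic layers (desk scale: SNP 5 000, methylation 2 000, expression 1 000,
CNV 500 features):

* **SNP** - genotypes 0/1/2 from two race-specific allele-frequency
  profiles; the frequency gap scales with the `race_snp` coupling, so at
  the default 0.9 the leading SNP PC separates the two groups
  ($R^2 > 0.9$), echoing the ancestry-on-PC1 phenomenon.
* **Methylation / expression / CNV** - latent-factor models with feature
  noise of SD 1. Each layer has a few separated leading factors plus a
  broad bank of weak factors (50/40/20), so leading PCs carry a few percent
  of the variance each and the kernel spectrum has the long tail seen in
  real array data. The 4th methylation factor mixes with standardised age
  (`age_meth`, default 0.4, putting $R^2\approx0.16$ on methylation PC4)
  and the 3rd expression factor with sex (`sex_ge`, default 0.3);
  CNV has no coupling by default.
* **Gene sets** - probes map to genes (5 probes/gene); one designated set
  (default 111 genes, with a disjoint 273-gene null set) receives an
  additive methylation slope per SD of age, making it truly differentially
  methylated for enrichment power analyses.

Survival draws $u_k \sim N(0, K_k\sigma_k^2)$ from each causal layer's
kernel (default $\sigma^2$: methylation 0.5, expression 0.3; residual 0.4).

What the generator does **not** emulate: CpG autocorrelation along
chromosomes, LD structure, platform artifacts, batch effects, non-Gaussian
survival shapes, or informative censoring. Passing tests therefore
demonstrate the machinery's correctness under the stated model, not
robustness to real-data misspecification. Per-omic missing samples are
available via `missing_fraction` (the real cohorts' overlap pattern is
unknown); causal layers must be complete.

A note on identifiability: with $K=XX'/p$ kernels, every layer's kernel
contains a near-identity bulk from feature noise that is mutually
confounded across layers and with the residual. A direct Gaussian ML
oracle fitted to the uncensored true log-times with the exact kernels
recovers the ordering of $\sigma^2=(0.5,0.3)$ at $n=300$ in roughly 90% of
replicates - an information limit of the design, which the Gibbs posterior
means attain. The factor-bank defaults were dimensioned to sit at this
ceiling while keeping the PC structure realistic.

## Numerical choices

* Kernel eigenvalue truncation at $10^{-8}\lambda_{\max}$; kernel symmetry
  enforced to $10^{-10}$.
* Preprocessing: feature-mean imputation, variance filter at $10^{-8}$,
  centring, optional unit-variance scaling - generic stand-ins for
  platform-specific QC, which is out of scope.
* BH-FDR is the exact step-up with a monotone floor; quartile ties go to
  the lower quartile.
* All samplers take explicit seeds; identical configuration and seed give
  bit-identical outputs.

## Known limitations

* Breslow ties only in the Cox screening (Efron would differ with heavy
  ties).
* The log-normal survival model is parametric; no Cox-frailty or
  semiparametric alternative is provided.
* Gaussian omic-effect priors only (no Bayes A/B/C or LASSO shrinkage).
* Gene-level aggregation by max-|t| is anti-conservative for genes with
  many probes if used for between-gene comparisons of significance; the
  enrichment rank test is unaffected because it compares genes processed
  identically.
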