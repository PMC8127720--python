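# Methods

## The model

An epigenetic clock is a linear model on methylation beta values. For a
sample with beta values $\beta_j \in [0,1]$ at a selected set of CpG probes,

$$\widehat{\text{age}} = b_0 + \sum_j c_j\,\beta_j \qquad \text{(years)}.$$

No nonlinear age transform is applied anywhere in the package: the clock is
linear on the beta scale, and negative predictions are legitimate (fetal
samples carry negative ages, e.g. −1 y). The packaged beluga age clock has
23 probe coefficients plus the intercept (24 terms) and is reported with a
± band taken from its leave-one-out median absolute error (2.87 y by
default; a flag switches to the mean absolute error, 3.65 y).

Sex is imputed by a single-CpG logistic model at a Y-linked probe
(cg15451847): $p_\text{female} = 1/(1+e^{-(0.6717 - 1.1579\,\beta)})$, with
$p>0.5$ calling female and anything else (including exactly 0.5) male.
Because the probe detects the presence of a Y chromosome, the probability
decreases monotonically in beta.

## Clock construction

Training data are a sample × probe beta matrix, a matching detection-p-value
matrix, and per-sample age and sex. The pipeline is:

1. **Detection filtering.** A probe enters model fitting only if its
   detection p-value is < 0.05 in at least 10 samples (both thresholds are
   parameters). Missing p-values count as failures.
2. **Outlier QC.** Pairwise sample–sample Pearson correlations on shared
   probes summarize array quality; average-linkage clustering on distance
   1 − r is emitted for inspection, and samples whose mean correlation to
   the rest of the cohort falls more than `z_cut` (default 2) SDs below the
   cohort mean are flagged. The rule's parameters (linkage type, z-score
   cut) are this package's own construction, chosen for determinism; the
   decision of what to do with a flagged array is left to the analyst.
3. **Screening (descriptive).** Per-CpG Pearson correlations with age (or
   with sex coded female = 1, male = 0) are computed on pairwise-complete
   observations, ranked by |r| (ties broken lexicographically by probe id),
   and summarized in deciles of |r| with the percent of negative
   correlations per bin (bins lower-inclusive, |r| = 1 closing the top bin).
   The screen is reported, not used to pre-select features for the solver.
4. **Elastic net.** Coefficients minimize
   $(1/2n)\,\mathrm{RSS} + \lambda\,[(1-\alpha)/2\,\lVert b\rVert_2^2 +
   \alpha \lVert b\rVert_1]$ with an unpenalized intercept. Predictors are
   standardized internally (mean 0, population 1/n variance 1) and
   coefficients back-transformed; zero-variance predictors get coefficient
   0. λ is selected on a 100-point log-spaced path from
   $\lambda_{\max} = \max_j |\langle x_j, y-\bar y\rangle|/(n\alpha)$ down
   to $\lambda_{\max}\cdot r_{\min}$ ($r_{\min}$ = 0.01 when predictors
   outnumber samples, else 1e-4) by 10-fold cross-validation: folds are a
   seeded shuffle with sizes differing by at most one, the CV error is the
   unweighted mean of per-fold MSEs, and `lambda.min` is the grid value
   minimizing it, with exact ties resolved to the larger (sparser) λ.
5. **Alpha sweep and selection.** One clock is fitted per mixing value α
   (default grid 0.1–0.9 in 0.1 steps, extensible to 1.0). Candidates are
   ranked by an equal-weight rank sum of three criteria evaluated on LOOCV:
   smaller median absolute error, larger R², smaller |regression
   intercept| (a large intercept signals systematic overestimation of young
   animals). The full ranking table is emitted for audit; ties resolve to
   the smaller α.
6. **LOOCV.** For every sample the *entire* selection — λ path plus the
   internal 10-fold CV — is re-run on the other n − 1 samples and the
   held-out sample is predicted by that model. Accuracy is summarized as
   mae, medae, and an OLS regression of predicted on chronological age
   (R², slope, intercept), overall and within each sex. Training-set
   predictions, by contrast, come from the single lambda.min fit on all
   samples.

The sex model is fitted with the same machinery at α = 1 (pure LASSO) on
the binomial family: IRLS with an inner penalized weighted coordinate
descent, λ chosen by cross-validated binomial deviance. The λ path never
includes 0, so complete separation cannot push coefficients to infinity.

## Solver details

The solver is cyclic coordinate descent written for this package (the
reference implementation is used only as an independent cross-check in the
test suite). Numerical choices:

- **Convergence** is declared when the maximum absolute change of any
  standardized coefficient in a sweep is below `tol` (default 1e-7) — a
  scale-free criterion.
- **Screening.** Along the path, warm starts are combined with sequential
  strong rules; every grid point ends with a full KKT verification over all
  predictors (zero coefficients must satisfy $|g_j| \le \lambda\alpha$,
  nonzero ones the exact stationarity condition), and violators are added
  back and re-solved. Screening therefore never changes the solution.
- **Acceleration.** When plain sweeps stall (correlated predictors), the
  solver solves the stationarity system restricted to the current nonzero
  support and sign pattern directly and accepts the result only if the
  signs are preserved *and* the subsequent verification sweep moves no
  coefficient by more than `tol`. This collapses hundreds of zigzag sweeps
  into one linear solve without altering the fixed point.
- **Degenerate cases.** λ = 0 on rank-deficient designs falls back to the
  minimum-norm solution via the least-squares solve inside the
  acceleration step; ridge (α = 0) has no finite λ_max, so the caller must
  supply a grid; IRLS weights are floored at 1e-5.

## Synthetic cohorts

The generator emulates the statistical shape of a small wildlife
calibration study, with every parameter exposed:

| parameter | default | meaning |
|---|---|---|
| n_samples | 67 | cohort size |
| n_probes | 3000 | probes on the (down-scaled) array |
| n_age_informative | 40 | CpGs with a linear age trend |
| frac_negative_slope | 0.9 | fraction of informative CpGs losing methylation with age |
| slope magnitude | 0.002–0.01 /y | beta-units per year |
| noise_sd | 0.03 | per-entry Gaussian noise (beta-units) |
| n_sex_linked | 10 | near-binary sex-separated CpGs |
| ages | −1 to 49 y | right-skewed (scaled Beta(2, 2.5)), median ≈ 21 y |
| sex ratio | 36:31 | male:female |
| detection_failure_rate | 0.02 | independent per entry |

Ages come first from the seeded stream, so cohorts with different probe
counts share age draws. Informative probes are `baseline + slope·age`
with baselines placed so the linear trend stays inside [0, 1] across the
age range; background probes have Beta-distributed baselines and no trait
dependence; sex-linked probes have two well-separated levels with random
direction. Betas are clipped to [0, 1] (a warning fires if ≥ 1 % of entries
clip). Detection p-values are near zero for passing entries and
Uniform(0.05, 1) for failures.

The generator does **not** emulate array chemistry, batch effects, probe
cross-reactivity, tissue heterogeneity, or correlated detection failures.
Passing recovery tests therefore demonstrate that the pipeline recovers
linear age signal of realistic effect size under realistic noise — not
that it is robust to every artifact of real array data. The number of
probes (3000 vs tens of thousands on a real array) keeps the default test
and acceptance runs at desk scale; the informative fraction is chosen so
that the share of probes with |r| > 0.5 lands near the ~2 % seen in real
calibration data.

## Evaluation pitfalls worth knowing

**Pearson R² of LOOCV predictions is inflated on null data.** If every
leave-one-out model is null (intercept-only), the prediction for sample i
is the mean of the other n − 1 ages — a perfectly linear *decreasing*
function of the held-out age. The regression of predicted on true age then
shows a high R² with a tiny negative slope (≈ −1/(n−1)), despite zero
predictive skill. The no-skill checks in the test suite therefore use
out-of-sample skill, Q² = 1 − SSE_model/SSE_null with SSE_null from the
leave-one-out mean predictor, which is exactly 0 for the null model; the
regression R² is reserved for settings where real signal exists.

**lambda.min wanders on null data.** On pure-noise responses the CV error
curve is flat from λ_max down to the path entry point and noisy below it,
so the minimizing λ often drifts below the entry point (the reference
implementation behaves identically). The stable property — asserted in the
tests — is that the null model stays within one CV standard error of the
minimum, i.e. a 1-SE rule would select it.

## Known limitations

- Probes with more than 20 % missing betas in a training cohort are
  excluded from fitting; remaining missing entries are mean-imputed within
  the training subset. Applying a fitted clock never imputes silently:
  missing clock probes are an error unless cohort-mean imputation is
  explicitly requested (with a warning).
- The interarray outlier rule is a deterministic z-score heuristic, not a
  replacement for inspecting the dendrogram.
- The LOOCV fold seeds derive from the top-level seed and the held-out
  sample id, so results are invariant to row order; they are not invariant
  to renaming samples.
- Ridge-path automation (α = 0) and families beyond gaussian/binomial are
  out of scope.
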