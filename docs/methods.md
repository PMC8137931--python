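# Methods

## Model

The hydrotime model treats germination as a threshold process. Seed *i*
has a base water potential ψb,i drawn from Normal(ψb₅₀, σψb); in a medium
of water potential ψ it germinates at the continuous time

t_i = θH / (ψ − ψb,i)   if ψ > ψb,i, and never otherwise,

where θH > 0 (MPa·day) is a hydrotime constant shared by the population.
Writing ψb(g) = ψb₅₀ + σψb·Φ⁻¹(g) for the threshold of population fraction
g gives the percentile form θH = (ψ − ψb(g))·t_g, the linear rate relation
GR(g) = (ψ − ψb(g))/θH, and the cumulative fraction
F(t; ψ) = Φ((ψ − θH/t − ψb₅₀)/σψb).

Assumptions: θH constant across seeds and percentiles (the rate lines are
parallel); thresholds normal; temperature fixed at the species' optimum so
no thermal-time interaction; no dormancy or seed deterioration over the
assay. Units are MPa and days throughout. The model's printed percentile
identity is implemented in the dimensionally consistent Gummerson form
θH = (ψ − ψb(g))·t_g, which the rate equation implies.

## Synthetic experiments

The simulator reproduces the structure of a PEG-osmoticum assay:
ψ ∈ {0, −0.8, −1, −1.6} MPa, four replicate dishes per ψ, 40 viable seeds
per dish, scoring every 2 days for 80 days. These defaults are the
experimental design of the reference study on nine *Festuca pallescens*
populations whose published parameter triples ship as a fixture; they are
also, deliberately, the conditions under which all recovery results below
are computed. Germination is interval-censored: an event in (day_{k−1},
day_k] is counted at day_k, so the count at a scoring day is exactly the
number of seeds with continuous time ≤ that day — the same convention the
fitter's CDF predictions use, which removes any half-interval bias by
construction. One integer seed deterministically spawns per-dish
substreams (`numpy.random.SeedSequence`), so individual dishes are
reproducible.

When viability < 1, the sown count is inflated to seeds/viability and the
realised viable count is binomial; dead seeds are carried in an `n_dead`
column but never enter fractions (fractions are of viable seeds, the
convention of tetrazolium-normalized scoring). Records are emitted for the
full duration; the observational stopping rule sometimes used in practice
(stop after several event-free days) is not applied, keeping records
rectangular and reproducible. Not emulated: dormancy loss, after-ripening,
temperature effects, PEG-solution degradation between changes, and
plate-level random effects beyond binomial sampling — so passing recovery
tests demonstrate statistical correctness of the estimator under the
model, not robustness to real-world model violations.

## Estimation

Three stages, the first two serving as the warm start of the third.

1. **Gompertz smoothing.** Each dish's cumulative fraction is fitted with
   G(t) = A·exp(−exp(−k(t − T_i))) by bounded least squares
   (`scipy.optimize.curve_fit`, A ≤ 1, k, T_i > 0). Starts are data-driven:
   A = final fraction, T_i = first day reaching half of final,
   k = 4/(t₉₀ − t₁₀) floored at 0.05. The three-parameter Gompertz was
   chosen for its analytic inverse t(g) = T_i − ln(−ln(g/A))/k. Percentiles
   g ∈ {0.05, …, 0.90} (step 0.05) are fractions of viable seeds;
   percentiles at or above A are "not reached" (NaN) and non-positive
   inverted times are likewise dropped.
2. **Rate regression.** For each g, GR(g) = 1/t(g) is regressed on ψ (OLS);
   the ψ-axis intercept is ψb(g). The mean slope across positive-slope
   lines gives θH = 1/slope with a coefficient-of-variation diagnostic for
   parallelism (no automatic exclusion of non-parallel lines). ψb₅₀ is the
   g = 0.5 line's intercept and σψb the slope of ψb(g) on Φ⁻¹(g).
   Note the Gompertz sigmoid is not the hydrotime CDF shape, so this stage
   carries a small systematic bias even on noise-free data (θH within a
   few percent, ψb(g) off by MPa-scale amounts at the extreme low
   percentiles where the Gompertz tail extrapolates poorly). It is
   reported for diagnostics and used as a warm start, not as the final
   estimate.
3. **Nonlinear least squares.** Per replicate (dish k pooled across all ψ
   levels — index pairing, the only rule available when dishes are not
   physically tracked across media), minimize
   Σ (y_obs − Φ((ψ − θH/t − ψb₅₀)/σψb))² over the triple with θH, σψb > 0
   (`scipy.optimize.least_squares`, trf, ftol = xtol = gtol = 1e−10,
   ≤ 10⁴ evaluations; deterministic given data and start; inputs are
   sorted internally so results are invariant to input order). The
   objective is on the fraction scale through the CDF rather than on
   probit-transformed fractions, so y ∈ {0, 1} needs no clipping.
   Post-plateau observations are retained — the plateau level is what
   identifies σψb. Fit quality is R² = 1 − SSres/SStot of observed vs
   predicted fractions pooled over all ψ and days. The fallback start
   (20, −2.5, 0.6) is mid-range of the packaged reference estimates.

Population summaries are replicate means with sample SD (ddof = 1; 0 when
n = 1) and SE = SD/√n. The packaged reference table's ± values are stored
as "dispersion" without committing to SD vs SE, which their source does
not state.

Verification: on noise-free model-generated curves the NLS recovers all
nine reference triples to < 1e−3 relative error with R² > 0.9999; on one
small replicate its optimum matches an exhaustive 0.01-step grid search
over θH ∈ [5,40] × ψb₅₀ ∈ [−4,−1] × σψb ∈ [0.2,1.2]; and a
probit-linearization fit over a θH grid agrees within 10% on θH and
0.15 MPa on ψb₅₀. A Monte-Carlo study at the reference design (200
experiments per parameter set, experiment estimate = mean of the four
replicate fits) shows the estimates unbiased, with |ψb₅₀ error| < 0.3 MPa
and θH relative error < 15% in well over 80% of runs; 200 replicates per
set keeps the whole study at about two minutes on one CPU while making the
95% Monte-Carlo interval stable.

## Population comparisons

- **Heteroscedastic ANOVA**: Welch's one-way ANOVA (pingouin), chosen as
  the closest standard, citable "ANOVA with heterogeneity of variances";
  pairwise Games–Howell comparisons at α = 0.05 feed a compact letter
  display computed as the maximal cliques of the non-significance graph,
  which guarantees two groups share a letter iff their pairwise test does
  not reject. Separate ANOVAs per parameter, no multiplicity correction
  across the three parameters. Welch's statistic carries an O(1/n)
  denominator correction, so it equals the classical F under equal
  variances only asymptotically.
- **Environmental regressions**: simple OLS of each parameter on each
  numeric environment variable (annual precipitation, precipitation
  seasonality, autumn and spring precipitation), r² = squared Pearson
  correlation. The environment table is user-supplied; none ships with
  the package.
- **PCA** on the correlation matrix (standardized variables), eigenvalues
  summing to the number of variables. The CLI's variable set is the four
  precipitation variables plus mean θH — five standardized variables, the
  natural "environment + the one parameter that differs" choice.
- **Clustering**: UPGMA on Euclidean distances over standardized numeric
  variables; categorical soil/floristic descriptors enter as 0/1 one-hot
  columns (already unit-range). Output is a Newick string whose branch
  lengths are differences of merge heights (ultrametric), since scipy has
  no Newick writer.

## Numerical and degenerate-input choices

- ψ ≤ ψb(g) yields infinite germination time (a sentinel, not an error) and
  zero rate; t ≤ 0 yields zero cumulative fraction.
- R² is an error when observations are constant (zero total sum of squares).
- Single-ψ score sheets are rejected as non-identifiable before fitting.
- Dishes with zero germination are skipped by the Gompertz stage; a whole
  replicate with zero germination is a fitting error.
- Fixed percentile grid and convergence tolerances favour bit-for-bit
  reproducibility over speed.

## Limitations

- Estimates inherit the model's assumptions; no goodness-of-fit test
  against alternative threshold distributions is provided.
- No bootstrap or profile-likelihood confidence intervals — dispersion is
  replicate-level only, as in the fitted-parameters summaries.
- The stage-1/2 estimator is a warm start, not a publication-grade
  estimator; its extreme-percentile ψb(g) values should not be interpreted.
- The compact letter display is exact but can need many letters for
  intransitive non-significance patterns.
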