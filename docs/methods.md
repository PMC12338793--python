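# Methods

## Pharmacy-desert definition

A census tract is classified as a pharmacy desert when it meets both of:

* **Low income** — ≥ 20% of the population below the Federal poverty level,
  *or* median household income below 80% of the median income of the
  tract's metropolitan statistical area (MSA).
* **Low access** — at least one third of the population living at or beyond
  the urbanicity-specific accessibility radius from the nearest open retail
  pharmacy: 1 mile for urban tracts (density > 5,000 per sq mi), 5 miles for
  suburban (1,000–5,000, inclusive at both ends), 10 miles for rural
  (< 1,000). A vehicle-ownership exception also marks a tract low-access
  when fewer than 100 individuals own a car and ≥ 1/3 of the population
  lives 0.5 miles or more from the nearest pharmacy; the assessment records
  `radius_used = 0.5` when only this exception fired.

A secondary *distance-only* mode classifies on the access criterion alone.

The access share is computed by areal interpolation at the block level:
each block centroid is tested against the radius, and the within-radius
fraction is the population of blocks strictly inside divided by the tract
population. Boundary conventions, all exercised by tests: "inside" means
distance < radius (a tract population living exactly at the radius counts
as beyond, matching the "x miles or more" phrasing); the one-third
threshold is exactly 1/3, not 0.33; zero-population blocks carry no weight;
tracts with zero population or missing income are excluded before
classification and counted in the run manifest.

Other categorisations:

* **Segregation** — the racial/ethnic group (non-Hispanic White, Black,
  Hispanic, Asian, AIAN) holding a *strict* majority (> 50%); exactly 50%
  or no majority ⇒ "Integrated".
* **DDI** — cohort-relative quartile bands of the 0–100 digital divide
  index: below Q1 "low", [Q1, Q3) "moderate", ≥ Q3 "high". Cut points use
  the lower order statistic (so 1..100 splits 1–24 / 25–74 / 75–100 and the
  bands are invariant under rank-preserving transformations); a tertile
  split would be an alternative reading of a three-way quantile rule, but
  the quartile split keeps a genuinely "moderate" interquartile band.
* **Redlining (RRI)** — mortgage-denial odds ratio vs the MSA: < 0.7
  "low", [0.7, 1.3) "neutral", ≥ 1.3 "high" (upper bound inclusive in
  "high"). A missing RRI is a retained category, not a dropped
  observation: missingness is common (the default generator makes it 39% of
  tracts) and informative, so listwise deletion would both discard most of
  a cohort and bias the comparison. In regressions "missing" enters as its
  own level with "neutral" as the reference.

## Distance computation

Planar coordinates are Euclidean miles; the haversine mode treats
coordinates as (lon, lat) on a sphere of mean radius 3,958.8 miles for
real-world data. Nearest-pharmacy queries use a k-d tree
(`scipy.spatial.cKDTree`); equivalence with the exhaustive scan is asserted
by tests to within last-ulp floating-point rounding, not assumed. An empty
(or fully closed) pharmacy set yields a +infinity sentinel so every access
fraction resolves to "all beyond".

## Synthetic cohorts

The generator emulates the structure of a merged tract/block/pharmacy
extract: tracts tile a rows × cols grid of squares (default 20 × 20 of
1-mile squares), each containing `blocks_per_tract` blocks on a jittered
sub-grid with populations drawn multinomially from the tract total (so
block populations sum exactly to the tract population). Four RNG streams
(geometry, covariates, pharmacies, labels) are spawned from the master
seed, so editing one configuration block leaves unrelated draws unchanged;
identical (config, seed) pairs reproduce byte-identical output files.

Covariate marginals default to values typical of US tracts: population
log-normal (median 3,743, log-sd 1.0 — giving a mix of urban, suburban and
rural densities on 1-square-mile tracts), median income log-normal (median
$62,557, log-sd 0.45), DDI centred at 18.8 with scale 7.4 and components
centred at 17.5 / 11.5, poverty share logit-normal around 12%, RRI
log-normal centred slightly above 1 so the low/neutral/high bands are all
populated, and race/ethnicity drawn from a Dirichlet whose concentration
spikes on a randomly chosen majority group (White 55%, Black 9%, Hispanic
11%, Asian 1.2%, AIAN 0.8%, Integrated 23%), so all six segregation
categories occur, including the rare AIAN stratum. A shared
neighbour-averaged Gaussian "deprivation" field correlates DDI, income,
poverty and RRI and gives every covariate spatial autocorrelation (3
smoothing passes by default), which is what makes the Moran diagnostics
meaningful on synthetic data.

* **Geometry mode** places pharmacies by an inhomogeneous Poisson process
  whose per-tract intensity depends on the DDI quartile stratum (defaults
  1.0 / 0.5 / 0.12 expected pharmacies per tract for low / moderate / high
  DDI), so desert status *emerges* from the layout and is associated with
  the digital divide. The cohort's truth labels are computed inside the
  generator by an exhaustive block-pharmacy distance scan that re-states
  the classification rules in straight-line code and shares nothing with
  the classifier modules; agreement between the two is a test, not a
  construction.
* **Label mode** draws the desert indicator from a Bernoulli with logit
  equal to `intercept + Σ coefficient × dummy` over the encoded covariates
  (DDI category, redlining category, segregation, urbanicity, and
  upper-quartile binary flags for low education, uninsurance and ambulatory
  disability). The shipped default coefficient vector mirrors published
  adjusted odds ratios where they are printed (e.g. high-vs-low DDI
  log 6.94). `generate_label_table` produces the same table as the
  object-building path (tested identical) without materialising 50,000
  dataclass instances, which keeps large simulation studies fast.

What the generator does **not** emulate: real tract geometries (all tracts
are equal squares), road networks or travel times (straight-line distance
only, as in the underlying desert definition), correlation between tract
area and population, inter-MSA migration of pharmacy supply, and any
reconstruction of the DDI or RRI from their raw broadband/mortgage
sources — both indices are generated directly as bounded scores. Passing
tests therefore validate the *rules and estimators*, not national desert
counts; reproducing published national prevalence would require the real
pharmacy/Census/ACS extracts, which ship no accession.

## Association analysis

The desert indicator is fitted by maximum-likelihood logistic regression
(`statsmodels`), with Wald 95% CIs exponentiated to the OR scale (Wald
rather than profile likelihood because the reported intervals are symmetric
on the log scale; the design object is user-configurable). Perfect or
quasi-separation is flagged (`convergence=False` with a diagnostic) rather
than raised. Multicollinearity uses VIF_j = 1/(1 − R²_j); exact
collinearity reports an infinite VIF. The default design dichotomises
education/insurance/disability at the cohort upper quartile; this cut is
configurable and makes no claim to match any particular published encoding.

**E-values.** ORs for a non-rare outcome are converted to approximate risk
ratios by the square root (protective ORs inverted first), then
E = RR + √(RR·(RR−1)). Reported E-values are rounded *toward 1* at two
decimals: a conservative convention under which the stated strength of
confounding needed to explain an association is never overstated.

**Spatial diagnostics.** Moran's I is computed on the model-predicted odds
p̂/(1−p̂) (a probability scale is available) with
I = (n/W)·Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)², null expectation −1/(n−1), and a
two-sided permutation p-value using the add-one rule (default 999
permutations, seeded). Weights default to row-standardized k-nearest-
neighbour with k = 8; rook and queen grid contiguity are available.
Contiguity schemes are symmetric by construction; knn neighbour sets are
kept asymmetric (standard practice) with distance ties broken toward the
lower index. Isolated units keep a zero weight row. This is a diagnostic
only — no spatially-correlated-error model is fitted, mirroring the
ordinary-logistic-plus-Moran design the package implements.

**Descriptive table.** Continuous variables: median (IQR), Wilcoxon
rank-sum. Categorical: n (%), chi-square, switching to Fisher's exact test
for 2×2 tables when any expected cell is below 5 (for larger sparse tables
the chi-square is retained with a note, since no exact r×c test is
available in the stack). Display percentages use the mixed-precision rule
(integer at ≥ 10%, one decimal below, "<0.1%" under 0.1%); machine output
keeps raw values at two decimals via half-up rounding.

## Problem sizes and numerical choices

Deterministic validation uses 20 seeded geometry cohorts of 400 tracts ×
3,600 blocks (classifier vs oracle, every tract). Stochastic calibration
uses 200 label-mode replicates of 50,000 tracts for the high-DDI
coefficient (mean OR within 2% of the generating value 6.94; CI coverage
within [0.92, 0.98]). Moran null checks use a 50 × 50 rook grid. Logistic
fits run Newton iterations to statsmodels defaults with maxiter 200;
degenerate inputs (single-class outcomes, constant vectors, zero-variance
predictors, all-equal DDI) raise typed errors rather than returning
numbers.

## Known limitations

* Square-grid geography cannot probe edge effects of irregular tract
  shapes or population-weighted centroid choices (synthetic blocks carry
  their own centroids, absorbing that distinction).
* E-values use the square-root OR conversion throughout; for genuinely
  rare outcomes the direct RR formula would be less conservative.
* The Fisher fallback is limited to 2×2 tables.
* CI coverage statements are Wald-based and degrade near separation; the
  package flags but does not penalise (e.g. Firth-correct) such fits.
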