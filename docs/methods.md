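# Methods

## Interval mass balance

Both reactor configurations are idealised as completely stirred tank reactors:
the measured suspension concentration is the outflow concentration. For an
analyte sampled at consecutive dates the estimator combines the observed
storage change with trapezoidal approximations of the dilution fluxes:

pr = ΔC_OUT/Δt + mean(C_OUT)/HRT − mean(C_IN)/HRT.

For the linear CSTR dC/dt = (C_IN − C)/HRT + p with constant p and C_IN this
is exact for linear trajectories and second-order accurate otherwise; the test
suite verifies bias < 2% of p at a sampling interval of HRT/10 and
< 2% on 0.5-day sampling of the exponential transient. The sign convention is
production-positive; removals are reported as rr = −pr. Intervals missing an
analyte at either endpoint are skipped with a warning — imputing
concentrations into a mass balance silently biases rates. When an event lacks
its interval HRT the campaign mean is substituted, with a warning.

Removal efficiency η = (C_IN − C_OUT)/C_IN × 100 is computed per sampling
instant; campaign summaries report both the mean of per-instant values and
the efficiency of period means, since the two differ under variable influent.

Free ammonia uses the Anthonisen (1976) speciation,
FA = (17/14)·TAN·10^pH/(exp(6344/(273+T)) + 10^pH), on the NH₃-mass basis by
default (`basis="NH3-N"` divides out the 17/14). FA is strictly increasing in
pH and temperature and bounded by (17/14)·TAN; both properties are
property-tested. Free ammonia is evaluated at sampling instants only, not on
interpolated series.

Biomass-productivity stability is the rolling sample standard deviation
(n−1 denominator) of three consecutive prVSS values (previous, current,
next). Paired reactor comparisons use two-sided paired t-tests on rate series
aligned at the intersection of interval endpoints; unmatched dates are
dropped and counted. Nitrogen analytes are carried on the N-mass basis
(mg N L⁻¹) throughout.

## qPCR quantification

Standard curves are ordinary least squares of Ct on log₁₀(copies) over the
ten-fold ladder (10¹–10⁸ copies µL⁻¹); amplification efficiency is
10^(−1/slope) − 1, warning outside [0.8, 1.2]. Unknowns are inverted
per replicate and averaged **on the copy scale** (copies are the quantity of
interest; Ct averaging, the geometric analogue, is available for comparison),
with the replicate CV reported and an extrapolation warning outside the
ladder's Ct range. Copy-to-cell conversion uses 4.2 rRNA operons per cell
(16S, total bacteria) and 2 amoA copies per cell (AOB); other targets require
an explicit constant. CSAOR converts prNOₓ (mg N L⁻¹ d⁻¹) to
fmol NH₄-N cell⁻¹ h⁻¹ via the nitrogen molar mass 14.007 g mol⁻¹ and the AOB
density (cells g VSS⁻¹ × g VSS L⁻¹); negative prNOₓ is clipped to zero with a
warning, and no default biomass is assumed when VSS is missing.

## Community statistics

Relative abundances are normalised per sample over **all** counts (classified
plus unclassified), aggregated to the requested rank by summing, and a taxon
is "dominant" when it exceeds the threshold in **at least one sample**
(transient blooms count; a campaign-mean criterion is available). The
aggregate-then-threshold order is fixed and guard-tested against the
alternative. Richness counts OTUs with non-zero counts per sample and pooled.
Shared-OTU partitions between reactors match by OTU id by default (requires a
common clustering space) or by taxon name at a rank; the identity
shared + onlyA + onlyB = total is property-tested.

Community shifts are detected by UPGMA (average-linkage) clustering of
Bray–Curtis dissimilarities combined with Clarke's similarity-profile
(SIMPROF) permutation test, re-implemented here: at each dendrogram node the
sorted dissimilarity profile of the member samples is compared with the mean
sorted profile of variable-wise permutations (999 by default, seeded);
π = Σ|d₍ₖ₎ − mean₍ₖ₎|, p = add-one-corrected upper-tail fraction of a second
permutation set. Recursion proceeds top-down into significant nodes and stops
at non-significant ones, whose leaves form one homogeneous group; nodes with
fewer than three samples are untested groups. The test permutes the raw
profile variables, never the distances. Its type-I error on exchangeable null
data is verified ≤ α + 2 MC standard errors over 200 runs.

Environmental covariates are averaged over the 7 days preceding each sampling
time (partial windows at campaign start are used and their day-count
reported). Taxon–environment screening uses tie-corrected Kendall tau-b with
two-sided p-values; cells at p ≥ 0.05 are masked. P-values are raw by
default — mirroring simple per-cell screening conventions — with an optional
Benjamini–Hochberg mode (off by default). Constant vectors are flagged, not
dropped.

## Bipartite co-occurrence networks

Association between each dominant bacterium and eukaryote is scored over the
shared sampling dates with four measures: Pearson, Spearman, Bray–Curtis and
symmetrised Kullback–Leibler divergence. KL is computed after adding a
pseudocount (default 10⁻⁶ on relative abundances) and renormalising, since
raw zeros make it undefined. Each method's null is built from sample
permutations of one vector (1000 iterations); p is the two-sided
add-one-corrected fraction of null scores at least as far from the null mean
as the observation. Bootstrap resampling of sampling dates (1000 iterations)
gives a 95% percentile interval; a method supports an edge only when that
interval excludes the null centre (ReBoot-style screening). An edge enters
the network when ≥ 2 supporting methods agree in direction (configurable);
discordant support drops the edge. Positive association (high correlation or
low dissimilarity) is a co-occurrence edge, negative a mutual exclusion.

Indices: density 2E/(N(N−1)); average degree 2E/N; degree heterogeneity as
the coefficient of variation of degrees (population sd) — a quantitative
proxy for "hubbiness"; Freeman degree centralization Σ(k_max − k_i)/((N−1)(N−2));
modularity of the best greedy agglomerative partition (deterministic
tie-breaking; exhaustive partition search is the test oracle at ≤ 7 nodes,
where greedy is verified to attain the optimum on bridged two-clique graphs);
diameter and average path length on the largest connected component,
disconnected pairs being ignored — a single path length over a highly
fragmented graph is only meaningful per component. The identity
interaction = co-occurrence + mutual exclusion is property-tested.

## Synthetic campaign generator

The generator defines the study conditions under which everything is tested:

- **Forcing**: daily seasonal sinusoid peaking at day 45 (early summer) with
  AR(1) noise, 188-day horizon, May-to-November temperature (19 ± 8 °C annual
  swing) and irradiance (200 ± 130 W m⁻²) shapes.
- **Reactor**: CSTR with HRT 11 d; influent centrate diluted 1:5
  (≈250 mg NH₄-N L⁻¹, with COD/P/NO₃ analogues), with an optional step to 1:3
  at day 143 in the raceway scenario. State variables NH₄-N, NO₂-N, NO₃-N,
  PO₄-P, sCOD, VSS; algal growth is Monod in N and P times saturating light
  and Gaussian temperature factors; nitritation is Monod in NH₄; nitratation
  is Monod in NO₂ inhibited by free ammonia through a Hill term
  K²/(K² + FA²) with K = 2 mg NH₃ L⁻¹ — the squared form gives the sharp
  on/off contrast between the pH 8.5 (column) and pH 7.2 (raceway) regimes.
  Decay remineralises biomass N and P, so the nitrogen budget closes exactly;
  the integrator (fixed-step RK4, 0.05 d, step-halving on negativity)
  conserves it to ~10⁻¹² relative, which the tests assert. Instantaneous true
  net production rates are stored beside the states for estimator validation.
  pH is a prescribed regime, not a solved state. All kinetic constants are
  order-of-magnitude literature-style placeholders — the campaign tables
  constrain none of them — chosen once so that the two presets reproduce the
  qualitative regime split (nitrite-accumulating column vs fully nitrifying
  raceway, TAN removal ≈ 70–80%, prVSS of tens of mg L⁻¹ d⁻¹), and labelled
  as such.
- **Community**: 8 microalgae, 10 bacteria, 2 ciliate grazers (small enough
  for exhaustive network oracles), each with Gaussian responses to
  temperature, irradiance, N species and pH; daily multiplicative update with
  grazers gaining from microalgal share and prey losing to grazer share; a
  10⁻⁵ immigration floor prevents extinction. The trajectory is deterministic
  given the forcing — stochasticity enters only at read sampling — so rank
  assertions (warm-specialist dominance windows, grazer–prey negative
  association) hold exactly.
- **Observation**: ~biweekly sampling (11 dates, 16-day interval);
  multiplicative lognormal measurement noise (cv 0.05, mean-one
  parameterisation); multinomial reads (depth 20 000) per marker; TSS
  reported as VSS/0.8. All draws come from a single seeded generator; outputs
  are bit-reproducible under a fixed seed.

What the generator does **not** emulate: real digestate chemistry (no CO₂ or
pH dynamics), spatial structure, sequencing artefacts (chimeras, copy-number
variation between taxa, compositional overdispersion beyond multinomial),
taxonomic misassignment, or OTU-space mismatch between campaigns. Passing
tests therefore demonstrate the correctness of the estimators and statistics
under their own model assumptions, not robustness to those real-data
complications.

## Numerical choices and degenerate inputs

- Permutation p-values are add-one corrected ((r+1)/(n+1)), so they are never
  zero and the extreme-tail bound p ≤ 1/(n+1) is attainable.
- Sample standard deviations use n−1 except degree heterogeneity (population
  sd, a distribution shape measure).
- Zero-variance vectors: correlations are skipped/flagged rather than
  propagated as NaN into screens or networks.
- Zero influent concentration makes efficiency undefined (error, not NaN);
  all-zero samples are rejected before Bray–Curtis or normalisation.
- Identical paired series short-circuit to t = 0, p = 1 (the t-test is
  otherwise 0/0).
- BIOM v1.0 (JSON) tables are read and written directly — the format is plain
  JSON — alongside TSV; writers and readers round-trip exactly.

## Problem sizes used in the validation suite

Monte-Carlo checks use 200 null runs × 999 permutations for SIMPROF
calibration, 20 seeds for noisy rate-recovery bias, 1000–2000 iterations for
network permutation/bootstrap agreement with exhaustive enumeration at n = 6
samples, and exhaustive graph oracles up to 7 nodes / Bell-number partition
search — sizes at which every oracle is exact and the whole suite runs in
well under a minute per module.
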