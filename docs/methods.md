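# Methods

## Data model

The unit of observation is a checklist record: a species seen in an area
in one of two survey periods, *historical* or *current*. Records carrying
a survey year instead of a period label are mapped by the rule
year < 2000 → historical, year ≥ 2000 → current; the boundary year itself
is assigned to the current period (the two ranges overlap in published
descriptions of such designs, so the tie had to be broken — it is broken
once, here, and documented). Records collapse to a binary area × species
incidence matrix per period; multiple sources for the same area and
period are reconciled by union, the only defensible rule when abundances
are absent. The species axis is sorted lexicographically so the matrix is
invariant to record order.

Name normalization trims and collapses whitespace but never case-folds
(capitalization is meaningful in binomials) and never fuzzy-matches;
synonyms are resolved only through an explicit user-supplied table, which
must be single-step (chains and cycles are rejected) so that applying it
twice equals applying it once.

Species attributes — order, family, native/introduced origin, three
ecological-type axes (life habit: migration / settlement / mountain
stream; feeding: carnivorous / herbivorous / omnivorous; water layer:
upper / lower / demersal), and a red-list class — are consumed as input
labels. Checklist species absent from the attribute table are treated as
native with unknown ecotypes and excluded from ecotype summaries;
attribute rows for unlisted species are allowed. Both cases warn rather
than fail, because basin checklists and trait compilations are maintained
by different people and rarely align perfectly.

## Extirpation accounting

Per area, a native species counts as extirpated when present historically
and absent currently; the extirpation percentage is 100 × extirpated /
historical natives, and the introduction percentage takes the *current
total assemblage* (current natives + established exotics) as denominator —
the only convention consistent with all published per-area values we
checked against. Percentages are rounded half-up to one decimal through a
single shared helper, so every report rounds identically. The basin-level
"mean extirpation per area" is the unweighted arithmetic mean of per-area
percentages. Ecotype losses are basin-wide: a species counts as lost only
when absent from *every* area currently, which is what single
per-category loss percentages imply.

## Beta-diversity partition

The pairwise Sørensen dissimilarity β_sor = (b+c)/(2a+b+c) is partitioned
into spatial turnover β_sim = min(b,c)/(a+min(b,c)) and nestedness
β_sne = |b−c|/(2a+b+c) · a/(a+min(b,c)). The nestedness formula uses the
absolute difference |b−c| rather than the signed b−c sometimes printed:
the signed form is order-dependent, can be negative, and breaks the
additive identity β_sor = β_sim + β_sne, which the absolute form restores
algebraically (verified to 1e−12 for every computed pair). Degenerate
pairs with one empty assemblage are treated as the limit of a vanishing
subset — β_sor = 1, β_sim = 0, β_sne = 1 — with a warning; two empty
assemblages are an error.

Group summaries come in two modes, because "mean ± SD per area" is
ambiguous when each area is a single sampling unit: (i) *area-focal* —
for each area, mean and SD over the n−1 pairs involving it, with a grand
mean defined as the unweighted mean of per-area means; (ii) *subset* —
the partition recomputed on a species subset (one family, natives only,
exotics only) and summarized over all pairs, after dropping areas where
the subset is entirely absent. SDs are sample SDs (ddof = 1). Neither
mode is claimed to reproduce any particular published table, whose
sampling units are not documented.

## Ordination

PCoA Gower-centres the squared dissimilarities, B = −½ J D² J, and
eigendecomposes B (LAPACK `eigh` via scipy). Coordinates are
eigenvector · √eigenvalue on the positive axes; variance fractions are
taken over positive eigenvalues only. Sørensen-family dissimilarities are
generally non-Euclidean, so negative eigenvalues are expected: the
default is to report their share of total absolute eigenvalue mass rather
than correct for them, with the Lingoes additive constant available by
flag. Axis signs are canonicalized (largest-magnitude loading positive)
so repeated runs and alternative eigensolvers agree; two axes are
retained by default, matching the planar ordination plots such studies
publish. Eigenvalues within 1e−10 of zero are treated as null.

## Mantel tests

The statistic is the Pearson or Spearman (midrank-tied) correlation of
the two upper triangles; the null permutes rows and columns of the second
matrix jointly; p = (k+1)/(n_perm+1). Default settings are Spearman,
9,999 permutations, and a **two-sided** tail: published driver tables in
this design report significant *negative* correlations, which a
one-sided "greater" test cannot yield, and the tail convention is
otherwise undocumented. Scalar drivers (drainage area, annual runoff)
become matrices of pairwise absolute differences; measured distance
matrices pass through directly. No multiple-testing adjustment is applied
across the driver grid by default (a Holm option exists). Each grid cell
draws its own child seed from the run seed and records it.

## Chao richness and completeness

Checklist data are presence/absence, so the incidence framing is the
default: with Q1/Q2 the numbers of species found in exactly one/two
sampling units, the classic estimator is S_obs + Q1²/(2Q2), falling back
to the bias-corrected S_obs + Q1(Q1−1)/(2(Q2+1)) when Q2 = 0; the
abundance framing uses the same formulas on singletons/doubletons and is
exposed through the same functions. Completeness is S_obs / estimate.
Confidence intervals are percentile bootstrap over sampling units, 100
replicates at 95% by default. Rarefaction interpolates expected richness
with the hypergeometric formula S(t) = S_obs − Σ_i C(T−Y_i, t)/C(T, t)
(computed with log-gammas) and extrapolates via the Chao-based asymptote,
capped at twice the observed effort with a warning — the standard
practical bound for asymptotic estimators. In the pipeline the areas act
as the sampling units for basin-level completeness; per-area completeness
requires sub-area survey structure the checklist format does not carry.

## Synthetic metacommunity generator

The generator is the package's validation instrument: it produces
two-period datasets with known ground truth at the scale of a six-area
basin checklist (pool of 212 species, per-area expected historical
richness spanning roughly 83–181, nine introduced exotics).

Historical ranges mix two mechanisms per species. With probability
1 − w (w = `turnover_weight`) the species is *nested*: it occupies every
area whose gradient threshold exceeds a uniform draw, so ranges are
prefixes of the areas ranked by richness and all assemblages are perfect
subsets of one another (at w = 0, β_sim is exactly 0 for every pair).
With probability w the species is a *turnover* species occupying a
contiguous window (default width 0.35 of the axis) centred uniformly on a
one-dimensional waterway axis, guaranteeing at least its nearest area.
The per-area gradient thresholds are calibrated so the mixture's expected
per-area richness equals pool × `richness_gradient` regardless of w
(clipped where infeasible). The default w = 0.2 produces the
nestedness-dominated regime typical of heavily dammed river–lake systems.

The current period deletes each native species *wholesale* with a
probability combined across its ecotype categories as 1 − Π(1 − p_cat)
over the categories present in `extirpation_prob` (default: migration
0.367, mountain stream 0.325, settlement 0.158 — migratory fish are the
most exposed when connectivity is lost). An optional independent per-area
thinning probability (default 0) creates additional local extirpations
without global loss. Introduced exotics (default 9) appear only in the
current period, in 1–3 random areas each. Geographical drivers are
|Δposition| along the waterway axis plus per-area drainage-area and
runoff scalars of realistic magnitude. All draws come from one seeded
generator in a fixed documented order (attributes → ranges →
extirpations → introductions), so output is bit-identical per seed.

What the generator does *not* emulate: river-network topology (the axis
is one-dimensional), abundance dynamics, invasion spread, detection
error, or correlated traits. Tests passing on synthetic data therefore
demonstrate the correctness and calibration of the statistics, not claims
about any real fauna.

## Problem sizes and numerical choices

The default analysis operates on 6 areas (15 pairs), a 212-species pool,
9,999 Mantel permutations and 100 bootstrap replicates; the test suite
uses 50 seeds per condition for parameter-recovery checks, 200 replicates
for type-I-error and bootstrap-coverage calibration, and 10,000 draws for
Monte-Carlo rarefaction and exact-enumeration Mantel oracles — sizes at
which the binomial tolerance bands in the tests are tight enough to be
informative. Dissimilarity symmetry is enforced at 1e−12, PCoA
reconstruction is validated at 1e−8, and the partition identity at 1e−12.

## Known limitations

- The partition is strictly pairwise; multiple-site (simultaneous n-area)
  beta metrics and abundance-based decompositions are out of scope.
- Percentile (not BCa) bootstrap intervals; at 100 replicates they are
  coarse, matching the procedure they emulate rather than best practice.
- The extirpation report assumes current natives are a subset of
  historical natives per area; apparent colonizations are counted in the
  current total and flagged with a warning rather than modelled.
- No significance testing of ordination group separation (PERMANOVA /
  ANOSIM) — the ordination is descriptive.
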