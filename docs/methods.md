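# Methods

## The index model

The package scores each anuran species from three categorical traits and
aggregates species scores into a per-site biotic-integrity index.

**Sub-scores.** A scoring scheme maps each trait axis to non-negative
integer scores that strictly increase across successive categories. Under
the default (five-ecozone) calibration:

| score | DBS (distribution)            | TBS (Red List) | SBS (sensitivity)              |
|------:|-------------------------------|----------------|--------------------------------|
| 0     | —                             | LC             | wide-range generalist          |
| 1     | present in 4–5 ecozones       | NT             | few disturbed microhabitats    |
| 2     | present in 2–3 ecozones       | VU / DD        | near-natural only              |
| 4     | present in 1 ecozone          | EN             | undisturbed only               |
| 8     | 1 ecozone **and** endemic     | CR             | —                              |

Positive scores double with each successive category: the scale is
exponential, not linear, so each step up represents a doubling of
conservation weight. Every species earns at least one distribution point,
which makes the site index sensitive to plain species richness as well as
to rarity.

**Species Index.** SI = DBS + TBS + SBS. Under the default scheme,
exhaustive enumeration of all 96 category combinations gives the attainable
range [1, 20].

**Site index.** The site index is the *sum* of the SIs of all species
recorded at the site (0 if no anuran is present). Summing rather than
averaging means that adding any species can never decrease a site's value,
which suits monitoring richness changes at a fixed site over time; it also
makes the index additive over any partition of the assemblage. A site is
flagged high priority when its index strictly exceeds a threshold
(default 20, configurable).

**Assumptions.** Occupancy ("present in *n* ecozones") is a supplied range
attribute of the species, not re-derived from the survey matrix being
scored; presence–absence records are taken at face value (no detection
modelling at scoring time); Red List categories are inputs, not assessed
here. DD species are scored with VU as a precautionary tie.

### Edge cases and policy decisions

* **Endemic species in ≥ 2 ecozones.** The top distribution class requires
  both single-ecozone occupancy and endemism; no scheme category covers an
  endemic occupying several zones. Such a species is scored by its
  occupancy class alone and a `ScoringWarning` is emitted, rather than
  guessing a bonus the scheme does not define.
* **Unassessed (NE) species** are rejected by default. A scheme file may
  map `NE` explicitly (e.g. to the DD score) as a deliberate opt-in.
* **Scores are integers.** Custom schemes with fractional scores are
  rejected so site indices stay exact integers.
* **Region generality.** The number of ecozones, the occupancy-class
  breakpoints and all score ladders are configuration; a region with a
  different zonation supplies its own breakpoints (the scheme validator
  enforces monotone scores and breakpoints ending at `n_ecozones`).

## Assemblage analytics

* **Ecozone summaries.** Per zone: site count, accumulated richness, mean
  per-site richness, the species unique to the zone (recorded in no other
  zone) with their percentage of the zone's richness, and the most
  frequently recorded species (ties included), plus an all-zones total row.
* **Shared-species matrix.** Counts of species shared between each ordered
  pair of zones; the percentage grid divides each row by the row zone's
  richness, so it is asymmetric with 100% on the diagonal. Zones without
  species yield undefined (NaN) percentage rows with a warning.
* **Composition chi-squared.** Pearson Σ(O−E)²/E without continuity
  correction on a species × ecozone contingency table with
  df = (rows−1)(cols−1). Cells default to the number of sites within the
  zone at which the species was recorded (`cells="site-counts"`), because
  counts use strictly more information than presence; `cells="binary"`
  reduces to presence/absence (the df is identical either way). Rows or
  columns summing to zero are dropped with a warning; a warning is emitted
  when any expected count is below 5.
* **Sub-index correlations.** Pearson product–moment correlation on the raw
  (doubling-scale) score values across species — the scores themselves, not
  category ranks — with `method="spearman"` available where rank
  correlation is preferred. Zero-variance pairs are reported as undefined.
* **Distributions and medians.** SI histograms span the scheme's full
  attainable range so empty classes are explicit. All medians (SI across
  species, site index within an ecozone) use the convention that an
  even-sized group reports the arithmetic mean of the two middle values.
* **Priority report.** Sites are binned by index value (width 10, with a
  separate bin for 0) and ranked by index descending; ties are broken by
  species richness descending, then site id ascending, a package convention
  chosen purely to make reports deterministic.
* **Accumulation curve.** For each of `n_runs` (default 1000) permutations,
  sites are added in uniformly random order and richness after *k* sites is
  the size of the union of their species sets; the curve reports the mean
  and the sample (n−1) standard deviation across runs at each *k*. A single
  integer seed makes the curve bit-reproducible. By construction each run
  is monotone non-decreasing and the final point equals total richness with
  zero spread.
* **Percentage printing.** Report writers round percentages half-up to one
  decimal (the print convention of such survey tables); internal values are
  kept at full precision, except `EcozoneSummary.unique_pct`, which is
  stored already rounded because it is purely a reporting field.

## Synthetic communities

The generator emulates a regional survey: a trait table plus an occurrence
matrix over `sum(sites_per_ecozone)` sites. Its defaults reproduce the
Rwandan anuran survey conditions — 54 species, five ecozones, 51 sites
split 6/21/8/2/14 — with the published marginal category frequencies:
occupancy classes 1 / 2–3 / 4–5 ecozones with probabilities 26/54, 16/54,
12/54 and an endemism probability of 1/26 within the single-zone class
(so DBS scores 4/8 have expected frequencies 46.3% and 1.9%), Red List
marginals LC 29, NT 5, VU 9, DD 8, EN 3, CR 0 of 54, and sensitivity
marginals 19/9/6/20 of 54. The published counts pool VU with DD (17
species); the 9/8 split used here is score-neutral since both categories
carry the same threat score.

Each species draws an occupancy class, then a uniform occupancy count
within the class, then a uniform ecozone subset of that size; Red List and
sensitivity categories are drawn independently from their marginals. With
`detection_prob = 1` (default) a species is recorded at every site of every
ecozone it occupies, so matrix-derived occupancy reproduces the assigned
ecozone sets exactly — the round-trip invariant the tests rely on. With
`detection_prob < 1`, detection is an independent Bernoulli draw per
eligible site, and any species left without a single record is redrawn so
the trait table and the matrix always cover the same species (dropping it
instead would silently shrink the community).

What the generator deliberately does **not** model: spatial autocorrelation
of assemblages within a zone, covariance between the three trait axes
(real range-restricted species tend to be threatened and sensitive, which
is what drives positive sub-index correlations in real data), heterogeneous
per-species detectability, and abundance. Passing tests on synthetic data
therefore demonstrate the correctness of the scoring and analytic
machinery, not field realism of any particular statistic; in particular the
sub-index correlations of a default simulation hover near zero by design.

## Numerical and interface choices

* All randomness flows through `numpy.random.default_rng` from a single
  integer seed per operation (`simulate_community` shares one generator
  between the trait and occurrence draws).
* Chi-squared uses `scipy.stats.chi2_contingency(correction=False)`;
  correlations use `scipy.stats.pearsonr`/`spearmanr`.
* Delimiter auto-detection for input tables is limited to comma and tab;
  species and site ids are opaque, case-sensitive strings (no taxonomic
  normalization). Trait files report all validation problems at once with
  line numbers.
* Scheme config files (YAML or JSON) override only the keys they mention;
  `tbs_scores` entries merge into the defaults so one extra category can be
  added without restating the table.
* The test suite's stochastic checks (accumulation curve vs. the
  exhaustive-ordering oracle on ≤ 4-site fixtures at 1000 runs; generator
  marginals at 10 000 species) use 3-standard-error bands under fixed
  seeds; the oracle sizes keep the full suite in the seconds range.

## Known limitations

* The index is as good as its trait inputs: occupancy tables and national
  Red List assessments must exist for the target region.
* No rarefaction or richness extrapolation (Chao, ACE); only the
  permutation accumulation curve.
* No spatial computation of ecozone membership from coordinates; ecozone
  labels are data.
* Site-index comparisons across regions with different schemes are not
  meaningful; the scheme digest logged by the CLI exists to catch exactly
  that mistake.
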