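# Methods

## The analysis model

The pipeline treats microhabitat selection as a use-versus-availability
problem on categorical resource states. Each sampling point is a 4 × 4 m
quadrat; habitat measurements are reduced to ordered categories (three
levels per factor in the default scheme of 13 factors). Presence quadrats
describe *use*; randomly placed pseudo-absence quadrats describe
*availability*. Presences carry a season × sex group label
(BM, BF, NBM, NBF), and availability is season-matched because background
points are generated per survey period.

### Electivity

For a group and factor with category counts `r` (use) and `p`
(availability), the Vanderploeg selectivity is
`W_i = (r_i/p_i) / Σ(r_i/p_i)` and the Scavia electivity
`E_i = (W_i − 1/n)/(W_i + 1/n)`, classified on the five-level rubric.
Conventions chosen here, where the rubric and formulas are silent:

- `p_i = 0` with `r_i = 0`: the category is dropped from the normalizing
  sum and reported as `no_data` (the ratio is undefined); `p_i = 0` with
  `r_i > 0` is an error, since the formula assigns infinite preference.
  This keeps `ΣW_i = 1` (tolerance 1e−12) over the informative categories.
- The rubric's strict inequalities leave `E_i = ±0.1` unassigned; the
  boundary is mapped to the adjacent non-random class (0.1 → selection,
  −0.1 → avoidance) so classification is total and deterministic. The ±1
  endpoints are matched with tolerance 1e−9.
- The availability pool is pseudo-absence-only by default; switches allow
  pooling both seasons or adding the season's presences to the pool.

### Niche breadth and overlap

Resource states are the factor categories, not individual sampling
points: with three-level factors this puts each per-factor Levins breadth
`B = 1/ΣP_j²` in [1, 3], matching the magnitude of reported aggregate
breadths, and is the only reading under which those magnitudes are
attainable. Per-factor values are aggregated by the arithmetic mean over
the 12 retained factors. Aspect is excluded from aggregation (it carries
at most weak selection for every group) but is still computed and flagged
in the electivity table.

Directional overlap `O_ik = ΣP_ij P_kj / ΣP_ij²` is averaged over the
retained factors per direction, then symmetrized. The default is the
arithmetic mean of the two directions; `row_reference`, `min` and
`geometric` (Pianka-style) are selectable. No clipping is applied at
100%: the index normalizes by group *i*'s concentration only, so values
above 1 are legitimate and do occur.

### The resampling null

Group labels are permuted across all presence records with the four group
sizes preserved, and the full symmetrized overlap matrix is recomputed
per resample. The six unordered-pair values of the observed matrix are
compared with those of the (first) resampled matrix by a paired t-test:
`t = mean(d)/(sd(d)/√6)`, df = 5, two-sided p, with sample (n−1) SDs
reported for both sets. The default `n_resamples = 1` mirrors the
single-resample design of the motivating survey; the recommended mode
uses many resamples (e.g. 999) and additionally reports a permutation p —
the fraction of null mean overlaps at or below the observed mean.

A caveat the test suite measures explicitly: the six pair values share
group profiles (each group enters three pairs), so the paired differences
are positively correlated and the df = 5 t-test is anti-conservative
under label exchangeability (empirical type-I rate ≈ 0.12–0.15 at
α = 0.05 across the simulation conditions in the acceptance tests, vs
≈ 0.03 for the permutation p). The permutation p is therefore the
recommended inferential summary; the paired t is retained as the
comparable legacy statistic. The phrase "resampled regardless of group
identity" could also be read as splitting records into two pooled groups;
this implementation relabels all four groups, which preserves the 4 × 4
matrix shape of the reported null.

### Group comparisons

Per continuous factor and grouping (sex or season): each level is checked
for normality (Shapiro–Wilk by default; D'Agostino selectable) and the
levels for variance homogeneity (Levene, median-centred), both at
α = 0.05; both passing dispatches to one-way ANOVA, otherwise to the
Mann–Whitney U test. The U statistic uses midranks, the variance carries
the tie correction, and Z = (U − n₁n₂/2)/σ_U with no continuity
correction by default (a switch enables it; the convention behind the
motivating survey's printed Z values is unknown, so they are not
reproduction targets). Categorical factors use Pearson chi-square on the
level × category table with a small-expected-count warning below 5. No
multiple-testing correction is applied across variables, matching the
survey's analysis.

## Preprocessing

"Extreme outliers" are defined as values outside median ± 3·IQR, computed
per factor and per point class; flagged values become missing (never row
deletions — record count is invariant) and every modification is logged.
An optional ln(x+1) transform for continuous factors is off by default:
the index/niche pipeline operates on binned categories, and binning raw
values against raw-scale cut points is the intended path. Missing values
are handled by per-analysis listwise deletion; model-based imputation is
out of scope.

## The synthetic-data generator

Defaults encode the study conditions: group sizes BM = 43, BF = 19,
NBM = 15, NBF = 15; 50 pseudo-absence points per season; a 50 m exclusion
radius; a 2 × 2 km planar extent with rectangular unsuitable zones.
Presence categories are drawn per factor from availability ⊙ preference
(renormalized); pseudo-absences from availability alone, placed by
rejection sampling (10 000 attempts per point, loud failure reporting the
shortfall) with the distance and zone constraints re-verified
exhaustively on every emitted point. Raw continuous values are realized
uniformly within the drawn category's interval so binning round-trips
exactly.

The survey reports no availability or preference distributions, so the
defaults are explicitly arbitrary: mildly non-uniform availability, a
shared moderate preference structure, and a planted NBF shift toward low
altitude, down-slope positions and far-from-road quadrats emulating the
study's qualitative finding. What the generator does **not** emulate:
spatial autocorrelation of habitat factors, movement or home-range
structure, detection error, and continuous within-category variation
beyond the uniform fill. Passing recovery tests therefore demonstrate
correctness of the estimators under independent categorical draws, not
robustness to spatially structured real data.

Simulation sizes used by the tests and the acceptance script were chosen
to make the targeted effects unambiguous at modest cost: 2000
presences/group against 2000 availability points per season for the
no-preference calibration (with only 50 background points, availability
noise alone dominates the ±0.1 band), 100–200 replicates for power and
ranking checks, 500 datasets for the type-I measurement.

## Numerical conventions

- Continuous bins are lower-closed `[a, b)` with an open-ended final bin;
  a value equal to a cut point belongs to the upper bin (200 m → level 2
  for edges 200/400). The published level descriptions ("<200", "200–400",
  ">400") do not assign the boundary; one consistent rule is used and
  documented in the scheme.
- Probability vectors are validated to sum to 1 within 1e−9; `ΣW_i = 1` is
  asserted at 1e−12.
- Overlaps are stored unitless and scaled ×100 only at reporting, with
  2 dp formatting; other pipeline CSV numerics use 4 significant figures.
- All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline derives stage seeds from the master seed, and equal configs
  yield byte-identical CSV bundles.

## Known limitations

- Aggregate breadth/overlap values depend on the resource-state and
  symmetrization conventions above; alternative conventions are exposed
  but no attempt is made to infer which convention an external dataset's
  published values used.
- The single-resample paired t inherits the anti-conservatism described
  above; use the permutation p for inference.
- Confidence intervals for electivity, and the Ivlev/Jacobs index
  families, are not implemented (extension points only).
- Coordinates are planar metres; no geodesy.
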