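# Methods

## The transmission model

A dispersing alate receives a propagule of N protist cells from a source
community described by a proportion vector p = (p₁ … p_k) over k countable
species groups. Cells are assumed to be sampled independently with
replacement — equivalently the per-group propagule counts are one
multinomial(N, p) draw. Whole-community transmission succeeds when every
group is represented at least once. Two estimators of the success
probability are provided:

* **Monte-Carlo**: I hypothetical alates are simulated at each N on a grid
  (default 500–10,000 cells in steps of 500; I = 5000); the transmission
  efficiency E(N) is the fraction holding all groups. One independent
  random substream per grid point is derived from the master seed, so the
  curve is independent of evaluation order and batching.
* **Exact**: by inclusion–exclusion over subsets S of groups,
  P(all present) = Σ_S (−1)^|S| (1 − Σ_{i∈S} p_i)^N. The enumeration is
  2^k and is capped at k = 25; values are clipped to [0, 1] and set to
  exactly 0 for N below the number of positive-proportion groups (N draws
  cannot cover more groups than N). P is non-decreasing in N and → 1 as
  N → ∞ whenever all p_i > 0, and the rarest group dominates the rate:
  1 − P ≈ Σ_i (1 − p_i)^N ≈ (1 − p_min)^N for large N.

The **minimum propagule size** is the smallest grid N with
E(N) ≥ threshold. The default threshold 1.0 on a Monte-Carlo curve means
"all I iterations succeeded", a quantity resolved only to grid precision
and dependent on I and the seed (the per-N probability that all I
iterations succeed is (1 − q)^I with q = 1 − P(N)). Because of that, the
minimum of the exact curve at threshold 1 − 1/(2I) is always reported
alongside as a seed-free twin, with an optional integer bisection refining
it below grid resolution. Reports include both values rather than
privileging either.

**Zero-proportion groups.** The strict default counts every group of the
panel in the success criterion, so a composition containing a zero entry
yields E ≡ 0 — a deliberate tripwire for data problems (empirical source
communities have no structural zeros). A flag restricts the criterion to
groups with p_i > 0.

## Community data model

Counts originate as haemocytometer observations: `raw_count` cells in a
counted chamber volume (3.2 µl for the two large parabasalid groups,
0.8 µl otherwise) of a gut-content suspension (150 µl for workers, 30 µl
for nymphs and alates). The per-gut population estimate is
`floor(raw_count × V_susp / V_counted)`, computed in exact rational
arithmetic on the printed decimal volumes so the floor is never corrupted
by binary floating-point error. Long-format files may carry either raw
observations (volumes defaulted from size class and caste when omitted)
or pre-estimated integer counts; decimals in count columns are rejected.

A caste's **source composition** is the arithmetic mean of per-individual
proportion vectors (counts / individual total), renormalized — every
individual weighted equally, which matches the per-individual emphasis of
the summaries the calibration targets. Pooled-count averaging (individuals
weighted by total abundance) is available via `method="pooled"`; whether a
published per-caste table was built one way or the other is generally not
stated, so both modes are first-class and the default is documented here.

## Bottleneck statistics

Caste summaries report mean ± s.e. (sd/√n; defined as 0 with a warning for
n = 1) of totals and of per-individual proportions; proportions are stored
as fractions and become percentages only at presentation. Fold enrichment
is the ratio of caste mean proportions with its nearest-integer fold.
Threshold exceedance uses a strict comparison (total > threshold).
Bray–Curtis dissimilarity follows the count form
1 − 2·Σmin(xᵢ,yᵢ)/(Σxᵢ+Σyᵢ) and is undefined (error) for two all-zero
vectors. Circularity is 4π·area/perimeter², ≤ 1 by the isoperimetric
inequality; values slightly above 1 from pixelated outlines are clipped,
with a warning beyond 1 + 10⁻⁶.

## Synthetic data generator

The generator emulates a two-colony caste survey of the 10-group protist
community; its defaults are the study conditions every end-to-end test
runs under.

* **Panel and compositions.** The two rare large parabasalids are anchored
  to the published caste mean percentage proportions — Tr. agilis 0.48%
  (worker), 2.93% (nymph), 3.30/2.93/3.98% (A2/A7/A7w); Te. mirabilis
  0.14%, 0.27%, 0.29/0.24/0.31% — and the remaining 8 groups share the
  remainder under a fixed documented split (Pyrsonympha 17%, D. exilis
  24%, D. porteri III 7%, IV 5%, Dinenympha spp.1 21%, spp.2 13%,
  Holomastigotes 4%, small protists 9% of the remainder). This split is a
  stated modeling default, *not* a reconstruction of the unpublished
  per-group table; Te. mirabilis is the rarest group in every caste, as
  observed. A0 compositions reuse the nymph values (eclosion preserves the
  community).
* **Totals.** Per-caste lognormal, moment-matched to mean ± sd with
  sd = printed s.e. × √20 (the approximate study caste size): worker
  79,248.6; nymph 8,992.1; A2 8,457.0; A7 5,193.5; A7w 6,770.2; moulted
  workers exactly 0 (protists are purged at worker–worker moults). A0
  totals are not published; 8,700 ± 2,000 (between nymph and A2) is a
  stated assumption. Lognormal rather than normal guarantees positivity at
  worker-scale dispersion.
* **Overdispersion.** Individual compositions are Dirichlet(κ·p) with a
  single κ = 200 per caste — counts are Dirichlet-multinomial. κ is a free
  modeling choice (individual-level dispersion is not published); at the
  defaults it makes rare-group proportions vary severalfold between
  individuals, qualitatively matching over-dispersed count data.
* **Colony effect.** One multiplicative lognormal perturbation vector
  (scale 0.10) per colony, renormalized — a significant but small colony
  effect. Sexes are assigned 50/50 and carry no compositional effect.

Everything is deterministic given the master seed (numpy `SeedSequence`
substreams). What the generator does **not** emulate: presence/absence
detection noise at the microscopy limit, within-colony relatedness
structure, temporal drift, or correlated totals and compositions. Tests
passing on synthetic data therefore demonstrate correctness of the
machinery and qualitative robustness of the nymph-vs-worker ordering, not
quantitative claims about any particular field colony.

## Calibrated headline numbers

With the calibrated compositions, the exact minimum propagule size at
threshold 1 − 1/10,000 on the 500:10,000:500 grid is 3,500 cells from the
nymph community and 7,000 from the worker community (single-cell
refinements 3,407 and 6,575). The Monte-Carlo minimum at threshold 1.0 and
I = 5000, averaged over 24 seeds and rounded to the grid, is 3,500 (nymph)
and 6,000–6,500 (worker): at N where (1 − p_min)^N ≈ 1/(2I) the
probability that all 5,000 iterations succeed crosses ½, which places the
worker Monte-Carlo minimum below its analytic twin. These are the
quantities `scripts/acceptance.py` recomputes; the acceptance test uses
24 seeds so the seed-mean's sampling error (~150 cells for the worker
scenario) is small against the 500-cell grid.

## Numerical and design choices

* Exact `Fraction` arithmetic for the count scale-up; integer counts
  enforced end-to-end.
* Inclusion–exclusion subset sums built by doubling (k concatenations, not
  2^k Python loops); (1 − p_S) clipped to [0, 1] before exponentiation.
* Efficiency curves clip to [0, 1]; minimum-N comparisons use a 10⁻¹²
  slack so a threshold of exactly 1.0 tolerates float representation.
* Minimum-N is grid-resolved by design; bisection refinement is available
  for the analytic mode only (exact monotonicity) and off by default.
* The pipeline derives the data seed and one seed per scenario from the
  master seed; manifests contain versions, seeds and a config hash but no
  timestamps, so identical runs are byte-identical.
* Single-observation standard errors are 0 with a warning; castes with no
  individuals are skipped with a warning.

## Known limitations

* The propagule model ignores biparental founding, post-founding protist
  proliferation, and serial bottlenecks across generations — it bounds
  what a single alate can carry, not colony-level outcomes.
* The minimum-N at threshold 1.0 is an artifact of the iteration count;
  treat the analytic twin as the stable quantity.
* The default 8-group split is a stand-in; users with real per-group data
  should build compositions from their own samples via
  `average_composition` and will get correspondingly different minima.
* The inclusion–exclusion enumeration is exponential in the number of
  groups (capped at 25); communities richer than that need the
  Monte-Carlo path.
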