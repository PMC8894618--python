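# Methods

## Model and assumptions

The analysis treats each published domestic-vs-wild differential-
expression call as a single binary observation: the sign of the log2
fold change (log2FC; expression in the domesticated or tame animal
relative to its wild or aggressive congener). Three assumptions follow:

1. **MRCA polarity.** A nonzero domestic-vs-wild difference reflects
   oppositely directed, equivalent changes of the two lineages since
   their divergence from an unobserved most recent common ancestor: the
   domestic lineage takes the sign of the log2FC, the wild lineage the
   opposite sign. This is a modeling convention, not an inference — no
   outgroup or ancestral-state reconstruction is attempted, and a real
   divergence need not be symmetric.
2. **Inherited significance.** The source study's differential-
   expression call is taken at face value. No magnitude threshold and no
   p-value filter are applied; magnitudes and p-values are carried for
   provenance only. The tame line of a tame-vs-aggressive selection
   experiment is mapped onto the domestic branch.
3. **Record as counting unit.** The unit of analysis is one DEG record
   (gene × species pair × tissue × source study). A gene observed in two
   species or tissues contributes each time, and records of the same
   gene with opposite signs each contribute independently. No multiple-
   testing correction is applied across genes; significance is assessed
   only on the final 2×2 table.

A matched record contributes, per lineage, one correspondence record
when the human annotation slot codirected with that lineage's change
(up → overexpression effect, down → underexpression effect) is not
UNKNOWN — hence 0, 1 or 2 records per matched DEG. The 2×2 table counts
correspondence records by lineage (domestic/wild) × annotated effect on
reproductive potential (decrease/increase).

## Symbol matching

Matching is deliberately conservative: uppercase-fold the symbol, keep
the first whitespace token, strip a trailing `_SPECIES` decoration, then
apply an explicit alias → canonical synonym table, then query the
knowledge base. Fuzzy matching is never attempted, because silent
near-matches would be untestable; anything beyond case and decoration
(e.g. animal hemoglobin subunit names versus human β-family symbols)
must be declared in the synonym file. Annotations are modeled on the
reproductive-potential axis only; entries with both directions UNKNOWN
load but are flagged and can never contribute a record. Extra columns in
the annotation TSV are tolerated on input and not preserved on round
trip — the serialized knowledge base is exactly the fields the analysis
uses.

## Statistical tests

All three tests are computed from first principles and cross-checked in
the test suite against independent routes (enumeration oracle, scipy,
numeric integration):

* **Fisher exact, two-sided, point-probability rule.** The p-value sums
  hypergeometric point probabilities, over the full support of the
  observed margins, of tables no more probable than the observed one.
  Probabilities are exact rationals (`fractions.Fraction` over integer
  binomial coefficients): the sum has no floating-point cancellation.
  The ≤-comparison uses a relative cushion of 1e−7 so that ties decided
  exactly in rational arithmetic cannot flip under any later float
  conversion. Two-sided conventions differ between packages; the
  point-probability rule is the common default and the one exposed here.
* **Pearson χ², df = 1.** Closed form N(ad−bc)²/(r₁r₂c₁c₂); with the
  Yates continuity correction |ad−bc| is reduced by N/2 (floored at 0)
  before squaring, so the corrected statistic never exceeds the
  uncorrected one. Both variants are always reported, because which
  correction a given commercial package applies is often opaque; the
  upper tail is computed through the identity p = erfc(√(x/2)).
* **Binomial tails, one-sided, p₀ = ½.** Per lineage, P(X ≥ k) with k
  the majority cell and n the row total, summed from exact binomial
  coefficients with the null probability held as an exact rational
  (P(X ≥ 0) = 1 and the complement identity hold exactly). The
  directional question — does a lineage's expression change
  preferentially track one effect direction — motivates the one-sided
  form; on the worked example it yields 0.0059 for the domestic 16/20
  and 0.4119 for the wild 11/20.

All three tests require every row and column margin to be positive;
otherwise the pipeline reports status `undefined margins` and attaches
no test results rather than guessing.

Degenerate inputs: a log2FC of exactly 0 carries no polarity and is
excluded with a logged reason by default (`zero_policy=exclude`); the
`error` policy aborts instead. Records are validated with line-numbered
errors (non-numeric or non-finite log2FC, p-values outside (0, 1],
duplicate gene × species × tissue × source observations).

## Worked-example fixture

The packaged fixture transcribes a published worked example: 14 DEG
records whose symbols have no annotated human ortholog, plus 20 matched
records whose correspondence tally is domestic 16 decrease / 4 increase
and wild 9 decrease / 11 increase. The source presents the full
comparison as a figure; signs were reconstructed from its narrative,
and three kinds of reconstruction are flagged in the fixture's `note`
column rather than silently resolved:

* magnitudes not stated verbatim are synthetic (only the sign enters the
  analysis);
* one record's narrative is self-contradictory about which lineage is
  upregulated; the fixture adopts the sign consistent with the published
  marginal counts;
* one record's sign is left open by the narrative but both human
  directions carry the same effect, so the counts are sign-invariant.

A regression test pins the fixture to the published marginals; any
edit that breaks them fails.

## Synthetic-data generator

`degconcord.simulate.generate` emulates the statistical structure the
analysis assumes — and only that structure. Per synthetic DEG: a
Bernoulli(match_rate) ortholog indicator; a uniform domestic direction
realized as a signed log2FC with Exponential(lfc_scale) magnitude
(magnitude is cosmetic; only the sign matters downstream); independent
Bernoulli(theta_dom) / Bernoulli(theta_wild) draws of whether each
lineage's correspondence is DECREASE; per-direction annotation blanking
with probability annot_missing. The generated annotation entry is
constructed so that the pipeline's direction → slot lookup lands exactly
on the sampled effects, and every fifth matched gene is emitted under an
alias resolvable only through the synonym table, so the synonym path is
always exercised. The generator records the ground-truth tally; pipeline
output must equal it exactly for every seed, which is tested.

Defaults mirror the worked example's structure: n_degs = 20,
match_rate = 1, theta_dom = 0.8 (16/20), theta_wild = 0.45 (9/20),
annot_missing = 0, lfc_scale = 1.5 (a realistic magnitude scale for the
published examples). One master seed drives a single numpy generator
with a fixed draw order; replicate seeds in `calibrate_type1` derive
from the master seed by unit increments.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: read-count noise and upstream DE
calling, correlation between genes or between tissues of one study,
per-study direction biases, symbol ambiguity beyond the alias scheme,
and any dependence between matching and effect direction. It validates
the counting and testing machinery, not the biology.

Problem sizes used by the shipped checks (chosen to make Monte-Carlo
error small relative to the tolerances): parameter recovery at
n_degs = 2000 (3-standard-error band), type-I calibration at 2000
replicates of 20 matched DEGs per replicate (the worked example's table
size), Fisher/enumeration equivalence on every table with N ≤ 30.

## Known limitations

* The curated annotation shipped here is the subset of the published
  68-gene knowledge base whose directions are stated in the body
  narrative; directions for the remainder are not invented.
* The full 3080-record DEG corpus behind the published funnel is not
  redistributed; the ingest layer defines the format and is exercised on
  the worked example and synthetic corpora.
* Effects are binary per direction; graded or context-dependent effects
  (dose, sex, tissue of the human evidence) are out of scope.
* The MRCA convention ignores unequal evolutionary rates on the two
  branches; results are conditional on that convention.
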