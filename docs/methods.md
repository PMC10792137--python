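# Methods

## The instrument

METRICS (METhodological RadiomICs Score) is a weighted 30-item checklist
for appraising the methodological quality of radiomics and
imaging-machine-learning studies. Items are grouped into 9 categories;
each item carries a weight expressed as a fraction of the total, and the
30 canonical 4-decimal weights sum to exactly 1.0000. The packaged table
(`data/metrics_v1.csv`) transcribes the published instrument; `metriscore`
treats it as data, validated on every load (cardinality, positive
weights, exact weight conservation, legal conditionality tags). Category
weights are stored as the sums of their member items' weights — they are
not published separately, and the rank-sum derivation makes the sum
relation hold by construction.

## Conditionality and the applicability profile

Seven items are conditional on the study's pipeline. A study is described
by five boolean flags:

| flag | gates items |
|---|---|
| `uses_segmentation` | 8, 10 (and is prerequisite for 9) |
| `fully_automated_segmentation` | 9 |
| `uses_handcrafted_features` | 12 |
| `uses_tabular_features` | 14–16 |
| `uses_end_to_end_dl` | 17 |

Two hard invariants define a *valid* profile: fully automated
segmentation implies segmentation, and at least one of
{hand-crafted, tabular, end-to-end} must hold (otherwise there is no
pipeline to assess). That leaves exactly 21 valid profiles, which the
package can enumerate exhaustively. Mixed pipelines simply set every
triggered flag; all matching conditional items then apply at once.
A hand-crafted pipeline without tabular features is legal but unusual
(hand-crafted extraction produces a feature table), so it draws an
advisory warning rather than an error.

## Scoring

An item scores its full weight when fulfilled and 0 otherwise; there is
no partial credit. The percentage score renormalizes by the maximum
achievable weight under the study's profile:

    percentage = 100 × Σ(w_i, fulfilled) / Σ(w_i, applicable)

so an ideal study scores exactly 100% regardless of pipeline. Statuses
must mark an item `not_applicable` exactly when the profile makes it
inapplicable; any disagreement is a hard error rather than a silent
reinterpretation, which protects batch audits against profile/status
drift. The percentage is computed in full double precision (the ratio is
taken before scaling by 100, so a perfect study is exactly 100.0) and is
binned *unrounded* into five quality grades at 20-point boundaries —
[0,20) very low, [20,40) low, [40,60) moderate, [60,80) good, [80,100]
excellent — because rounding before binning could misgrade values such
as 79.996. Display rounds to 2 decimals. The grade cut-offs are the
published proposal and are deliberately not tuned here; they await
validation in systematic reviews.

## Delphi computations

**Consensus.** Five-point Likert votes per item; strongly agree + agree
form the agreement rate and the disagree side mirrors it. Consensus is
declared when either rate reaches the a-priori 75% threshold, compared
with ≥. Neutral votes count toward neither side; by default they stay in
the denominator (the stricter reading, consistent with a 100% maximum
agreement being attainable), and an alternative mode excludes them from
the denominator as well, since the original description does not fix this
choice. Items without consensus are re-voted once; a second failure
removes them, and consensus disagreement removes an item immediately. A
*newly proposed* item that fails its first vote is reported as `pending`
rather than removed — it is entitled to its own second vote.

**Rank-sum weights.** Panelists rank the 9 categories and the items
within each category. Ranks are aggregated per entity as the median over
panelists; an even panel's median is the mean of the two central order
statistics, so half-integer medians occur. Median ranks convert to
importance scores by `score = (N + 1) − rank` with N the number of
entities at that level; scores are rescaled to sum to 1, and an item's
final weight is its category weight times its within-category weight.
Final weights therefore sum to 1 at machine precision. Display rounding
is 4 decimals, half away from zero — on the canonical table every derived
weight is ≥ 2.5e-5 from a rounding boundary, so the convention is fixed
purely for determinism.

**Certification (weight inversion).** `invert_weights_to_ranks`
brute-force searches half-integer median configurations whose derived
final weights fall within half a 4-decimal ulp (5e-5) of a weight table,
scanning candidate score sums on the half-integer grid at each level.
Score vectors that differ by a positive scalar give identical weights, so
the search additionally rejects candidates that no even panel of strict
rankings could actually produce as medians (e.g. two out of four entities
both at median 4 would need 44 last-place ranks from a 42-member panel);
the first surviving end-to-end-consistent configuration is returned. On
the packaged table this recovers category medians
(1, 3.5, 7, 4, 6, 6, 4, 5, 9) in table order with per-category item
medians reproducing all 30 published weights at 4 decimals (maximum
absolute deviation ≈ 4.9e-5 before rounding), in about 10 ms. A table
inconsistent with the derivation chain — e.g. any single weight
perturbed — fails with a certification error.

## Synthetic data

The generators make every pipeline stage testable without the study's raw
panel data, which is not distributed. All are bit-reproducible under a
fixed seed.

* **Votes**: independent per (panelist, item) draws with configurable
  agree/disagree side probabilities; the strong/plain split within a side
  is fixed at 50/50 because consensus logic only distinguishes sides.
  Defaults mirror the study's scale: 40-panelist rounds.
* **Rank matrices** are *median-exact*, not approximately so. For an even
  panel n = 2m, a column's median is pinned by its two central order
  statistics (a, b) with a + b = 2·target. The generator enumerates
  central-pair choices per entity (entities sharing a target are
  exchangeable, collapsing the product to multiset combinations), tests
  each assignment with an exact Hall-type condition on prefix/suffix
  rank-value budgets, routes value copies into columns by max-flow, and
  splits the resulting doubly-regular count matrix into n permutations
  (Birkhoff decomposition by repeated seeded bipartite matching, which
  also varies the rows between equivalent solutions). Because the search
  is exhaustive, a `FeasibilityError` is a proof that no panel of that
  size realizes the requested medians — not a sampling timeout. An
  earlier, simpler design using elementwise-symmetric panelist pairs was
  discarded: it implies a rank-total conservation law that column medians
  of real panels do not obey (the certified category medians sum to 45.5,
  not 45).
* **Assessments**: applicable items fulfilled independently with a given
  probability, inapplicable items marked `not_applicable`, so generated
  assessments always pass scoring validation.

What the generators do not model: panelist anchoring, fatigue,
round-to-round opinion shift, or correlated voting. Passing tests on
synthetic panels therefore demonstrate the *computations* (consensus
arithmetic, median aggregation, weight chain, scoring), not the
behavioral realism of Delphi panels.

## Problem sizes and numerics

Tests and the acceptance script run the pipeline at the study's own
scale — 30 items, 9 categories, 21 valid profiles (enumerated
exhaustively), 40–42 simulated panelists — plus randomized sweeps of
1,000 scoring-oracle comparisons and 10,000 half-probability assessments;
the whole suite completes in a few seconds. Weight normalization is
checked at 1e-12; the inversion tolerance is 5e-5 (half a printed ulp);
scores are compared at 1e-9 against a brute-force item-by-item oracle.
Ties in medians produce exactly equal weights; ties in category weights
keep published table order.

## Known limitations

* The anonymized round-level votes behind the published consensus counts
  are not distributed with the original work, so those counts are not
  reproduced here; the consensus machinery is exercised on synthetic
  votes only.
* Inter-rater agreement and score reproducibility across raters are out
  of scope, as is any re-weighting scheme (e.g. pairwise-comparison
  methods).
* Partial-pipeline edge cases (e.g. deep features fed into classical
  machine learning) are expressed through the five flags; the instrument
  itself does not enumerate them further.
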