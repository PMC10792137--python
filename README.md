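# metriscore

Quality scoring for radiomics studies with the METRICS instrument
(METhodological RadiomICs Score), plus the modified-Delphi computations
that produced its weights.

Radiomics studies — predictive clinical models built from quantitative
medical-image features — vary enormously in methodological rigor, and
systematic reviewers need a principled way to grade them. METRICS is a
30-item, 9-category checklist in which each item *i* carries an
expert-panel weight *wᵢ* (the 30 weights sum to 1). Seven items are
conditional on the study's pipeline (segmentation, fully automated
segmentation, hand-crafted features, tabular features, end-to-end deep
learning), and the score renormalizes by what the study could actually
have achieved:

```
score = 100 × Σ_{i fulfilled} wᵢ / Σ_{i applicable} wᵢ   (percent)
```

binned into five grades: very low [0, 20), low [20, 40), moderate
[40, 60), good [60, 80), excellent [80, 100].

The weights come from a modified Delphi exercise: panelists rank the
categories, and the items within each category, by importance; ranks are
aggregated as medians, converted to scores by `score = (N+1) − rank`,
rescaled to sum to 1 per level, and multiplied (category × item-within-
category) into final weights. `metriscore` implements that chain too —
consensus determination at the ≥75% threshold, median aggregation,
rank-sum weighting — and can *certify* the packaged weight table by
recovering a median-rank configuration that reproduces every published
4-decimal weight.

Intended users: systematic reviewers and meta-researchers scoring batches
of studies, and anyone auditing or extending the instrument's weights.

## Worked example

An assessment file describes one study: its pipeline profile and a
status (`fulfilled` / `not_fulfilled` / `not_applicable`) per item. A
hand-crafted radiomics study with manual segmentation
(`"uses_end_to_end_dl": false`, so item 17 is not applicable; manual
segmentation, so item 9 is not applicable) that fulfils items
1–4, 6, 8, 11, 13, 18, 20, 26:

```
$ metriscore score lung-ct-2024.json --format json
{
  "study_id": "lung-ct-2024",
  "percentage": 58.46475195822455,
  "quality_category": "moderate",
  "achieved_weight": 0.5598,
  "achievable_weight": 0.9575,
  ...
}
```

The study earned weight 0.5598 out of the 0.9575 achievable under its
profile (1 minus the weights of inapplicable items 9 and 17), i.e.
58.46% — grade "moderate". `--format markdown` renders the same result
as a per-item report mirroring the instrument's table layout, and
`metriscore batch` scores a directory of JSON/YAML files or a CSV (one
row per study) into one table.

The Delphi side works from rank CSVs:

```
$ metriscore certify                     # packaged table vs. the rank-sum chain
$ metriscore derive-weights ranks.csv --certify
$ metriscore simulate-ranks --seed 7 --targets "A=1,B=2.5,C=2.5" --panelists 6
```

`certify` recovers half-integer median ranks from the packaged weights
and reports the maximum deviation after re-deriving them (≈4.9e-5,
i.e. all 30 weights agree at the printed 4 decimals). The `simulate-*`
commands generate seeded synthetic votes, rank matrices with exactly
prescribed medians, and study assessments.

As a library:

```python
from metriscore import load_instrument, ApplicabilityProfile, compute_score
from metriscore.scoring import Assessment

inst = load_instrument()
profile = ApplicabilityProfile(
    uses_segmentation=True, fully_automated_segmentation=False,
    uses_handcrafted_features=True, uses_tabular_features=True,
    uses_end_to_end_dl=False,
)
statuses = {i: "not_fulfilled" for i in range(1, 31)}
statuses.update({1: "fulfilled", 2: "fulfilled", 3: "fulfilled"})
statuses.update({9: "not_applicable", 17: "not_applicable"})
result = compute_score(inst, Assessment("demo", profile, statuses))
print(f"{result.percentage:.2f}% — {result.quality_category}")
# 21.12% — low
```

## Layout

- `src/metriscore/instrument.py` — data model, canonical table, applicability
- `src/metriscore/scoring.py` — percentage score, grades, batch scoring
- `src/metriscore/delphi.py` — consensus, median ranks, rank-sum weights, certification
- `src/metriscore/synthetic.py` — seeded generators (votes, ranks, assessments)
- `src/metriscore/io.py`, `cli.py` — file formats and the `metriscore` CLI
- `docs/methods.md` — models, assumptions, numerical choices, limitations
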