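# facedim

Landmark-based 3D facial masculinity analysis: extraction of 11
inter-landmark facial distances (3 straight-line, 8 surface-geodesic) and
facial area from triangulated face meshes, a two-class linear-discriminant
sex classifier with a 0–20 facial masculinity score, the accompanying
statistical toolkit (Welch's *t* with Satterthwaite df, rank-sum tests,
pooled-SD Cohen's *d* with CIs, one-way ANOVA with Tukey HSD, noncentral-F
minimum-sample-size search), and a synthetic-data generator so the whole
pipeline runs end-to-end without any external data.

The published group-summary tables of the motivating study (typically
developing boys vs girls; male and female siblings of autistic children vs
same-sex controls; proband masculinity scores) ship as package fixtures
and every printed statistic can be recomputed from them.

## Layout

| module                | contents |
| --------------------- | -------- |
| `facedim.geometry`    | PLY/OBJ mesh + landmark CSV I/O, Steiner-refined graph geodesics, the distance registry, facial area |
| `facedim.gender_model`| regularized two-class LDA, sex classification, 0–20 masculinity score, JSON model serialization |
| `facedim.stats`       | Welch/Satterthwaite, Cohen's *d* + CI, Mann–Whitney (exact for small n), Shapiro–Wilk test selection, summary/raw ANOVA, Tukey HSD, power search |
| `facedim.tables`      | published summary-table fixtures and their recomputation report |
| `facedim.synthetic`   | multivariate-normal cohort generator and a parametric face-mesh surrogate |
| `facedim.pipeline`    | the three study analyses (validation, sibling comparison, three-group ANOVA) as reproducible report-producing steps |
| `facedim.cli`         | `facedim` command-line entry point |

## CLI

```sh
facedim simulate --seed 1 --out out/bundle          # synthetic study cohorts
facedim fit --features out/bundle/validation.csv --out out/model.json
facedim score --features out/bundle/comparison.csv --model out/model.json --out out/scored.csv
facedim classify --features out/bundle/validation.csv --model out/model.json --out out/pred.csv
facedim validate --fixtures                          # dimorphism tests from printed summaries
facedim compare-siblings --sex male --fixtures
facedim three-group --sex male --fixtures
facedim recompute-tables --out out/recomputed.csv
facedim extract --mesh-dir meshes/ --landmarks landmarks.csv --out features.csv
```

Feature tables are CSV with columns
`subject_id,sex,group,<11 distance columns>,facial_area`; landmark files
are CSV with `subject_id,landmark,x,y,z` (mm). Meshes are ascii/binary
little-endian PLY or OBJ, assumed to be in mm.

## Tests and acceptance report

```sh
python -m pytest tests/                              # full suite, ~1 min
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` holds one test per acceptance criterion:
deterministic recomputation of the published power-analysis sample sizes,
Satterthwaite dfs, effect sizes and the significant-feature count from the
fixture tables, the geometry/statistics property suites, and the scaled
Monte-Carlo gates on synthetic cohorts. `scripts/acceptance.py` recomputes
each reported target quantity from scratch at run time and writes them as
JSON (all targets are deterministic; `--seed` is accepted for interface
uniformity).

## Conventions worth knowing

- The 13 landmark names and the 11 distance pairings live in
  `facedim.geometry.DISTANCE_REGISTRY` and are overridable per call.
- Geodesics are shortest paths over the mesh graph augmented with
  2^r − 1 Steiner points per edge (default r = 2), endpoints snapped to
  the nearest node within a 2 mm tolerance; a geodesic is therefore never
  shorter than the straight-line distance between the same points.
- The masculinity score maps the LDA projection affinely so that the
  female class mean scores 5, the male class mean 15 and the midpoint 10,
  clipped to [0, 20]; ties at the midpoint classify as male.
- Median/IQR table rows are converted to mean/SD under normality
  (SD = IQR/1.349) wherever a parametric quantity is required, and every
  such result carries an approximation flag.
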