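# phenomap

Computable representations of visually observed plant phenotypes.

Curators describe plant phenotypes with words — "small irregular brown
lesions on the leaf", "oxheart-shaped medium tomato" — and those words are
ambiguous, heterogeneous and coarse. `phenomap` makes such descriptions
computable: it quantifies phenotype images, learns quantitative definitions of
the semantic terms from curator-labeled examples, and stores the learned
definitions in a layered ontology. It is aimed at plant-phenomics and
bio-curation groups who want semantic image search and automatic annotation
over their own collections.

The package covers the full pipeline:

* **Synthetic data** (`phenomap.synthetic`) — seeded generators for labeled
  maize-style leaf images (brown necrotic / yellow chlorotic lesions with
  controlled count, area, ellipticity and spatial pattern) and tomato-style
  fruit silhouettes (8 shape families × 3 size classes), with exact
  ground-truth masks and degree-coded labels.
* **Segmentation** (`phenomap.segmentation`) — leaf isolation on a solid
  protocol background, HSV tissue gates (necrotic / chlorotic / normal), and
  8-connected lesion components with area, centroid, perimeter and maximum
  Feret diameter.
* **Features** — the fixed 452-feature leaf vector (`phenomap.leaf_features`:
  per-region RGB/HSV histograms plus 12-bin lesion size, roundness and
  nearest-neighbour distance histograms per tissue class) and the 56-feature
  fruit vector (`phenomap.fruit_features`: geometry, three shape indices,
  RGB/L\*a\*b\* colour averages and a 37-bin HCL hue histogram).
* **Semantic mapping** (`phenomap.rules`) — the core: class-association rules
  whose antecedents are conjunctions of feature intervals, e.g.

      {F006 ∈ [0.09, 0.16] ∧ F399 ∈ [0.12, 0.21]} → elliptical_lesions

  mined exhaustively under support/confidence thresholds, then *fuzzified*:
  each interval becomes a possibility distribution
  π(x) = s(λ₃(x−a))·s(λ₃(b−x)) / s(λ₃λ₂/2)² with centre λ₁, width λ₂ and
  slope λ₃, so relevance of a new image is graded rather than binary.
  Exposed as the scikit-learn-style estimator `SemanticRuleMiner`
  (`fit(X, y)` → `rules_`, `relevance(X)`, `predict(X)`).
* **Retrieval & evaluation** (`phenomap.retrieval`) — multi-term semantic
  search with CombSUM fusion, automatic annotation, and the resubstitution
  protocol: per-term average precision, per-class mean average precision
  (MAP), 11-point precision–recall curves.
* **Ontology** (`phenomap.ontology`) — the five-layer visual phenotype
  ontology (taxon → structure → abnormality → expression → quantification)
  with typed relations, rule embedding as quantification nodes, JSON and
  OWL 2 (RDF/XML) serialization, plus the imagery/algorithms ontology and
  validated computational pipeline specs.

See `docs/methods.md` for the models, parameter defaults and design choices.

## Worked example

Mine semantic rules on a generated leaf collection and evaluate them:

```python
from phenomap.experiments import build_leaf_study, fit_annotator
from phenomap.retrieval import evaluate_resubstitution, semantic_search
from phenomap.rules import render_rule

X, labels, data = build_leaf_study(n_per_class=6, seed=7)   # 36 images
annotator = fit_annotator(X, labels, min_confidence=1.0)

print(render_rule(annotator.miners["lesion_shape"].crisp_rules_[0]))
report = evaluate_resubstitution(X, labels, annotator)
for cls, m in sorted(report.class_map.items()):
    print(f"{cls}: MAP = {m:.3f}")

ranked = semantic_search(["medium_lesions", "brown_lesions"], X, annotator)
print([(i, round(s, 3)) for i, s in ranked.entries[:3]])
```

prints

```
{F216 ∈ [0.3, 1] ∧ F420 ∈ [0, 0.1]} → elliptical_lesions
lesion_color: MAP = 1.000
lesion_coverage: MAP = 1.000
lesion_shape: MAP = 1.000
lesion_size: MAP = 1.000
[('img028', 1.943), ('img026', 1.943), ('img024', 1.943)]
```

The rule reads: images whose rescaled hue-histogram feature F216 lies in
[0.3, 1] *and* whose necrotic-roundness feature F420 lies in [0, 0.1] are
elliptical-lesion images. MAP = 1.000 for every class says the mined rules
rank every training image carrying a term above every image without it —
expected here, because the generator gives the four semantic classes disjoint
feature ranges. The search query fuses the two terms' relevance scores; the
top hits (score ≈ 1.94 of a possible 2.0) are exactly the brown, medium-lesion
images.

The same workflow is available from the shell:

```bash
phenomap synth --kind leaf --config cfg.json --n 20 --seed 3 --out imgs/
phenomap extract --kind leaf --in imgs/ --out features.csv
phenomap mine --features features.csv --labels imgs/labels.csv \
              --class lesion_shape --out rules.json
phenomap eval --features features.csv --labels imgs/labels.csv
phenomap export-ontology --rules rules.json --skeleton vpheno.json --out vpheno.owl
```

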