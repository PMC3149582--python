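# Methods

`phenomap` turns curator language about visually observed plant phenotypes
("small irregular brown lesions", "oxheart fruit") into computable objects: it
measures images, mines interval-based association rules that tie measurements
to semantic terms, softens those rules into possibility distributions, and
files the result in a layered ontology. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Image quantification

**Leaf pipeline.** Images follow a simple protocol: a single blade on a solid
background. Segmentation thresholds the Euclidean RGB distance to the declared
background colour (`tol`, default 40 on the 0–255 scale), keeps the largest
8-connected component and fills holes. Tissue classification is a set of HSV
gates (hue in degrees on [0, 360)): necrotic tissue at hue 5–45° with value
≤ 0.7, chlorotic at hue 45–75° with value ≥ 0.35, both requiring saturation
≥ 0.15; everything else on the blade is normal tissue. These gates are a
declared classifier — simple, auditable, and validated only on synthetic
imagery; on real field images they would need re-tuning or replacement, which
is why they sit in a config dataclass (`TissueGates`).

Lesions are 8-connected components per tissue class (so diagonally touching
necrosis merges into one lesion, matching what happens on real scans where
apparently separate lesions share pixels), with components below
`min_lesion_area` = 5 px² discarded as speckle. Geometry per lesion: area,
unweighted centroid (x right, y down, 0-based), perimeter, and the maximum
Feret diameter computed exactly on convex-hull vertices.

**The 452-feature leaf vector.** Four pixel regions (entire blade, necrotic,
chlorotic, non-lesion) each get an RGB histogram (16+16+16 bins) and an HSV
histogram (15 hue + 16 + 16), with the non-lesion HSV block deliberately
placed before the chlorotic one to preserve the fixed published ordering of
this layout. Each tissue class then gets three 12-bin count histograms: lesion
area ("size"), roundness, and nearest-neighbour centroid distance. Roundness
is area over the area of the circle on the maximum Feret diameter (1 for a
disk; a single-pixel lesion returns 1 by convention). Bin ranges the layout
itself does not fix are config defaults: size bins span [0, leaf area / 10],
NN bins span [0, leaf long-axis length], roundness spans [0, 1]; values beyond
a range are clamped into the final bin. Colour histograms are normalised per
channel; count histograms are divided by their block sum in post-processing
(raw counts are kept on the feature vector). Whether "size" bins areas or
diameters was an open choice; areas are used and declared.

**The 56-feature fruit vector.** Single-fruit masks are measured with the
conventions of common fruit-phenotyping software: bounding box for maximum
width/height, mid-row and mid-column slices for the "at middle" measures, and
curved height as the arc length of the per-row midpoint (medial) curve.
Shape index 1 is maximum height / maximum width reported at two decimals; this
definition reproduces all eight printed values of the bundled Anna Russian
reference table exactly. Shape index 2 (mid-height / mid-width slice ratio)
and the curved shape index (curved height / mid-width) follow the same
software's documented conventions but have no printed values to verify
against; they are flagged as unverified conventions. Colour features: mean
RGB, mean L\*a\*b\* (D65), luminosity = mean L\*, hue = atan2(b\*, a\*) in
degrees, chroma = sqrt(a\*² + b\*²), and a 37-bin equi-width hue histogram in
HCL space (unweighted by chroma by default).

## Semantic mapping

**Training table.** Rows are images, columns are features min–max rescaled to
[0, 1] over the training table (parameters persisted for inference). Labels
carry a degree of appearance (none / few / moderate / extensive); mining and
evaluation binarise relevance as degree ≠ none, keeping the degree as
metadata.

**Feature selection.** Correlation-based subset merit (mean absolute
feature–class correlation penalised by mean absolute inter-feature
correlation), searched by greedy stepwise forward selection (default),
best-first with a small backtracking budget, or exhaustively for ≤ 15
candidates. All three are deterministic given the table.

**Rule mining.** Antecedents are conjunctions of per-feature intervals, an
interval being any run of adjacent discretisation bins (10 equal-width bins by
default, half-open [lo, hi) with the final bin closed). `mine_rules` returns
every rule meeting `min_support` (joint antecedent-and-consequent fraction,
default 0.05) and `min_confidence` (default 0.8) up to `max_len` = 3
conditions — its output is identical to brute-force enumeration, with
support-monotone pruning used only as a speed-up; the tree-structured miners
used for this problem in the literature are treated as equivalent-output
optimisations and not reproduced structurally. Because the exhaustive set
grows combinatorially on strongly separable data (every sub-interval of a pure
region qualifies), the `SemanticRuleMiner` estimator defaults to generality
pruning: an antecedent that already meets the confidence threshold is not
specialised further, the standard compaction of class-association-rule
classifiers. Rules are ordered by confidence, then support, then antecedent
size, deterministically.

**Fuzzification and possibility.** Each crisp interval [lo, hi] becomes a
possibility distribution with centre λ1 = (lo+hi)/2, width λ2 = hi−lo and
slope λ3 = `slope_scale`/λ2 (default scale 1). The distribution is a
normalised product of two logistic edges,

    π(x) = s(λ3(x−a))·s(λ3(b−x)) / s(λ3·λ2/2)²,   a = λ1−λ2/2, b = λ1+λ2/2,

so π(λ1) = 1 exactly, π decays monotonically away from the interval, and as
λ3 → ∞ it converges to the crisp indicator. One numerical subtlety: interval
upper bounds are exclusive, so the estimator shrinks exclusive upper edges by
1e-9 before fuzzifying. Without this, a value sitting exactly on an open upper
edge of one rule and a value on a closed lower edge of another tie at the
identical edge constant s(0)·s(λ3λ2)/s(λ3λ2/2)², and rankings then hinge on
arbitrary id tie-breaks. The shrink moves λ1/λ2 by ≤ 5e-10 — far below any
measurement resolution — and makes the possibility honour the half-open
convention the discretiser declares.

Rule relevance of an image is the minimum (t-norm; product optional) of its
condition possibilities; term relevance is the maximum over the term's rules;
ties in rankings break by ascending image id.

## Retrieval applications and evaluation

Semantic search scores the database per query term and fuses lists by summed
scores (CombSUM; product available). Annotation returns every term with
non-zero relevance, best first. Evaluation is the standard resubstitution
protocol: for each term, all training images are ranked by relevance, average
precision is taken over images labeled with the term at degree ≠ none, class
MAP is the mean of member-term APs, and precision–recall curves use 11-point
interpolation (maximum precision at recall ≥ r), which makes them
non-increasing by construction.

## Synthetic study conditions

No usable public collection exists for this pipeline's exact protocol, so the
package ships seeded generators whose outputs are a pure function of their
spec. Leaves are an elongated elliptical blade (long axis horizontal, base to
tip) on a solid background; lesions are either rotated ellipses with axis
ratio 0.45–0.62 (roundness ≈ the axis ratio, pinning them into the middle
roundness bins) or radially noise-perturbed polygons stretched 2.2–3.2×
(roundness ≲ 0.35, pinning them low). Lesion areas are drawn from disjoint
ranges per size class (small 30–80 px², medium 140–280, large 330–520);
spatial patterns are uniform, clustered, tip- or base-biased; touching lesions
are allowed deliberately so the merge behaviour of the segmenter is
exercised. Coverage degrees are declared count thresholds (few ≤ 5, moderate
6–20, extensive > 20); the degree attached to colour/size/shape labels equals
the coverage degree, since how strongly those semantics appear scales with how
much of the blade is affected. Fruits are single silhouettes from eight
parametric outline families (profiles of a circle, ellipses, a superellipse,
and tapered egg/heart variants with fixed aspect ratios) at three size
classes.

The canned separability study (`phenomap.experiments`) uses six leaf templates
× 20 images: colour (brown/yellow) and shape (elliptical/irregular) vary
independently, while size and coverage co-vary (small+few, medium+moderate,
large+extensive) so that all four semantic classes have disjoint generative
ranges — coverage terms are then separable through total lesion fraction, not
only lesion counts. On this study the experiment mines exact rules
(`min_confidence` = 1.0, against the package default of 0.8): the premise of
the experiment is perfect separability, and admitting confidence-0.8 rules
deliberately places some non-relevant images inside rule support regions,
capping MAP below 1 by construction rather than by defect. The 120-image size
keeps the full pipeline comfortably within a desktop run while leaving ≥ 20
images per term.

What the generators do *not* emulate — illumination drift, colour-checker
calibration, leaf venation and midribs, specular highlights, camera noise,
photorealistic lesion texture — bounds what passing tests show: they certify
the measurement definitions, the mining/fuzzification machinery and the
evaluation protocol, not robustness of the HSV gates on field imagery.

## Ontology

The visual phenotype ontology is a five-layer DAG (plant taxon → plant
structure → plant abnormality → phenotype expression → phenotype
quantification) with typed cross-layer relations (part_of, expressed_on,
expressed_by, describes) and is_a permitted within any single layer. Mined
rules embed as quantification nodes carrying their conditions (λ parameters,
support, confidence) as payload, one `describes` edge each. External
ontology terms (NCBI Taxonomy, PO, TO, PATO) are identifier strings only,
never fetched. OWL export is OWL 2 in RDF/XML with relations as object
properties and rule payloads as a JSON-valued annotation property — OWL has no
economical native encoding for interval antecedents, so the annotation
carrying is a declared choice. The three-layer imagery/algorithms ontology
backs an annotated pipeline spec (ordered stages with term, parameters and
input/output kinds) validated for term resolution, kind chaining and parameter
completeness.

## Known limitations

* The tissue gates and the possibility function's exact parametric form are
  declared stand-ins satisfying stated properties, not recovered from any
  reference implementation.
* Shape index 2 and the curved shape index cannot be cross-validated against
  printed values; the medial-curve construction of curved height is an
  approximation.
* Genetic-search feature selection is out of scope; three deterministic
  methods are provided.
* Resubstitution overstates accuracy on real data by construction; the
  package reports it because it is the protocol being reproduced, with the
  shuffled-label null control as the calibration.
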