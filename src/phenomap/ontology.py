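"""The layered visual phenotype ontology and the imagery/algorithms ontology.

Two layered DAGs are modeled here.  The visual phenotype ontology (VPhenoO)
has five layers — Plant Taxon, Plant Structure, Plant Abnormality, Phenotype
Expression, Phenotype Quantification — with typed cross-layer relations:
structure is ``part_of`` a taxon, an abnormality is ``expressed_on`` a
structure, an expression is ``expressed_by`` an abnormality, and a
quantification node ``describes`` an expression.  ``is_a`` hierarchies are
permitted within any single layer.  Mined fuzzy rules are embedded as
Phenotype Quantification nodes carrying their antecedent intervals and
possibility parameters as payload.

The imagery-and-algorithms ontology has three layers (imagery, algorithms,
machine representation) and underwrites the annotated computational pipeline:
an ordered stage list in which each stage names an ontology term, its
parameters, and its input/output kinds, validated for term resolution, kind
chaining and parameter completeness.

External ontology terms (NCBI Taxonomy, PO, TO, PATO) are referenced by
identifier string only and never fetched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
from rdflib import Graph as RDFGraph
from rdflib import Literal, Namespace, RDF, RDFS, OWL, URIRef

__all__ = [
    "VPHENO_LAYERS",
    "IMAGERY_LAYERS",
    "RELATIONS",
    "OntologyNode",
    "OntologyEdge",
    "OntologyError",
    "VPhenoOntology",
    "PipelineStage",
    "PipelineSpec",
    "PipelineReport",
    "validate_pipeline",
    "build_imagery_ontology",
    "build_maize_vpheno_skeleton",
    "maize_leaf_pipeline",
]

VPHENO_LAYERS = (
    "plant_taxon",
    "plant_structure",
    "plant_abnormality",
    "phenotype_expression",
    "phenotype_quantification",
)
IMAGERY_LAYERS = ("imagery", "algorithms", "machine_representation")
RELATIONS = ("is_a", "part_of", "expressed_on", "expressed_by", "describes")

#: Required relation for each (child layer, parent layer) pair in a VPhenoO.
_CROSS_LAYER = {
    ("plant_structure", "plant_taxon"): "part_of",
    ("plant_abnormality", "plant_structure"): "expressed_on",
    ("phenotype_expression", "plant_abnormality"): "expressed_by",
    ("phenotype_quantification", "phenotype_expression"): "describes",
}
#: Imagery-side cross-layer links (a declared convention: components of the
#: processing chain are part_of the stage category above them).
_IMAGERY_CROSS = {
    ("algorithms", "imagery"): "part_of",
    ("machine_representation", "algorithms"): "part_of",
}


class OntologyError(ValueError):
    """Typed validation failure (layer/relation mismatch, cycle, dangling id)."""


@dataclass(frozen=True)
class OntologyNode:
    id: str
    label: str
    layer: str
    external_xref: str | None = None
    payload: dict | None = None


@dataclass(frozen=True)
class OntologyEdge:
    child: str
    parent: str
    relation: str


class VPhenoOntology:
    """Layered, acyclic, relation-typed ontology graph."""

    def __init__(self, layers: tuple[str, ...] = VPHENO_LAYERS):
        self.layers = tuple(layers)
        self.nodes: dict[str, OntologyNode] = {}
        self.edges: list[OntologyEdge] = []
        self._g = nx.DiGraph()
        self._cross = _CROSS_LAYER if layers == VPHENO_LAYERS else _IMAGERY_CROSS

    # -- construction ------------------------------------------------------
    def add_node(self, node: OntologyNode) -> "VPhenoOntology":
        if node.id in self.nodes:
            raise OntologyError(f"duplicate node id {node.id!r}")
        if node.layer not in self.layers:
            raise OntologyError(f"unknown layer {node.layer!r} for node {node.id!r}")
        self.nodes[node.id] = node
        self._g.add_node(node.id)
        return self

    def add_edge(self, edge: OntologyEdge) -> "VPhenoOntology":
        if edge.child not in self.nodes or edge.parent not in self.nodes:
            raise OntologyError(f"edge endpoints must exist: {edge}")
        if edge.child == edge.parent:
            raise OntologyError(f"self-edge rejected: {edge.child!r}")
        if edge.relation not in RELATIONS:
            raise OntologyError(f"unknown relation {edge.relation!r}")
        cl = self.nodes[edge.child].layer
        pl = self.nodes[edge.parent].layer
        if cl == pl:
            required = "is_a"
        else:
            required = self._cross.get((cl, pl))
            if required is None:
                raise OntologyError(
                    f"no relation is permitted from layer {cl!r} to {pl!r}"
                )
        if edge.relation != required:
            raise OntologyError(
                f"edge {edge.child!r} -> {edge.parent!r} must use "
                f"{required!r}, not {edge.relation!r}"
            )
        if nx.has_path(self._g, edge.parent, edge.child):
            raise OntologyError(
                f"edge {edge.child!r} -> {edge.parent!r} would create a cycle"
            )
        self.edges.append(edge)
        self._g.add_edge(edge.child, edge.parent, relation=edge.relation)
        return self

    # -- queries -----------------------------------------------------------
    def layer_counts(self) -> dict[str, int]:
        counts = {layer: 0 for layer in self.layers}
        for node in self.nodes.values():
            counts[node.layer] += 1
        return counts

    def nodes_in_layer(self, layer: str) -> list[OntologyNode]:
        return [n for n in self.nodes.values() if n.layer == layer]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, VPhenoOntology)
            and self.layers == other.layers
            and self.nodes == other.nodes
            and sorted(self.edges, key=lambda e: (e.child, e.parent))
            == sorted(other.edges, key=lambda e: (e.child, e.parent))
        )

    # -- rule embedding ----------------------------------------------------
    def embed_rules(self, fuzzy_rules, feature_stage_map: dict | None = None):
        """Add one phenotype-quantification node per rule, linked by a
        ``describes`` edge to the expression node matching its consequent.

        The rule payload (conditions with possibility parameters, support,
        confidence) is stored on the node; if ``feature_stage_map`` is given,
        each antecedent feature is also linked to the pipeline stage term that
        produced it.
        """
        by_label = {
            n.label: n.id for n in self.nodes_in_layer("phenotype_expression")
        }
        by_id = {n.id for n in self.nodes_in_layer("phenotype_expression")}
        missing = sorted(
            {
                r.consequent
                for r in fuzzy_rules
                if r.consequent not in by_label and r.consequent not in by_id
            }
        )
        if missing:
            raise OntologyError(
                "rule consequents without a phenotype_expression node: "
                + ", ".join(missing)
            )
        start = sum(
            1 for n in self.nodes.values() if n.layer == "phenotype_quantification"
        )
        for k, rule in enumerate(fuzzy_rules, start=start + 1):
            target = by_label.get(rule.consequent, rule.consequent)
            payload = {
                "conditions": [
                    {
                        "feature": c.feature,
                        "lambda1": c.lam1,
                        "lambda2": c.lam2,
                        "lambda3": c.lam3,
                    }
                    for c in rule.conditions
                ],
                "support": rule.support,
                "confidence": rule.confidence,
            }
            if feature_stage_map:
                payload["feature_links"] = [
                    {"feature": c.feature, "stage": feature_stage_map.get(c.feature)}
                    for c in rule.conditions
                ]
            node = OntologyNode(
                id=f"rule_{k:04d}",
                label=f"rule for {rule.consequent} #{k}",
                layer="phenotype_quantification",
                payload=payload,
            )
            self.add_node(node)
            self.add_edge(OntologyEdge(node.id, target, "describes"))
        return self

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "layers": list(self.layers),
                "nodes": [asdict(n) for n in self.nodes.values()],
                "edges": [asdict(e) for e in self.edges],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "VPhenoOntology":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise OntologyError(
                f"malformed ontology file at line {exc.lineno}, col {exc.colno}: "
                f"{exc.msg}"
            ) from exc
        graph = cls(layers=tuple(payload["layers"]))
        for n in payload["nodes"]:
            graph.add_node(OntologyNode(**n))
        for e in payload["edges"]:
            graph.add_edge(OntologyEdge(**e))
        return graph

    def to_owl(self) -> str:
        """OWL 2 RDF/XML export: one class per node, subclass axioms for
        ``is_a``, object properties for the typed relations, and rule payloads
        as an annotation property carrying JSON."""
        ns = Namespace("http://phenomap.example.org/vpheno#")
        g = RDFGraph()
        g.bind("vpheno", ns)
        props = {rel: ns[rel] for rel in RELATIONS if rel != "is_a"}
        for prop in props.values():
            g.add((prop, RDF.type, OWL.ObjectProperty))
        payload_prop = ns["ruleJSON"]
        g.add((payload_prop, RDF.type, OWL.AnnotationProperty))
        xref_prop = ns["externalXref"]
        g.add((xref_prop, RDF.type, OWL.AnnotationProperty))
        for node in self.nodes.values():
            uri = ns[node.id]
            g.add((uri, RDF.type, OWL.Class))
            g.add((uri, RDFS.label, Literal(node.label)))
            g.add((uri, ns["layer"], Literal(node.layer)))
            if node.external_xref:
                g.add((uri, xref_prop, Literal(node.external_xref)))
            if node.payload:
                g.add((uri, payload_prop, Literal(json.dumps(node.payload))))
        for edge in self.edges:
            child, parent = ns[edge.child], ns[edge.parent]
            if edge.relation == "is_a":
                g.add((child, RDFS.subClassOf, parent))
            else:
                g.add((child, props[edge.relation], parent))
        return g.serialize(format="xml")


# ---------------------------------------------------------------------------
# computational pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineStage:
    term: str  # id of a node in the imagery/algorithms ontology
    parameters: dict = field(default_factory=dict)
    input_kind: str = ""
    output_kind: str = ""


@dataclass
class PipelineSpec:
    stages: list[PipelineStage]

    def to_json(self) -> str:
        return json.dumps({"stages": [asdict(s) for s in self.stages]}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineSpec":
        payload = json.loads(text)
        return cls(stages=[PipelineStage(**s) for s in payload["stages"]])


@dataclass
class PipelineReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_pipeline(pipeline: PipelineSpec, imagery_graph: VPhenoOntology) -> PipelineReport:
    """Check term resolution, kind chaining and parameter completeness."""
    report = PipelineReport()
    for i, stage in enumerate(pipeline.stages):
        node = imagery_graph.nodes.get(stage.term)
        if node is None:
            report.issues.append(f"stage {i}: term {stage.term!r} not in ontology")
            continue
        required = (node.payload or {}).get("required_parameters", [])
        for name in required:
            if name not in stage.parameters:
                report.issues.append(
                    f"stage {i} ({stage.term}): missing parameter {name!r}"
                )
    for i in range(len(pipeline.stages) - 1):
        out_k = pipeline.stages[i].output_kind
        in_k = pipeline.stages[i + 1].input_kind
        if out_k != in_k:
            report.issues.append(
                f"kind chain broken between stages {i} and {i + 1}: "
                f"{out_k!r} != {in_k!r}"
            )
    return report


# ---------------------------------------------------------------------------
# shipped fixtures: imagery ontology, maize skeleton, maize pipeline
# ---------------------------------------------------------------------------


def build_imagery_ontology() -> VPhenoOntology:
    """A compact imagery-and-algorithms ontology covering the leaf pipeline."""
    g = VPhenoOntology(layers=IMAGERY_LAYERS)
    imagery = [
        ("raw_image", "raw phenotype image", {}),
        ("standardized_image", "color-standardized image", {}),
        ("color_standardization", "color standardization", {"required_parameters": ["method"]}),
        ("leaf_segmentation", "leaf segmentation", {"required_parameters": ["background_color", "tol"]}),
        ("tissue_classification", "lesion tissue classification", {"required_parameters": ["gates"]}),
        ("lesion_extraction", "lesion component extraction", {"required_parameters": ["min_lesion_area"]}),
    ]
    algorithms = [
        ("rgb_histogram", "RGB histogram", {"required_parameters": ["bins"]}),
        ("hsv_histogram", "HSV histogram", {"required_parameters": ["bins"]}),
        ("size_histogram", "lesion size histogram", {"required_parameters": ["bins"]}),
        ("roundness_histogram", "lesion roundness histogram", {"required_parameters": ["bins"]}),
        ("nn_distance_histogram", "nearest-neighbor distance histogram", {"required_parameters": ["bins"]}),
        ("feature_extraction", "feature extraction", {"required_parameters": ["layout"]}),
    ]
    machine = [
        ("raw_vector", "raw measurement vector", {}),
        ("normalized_vector", "normalized measurement vector", {}),
        ("normalization", "block normalization", {"required_parameters": ["mode"]}),
    ]
    for layer, items in (
        ("imagery", imagery),
        ("algorithms", algorithms),
        ("machine_representation", machine),
    ):
        for nid, label, payload in items:
            g.add_node(OntologyNode(nid, label, layer, payload=payload or None))
    g.add_edge(OntologyEdge("standardized_image", "raw_image", "is_a"))
    for alg, _, _ in algorithms[:-1]:
        g.add_edge(OntologyEdge(alg, "feature_extraction", "is_a"))
    g.add_edge(OntologyEdge("feature_extraction", "standardized_image", "part_of"))
    g.add_edge(OntologyEdge("normalization", "feature_extraction", "part_of"))
    g.add_edge(OntologyEdge("normalized_vector", "feature_extraction", "part_of"))
    g.add_edge(OntologyEdge("raw_vector", "feature_extraction", "part_of"))
    return g


def build_maize_vpheno_skeleton() -> VPhenoOntology:
    """Top four layers of a maize lesion-mimic VPhenoO, with external xrefs."""
    g = VPhenoOntology()
    g.add_node(OntologyNode("zea_mays", "Zea mays", "plant_taxon", "NCBITaxon:4577"))
    g.add_node(OntologyNode("leaf", "leaf", "plant_structure", "PO:0009025"))
    g.add_node(
        OntologyNode(
            "lesion_mimic_mutation", "lesion mimic mutation", "plant_abnormality"
        )
    )
    g.add_edge(OntologyEdge("leaf", "zea_mays", "part_of"))
    g.add_edge(OntologyEdge("lesion_mimic_mutation", "leaf", "expressed_on"))
    expressions = [
        ("brown_lesions", "brown lesions", "PATO:0000952"),
        ("yellow_lesions", "yellow lesions", "PATO:0001324"),
        ("small_lesions", "small lesions", "PATO:0000587"),
        ("medium_lesions", "medium lesions", None),
        ("large_lesions", "large lesions", "PATO:0000586"),
        ("elliptical_lesions", "elliptical lesions", "PATO:0002228"),
        ("irregular_lesions", "irregular lesions", "PATO:0001781"),
        ("few", "few lesions", None),
        ("moderate", "moderate lesion coverage", None),
        ("extensive", "extensive lesion coverage", None),
    ]
    for nid, label, xref in expressions:
        g.add_node(OntologyNode(nid, label, "phenotype_expression", xref))
        g.add_edge(OntologyEdge(nid, "lesion_mimic_mutation", "expressed_by"))
    return g


def maize_leaf_pipeline() -> PipelineSpec:
    """The shipped leaf pipeline: standardize, segment, classify tissue,
    extract lesions and features, normalize — each stage annotated with an
    imagery/algorithms ontology term plus parameters."""
    return PipelineSpec(
        stages=[
            PipelineStage(
                "color_standardization",
                {"method": "identity"},
                "raw_image",
                "standardized_image",
            ),
            PipelineStage(
                "leaf_segmentation",
                {"background_color": [150, 150, 160], "tol": 40.0},
                "standardized_image",
                "leaf_mask",
            ),
            PipelineStage(
                "tissue_classification",
                {"gates": "default_hsv_gates"},
                "leaf_mask",
                "tissue_labels",
            ),
            PipelineStage(
                "lesion_extraction",
                {"min_lesion_area": 5},
                "tissue_labels",
                "lesion_set",
            ),
            PipelineStage(
                "feature_extraction",
                {"layout": "leaf_452"},
                "lesion_set",
                "raw_vector",
            ),
            PipelineStage(
                "normalization",
                {"mode": "per_block_sum"},
                "raw_vector",
                "normalized_vector",
            ),
        ]
    )
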