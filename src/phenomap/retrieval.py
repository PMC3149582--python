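"""Semantic image search, automatic annotation and retrieval evaluation.

Applications built on the fuzzy rule base: rank a database of feature vectors
against one or several semantic terms (per-term relevance lists fused by
summed scores, CombSUM, or by product), annotate a single image with every
term of non-zero relevance, and score the rule base by the standard retrieval
protocol — average precision per term, mean average precision (MAP) per
semantic class, and interpolated precision-recall curves — in a resubstitution
experiment over the training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rules import FuzzyRule, SemanticRuleMiner

__all__ = [
    "RankedList",
    "EvalReport",
    "SemanticAnnotator",
    "rank_by_score",
    "semantic_search",
    "annotate_image",
    "average_precision",
    "interpolated_pr_curve",
    "evaluate_resubstitution",
]


@dataclass
class RankedList:
    """Ordered (image id, score) pairs, scores non-increasing, ids unique.

    Ties are broken by ascending image id so rankings are deterministic.
    """

    entries: list[tuple[str, float]]

    def ids(self) -> list[str]:
        return [i for i, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def rank_by_score(scores: pd.Series) -> RankedList:
    order = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
    return RankedList([(str(i), float(s)) for i, s in order])


class SemanticAnnotator:
    """A rule base spanning several semantic classes.

    Wraps one fitted :class:`SemanticRuleMiner` per semantic class and exposes
    a single relevance matrix over all their terms.
    """

    def __init__(self, miners: dict[str, SemanticRuleMiner]):
        self.miners = dict(miners)
        seen: dict[str, str] = {}
        for cls, miner in self.miners.items():
            for t in miner.terms_:
                if t in seen:
                    raise ValueError(f"term {t!r} appears in two semantic classes")
                seen[t] = cls
        self.term_class = seen

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_class)

    def rules_for(self, term: str) -> list[FuzzyRule]:
        cls = self.term_class.get(term)
        if cls is None:
            return []
        return self.miners[cls].rules_for(term)

    def relevance(self, X: pd.DataFrame) -> pd.DataFrame:
        parts = [m.relevance(X) for m in self.miners.values()]
        return pd.concat(parts, axis=1)


def semantic_search(
    query_terms: list[str],
    X: pd.DataFrame,
    annotator: SemanticAnnotator,
    fusion: str = "sum",
) -> RankedList:
    """Rank the database against a conjunction of query terms.

    Per-term relevance lists are fused by summed scores (CombSUM) or by
    product.  Terms without rules are dropped with a warning; if none remain
    the query is an error.
    """
    if fusion not in ("sum", "product"):
        raise ValueError(f"unknown fusion {fusion!r}")
    usable = []
    for t in query_terms:
        if annotator.rules_for(t):
            usable.append(t)
        else:
            warnings.warn(f"query term {t!r} has no rules; dropped")
    if not usable:
        raise ValueError("no query term has any rules")
    rel = annotator.relevance(X)[usable]
    scores = rel.sum(axis=1) if fusion == "sum" else rel.prod(axis=1)
    return rank_by_score(scores)


def annotate_image(v: pd.Series, annotator: SemanticAnnotator) -> list[tuple[str, float]]:
    """All terms with non-zero relevance for one feature vector, best first."""
    X = v.to_frame().T
    rel = annotator.relevance(X).iloc[0]
    pairs = [(t, float(r)) for t, r in rel.items() if r > 0]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return pairs


def average_precision(ranked: RankedList | list, relevant: set) -> float:
    """Standard retrieval AP: mean over relevant items of precision at their
    rank (relevant items absent from the ranking contribute precision 0)."""
    relevant = set(relevant)
    if not relevant:
        raise ValueError("relevant set is empty")
    ids = ranked.ids() if isinstance(ranked, RankedList) else [str(i) for i in ranked]
    hits = 0
    precisions = []
    for rank, item in enumerate(ids, start=1):
        if item in relevant:
            hits += 1
            precisions.append(hits / rank)
    precisions.extend([0.0] * (len(relevant) - hits))
    return float(np.mean(precisions))


def interpolated_pr_curve(
    ranked: RankedList | list, relevant: set, n_points: int = 11
) -> tuple[np.ndarray, np.ndarray]:
    """11-point interpolated precision-recall curve.

    Precision at recall level r is the maximum precision at any recall >= r,
    which makes the curve non-increasing.
    """
    relevant = set(relevant)
    ids = ranked.ids() if isinstance(ranked, RankedList) else [str(i) for i in ranked]
    hits = 0
    rec, prec = [], []
    for rank, item in enumerate(ids, start=1):
        if item in relevant:
            hits += 1
            rec.append(hits / len(relevant))
            prec.append(hits / rank)
    recall_levels = np.linspace(0, 1, n_points)
    rec_arr, prec_arr = np.asarray(rec), np.asarray(prec)
    interp = np.zeros(n_points)
    for i, r in enumerate(recall_levels):
        mask = rec_arr >= r - 1e-12
        interp[i] = prec_arr[mask].max() if mask.any() else 0.0
    return recall_levels, interp


@dataclass
class EvalReport:
    term_ap: dict[str, float] = field(default_factory=dict)
    class_map: dict[str, float] = field(default_factory=dict)
    pr_curves: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"term": t, "average_precision": ap} for t, ap in self.term_ap.items()
        ]
        return pd.DataFrame(rows)


def evaluate_resubstitution(
    X: pd.DataFrame,
    labels: pd.DataFrame,
    annotator: SemanticAnnotator,
) -> EvalReport:
    """Rank the training images by relevance for every term and score them.

    ``labels`` is a long table with columns ``image_id``, ``semantic_class``,
    ``term``, ``degree``; an image counts as relevant to a term iff it carries
    that term with degree != "none".  Terms with no relevant image are skipped
    with a warning.
    """
    rel_matrix = annotator.relevance(X)
    report = EvalReport()
    by_class: dict[str, list[float]] = {}
    present = labels[labels["degree"] != "none"]
    for term in annotator.terms:
        relevant = set(
            present.loc[present["term"] == term, "image_id"].astype(str)
        )
        if not relevant:
            warnings.warn(f"term {term!r} has no relevant training images; skipped")
            continue
        ranked = rank_by_score(rel_matrix[term])
        ap = average_precision(ranked, relevant)
        report.term_ap[term] = ap
        report.pr_curves[term] = interpolated_pr_curve(ranked, relevant)
        by_class.setdefault(annotator.term_class[term], []).append(ap)
    for cls, aps in by_class.items():
        report.class_map[cls] = float(np.mean(aps))
    return report
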