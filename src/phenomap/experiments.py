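"""Reproducible study conditions: canned end-to-end experiments.

These functions fix the generative templates and pipeline settings used to
characterise the framework on synthetic data, so tests, scripts and the
documentation all run the same experiments:

* a balanced leaf training set whose four semantic classes (lesion color,
  shape, size, coverage) have disjoint generative ranges, on which the mined
  rule base is expected to achieve resubstitution MAP of 1.0 per class;
* a label-shuffling null control whose MAP should fall at the chance level of
  a random ranking;
* a parameter-recovery experiment on plain feature tables, checking that the
  top mined rule recovers the interval a class was generated from;
* a balanced fruit set over the eight silhouette families and three size
  classes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .leaf_features import LeafFeatureExtractor
from .retrieval import EvalReport, SemanticAnnotator, evaluate_resubstitution
from .rules import SemanticRuleMiner, discretize, mine_rules
from .synthetic import FruitSpec, LeafSpec, FRUIT_SHAPE_CLASSES, generate_training_set

__all__ = [
    "separable_leaf_templates",
    "fruit_templates",
    "build_leaf_study",
    "fit_annotator",
    "leaf_resubstitution",
    "shuffled_label_map",
    "recover_interval",
]


def separable_leaf_templates() -> list[LeafSpec]:
    """Six leaf templates covering four semantic classes with disjoint
    generative ranges.

    Lesion color (brown/yellow) and shape (elliptical/irregular) vary
    independently; size and coverage co-vary (small+few, medium+moderate,
    large+extensive) so that the total lesion fraction — the measurement
    coverage rules latch onto — is itself disjoint across coverage terms.
    """
    mk = lambda color, shape, size, n: LeafSpec(  # noqa: E731
        seed=0,
        lesion_color_class=color,
        lesion_shape_class=shape,
        lesion_size_class=size,
        lesion_count=n,
    )
    return [
        mk("brown_necrotic", "elliptical", "small", 4),
        mk("yellow_chlorotic", "elliptical", "medium", 12),
        mk("brown_necrotic", "irregular", "large", 26),
        mk("yellow_chlorotic", "irregular", "small", 4),
        mk("brown_necrotic", "elliptical", "medium", 12),
        mk("yellow_chlorotic", "irregular", "large", 26),
    ]


def fruit_templates(size_classes=("small", "medium", "large")) -> list[FruitSpec]:
    """One template per (shape family, size class) combination."""
    return [
        FruitSpec(seed=0, shape_class=shape, size_class=size)
        for shape in FRUIT_SHAPE_CLASSES
        for size in size_classes
    ]


def build_leaf_study(
    n_per_class: int = 20, seed: int = 42
) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Generate the separable leaf set and extract its feature matrix.

    Returns (features, labels, dataset); ``labels`` is the long table
    (image_id, semantic_class, term, degree).
    """
    data = generate_training_set(n_per_class, separable_leaf_templates(), seed=seed)
    X = LeafFeatureExtractor().fit().transform([img for img, _ in data])
    X.index = [f"img{i:03d}" for i in range(len(data))]
    rows = []
    for i, (_, truth) in enumerate(data):
        for c, t, d in truth.labels:
            rows.append((f"img{i:03d}", c, t, d))
    labels = pd.DataFrame(
        rows, columns=["image_id", "semantic_class", "term", "degree"]
    )
    return X, labels, data


def _term_map(labels: pd.DataFrame, semantic_class: str) -> dict[str, str]:
    sub = labels[
        (labels["semantic_class"] == semantic_class) & (labels["degree"] != "none")
    ]
    return dict(zip(sub["image_id"], sub["term"]))


def fit_annotator(
    X: pd.DataFrame, labels: pd.DataFrame, **miner_kwargs
) -> SemanticAnnotator:
    """One miner per semantic class present in the label table."""
    miners = {}
    for cls in sorted(labels["semantic_class"].unique()):
        mp = _term_map(labels, cls)
        y = np.asarray([mp.get(str(i)) for i in X.index], dtype=object)
        if len({t for t in y if t}) < 1:
            continue
        miners[cls] = SemanticRuleMiner(**miner_kwargs).fit(X, y)
    return SemanticAnnotator(miners)


def leaf_resubstitution(
    n_per_class: int = 20, seed: int = 42, **miner_kwargs
) -> EvalReport:
    """The separability experiment: mine exact rules on the disjoint-range
    leaf set and evaluate them by resubstitution.

    Exact (confidence 1.0) rules are mined because the experiment's premise is
    perfect class separability; the package-wide default of 0.8 is meant for
    noisy real collections.
    """
    miner_kwargs.setdefault("min_confidence", 1.0)
    X, labels, _ = build_leaf_study(n_per_class, seed)
    annotator = fit_annotator(X, labels, **miner_kwargs)
    return evaluate_resubstitution(X, labels, annotator)


def shuffled_label_map(labels: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Permute which image carries which label rows (the null control)."""
    rng = np.random.default_rng(seed)
    ids = labels["image_id"].unique()
    perm = dict(zip(ids, rng.permutation(ids)))
    out = labels.copy()
    out["image_id"] = out["image_id"].map(perm)
    return out


def recover_interval(
    n: int = 200,
    interval: tuple[float, float] = (0.2, 0.6),
    n_noise_features: int = 3,
    seed: int = 0,
    **mine_kwargs,
):
    """Parameter-recovery table: class "c" has its signal feature uniform on
    ``interval``, class "d" uniform just above it; noise features are uniform
    on [0, 1] for both.  Returns (top rule for "c", the signal interval).
    """
    rng = np.random.default_rng(seed)
    a, b = interval
    half = n // 2
    signal = np.r_[rng.uniform(a, b, half), rng.uniform(b + 0.05, 1.0, n - half)]
    cols = {"F001": signal}
    for j in range(n_noise_features):
        cols[f"F{j + 2:03d}"] = rng.uniform(0, 1, n)
    X = pd.DataFrame(cols)
    y = np.asarray(["c"] * half + ["d"] * (n - half), dtype=object)
    mine_kwargs.setdefault("min_support", 0.05)
    mine_kwargs.setdefault("min_confidence", 0.8)
    mine_kwargs.setdefault("max_len", 3)
    rules = mine_rules(discretize(X, n_bins=10), y, **mine_kwargs)
    rules_c = [r for r in rules if r.consequent == "c"]
    return (rules_c[0] if rules_c else None), (a, b)
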