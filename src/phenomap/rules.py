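"""Quantitative class-association rules with fuzzified antecedents.

This is the semantic-mapping core of the package: given a table of per-image
measurements and curator-assigned semantic terms, it mines crisp association
rules whose antecedents are conjunctions of per-feature intervals and whose
consequents are semantic terms (e.g. ``{F006 in [0.09, 0.16] and F399 in
[0.12, 0.21]} -> elliptical_lesions``), then replaces each crisp interval by
an asymmetric possibility distribution so that the relevance of a new image to
a semantic becomes a graded value in [0, 1] rather than a binary hit.

The possibility distribution over a feature axis is a normalised product of
two logistic edges,

    pi(x) = s(l3 (x - a)) * s(l3 (b - x)) / s(l3 l2 / 2)^2,
    a = l1 - l2/2,  b = l1 + l2/2,  s = logistic,

parameterised by a center l1, width l2 and slope l3.  pi(l1) = 1 exactly, pi
decays monotonically away from the interval, and as l3 grows it converges to
the crisp indicator of [a, b].

Mining is exhaustive over antecedents: every conjunction of up to ``max_len``
per-feature intervals (an interval being any run of adjacent discretisation
bins) that meets the support and confidence thresholds is returned, using
support-monotone (apriori-style) pruning purely as an optimisation — the
output is identical to brute-force enumeration.
"""

from __future__ import annotations

import itertools
import json
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = [
    "CrispRule",
    "FuzzyCondition",
    "FuzzyRule",
    "DiscretizedTable",
    "discretize",
    "select_features",
    "cfs_merit",
    "mine_rules",
    "fuzzify",
    "possibility",
    "rule_relevance",
    "semantic_relevance",
    "render_rule",
    "parse_rule_text",
    "rules_to_json",
    "rules_from_json",
    "SemanticRuleMiner",
]


# ---------------------------------------------------------------------------
# rule types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrispRule:
    """Interval-conjunction association rule A -> C.

    ``antecedent`` is a tuple of (feature name, lo, hi) conditions on distinct
    features; ``support`` is the fraction of rows matching both antecedent and
    consequent, ``confidence`` the fraction of antecedent-matching rows that
    carry the consequent.
    """

    antecedent: tuple[tuple[str, float, float], ...]
    consequent: str
    support: float
    confidence: float

    def key(self):
        return (self.consequent, tuple(sorted(self.antecedent)))


@dataclass(frozen=True)
class FuzzyCondition:
    feature: str
    lam1: float  # center
    lam2: float  # width
    lam3: float  # slope

    def __post_init__(self):
        if self.lam2 <= 0 or self.lam3 <= 0:
            raise ValueError("lam2 and lam3 must be positive")


@dataclass(frozen=True)
class FuzzyRule:
    conditions: tuple[FuzzyCondition, ...]
    consequent: str
    support: float
    confidence: float
    provenance: CrispRule | None = None


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


@dataclass
class DiscretizedTable:
    """Per-feature bin codes plus the interval edges they stand for."""

    codes: np.ndarray  # (n_rows, n_features) int
    edges: list[np.ndarray]  # per feature, length n_bins_f + 1
    feature_names: list[str]

    def interval(self, f: int, lo_bin: int, hi_bin: int) -> tuple[float, float]:
        return float(self.edges[f][lo_bin]), float(self.edges[f][hi_bin + 1])


def discretize(
    table: pd.DataFrame | np.ndarray,
    n_bins: int = 10,
    scheme: str = "equal_width",
) -> DiscretizedTable:
    """Map every feature value to a bin item carrying its interval.

    Intervals are half-open [lo, hi) with the final bin closed, so every value
    lies inside the interval of its assigned bin.  ``equal_width`` splits the
    observed [min, max] of each column; ``equal_frequency`` uses empirical
    quantiles (a constant column collapses to a single bin with a warning).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if scheme not in ("equal_width", "equal_frequency"):
        raise ValueError(f"unknown discretization scheme {scheme!r}")
    if isinstance(table, pd.DataFrame):
        names = [str(c) for c in table.columns]
        X = table.to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        names = [f"F{i + 1:03d}" for i in range(X.shape[1])]
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")

    codes = np.zeros(X.shape, dtype=int)
    edges_out: list[np.ndarray] = []
    for j in range(X.shape[1]):
        col = X[:, j]
        lo, hi = float(col.min()), float(col.max())
        if hi <= lo:
            if scheme == "equal_frequency":
                warnings.warn(
                    f"constant feature {names[j]!r}: single discretization bin"
                )
            edges = np.array([lo, lo + 1.0])
        elif scheme == "equal_width":
            edges = np.linspace(lo, hi, n_bins + 1)
        else:
            qs = np.quantile(col, np.linspace(0, 1, n_bins + 1))
            edges = np.unique(qs)
            if len(edges) < 2:
                edges = np.array([lo, lo + 1.0])
        k = len(edges) - 1
        idx = np.searchsorted(edges, col, side="right") - 1
        codes[:, j] = np.clip(idx, 0, k - 1)
        edges_out.append(edges)
    return DiscretizedTable(codes=codes, edges=edges_out, feature_names=names)


# ---------------------------------------------------------------------------
# feature selection (correlation-based subset merit)
# ---------------------------------------------------------------------------


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def cfs_merit(X: np.ndarray, rcf: np.ndarray, subset: list[int],
              corr_cache: dict) -> float:
    """Correlation-based subset merit: mean feature-class correlation
    penalised by mean inter-feature correlation."""
    k = len(subset)
    if k == 0:
        return 0.0
    mean_rcf = rcf[subset].mean()
    if k == 1:
        return mean_rcf
    rff = []
    for i, j in itertools.combinations(subset, 2):
        if (i, j) not in corr_cache:
            corr_cache[(i, j)] = abs(_safe_corr(X[:, i], X[:, j]))
        rff.append(corr_cache[(i, j)])
    mean_rff = float(np.mean(rff))
    return k * mean_rcf / np.sqrt(k + k * (k - 1) * mean_rff)


def select_features(
    table: pd.DataFrame,
    y: np.ndarray,
    method: str = "greedy_stepwise",
    max_features: int = 10,
) -> list[str]:
    """Pick a feature subset that separates the terms of one semantic class.

    ``y`` holds one term per row (None/NaN for rows not labeled with any term
    of the class).  The score is the correlation-based merit above; all three
    methods are deterministic given the table.
    """
    if method not in ("greedy_stepwise", "best_first", "exhaustive"):
        raise ValueError(f"unknown selection method {method!r}")
    terms = sorted({t for t in y if isinstance(t, str)})
    if not terms:
        raise ValueError("semantic class has no labeled terms in y")
    X = table.to_numpy(dtype=float)
    names = [str(c) for c in table.columns]
    m = X.shape[1]
    onehot = np.stack([np.asarray([t == term for t in y], float) for term in terms])
    rcf = np.zeros(m)
    for j in range(m):
        rcf[j] = np.mean([abs(_safe_corr(X[:, j], oh)) for oh in onehot])

    cache: dict = {}
    if method == "exhaustive":
        if m > 15:
            raise ValueError("exhaustive search is only permitted for <= 15 features")
        best, best_merit = [], -np.inf
        for k in range(1, m + 1):
            for subset in itertools.combinations(range(m), k):
                merit = cfs_merit(X, rcf, list(subset), cache)
                if merit > best_merit + 1e-12:
                    best, best_merit = list(subset), merit
        return [names[j] for j in best]

    # forward selection; best_first keeps exploring past plateaus a little
    selected: list[int] = []
    merit = 0.0
    stale_limit = 5 if method == "best_first" else 0
    stale = 0
    best_seen: tuple[float, list[int]] = (0.0, [])
    while len(selected) < min(max_features, m):
        candidates = [j for j in range(m) if j not in selected]
        scored = [(cfs_merit(X, rcf, selected + [j], cache), j) for j in candidates]
        new_merit, j_best = max(scored, key=lambda t: (t[0], -t[1]))
        if new_merit > merit + 1e-12:
            selected.append(j_best)
            merit = new_merit
            stale = 0
            if merit > best_seen[0]:
                best_seen = (merit, list(selected))
        else:
            stale += 1
            if stale > stale_limit:
                break
            selected.append(j_best)
            merit = new_merit
    if method == "best_first" and best_seen[1]:
        selected = best_seen[1]
    if not selected:  # degenerate table: keep the single best-correlated feature
        selected = [int(np.argmax(rcf))]
    return [names[j] for j in sorted(selected)]


# ---------------------------------------------------------------------------
# rule mining
# ---------------------------------------------------------------------------


def _interval_members(disc: DiscretizedTable) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """All contiguous bin-run intervals of every feature, as boolean columns.

    Returns the (n_rows, n_intervals) membership matrix and a descriptor
    (feature index, lo bin, hi bin) per column.
    """
    cols, meta = [], []
    for f in range(disc.codes.shape[1]):
        k = len(disc.edges[f]) - 1
        code = disc.codes[:, f]
        for lo in range(k):
            ge = code >= lo
            for hi in range(lo, k):
                cols.append(ge & (code <= hi))
                meta.append((f, lo, hi))
    M = np.stack(cols, axis=1) if cols else np.zeros((disc.codes.shape[0], 0), bool)
    return M, meta


def mine_rules(
    disc: DiscretizedTable,
    y,
    min_support: float = 0.05,
    min_confidence: float = 0.8,
    max_len: int = 3,
    prune_specializations: bool = False,
) -> list[CrispRule]:
    """All interval-conjunction rules meeting the thresholds, for every term.

    ``y`` is a per-row term label (None for unlabeled rows).  By default the
    result is exactly the brute-force enumeration over all antecedents of up
    to ``max_len`` conditions on distinct features; frequent-conjunction
    pruning only speeds the search up.

    With ``prune_specializations=True`` an antecedent that already meets the
    confidence threshold is not specialised further (narrower intervals and
    extra conjuncts fire on a subset of the same rows, so the general rule
    subsumes them).  This is the classic generality pruning of class-
    association-rule classifiers and keeps rule bases compact on strongly
    separable data, where the exhaustive set grows combinatorially.
    """
    if not (0 < min_support <= 1) or not (0 < min_confidence <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    n = disc.codes.shape[0]
    y = np.asarray(y, dtype=object)
    M, meta = _interval_members(disc)
    Mf = M.astype(np.float32)
    feat_of = np.array([m[0] for m in meta])
    ant_count = M.sum(axis=0).astype(float)
    eps = 1e-9
    s_min = min_support * n - eps

    rules: list[CrispRule] = []
    terms = sorted({t for t in y if isinstance(t, str)})
    for term in terms:
        yv = (y == term).astype(bool)

        def emit(cols_idx: tuple[int, ...], joint: float, ant: float) -> bool:
            conf = joint / ant
            if conf < min_confidence - eps:
                return False
            conds = tuple(
                (disc.feature_names[meta[c][0]],)
                + disc.interval(meta[c][0], meta[c][1], meta[c][2])
                for c in sorted(cols_idx, key=lambda c: meta[c][0])
            )
            rules.append(
                CrispRule(
                    antecedent=conds,
                    consequent=term,
                    support=joint / n,
                    confidence=conf,
                )
            )
            return True

        cnt1 = yv.astype(np.float32) @ Mf
        freq1 = np.nonzero(cnt1 >= s_min)[0]
        confident1 = np.zeros(M.shape[1], dtype=bool)
        for c in freq1:
            confident1[c] = emit((c,), float(cnt1[c]), ant_count[c])

        # level k >= 2: extend each frequent antecedent by every interval of a
        # later feature, scoring all extensions in one matrix-vector product
        frontier: list[tuple[tuple[int, ...], np.ndarray, np.ndarray]] = [
            ((c,), M[:, c] & yv, M[:, c])
            for c in freq1
            if not (prune_specializations and confident1[c])
        ]
        level = 1
        while frontier and level < max_len:
            next_frontier = []
            for combo, joint_vec, ant_vec in frontier:
                last_feat = feat_of[combo[-1]]
                joint_cnt = joint_vec.astype(np.float32) @ Mf
                cand_mask = (feat_of > last_feat) & (joint_cnt >= s_min)
                if prune_specializations:
                    cand_mask &= ~confident1
                cand = np.nonzero(cand_mask)[0]
                if cand.size == 0:
                    continue
                ant_cnt = ant_vec.astype(np.float32) @ Mf[:, cand]
                for c, ant in zip(cand, ant_cnt):
                    confident = emit(combo + (int(c),), float(joint_cnt[c]), float(ant))
                    if prune_specializations and confident:
                        continue
                    next_frontier.append(
                        (combo + (int(c),), joint_vec & M[:, c], ant_vec & M[:, c])
                    )
            frontier = next_frontier
            level += 1

    rules.sort(
        key=lambda r: (r.consequent, -r.confidence, -r.support, len(r.antecedent), r.antecedent)
    )
    return rules


# ---------------------------------------------------------------------------
# fuzzification and possibility
# ---------------------------------------------------------------------------


#: Infinitesimal shrink applied to exclusive upper interval edges so that a
#: value exactly on an open boundary scores strictly below one on a closed
#: boundary.  Negligible against any real feature scale.
_OPEN_EDGE_EPS = 1e-9


def fuzzify(
    rule: CrispRule,
    slope_scale: float = 1.0,
    upper_open=False,
) -> FuzzyRule:
    """Replace each crisp interval [lo, hi] by a possibility distribution with
    center (lo+hi)/2, width hi-lo and slope ``slope_scale``/width.

    ``upper_open`` marks conditions whose upper bound is exclusive (the
    half-open bins of :func:`discretize`; the final bin is closed).  It may be
    a single bool or a per-condition sequence; exclusive upper edges are
    shrunk by an infinitesimal so the possibility honours the half-openness.
    """
    if isinstance(upper_open, bool):
        upper_open = [upper_open] * len(rule.antecedent)
    conds = []
    for (feature, lo, hi), open_hi in zip(rule.antecedent, upper_open):
        if open_hi:
            hi = hi - _OPEN_EDGE_EPS
        width = hi - lo
        if width <= 0:
            raise ValueError(f"zero-width interval for feature {feature!r}")
        conds.append(
            FuzzyCondition(
                feature=feature,
                lam1=(lo + hi) / 2.0,
                lam2=width,
                lam3=slope_scale / width,
            )
        )
    return FuzzyRule(
        conditions=tuple(conds),
        consequent=rule.consequent,
        support=rule.support,
        confidence=rule.confidence,
        provenance=rule,
    )


def possibility(x, c: FuzzyCondition):
    """Asymmetric two-logistic possibility of x under a fuzzy condition.

    Equal to 1 at the center lam1, decaying through the interval edges
    lam1 +/- lam2/2 with logistic slope lam3, and to 0 far away.  Vectorised
    over ``x``.
    """
    x = np.asarray(x, dtype=float)
    u = c.lam3 * (x - c.lam1)  # signed slope-scaled offset from the center
    h = c.lam3 * c.lam2 / 2.0  # half-width on the same scale
    val = expit(h + u) * expit(h - u) / expit(h) ** 2
    val = np.clip(val, 0.0, 1.0)
    return float(val) if val.ndim == 0 else val


def rule_relevance(v, rule: FuzzyRule, tnorm: str = "min") -> float:
    """Relevance of one feature vector to one fuzzy rule: the t-norm of its
    condition possibilities (min by default, product optional)."""
    if tnorm not in ("min", "product"):
        raise ValueError(f"unknown t-norm {tnorm!r}")
    pis = []
    for cond in rule.conditions:
        try:
            x = v[cond.feature]
        except (KeyError, IndexError, TypeError) as exc:
            raise ValueError(f"feature {cond.feature!r} missing from vector") from exc
        pis.append(possibility(float(x), cond))
    if not pis:
        return 0.0
    return float(min(pis)) if tnorm == "min" else float(np.prod(pis))


def semantic_relevance(v, rules_for_term, tnorm: str = "min") -> float:
    """Max over the term's rules; 0 when the term has no rules."""
    if not rules_for_term:
        return 0.0
    return max(rule_relevance(v, r, tnorm) for r in rules_for_term)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def render_rule(rule: CrispRule | FuzzyRule) -> str:
    """Human-readable form: ``{F006 ∈ [0.09, 0.16] ∧ ...} → term``."""
    if isinstance(rule, FuzzyRule):
        parts = [
            f"{c.feature} ∈ [{c.lam1 - c.lam2 / 2:g}, {c.lam1 + c.lam2 / 2:g}]"
            for c in rule.conditions
        ]
    else:
        parts = [f"{f} ∈ [{lo:g}, {hi:g}]" for f, lo, hi in rule.antecedent]
    return "{" + " ∧ ".join(parts) + "} → " + rule.consequent


_RULE_RE = re.compile(
    r"\{(?P<body>.*)\}\s*(?:→|->)\s*(?P<term>\S+)", re.UNICODE
)
_COND_RE = re.compile(
    r"(?P<f>\w+)\s*(?:∈|in)\s*\[(?P<lo>[-+0-9.eE]+)\s*,\s*(?P<hi>[-+0-9.eE]+)\]"
)


def parse_rule_text(text: str, support: float = 0.0, confidence: float = 1.0) -> CrispRule:
    """Parse the ``{F ∈ [lo, hi] ∧ ...} → term`` syntax back into a rule."""
    m = _RULE_RE.search(text)
    if m is None:
        raise ValueError(f"cannot parse rule text: {text!r}")
    conds = tuple(
        (c.group("f"), float(c.group("lo")), float(c.group("hi")))
        for c in _COND_RE.finditer(m.group("body"))
    )
    if not conds:
        raise ValueError(f"rule has no parseable conditions: {text!r}")
    return CrispRule(conds, m.group("term"), support, confidence)


def rules_to_json(rules: list[FuzzyRule]) -> str:
    payload = {
        "rules": [
            {
                "antecedent": [
                    {
                        "feature": c.feature,
                        "lo": c.lam1 - c.lam2 / 2.0,
                        "hi": c.lam1 + c.lam2 / 2.0,
                        "lambda1": c.lam1,
                        "lambda2": c.lam2,
                        "lambda3": c.lam3,
                    }
                    for c in r.conditions
                ],
                "consequent": r.consequent,
                "support": r.support,
                "confidence": r.confidence,
            }
            for r in rules
        ]
    }
    return json.dumps(payload, indent=1)


def rules_from_json(text: str) -> list[FuzzyRule]:
    payload = json.loads(text)
    out = []
    for r in payload["rules"]:
        conds = tuple(
            FuzzyCondition(
                feature=c["feature"],
                lam1=c["lambda1"],
                lam2=c["lambda2"],
                lam3=c["lambda3"],
            )
            for c in r["antecedent"]
        )
        out.append(
            FuzzyRule(
                conditions=conds,
                consequent=r["consequent"],
                support=r["support"],
                confidence=r["confidence"],
            )
        )
    return out


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------


class SemanticRuleMiner(BaseEstimator):
    """Mine fuzzified class-association rules for one semantic class.

    Fit takes the raw feature table ``X`` (DataFrame, rows = images) and per-
    row term labels ``y`` (strings; None/NaN marks rows not labeled with any
    term of the class).  Fitting rescales features to [0, 1] by min-max over
    the training table, selects a discriminative subset, discretises it, mines
    crisp rules and fuzzifies them.

    Parameters
    ----------
    min_support, min_confidence, max_len : rule thresholds.
    n_bins, scheme : discretisation of the rescaled features.
    selection : feature-subset search ("greedy_stepwise", "best_first",
        "exhaustive", or None to mine on all columns).
    max_features : cap on the selected subset size.
    slope_scale : fuzzification slope, lam3 = slope_scale / width.
    tnorm : conjunction t-norm for relevance ("min" or "product").

    Attributes
    ----------
    rules_ : list of FuzzyRule.
    crisp_rules_ : list of CrispRule.
    terms_ : terms of the class seen at fit time.
    selected_features_ : columns the rules draw from.
    scale_min_, scale_range_ : per-feature min-max rescaling parameters.
    """

    def __init__(
        self,
        min_support: float = 0.05,
        min_confidence: float = 0.8,
        max_len: int = 3,
        n_bins: int = 10,
        scheme: str = "equal_width",
        selection: str | None = "greedy_stepwise",
        max_features: int = 8,
        slope_scale: float = 1.0,
        tnorm: str = "min",
        prune_specializations: bool = True,
    ):
        self.min_support = min_support
        self.min_confidence = min_confidence
        self.max_len = max_len
        self.n_bins = n_bins
        self.scheme = scheme
        self.selection = selection
        self.max_features = max_features
        self.slope_scale = slope_scale
        self.tnorm = tnorm
        self.prune_specializations = prune_specializations

    # -- helpers -----------------------------------------------------------
    def _rescaled(self, X: pd.DataFrame) -> pd.DataFrame:
        Z = (X[self.feature_names_in_] - self.scale_min_) / self.scale_range_
        return Z

    @staticmethod
    def _clean_labels(y) -> np.ndarray:
        out = np.asarray(
            [t if isinstance(t, str) and t else None for t in np.asarray(y, object)],
            dtype=object,
        )
        return out

    # -- estimator API -----------------------------------------------------
    def fit(self, X: pd.DataFrame, y):
        X = pd.DataFrame(X)
        y = self._clean_labels(y)
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        terms, counts = np.unique([t for t in y if t is not None], return_counts=True)
        self.terms_ = list(terms)
        n = len(X)
        usable = [
            t for t, c in zip(terms, counts) if c >= max(self.min_support * n, 1)
        ]
        if len(usable) < 2:
            warnings.warn(
                "semantic class needs >= 2 terms with at least min_support "
                "coverage; mining skipped"
            )
            self.feature_names_in_ = [str(c) for c in X.columns]
            self.scale_min_ = X.min(axis=0)
            self.scale_range_ = (X.max(axis=0) - self.scale_min_).replace(0, 1.0)
            self.selected_features_ = []
            self.crisp_rules_ = []
            self.rules_ = []
            return self

        self.feature_names_in_ = [str(c) for c in X.columns]
        X = X.set_axis(self.feature_names_in_, axis=1)
        self.scale_min_ = X.min(axis=0)
        self.scale_range_ = (X.max(axis=0) - self.scale_min_).replace(0, 1.0)
        Z = self._rescaled(X)

        if self.selection is None:
            selected = list(Z.columns)
        else:
            selected = select_features(
                Z, y, method=self.selection, max_features=self.max_features
            )
        self.selected_features_ = selected

        disc = discretize(Z[selected], n_bins=self.n_bins, scheme=self.scheme)
        self.discretized_ = disc
        self.crisp_rules_ = mine_rules(
            disc,
            y,
            min_support=self.min_support,
            min_confidence=self.min_confidence,
            max_len=self.max_len,
            prune_specializations=self.prune_specializations,
        )
        last_edge = {
            name: float(disc.edges[i][-1]) for i, name in enumerate(disc.feature_names)
        }
        self.rules_ = [
            fuzzify(
                r,
                self.slope_scale,
                upper_open=[hi < last_edge[f] for f, _, hi in r.antecedent],
            )
            for r in self.crisp_rules_
        ]
        return self

    def rules_for(self, term: str) -> list[FuzzyRule]:
        return [r for r in self.rules_ if r.consequent == term]

    def relevance(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-term semantic relevance for every row of ``X`` (raw scale)."""
        X = pd.DataFrame(X)
        Z = self._rescaled(X)
        out = pd.DataFrame(0.0, index=X.index, columns=self.terms_)
        for term in self.terms_:
            term_rules = self.rules_for(term)
            if not term_rules:
                continue
            scores = np.zeros(len(Z))
            for rule in term_rules:
                pis = np.ones((len(Z), len(rule.conditions)))
                for i, cond in enumerate(rule.conditions):
                    if cond.feature not in Z.columns:
                        raise ValueError(f"feature {cond.feature!r} missing from X")
                    pis[:, i] = possibility(Z[cond.feature].to_numpy(), cond)
                r = pis.min(axis=1) if self.tnorm == "min" else pis.prod(axis=1)
                scores = np.maximum(scores, r)
            out[term] = scores
        return out

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        rel = self.relevance(X)
        if rel.shape[1] == 0:
            return np.array([None] * len(rel), dtype=object)
        best = rel.idxmax(axis=1).to_numpy(dtype=object)
        best[rel.max(axis=1).to_numpy() <= 0] = None
        return best
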