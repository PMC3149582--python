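"""Independent brute-force oracles used to pin expected values.

These deliberately re-derive results from first principles (naive nested
loops, explicit enumeration) and share no code with the implementation paths
they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_rules(codes, edges, names, y, min_support, min_confidence, max_len):
    """Enumerate every interval-conjunction rule by exhaustive search.

    Returns a set of hashable rule descriptors:
    (consequent, ((feature, lo, hi), ...) sorted by feature, support, confidence)
    with support/confidence rounded to 12 decimals.
    """
    n, m = codes.shape
    per_feature = []
    for f in range(m):
        k = len(edges[f]) - 1
        ivals = []
        for lo_bin in range(k):
            for hi_bin in range(lo_bin, k):
                member = [(lo_bin <= codes[i, f] <= hi_bin) for i in range(n)]
                ivals.append(
                    (float(edges[f][lo_bin]), float(edges[f][hi_bin + 1]), member)
                )
        per_feature.append(ivals)

    terms = sorted({t for t in y if isinstance(t, str)})
    found = set()
    for size in range(1, max_len + 1):
        for feats in itertools.combinations(range(m), size):
            for choice in itertools.product(*(per_feature[f] for f in feats)):
                member = [all(c[2][i] for c in choice) for i in range(n)]
                ant = sum(member)
                if ant == 0:
                    continue
                for term in terms:
                    joint = sum(1 for i in range(n) if member[i] and y[i] == term)
                    support = joint / n
                    if support < min_support - 1e-9:
                        continue
                    conf = joint / ant
                    if conf < min_confidence - 1e-9:
                        continue
                    conds = tuple(
                        (names[f], c[0], c[1]) for f, c in zip(feats, choice)
                    )
                    found.add((term, conds, round(support, 12), round(conf, 12)))
    return found


def average_precision_oracle(ranking, relevant):
    """AP straight from its definition, one precision term per relevant item."""
    precisions = []
    seen = 0
    for rank, item in enumerate(ranking, start=1):
        if item in relevant:
            seen += 1
            precisions.append(seen / rank)
    precisions += [0.0] * (len(relevant) - seen)
    return float(np.mean(precisions))


def simulate_null_ap(n_total, n_relevant, n_sim, rng):
    """Average precision of uniformly random rankings (null model)."""
    items = list(range(n_total))
    out = np.empty(n_sim)
    for s in range(n_sim):
        ranking = rng.permutation(items)
        relevant = set(rng.choice(items, size=n_relevant, replace=False).tolist())
        out[s] = average_precision_oracle(ranking.tolist(), relevant)
    return out
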