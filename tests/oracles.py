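"""Independent brute-force oracles for the information estimators and criteria.

Everything here enumerates contingency-table cells directly from the
definitions — probability dictionaries and explicit sums, no entropy
identities, no numpy vectorisation, no memoization — so it is a genuinely
independent re-derivation of what the package computes.
"""

from __future__ import annotations

import math
from collections import Counter


def _probs(*vectors):
    n = len(vectors[0])
    counts = Counter(tuple(v[i] for v in vectors) for i in range(n))
    return {k: c / n for k, c in counts.items()}


def entropy(x, base=2.0):
    return -sum(p * math.log(p, base) for p in _probs(x).values() if p > 0)


def mutual_information(x, y, base=2.0):
    pxy = _probs(x, y)
    px = _probs(x)
    py = _probs(y)
    total = 0.0
    for (a, b), p in pxy.items():
        total += p * math.log(p / (px[(a,)] * py[(b,)]), base)
    return total


def conditional_mutual_information(x, y, z, base=2.0):
    """Sum over strata of z: p(z) * MI(x, y within the stratum)."""
    n = len(x)
    total = 0.0
    for zv, pz in _probs(z).items():
        idx = [i for i in range(n) if z[i] == zv[0]]
        xs = [x[i] for i in idx]
        ys = [y[i] for i in idx]
        total += pz * mutual_information(xs, ys, base)
    return total


def interaction_information(x, y, z, base=2.0):
    xy = [(x[i], y[i]) for i in range(len(x))]
    return (
        mutual_information(xy, z, base)
        - mutual_information(x, z, base)
        - mutual_information(y, z, base)
    )


def weight_omega(fj, fk, c, base=2.0):
    denom = entropy(fj, base) + entropy(c, base)
    if denom == 0:
        return 1.0
    return 1.0 + 2.0 * (
        conditional_mutual_information(fj, c, fk, base) - mutual_information(fj, c, base)
    ) / denom


def joint_entropy(*vectors, base=2.0):
    return -sum(p * math.log(p, base) for p in _probs(*vectors).values())


def criterion_score(name, columns, c, selected, fk, beta=1.0, base=2.0):
    """Re-derive one candidate's score for any criterion, from definitions.

    ``columns`` maps feature name -> plain list of codes; ``selected`` is the
    ordered list of already-chosen names; ``fk`` the candidate.
    """
    xk = columns[fk]
    if not selected:
        return mutual_information(xk, c, base)
    if name == "wbfs":
        return sum(
            weight_omega(columns[fj], xk, c, base)
            * conditional_mutual_information(xk, c, columns[fj], base)
            for fj in selected
        )
    if name == "mim":
        return mutual_information(xk, c, base)
    if name == "mifs":
        return mutual_information(xk, c, base) - beta * sum(
            mutual_information(xk, columns[fj], base) for fj in selected
        )
    if name == "mrmr":
        return mutual_information(xk, c, base) - sum(
            mutual_information(xk, columns[fj], base) for fj in selected
        ) / len(selected)
    if name == "cife":
        return (
            mutual_information(xk, c, base)
            - sum(mutual_information(xk, columns[fj], base) for fj in selected)
            + sum(
                conditional_mutual_information(xk, columns[fj], c, base)
                for fj in selected
            )
        )
    if name == "condred":
        return mutual_information(xk, c, base) + sum(
            conditional_mutual_information(xk, columns[fj], c, base)
            for fj in selected
        )
    if name == "disr":
        total = 0.0
        for fj in selected:
            pair = [(xk[i], columns[fj][i]) for i in range(len(xk))]
            h = joint_entropy(xk, columns[fj], c, base=base)
            total += mutual_information(pair, c, base) / h if h > 0 else 0.0
        return total
    raise ValueError(name)


def greedy_select(name, columns, c, K, beta=1.0, base=2.0, tie_tol=1e-9):
    """Full greedy ranking from the definitions, ties to earliest name order.

    Scores within ``tie_tol`` are treated as mathematically tied so that this
    oracle's own floating-point noise cannot break an exact tie differently
    from the convention (earliest column wins).
    """
    names = list(columns)
    selected = []
    scores = []
    for _ in range(K):
        best, best_score = None, None
        for fk in names:
            if fk in selected:
                continue
            s = criterion_score(name, columns, c, selected, fk, beta, base)
            if best_score is None or s > best_score + tie_tol:
                best, best_score = fk, s
        selected.append(best)
        scores.append(best_score)
    return selected, scores
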