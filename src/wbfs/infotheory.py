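"""Plug-in information estimators on integer-coded vectors.

All quantities are computed from empirical contingency frequencies (the
plug-in estimator) with the ``0·log 0 := 0`` convention and no bias
correction.  The default logarithm base is 2, i.e. results are in bits;
every ranking decision downstream is invariant to the base.

The interaction-gain weight ω multiplies a candidate feature's conditional
mutual information in the WBFS objective:

    ω(fj, fk) = 1 + 2·(I(fj;C|fk) − I(fj;C)) / (H(fj) + H(C))

ω exceeds 1 exactly when conditioning on the candidate fk *increases* what
the already-selected fj says about the class — positive interaction — and
falls below 1 when fk screens fj off (redundancy).  The normalisation pins
ω to [0, 2]; a noise-free XOR pair attains the upper bound.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "entropy",
    "joint_entropy",
    "mutual_information",
    "conditional_mutual_information",
    "interaction_information",
    "weight_omega",
    "pair_codes",
]


def _counts(*vectors: np.ndarray) -> np.ndarray:
    """Joint contingency counts over 1–3 coded vectors (flat, nonzero kept)."""
    vs = [np.asarray(v) for v in vectors]
    n = vs[0].shape[0]
    if n == 0:
        raise ValueError("empty vector")
    for v in vs[1:]:
        if v.shape[0] != n:
            raise ValueError(f"length mismatch: {n} vs {v.shape[0]}")
    if len(vs) == 1:
        _, counts = np.unique(vs[0], return_counts=True)
        return counts
    stacked = np.column_stack(vs)
    _, counts = np.unique(stacked, axis=0, return_counts=True)
    return counts


def _entropy_from_counts(counts: np.ndarray, base: float) -> float:
    n = counts.sum()
    p = counts / n
    return float(-(p * np.log(p)).sum() / math.log(base))


def entropy(x: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy H(X) of one coded vector."""
    if base <= 1:
        raise ValueError("base must exceed 1")
    return _entropy_from_counts(_counts(x), base)


def joint_entropy(*vectors: np.ndarray, base: float = 2.0) -> float:
    """Joint entropy H(X1, ..., Xk) of up to three coded vectors."""
    if base <= 1:
        raise ValueError("base must exceed 1")
    return _entropy_from_counts(_counts(*vectors), base)


def mutual_information(x: np.ndarray, y: np.ndarray, base: float = 2.0) -> float:
    """I(X;Y) = H(X) + H(Y) − H(X,Y); symmetric and nonnegative."""
    h = (
        _entropy_from_counts(_counts(x), base)
        + _entropy_from_counts(_counts(y), base)
        - _entropy_from_counts(_counts(x, y), base)
    )
    return max(h, 0.0)


def conditional_mutual_information(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, base: float = 2.0
) -> float:
    """I(X;Y|Z) = H(X,Z) + H(Y,Z) − H(X,Y,Z) − H(Z).

    Equals the p(z)-weighted average of within-stratum mutual informations;
    strata with zero mass contribute nothing.
    """
    h = (
        _entropy_from_counts(_counts(x, z), base)
        + _entropy_from_counts(_counts(y, z), base)
        - _entropy_from_counts(_counts(x, y, z), base)
        - _entropy_from_counts(_counts(z), base)
    )
    return max(h, 0.0)


def pair_codes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Code the pair (x, y) as a single categorical variable."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("length mismatch")
    _, inv = np.unique(np.column_stack([x, y]), axis=0, return_inverse=True)
    return inv


def interaction_information(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, base: float = 2.0
) -> float:
    """Three-way interaction I(X;Y;Z) = I(X,Y;Z) − I(X;Z) − I(Y;Z).

    The joint variable (X,Y) is formed by pairing codes.  Positive values
    mean synergy: the pair carries class information neither member carries
    alone.  May be negative (redundancy) or zero.
    """
    xy = pair_codes(x, y)
    return (
        mutual_information(xy, z, base)
        - mutual_information(x, z, base)
        - mutual_information(y, z, base)
    )


def weight_omega(
    fj: np.ndarray, fk: np.ndarray, c: np.ndarray, base: float = 2.0
) -> float:
    """Interaction-gain weight ω(fj, fk) ∈ [0, 2].

    ``fj`` is the already-selected feature, ``fk`` the candidate, ``c`` the
    class.  When both fj and c are constant the ratio degenerates to 0/0;
    the weight is then defined as the neutral value 1.
    """
    denom = entropy(fj, base) + entropy(c, base)
    if denom == 0.0:
        return 1.0
    gain = conditional_mutual_information(fj, c, fk, base) - mutual_information(
        fj, c, base
    )
    return 1.0 + 2.0 * gain / denom
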