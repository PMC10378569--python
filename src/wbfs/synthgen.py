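"""Planted-structure synthetic tables with known ground truth.

The generator emulates the statistical structure a weight-based selector
must resolve on omics-style tables: features that are noisy copies of the
class (*relevant*), noisy duplicates of those copies (*redundant*), pairs
whose XOR equals a binary class while each parent alone is independent of
it (*xor_parent* — pure interaction), and independent uniform *noise*.
An optional bounded jitter turns the integer codes into continuous values
so the equal-width discretizer can be exercised end to end: the jitter
amplitude stays below half the unit code spacing, so binning with
``bins == arity`` recovers the codes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatable import FeatureTable
from .selectors import SelectionTrace

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "recovery_score"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic table.

    Probabilities are symmetric corruption rates in [0, 0.5]: a *flip*
    replaces the code by a uniformly random different code.
    """

    n_samples: int = 400
    n_classes: int = 2
    n_relevant: int = 0
    flip_probability: float = 0.1
    n_redundant: int = 0
    duplicate_noise: float = 0.1
    n_xor_pairs: int = 0
    pair_flip_probability: float = 0.05
    n_noise: int = 0
    continuous_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_classes < 2:
            raise ValueError("need n_samples >= 1 and n_classes >= 2")
        counts = (self.n_relevant, self.n_redundant, self.n_xor_pairs,
                  self.n_noise)
        if any(c < 0 for c in counts) or sum(counts) == 0:
            raise ValueError("feature counts must be >= 0 with at least one feature")
        if self.n_redundant > 0 and self.n_relevant == 0:
            raise ValueError("redundant features require at least one relevant feature")
        for p in (self.flip_probability, self.duplicate_noise,
                  self.pair_flip_probability):
            if not 0.0 <= p <= 0.5:
                raise ValueError("corruption probabilities must lie in [0, 0.5]")
        if self.n_xor_pairs > 0 and self.n_classes != 2:
            raise ValueError("xor pairs require a binary class")
        if not 0.0 <= self.continuous_jitter < 0.5:
            raise ValueError("continuous_jitter must lie in [0, 0.5)")


@dataclass
class GroundTruth:
    """Role per feature and the index pairs of planted XOR parents."""

    roles: list[str]  # each in {relevant, redundant, xor_parent, noise}
    xor_pairs: list[tuple[int, int]] = field(default_factory=list)

    def target_features(self) -> list[int]:
        """Indices of planted non-noise, non-duplicate features."""
        return [i for i, r in enumerate(self.roles)
                if r in ("relevant", "xor_parent")]


def _flip(rng: np.ndarray, codes: np.ndarray, arity: int, p: float,
          gen: np.random.Generator) -> np.ndarray:
    """Symmetric corruption: with prob p replace by a uniform *other* code."""
    out = codes.copy()
    hit = gen.random(len(codes)) < p
    if hit.any() and arity > 1:
        shift = gen.integers(1, arity, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % arity
    return out


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one table; a fixed seed yields an identical result."""
    gen = np.random.default_rng(spec.seed)
    n, c = spec.n_samples, spec.n_classes
    y = gen.integers(0, c, size=n)

    cols: list[np.ndarray] = []
    names: list[str] = []
    roles: list[str] = []
    xor_pairs: list[tuple[int, int]] = []

    relevant_idx: list[int] = []
    for i in range(spec.n_relevant):
        cols.append(_flip(None, y, c, spec.flip_probability, gen))
        names.append(f"rel{i}")
        roles.append("relevant")
        relevant_idx.append(len(cols) - 1)
    for i in range(spec.n_redundant):
        src = relevant_idx[i % len(relevant_idx)]
        cols.append(_flip(None, cols[src], c, spec.duplicate_noise, gen))
        names.append(f"red{i}")
        roles.append("redundant")
    for i in range(spec.n_xor_pairs):
        a = gen.integers(0, 2, size=n)
        b = y ^ a
        a = _flip(None, a, 2, spec.pair_flip_probability, gen)
        b = _flip(None, b, 2, spec.pair_flip_probability, gen)
        cols.extend([a, b])
        names.extend([f"xorA{i}", f"xorB{i}"])
        roles.extend(["xor_parent", "xor_parent"])
        xor_pairs.append((len(cols) - 2, len(cols) - 1))
    for i in range(spec.n_noise):
        cols.append(gen.integers(0, c, size=n))
        names.append(f"noise{i}")
        roles.append("noise")

    values = np.column_stack(cols).astype(float)
    if spec.continuous_jitter > 0:
        j = spec.continuous_jitter
        values = values + gen.uniform(-j, j, size=values.shape)

    table = FeatureTable(values, names, y.astype(object))
    return table, GroundTruth(roles, xor_pairs)


def recovery_score(trace: SelectionTrace, truth: GroundTruth,
                   top_k: int) -> float:
    """Fraction of planted target features found in the first ``top_k``.

    Targets are the relevant features and XOR parents; redundant duplicates
    and noise do not count toward the denominator.
    """
    if top_k > len(trace):
        raise ValueError("top_k exceeds trace length")
    targets = truth.target_features()
    if not targets:
        return 0.0
    # trace stores names; map truth indices through the generator's naming
    top = set(trace.selected[:top_k])
    found = sum(1 for i in targets if _name_of(truth, i) in top)
    return found / len(targets)


def _name_of(truth: GroundTruth, index: int) -> str:
    """Reconstruct the generated feature name for a truth index."""
    role = truth.roles[index]
    prior = sum(1 for r in truth.roles[:index] if r == role)
    if role == "relevant":
        return f"rel{prior}"
    if role == "redundant":
        return f"red{prior}"
    if role == "noise":
        return f"noise{prior}"
    # xor parents alternate A/B within each pair
    for p, (a, b) in enumerate(truth.xor_pairs):
        if index == a:
            return f"xorA{p}"
        if index == b:
            return f"xorB{p}"
    raise ValueError(f"index {index} not found in ground truth")
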