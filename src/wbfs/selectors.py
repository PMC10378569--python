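"""Greedy forward feature-ranking criteria.

All seven criteria share one loop: at each step every remaining candidate
``fk`` is scored against the selected set ``S`` and the argmax is appended,
with ties broken by the lowest original column index.  At step 1 every
criterion reduces to plain mutual information with the class (empty sums
vanish), so the first feature is always ``argmax I(f;C)``.

Criteria
--------
``wbfs``
    J = Σ_{fj∈S} ω(fj, fk) · I(fk;C|fj) — conditional relevance weighted by
    the interaction gain the candidate confers on each selected feature.
``mim``
    J = I(fk;C) — relevance only.
``mifs``
    J = I(fk;C) − β · Σ I(fk;fj).
``mrmr``
    J = I(fk;C) − (1/|S|) · Σ I(fk;fj).
``cife``
    J = I(fk;C) − Σ I(fk;fj) + Σ I(fk;fj|C).
``condred``
    J = I(fk;C) + Σ I(fk;fj|C).
``disr``
    J = Σ I((fk,fj);C) / H(fk,fj,C), the double-input symmetrical relevance.

Information quantities are memoized per selection run; results are
identical to the unmemoized evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discretize import DiscreteTable
from .infotheory import (
    conditional_mutual_information,
    entropy,
    joint_entropy,
    mutual_information,
    pair_codes,
    weight_omega,
)

__all__ = [
    "CRITERIA",
    "CriterionSpec",
    "SelectionTrace",
    "score_wbfs_candidate",
    "select",
    "rank_full",
    "write_ranking",
]

CRITERIA = ("wbfs", "mim", "mifs", "mrmr", "cife", "condred", "disr")


@dataclass(frozen=True)
class CriterionSpec:
    """A named ranking criterion with its parameters."""

    name: str = "wbfs"
    beta: float = 1.0  # MIFS redundancy coefficient
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.name not in CRITERIA:
            raise ValueError(
                f"unknown criterion {self.name!r}; valid: {', '.join(CRITERIA)}"
            )
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")


@dataclass
class SelectionTrace:
    """Ordered selection result with full per-step audit information.

    ``candidate_scores[t]`` maps every candidate name still available at
    step ``t`` to its criterion score; ``omega_terms[t]`` (WBFS only, empty
    otherwise) lists ``(fj, ω, cmi)`` contributions for the step winner.
    """

    selected: list[str]
    step_scores: list[float]
    candidate_scores: list[dict[str, float]]
    omega_terms: list[list[tuple[str, float, float]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.selected)


class _InfoCache:
    """Memoized information quantities over one discrete table."""

    def __init__(self, data: DiscreteTable, base: float):
        self.cols = {n: data.codes[:, j] for j, n in enumerate(data.feature_names)}
        self.c = data.class_codes
        self.base = base
        self._h: dict[str, float] = {}
        self._mi_c: dict[str, float] = {}
        self._mi_ff: dict[tuple[str, str], float] = {}
        self._cmi_kc_j: dict[tuple[str, str], float] = {}
        self._cmi_ff_c: dict[tuple[str, str], float] = {}
        self._disr: dict[tuple[str, str], float] = {}
        self.h_c = entropy(self.c, base)

    def h(self, f: str) -> float:
        if f not in self._h:
            self._h[f] = entropy(self.cols[f], self.base)
        return self._h[f]

    def mi_c(self, f: str) -> float:
        if f not in self._mi_c:
            self._mi_c[f] = mutual_information(self.cols[f], self.c, self.base)
        return self._mi_c[f]

    def mi_ff(self, a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in self._mi_ff:
            self._mi_ff[key] = mutual_information(
                self.cols[a], self.cols[b], self.base
            )
        return self._mi_ff[key]

    def cmi_kc_j(self, fk: str, fj: str) -> float:
        """I(fk; C | fj)."""
        if (fk, fj) not in self._cmi_kc_j:
            self._cmi_kc_j[(fk, fj)] = conditional_mutual_information(
                self.cols[fk], self.c, self.cols[fj], self.base
            )
        return self._cmi_kc_j[(fk, fj)]

    def cmi_ff_c(self, a: str, b: str) -> float:
        """I(a; b | C)."""
        key = (a, b) if a <= b else (b, a)
        if key not in self._cmi_ff_c:
            self._cmi_ff_c[key] = conditional_mutual_information(
                self.cols[a], self.cols[b], self.c, self.base
            )
        return self._cmi_ff_c[key]

    def omega(self, fj: str, fk: str) -> float:
        """ω(fj, fk) = 1 + 2(I(fj;C|fk) − I(fj;C)) / (H(fj) + H(C))."""
        denom = self.h(fj) + self.h_c
        if denom == 0.0:
            return 1.0
        return 1.0 + 2.0 * (self.cmi_kc_j(fj, fk) - self.mi_c(fj)) / denom

    def disr_term(self, fk: str, fj: str) -> float:
        """I((fk,fj); C) / H(fk, fj, C)."""
        key = (fk, fj) if fk <= fj else (fj, fk)
        if key not in self._disr:
            xy = pair_codes(self.cols[key[0]], self.cols[key[1]])
            h_all = joint_entropy(
                self.cols[key[0]], self.cols[key[1]], self.c, base=self.base
            )
            num = mutual_information(xy, self.c, self.base)
            self._disr[key] = num / h_all if h_all > 0 else 0.0
        return self._disr[key]


def _score(cache: _InfoCache, spec: CriterionSpec, selected: list[str],
           fk: str) -> float:
    name = spec.name
    if name == "wbfs":
        return sum(
            cache.omega(fj, fk) * cache.cmi_kc_j(fk, fj) for fj in selected
        )
    if name == "mim":
        return cache.mi_c(fk)
    if name == "mifs":
        return cache.mi_c(fk) - spec.beta * sum(
            cache.mi_ff(fk, fj) for fj in selected
        )
    if name == "mrmr":
        red = sum(cache.mi_ff(fk, fj) for fj in selected)
        return cache.mi_c(fk) - red / len(selected)
    if name == "cife":
        return cache.mi_c(fk) + sum(
            cache.cmi_ff_c(fk, fj) - cache.mi_ff(fk, fj) for fj in selected
        )
    if name == "condred":
        return cache.mi_c(fk) + sum(cache.cmi_ff_c(fk, fj) for fj in selected)
    if name == "disr":
        return sum(cache.disr_term(fk, fj) for fj in selected)
    raise ValueError(f"unknown criterion {name!r}")


def score_wbfs_candidate(
    data: DiscreteTable,
    selected: list[str],
    fk: str,
    log_base: float = 2.0,
) -> float:
    """WBFS objective J(fk) = Σ_{fj∈S} ω(fj, fk) · I(fk;C|fj)."""
    unknown = [f for f in list(selected) + [fk] if f not in data.feature_names]
    if unknown:
        raise ValueError(f"unknown feature names: {unknown}")
    if fk in selected:
        raise ValueError(f"candidate {fk!r} already selected")
    if not selected:
        raise ValueError("selected set must be nonempty")
    cache = _InfoCache(data, log_base)
    return _score(cache, CriterionSpec("wbfs", log_base=log_base),
                  list(selected), fk)


def select(data: DiscreteTable, criterion: CriterionSpec, K: int) -> SelectionTrace:
    """Greedy forward selection of ``K`` features under one criterion.

    Step 1 picks ``argmax I(f;C)``; each later step scores every remaining
    candidate and appends the single argmax.  Ties break to the lowest
    original column index at every step, deterministically.
    """
    m = data.n_features
    if K < 1 or K > m:
        raise ValueError(f"K={K} out of range 1..{m}")
    if data.n_classes < 2:
        raise ValueError("class vector is constant; selection is undefined")
    cache = _InfoCache(data, criterion.log_base)
    order = list(data.feature_names)  # original column order for tie-breaks
    remaining = list(order)
    selected: list[str] = []
    step_scores: list[float] = []
    candidate_scores: list[dict[str, float]] = []
    omega_terms: list[list[tuple[str, float, float]]] = []

    for _ in range(K):
        if not selected:
            scores = {f: cache.mi_c(f) for f in remaining}
        else:
            scores = {
                f: _score(cache, criterion, selected, f) for f in remaining
            }
        best = max(remaining, key=lambda f: scores[f])  # first max wins ties
        candidate_scores.append(scores)
        step_scores.append(scores[best])
        if criterion.name == "wbfs" and selected:
            omega_terms.append(
                [
                    (fj, cache.omega(fj, best), cache.cmi_kc_j(best, fj))
                    for fj in selected
                ]
            )
        else:
            omega_terms.append([])
        selected.append(best)
        remaining.remove(best)

    return SelectionTrace(selected, step_scores, candidate_scores, omega_terms)


def rank_full(data: DiscreteTable, criterion: CriterionSpec) -> SelectionTrace:
    """Rank all features (``select`` with K = m)."""
    return select(data, criterion, data.n_features)


def write_ranking(trace: SelectionTrace, path) -> None:
    """Write a rank / feature / score TSV."""
    with open(path, "w") as fh:
        fh.write("rank\tfeature\tscore\n")
        for i, (name, score) in enumerate(zip(trace.selected, trace.step_scores), 1):
            fh.write(f"{i}\t{name}\t{score:.10g}\n")
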