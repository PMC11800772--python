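"""Brute-force exact inference by enumeration.

Ground truth for every message formula and for small-graph tests: the
partition function, exact marginals, the global MAP assignment, and the
literal tempered factor-to-variable update evaluated by enumerating all
joint states of the factor's other neighbors.

Everything is evaluated in the log domain; joint scores for a whole graph
are materialized as a single vector over all joint states (row-major, the
first variable most significant), subject to an enumeration budget.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .factor_graph import SENTINEL, FactorGraph, FactorSpec, apply_evidence
from .factors import MAX_PRODUCT, dense_log_potential


@dataclass(frozen=True)
class EnumerationBudget:
    """Hard cap on the number of joint states an oracle call may visit."""

    max_joint_states: int = 2**20


class BudgetExceeded(RuntimeError):
    pass


def _joint_scores(graph: FactorGraph, budget: EnumerationBudget):
    """Return (variable order, per-variable state index arrays, joint
    log-score vector) over all joint states."""
    order = list(graph.variables)
    cards = [graph.cardinality(v) for v in order]
    total = int(np.prod(cards, dtype=np.int64)) if cards else 1
    if total > budget.max_joint_states:
        raise BudgetExceeded(
            f"{total} joint states exceed budget {budget.max_joint_states}"
        )
    # row-major decode: first variable most significant
    strides = np.ones(len(cards), dtype=np.int64)
    for k in range(len(cards) - 2, -1, -1):
        strides[k] = strides[k + 1] * cards[k + 1]
    idx = np.arange(total, dtype=np.int64)
    states = {
        v: (idx // strides[k]) % cards[k] for k, v in enumerate(order)
    }
    scores = np.zeros(total)
    for factor in graph.factors.values():
        table = dense_log_potential(factor, graph.neighbor_cards(factor))
        scores += table[tuple(states[v] for v in factor.neighbor_ids)]
    # clamps as hard unary constraints
    for vid, state in graph.clamps.items():
        scores = np.where(states[vid] == state, scores, -np.inf)
    scores = np.where(scores <= -SENTINEL / 2, -np.inf, scores)
    return order, states, scores


def _with_evidence(graph: FactorGraph, evidence) -> FactorGraph:
    g = graph.copy()
    if evidence:
        apply_evidence(g, evidence)
    return g


def enumerate_log_partition(
    graph: FactorGraph,
    evidence: Mapping | None = None,
    T: float = 1.0,
    budget: EnumerationBudget = EnumerationBudget(),
) -> float:
    """Tempered log-partition function T * log sum_x exp(sum_a f_a / T)."""
    g = _with_evidence(graph, evidence)
    _, _, scores = _joint_scores(g, budget)
    T = float(T)
    return float(T * logsumexp(scores / T))


def enumerate_marginals(
    graph: FactorGraph,
    evidence: Mapping | None = None,
    T: float = 1.0,
    budget: EnumerationBudget = EnumerationBudget(),
) -> dict[str, np.ndarray]:
    """Exact per-variable marginals of the tempered distribution
    p_T(x) propto exp(sum_a f_a(x_a) / T)."""
    g = _with_evidence(graph, evidence)
    order, states, scores = _joint_scores(g, budget)
    T = float(T)
    w = np.exp(scores / T - np.max(scores / T))
    out = {}
    for v in order:
        card = g.cardinality(v)
        marg = np.bincount(states[v], weights=w, minlength=card)
        out[v] = marg / marg.sum()
    return out


def enumerate_map(
    graph: FactorGraph,
    evidence: Mapping | None = None,
    budget: EnumerationBudget = EnumerationBudget(),
) -> tuple[dict[str, int], float]:
    """Global maximizing configuration and its joint log-potential.

    Ties resolve to the lexicographically smallest assignment in variable
    insertion order (state 0 first).
    """
    g = _with_evidence(graph, evidence)
    order, states, scores = _joint_scores(g, budget)
    best = int(np.argmax(scores))  # first occurrence = lexicographically least
    assignment = {v: int(states[v][best]) for v in order}
    return assignment, float(scores[best])


def map_is_unique(
    graph: FactorGraph,
    evidence: Mapping | None = None,
    margin: float = 1e-9,
    budget: EnumerationBudget = EnumerationBudget(),
) -> bool:
    """True if the optimum is unique up to ``margin``."""
    g = _with_evidence(graph, evidence)
    _, _, scores = _joint_scores(g, budget)
    top = np.partition(scores, -2)[-2:]
    return bool(top[1] - top[0] > margin)


def enumerate_factor_message(
    factor: FactorSpec,
    cards: Sequence[int],
    incoming: Sequence[np.ndarray],
    target: int,
    T=1.0,
) -> np.ndarray:
    """Literal tempered factor-to-variable update by enumeration.

    ``incoming[j]`` is the full message vector from neighbor j (the
    target's own entry is ignored); ``target`` indexes into the factor's
    neighbor order.  Returns the unnormalized message vector

    ``m(x_i) = T log sum_{x_others} exp[(f(x) + sum_{j != i} m_j(x_j)) / T]``

    or the (max, +) analogue for MAX_PRODUCT.
    """
    cards = tuple(int(c) for c in cards)
    table = dense_log_potential(factor, cards).astype(float)
    table = np.where(table <= -SENTINEL / 2, -np.inf, table)
    total = table.copy()
    for j, card in enumerate(cards):
        if j == target:
            continue
        vec = np.asarray(incoming[j], dtype=float)
        shape = [1] * len(cards)
        shape[j] = card
        total = total + vec.reshape(shape)
    axes = tuple(j for j in range(len(cards)) if j != target)
    if T == MAX_PRODUCT:
        out = np.max(total, axis=axes)
    else:
        T = float(T)
        with np.errstate(divide="ignore"):
            out = T * logsumexp(total / T, axis=axes)
    return np.where(np.isneginf(out), -SENTINEL, out)
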