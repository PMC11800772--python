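"""Temperature-parameterized belief propagation.

The engine iterates two kinds of log-domain message updates on a factor
graph:

- variable -> factor: the sum of the variable's other incoming messages,
- factor -> variable: the tempered marginalization
  ``m(x_i) = T log sum_{x_others} exp[(f(x) + sum_{j!=i} m_j(x_j)) / T]``
  for temperature T in (0, 1], or the exact (max, +) form
  ``m(x_i) = max_{x_others} [f(x) + sum_j m_j(x_j)]`` for MAX_PRODUCT.

T = 1 is sum-product (beliefs approximate marginals); MAX_PRODUCT is
max-product (beliefs approximate max-marginals, decoded to a MAP
assignment).  MAX_PRODUCT is exact algebra on the (max, +) semiring, never
a small-temperature numeric limit.

Messages are normalized after every update: binary messages are stored
with the x=0 entry pinned at 0 (the single-scalar convention), categorical
messages are shifted so their maximum is 0.  Beliefs are invariant to
these shifts.  Specialized closed-form updates from :mod:`rcnbp.factors`
handle OR / POOL / EDGE_APPEARANCE factors; TABLE and CHANNEL factors go
through the generic tempered update.

Fixed points of these updates are stationary points of the Bethe free
energy; on trees one leaves-in/root-out sweep pair is exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from . import factors as _factors
from .factor_graph import (
    SENTINEL,
    FactorGraph,
    FactorSpec,
    apply_evidence,
    clamp as _clamp,
    clamp_message,
)
from .factors import (
    MAX_PRODUCT,
    EdgeAppearanceParams,
    ORFactorParams,
    PoolFactorParams,
    dense_log_potential,
    edge_appearance_messages,
    or_messages,
    pool_messages_checked,
)

#: A schedule is an ordered list of update groups.  Each group is a list of
#: directed edges (factor id, target variable id or None for all targets);
#: updates within a group are computed jointly from the pre-group messages
#: (parallel/Jacobi semantics), groups apply sequentially.
Schedule = list[list[tuple[str, str | None]]]


@dataclass
class BPSettings:
    """Inference settings.

    temperature: real in (0, 1] or MAX_PRODUCT.
    damping: in [0, 1); each applied message is
        damping * old + (1 - damping) * computed.
    tolerance: max-abs message change declaring convergence.
    perturbation: scale of seeded Gaussian noise added to the initial
        messages (and an infinitesimal seeded tie-break in decoding); used
        to explore bistable solutions.
    """

    temperature: object = 1.0
    damping: float = 0.0
    max_iterations: int = 200
    tolerance: float = 1e-6
    seed: int = 0
    sentinel: float = SENTINEL
    perturbation: float = 0.0

    def __post_init__(self):
        if self.temperature != MAX_PRODUCT and not (0 < float(self.temperature) <= 1):
            raise ValueError("temperature must be in (0, 1] or MAX_PRODUCT")
        if not (0 <= self.damping < 1):
            raise ValueError("damping must be in [0, 1)")


class DivergenceError(RuntimeError):
    """A message became non-finite; reports the offending edge."""

    def __init__(self, fid: str, vid: str):
        super().__init__(f"non-finite message on edge {fid!r} -> {vid!r}")
        self.edge = (fid, vid)


@dataclass
class Beliefs:
    """Per-variable log-beliefs (sum of incoming factor messages) plus the
    temperature they were computed at."""

    log_beliefs: dict[str, np.ndarray]
    temperature: object = 1.0

    def llr(self, vid: str) -> float:
        b = self.log_beliefs[vid]
        return float(b[1] - b[0])

    def marginal(self, vid: str) -> np.ndarray:
        """Normalized (pseudo)marginal: softmax of belief / T."""
        T = 1.0 if self.temperature == MAX_PRODUCT else float(self.temperature)
        b = self.log_beliefs[vid] / T
        b = b - np.max(b)
        p = np.exp(b)
        return p / p.sum()

    def argmax(self, vid: str) -> int:
        return int(np.argmax(self.log_beliefs[vid]))


Assignment = dict[str, int]


class MessageStore:
    """Directed factor->variable messages plus per-variable accumulators.

    The accumulator ``belief_acc[v]`` always equals the sum of all stored
    messages into ``v``, so a variable->factor message is the O(1)
    difference ``belief_acc[v] - msg[(f, v)]``.
    """

    def __init__(self, graph: FactorGraph):
        self.graph = graph
        self.msg: dict[tuple[str, str], np.ndarray] = {}
        self.belief_acc: dict[str, np.ndarray] = {
            v: np.zeros(graph.cardinality(v)) for v in graph.variables
        }
        self.iteration = 0
        for fid, f in graph.factors.items():
            for vid in f.neighbor_ids:
                self.msg[(fid, vid)] = np.zeros(graph.cardinality(vid))

    def perturb(self, scale: float, seed: int) -> None:
        """Add seeded Gaussian noise to every message (normalized)."""
        rng = np.random.default_rng(seed)
        for key, vec in self.msg.items():
            noisy = normalize_message(vec + rng.normal(0.0, scale, vec.shape))
            self.belief_acc[key[1]] += noisy - vec
            self.msg[key] = noisy

    def set_message(self, fid: str, vid: str, vec: np.ndarray) -> float:
        old = self.msg[(fid, vid)]
        delta = float(np.max(np.abs(vec - old)))
        self.belief_acc[vid] += vec - old
        self.msg[(fid, vid)] = vec
        return delta


def normalize_message(vec: np.ndarray) -> np.ndarray:
    """Binary: pin entry 0 at 0; categorical: shift the max to 0."""
    vec = np.clip(vec, -SENTINEL, SENTINEL)
    if len(vec) == 2:
        return vec - vec[0]
    return vec - np.max(vec)


# -- the two update rules -------------------------------------------------


def variable_to_factor(
    store: MessageStore, graph: FactorGraph, vid: str, fid: str
) -> np.ndarray:
    """Outgoing message of a variable: sum of its other incoming messages.

    Clamped variables emit their clamp vector and ignore all incoming
    messages.  Missing messages default to zero (uniform), so with a single
    incident factor the outgoing message is identically 0.
    """
    if vid in graph.clamps:
        return clamp_message(graph.cardinality(vid), graph.clamps[vid])
    return normalize_message(store.belief_acc[vid] - store.msg[(fid, vid)])


def factor_to_variable_generic(
    factor: FactorSpec,
    cards: Sequence[int],
    incoming: Sequence[np.ndarray],
    target: int,
    T=1.0,
) -> np.ndarray:
    """Generic tempered update for TABLE/CHANNEL (or any dense) factors."""
    cards = tuple(int(c) for c in cards)
    table = dense_log_potential(factor, cards)
    total = table
    for j, card in enumerate(cards):
        if j == target:
            continue
        shape = [1] * len(cards)
        shape[j] = card
        total = total + np.asarray(incoming[j], dtype=float).reshape(shape)
    axes = tuple(j for j in range(len(cards)) if j != target)
    if not axes:
        return total.copy()
    if T == MAX_PRODUCT:
        return np.max(total, axis=axes)
    T = float(T)
    return T * logsumexp(total / T, axis=axes)


# -- engine ---------------------------------------------------------------


class BeliefPropagation:
    """Scheduler-driven BP over one graph.

    Evidence should already be attached to the graph (as unary factors);
    clamps are read from ``graph.clamps`` at message time, so clamping and
    unclamping between calls needs no graph surgery.
    """

    def __init__(self, graph: FactorGraph, settings: BPSettings | None = None):
        self.graph = graph
        self.settings = settings or BPSettings()
        self.store = MessageStore(graph)
        self.trace: list[dict] = []
        if self.settings.perturbation > 0:
            self.store.perturb(self.settings.perturbation, self.settings.seed)

    def add_factor(self, factor: FactorSpec) -> None:
        """Attach a factor mid-run (e.g. evidence or a top-down attention
        boost); its messages start at zero (uniform)."""
        self.graph.add_factor(factor)
        for vid in factor.neighbor_ids:
            self.store.msg[(factor.id, vid)] = np.zeros(self.graph.cardinality(vid))

    def remove_factor(self, fid: str) -> None:
        """Detach a factor mid-run, retracting its messages."""
        factor = self.graph.factors[fid]
        for vid in factor.neighbor_ids:
            vec = self.store.msg.pop((factor.id, vid))
            self.store.belief_acc[vid] -= vec
        self.graph.remove_factor(fid)

    # message computation (no side effects)

    def compute_factor_messages(
        self, fid: str, targets: Iterable[str] | None = None
    ) -> list[tuple[str, str, np.ndarray]]:
        graph, store = self.graph, self.store
        factor = graph.factors[fid]
        T = self.settings.temperature
        nbrs = factor.neighbor_ids
        cards = graph.neighbor_cards(factor)
        incoming = [variable_to_factor(store, graph, v, fid) for v in nbrs]
        want = set(nbrs if targets is None else targets)
        kind = factor.factor_kind
        out: list[tuple[str, str, np.ndarray]] = []
        if kind == "OR":
            M = factor.arity - 1
            scalars = [float(m[1] - m[0]) for m in incoming]
            res = or_messages(ORFactorParams(M), scalars, T)
            for vid, s in zip(nbrs, res):
                if vid in want:
                    out.append((fid, vid, np.array([0.0, s])))
        elif kind == "POOL":
            M = factor.arity - 1
            scalars = [float(m[1] - m[0]) for m in incoming]
            res = pool_messages_checked(PoolFactorParams(M), scalars, T)
            for vid, s in zip(nbrs, res):
                if vid in want:
                    out.append((fid, vid, np.array([0.0, s])))
        elif kind == "EDGE_APPEARANCE":
            params = EdgeAppearanceParams(cards[0], factor.params["c_penalty"])
            e_scalar = float(incoming[2][1] - incoming[2][0])
            to_a, to_b, to_e = edge_appearance_messages(
                params, incoming[0], incoming[1], e_scalar, T
            )
            results = [to_a, to_b, np.array([0.0, to_e])]
            for vid, vec in zip(nbrs, results):
                if vid in want:
                    out.append((fid, vid, np.asarray(vec, dtype=float)))
        else:  # TABLE, CHANNEL
            for j, vid in enumerate(nbrs):
                if vid in want:
                    vec = factor_to_variable_generic(factor, cards, incoming, j, T)
                    out.append((fid, vid, vec))
        return out

    # group application

    def step_group(self, group: Sequence[tuple[str, str | None]]) -> float:
        """Compute all messages in a group from the current store, then
        apply them with damping.  Returns the max message change."""
        computed: list[tuple[str, str, np.ndarray]] = []
        for fid, target in group:
            targets = None if target is None else [target]
            computed.extend(self.compute_factor_messages(fid, targets))
        damping = self.settings.damping
        max_delta = 0.0
        for fid, vid, vec in computed:
            vec = normalize_message(vec)
            if not np.all(np.isfinite(vec)):
                raise DivergenceError(fid, vid)
            old = self.store.msg[(fid, vid)]
            mixed = damping * old + (1 - damping) * vec
            max_delta = max(max_delta, self.store.set_message(fid, vid, mixed))
        return max_delta

    def run_schedule(
        self,
        schedule: Schedule,
        max_iterations: int | None = None,
        tolerance: float | None = None,
        record: bool = False,
        snapshot_vars: Sequence[str] | None = None,
        stage_label: str = "",
    ) -> bool:
        """Iterate the schedule until convergence or the iteration cap.

        Returns the converged flag.  With ``record`` the trace gets one
        JSON-serializable entry per group per iteration.
        """
        max_iterations = max_iterations or self.settings.max_iterations
        tolerance = self.settings.tolerance if tolerance is None else tolerance
        converged = False
        for it in range(max_iterations):
            sweep_delta = 0.0
            for gi, group in enumerate(schedule):
                delta = self.step_group(group)
                sweep_delta = max(sweep_delta, delta)
                if record:
                    entry = {
                        "iteration": self.store.iteration,
                        "group": f"{stage_label}[{gi}]" if stage_label else str(gi),
                        "max_delta": delta,
                    }
                    if snapshot_vars is not None:
                        entry["beliefs"] = {
                            v: float(
                                self.store.belief_acc[v][1]
                                - self.store.belief_acc[v][0]
                            )
                            for v in snapshot_vars
                        }
                    self.trace.append(entry)
            self.store.iteration += 1
            if sweep_delta < tolerance:
                converged = True
                break
        return converged

    # results

    def beliefs(self) -> Beliefs:
        logs = {}
        for vid in self.graph.variables:
            if vid in self.graph.clamps:
                vec = clamp_message(
                    self.graph.cardinality(vid), self.graph.clamps[vid]
                )
            else:
                vec = self.store.belief_acc[vid].copy()
            logs[vid] = np.clip(vec - np.max(vec), -SENTINEL, 0.0)
        return Beliefs(logs, self.settings.temperature)

    def decode_map(self, beliefs: Beliefs | None = None) -> Assignment:
        """Per-variable argmax with lowest-index tie-break; clamps copied
        through.  With perturbation enabled an infinitesimal seeded jitter
        breaks exact ties randomly (to explore bistable solutions)."""
        beliefs = beliefs or self.beliefs()
        jitter = None
        if self.settings.perturbation > 0:
            jitter = np.random.default_rng(self.settings.seed + 1)
        out: Assignment = {}
        for vid in self.graph.variables:
            if vid in self.graph.clamps:
                out[vid] = self.graph.clamps[vid]
                continue
            b = beliefs.log_beliefs[vid].copy()
            if jitter is not None:
                b = b + jitter.normal(0.0, 1e-9, b.shape)
            out[vid] = int(np.argmax(b))
        return out

    def factor_pseudomarginal(self, fid: str) -> np.ndarray:
        """q(x_a) propto exp[(f_a(x_a) + sum_j m_{j->a}(x_j)) / T]."""
        graph, store = self.graph, self.store
        factor = graph.factors[fid]
        cards = graph.neighbor_cards(factor)
        total = dense_log_potential(factor, cards)
        for j, vid in enumerate(factor.neighbor_ids):
            shape = [1] * len(cards)
            shape[j] = cards[j]
            total = total + variable_to_factor(store, graph, vid, fid).reshape(shape)
        T = self.settings.temperature
        T = 1.0 if T == MAX_PRODUCT else float(T)
        q = np.exp(total / T - np.max(total) / T)
        return q / q.sum()

    def bethe_free_energy(self, consistency_tol: float = 1e-4) -> float:
        return bethe_free_energy(self, consistency_tol)


def bethe_free_energy(engine: BeliefPropagation, consistency_tol: float = 1e-4) -> float:
    """Bethe free energy at the current messages:

    F = -sum_a E_q[f_a] - T [ sum_a H(q_a) + sum_i (1 - n_i) H(q_i) ]

    with factor pseudomarginals q_a and variable beliefs q_i.  Exact -log Z
    at a sum-product fixed point on a tree.  Inconsistent pseudomarginals
    (beyond ``consistency_tol``) trigger a warning; F is still computed.
    """
    graph = engine.graph
    T = engine.settings.temperature
    T = 1.0 if T == MAX_PRODUCT else float(T)
    beliefs = engine.beliefs()
    q_i = {v: beliefs.marginal(v) for v in graph.variables}

    def entropy(q: np.ndarray) -> float:
        nz = q > 0
        return float(-np.sum(q[nz] * np.log(q[nz])))

    energy = 0.0
    factor_entropy = 0.0
    worst = 0.0
    for fid, factor in graph.factors.items():
        cards = graph.neighbor_cards(factor)
        table = dense_log_potential(factor, cards)
        q_a = engine.factor_pseudomarginal(fid)
        nz = q_a > 1e-300
        energy += float(np.sum(q_a[nz] * table[nz]))
        factor_entropy += entropy(q_a.ravel())
        for j, vid in enumerate(factor.neighbor_ids):
            axes = tuple(k for k in range(len(cards)) if k != j)
            marg = q_a.sum(axis=axes) if axes else q_a
            worst = max(worst, float(np.max(np.abs(marg - q_i[vid]))))
    if worst > consistency_tol:
        warnings.warn(
            f"pseudomarginals locally inconsistent (max dev {worst:.2e}); "
            "Bethe free energy computed anyway",
            stacklevel=2,
        )
    var_entropy = sum(
        (1 - graph.n_factors(v)) * entropy(q_i[v]) for v in graph.variables
    )
    return -energy - T * (factor_entropy + var_entropy)


# -- schedules ------------------------------------------------------------


def parallel_schedule(graph: FactorGraph) -> Schedule:
    """One group updating every factor jointly (Jacobi; use damping)."""
    return [[(fid, None) for fid in graph.factors]]


def sequential_schedule(graph: FactorGraph) -> Schedule:
    """One factor per group, in insertion order (Gauss-Seidel)."""
    return [[(fid, None)] for fid in graph.factors]


def tree_schedule(graph: FactorGraph) -> Schedule:
    """Leaves-in then root-out ordering of all directed factor->variable
    edges; exact in a single pass on trees/forests."""
    if not graph.is_tree():
        raise ValueError("tree_schedule requires an acyclic factor graph")
    depth: dict[str, int] = {}
    parent_var: dict[str, str | None] = {}
    seen_vars: set[str] = set()
    order_up: list[tuple[str, str]] = []
    for root in graph.variables:
        if root in seen_vars:
            continue
        seen_vars.add(root)
        queue: list[tuple[str, int, str | None]] = [(root, 0, None)]
        comp_factors: list[tuple[str, int, str]] = []
        qi = 0
        while qi < len(queue):
            vid, d, via = queue[qi]
            qi += 1
            for fid in graph.adjacency[vid]:
                if fid == via:
                    continue
                comp_factors.append((fid, d, vid))
                for nb in graph.factors[fid].neighbor_ids:
                    if nb != vid and nb not in seen_vars:
                        seen_vars.add(nb)
                        queue.append((nb, d + 1, fid))
        comp_factors.sort(key=lambda t: -t[1])
        order_up.extend((fid, pvar) for fid, _, pvar in comp_factors)
    schedule: Schedule = [[edge] for edge in order_up]
    for fid, pvar in reversed(order_up):
        for nb in graph.factors[fid].neighbor_ids:
            if nb != pvar:
                schedule.append([(fid, nb)])
    return schedule


# -- one-call driver ------------------------------------------------------


@dataclass
class RunResult:
    engine: BeliefPropagation
    beliefs: Beliefs
    converged: bool
    trace: list[dict] = field(default_factory=list)

    @property
    def store(self) -> MessageStore:
        return self.engine.store


def run(
    graph: FactorGraph,
    evidence: Mapping | None = None,
    clamps: Mapping[str, int] | None = None,
    settings: BPSettings | None = None,
    schedule: Schedule | None = None,
    record: bool = False,
    snapshot_vars: Sequence[str] | None = None,
) -> RunResult:
    """Attach evidence and clamps to a copy of the graph, run BP to
    convergence under the given schedule, and return messages + beliefs."""
    g = graph.copy()
    if evidence:
        apply_evidence(g, evidence)
    if clamps:
        _clamp(g, clamps)
    settings = settings or BPSettings()
    if schedule is None:
        if g.is_tree():
            schedule = tree_schedule(g)
        else:
            schedule = parallel_schedule(g)
            if settings.damping == 0:
                settings = BPSettings(**{**settings.__dict__, "damping": 0.5})
    engine = BeliefPropagation(g, settings)
    converged = engine.run_schedule(
        schedule, record=record, snapshot_vars=snapshot_vars
    )
    return RunResult(engine, engine.beliefs(), converged, engine.trace)


def trace_to_jsonl(trace: Sequence[Mapping]) -> str:
    """Serialize a trace as JSON-lines (one record per update group)."""
    return "\n".join(json.dumps(entry) for entry in trace)
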