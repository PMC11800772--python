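"""Discrete factor-graph data model.

Variables are discrete (binary or categorical); factors carry a typed kind
(TABLE, OR, POOL, EDGE_APPEARANCE, CHANNEL) and kind-specific parameters.
All potentials and messages live in the log domain.  Hard-zero probabilities
(log-potential -inf) are represented by a large negative sentinel inside
arithmetic so that normalization never produces NaN; the default sentinel
magnitude is 1e9.

Binary messages and evidence follow the single-scalar convention
``m = m(x=1) - m(x=0)`` at module boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Magnitude of the large-negative stand-in for log(0).
SENTINEL = 1e9

FACTOR_KINDS = ("TABLE", "OR", "POOL", "EDGE_APPEARANCE", "CHANNEL")

SCHEMA_NAME = "rcnbp-factor-graph"
SCHEMA_VERSION = 1


class GraphError(ValueError):
    """Raised for structural problems in a factor graph."""


@dataclass(frozen=True)
class VariableSpec:
    """A discrete random variable.

    ``kind_label`` is a free-form annotation ("feature", "pool", "pixel",
    "surface-patch", "edge", ...) used only for traces and reporting.
    """

    id: str
    cardinality: int = 2
    kind_label: str = "variable"

    def __post_init__(self) -> None:
        if self.cardinality < 2:
            raise GraphError(f"variable {self.id!r}: cardinality must be >= 2")


@dataclass
class FactorSpec:
    """A factor over an ordered list of neighboring variables.

    The neighbor role order is fixed per kind:

    - ``TABLE``/``CHANNEL``: free order; ``params['log_potential']`` is an
      array whose axes follow ``neighbor_ids``.  CHANNEL order is
      ``(source, pixel)``.
    - ``OR``: ``(c1, ..., cM, e)`` -- M binary children then the output.
    - ``POOL``: ``(a, b1, ..., bM)`` -- pooling variable then M members.
    - ``EDGE_APPEARANCE``: ``(a, b, e)`` -- two appearance patches and the
      binary contour/edge variable.
    """

    id: str
    factor_kind: str
    neighbor_ids: tuple[str, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.factor_kind not in FACTOR_KINDS:
            raise GraphError(
                f"factor {self.id!r}: unknown kind {self.factor_kind!r}"
            )
        self.neighbor_ids = tuple(self.neighbor_ids)

    @property
    def arity(self) -> int:
        return len(self.neighbor_ids)


class FactorGraph:
    """Validated factor graph with adjacency bookkeeping.

    ``adjacency[v]`` lists the ids of factors incident to variable ``v``;
    its length is the per-variable factor count used by the Bethe entropy.
    """

    def __init__(self) -> None:
        self.variables: dict[str, VariableSpec] = {}
        self.factors: dict[str, FactorSpec] = {}
        self.adjacency: dict[str, list[str]] = {}
        self.clamps: dict[str, int] = {}

    # -- construction -----------------------------------------------------

    def add_variable(self, var: VariableSpec) -> None:
        if var.id in self.variables:
            raise GraphError(f"duplicate variable id {var.id!r}")
        self.variables[var.id] = var
        self.adjacency[var.id] = []

    def add_factor(self, factor: FactorSpec) -> None:
        if factor.id in self.factors:
            raise GraphError(f"duplicate factor id {factor.id!r}")
        _validate_factor(self, factor)
        self.factors[factor.id] = factor
        for vid in factor.neighbor_ids:
            self.adjacency[vid].append(factor.id)

    def remove_factor(self, fid: str) -> None:
        factor = self.factors.pop(fid)
        for vid in factor.neighbor_ids:
            self.adjacency[vid].remove(fid)

    # -- queries ----------------------------------------------------------

    def cardinality(self, vid: str) -> int:
        return self.variables[vid].cardinality

    def n_factors(self, vid: str) -> int:
        """n_i: number of factors variable ``vid`` is connected to."""
        return len(self.adjacency[vid])

    def neighbor_cards(self, factor: FactorSpec) -> tuple[int, ...]:
        return tuple(self.cardinality(v) for v in factor.neighbor_ids)

    def copy(self) -> "FactorGraph":
        g = FactorGraph()
        g.variables = dict(self.variables)
        g.factors = dict(self.factors)
        g.adjacency = {v: list(fs) for v, fs in self.adjacency.items()}
        g.clamps = dict(self.clamps)
        return g

    def is_tree(self) -> bool:
        """True if the bipartite variable/factor graph is acyclic and edges
        = nodes - components (i.e. a forest)."""
        n_nodes = len(self.variables) + len(self.factors)
        n_edges = sum(f.arity for f in self.factors.values())
        # count connected components by union-find over edges
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent.setdefault(x, x) != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for f in self.factors.values():
            fx = find("f#" + f.id)
            for v in f.neighbor_ids:
                vx = find("v#" + v)
                if fx == vx:
                    return False  # cycle
                parent[vx] = fx
                fx = find(fx)
        return n_edges <= n_nodes

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "format": SCHEMA_NAME,
            "version": SCHEMA_VERSION,
            "variables": [
                {"id": v.id, "cardinality": v.cardinality, "kind_label": v.kind_label}
                for v in self.variables.values()
            ],
            "factors": [
                {
                    "id": f.id,
                    "factor_kind": f.factor_kind,
                    "neighbor_ids": list(f.neighbor_ids),
                    "params": _params_to_json(f.params),
                }
                for f in self.factors.values()
            ],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "FactorGraph":
        doc = json.loads(text)
        if doc.get("format") != SCHEMA_NAME:
            raise GraphError(f"not a {SCHEMA_NAME} document")
        if doc.get("version") != SCHEMA_VERSION:
            raise GraphError(
                f"unsupported {SCHEMA_NAME} version {doc.get('version')!r}"
            )
        variables = [
            VariableSpec(d["id"], d["cardinality"], d.get("kind_label", "variable"))
            for d in doc["variables"]
        ]
        factors = [
            FactorSpec(
                d["id"],
                d["factor_kind"],
                tuple(d["neighbor_ids"]),
                _params_from_json(d.get("params", {})),
            )
            for d in doc["factors"]
        ]
        return build_graph(variables, factors)


def _params_to_json(params: Mapping) -> dict:
    out = {}
    for k, v in params.items():
        if isinstance(v, np.ndarray):
            out[k] = {"__array__": v.tolist()}
        else:
            out[k] = v
    return out


def _params_from_json(params: Mapping) -> dict:
    out = {}
    for k, v in params.items():
        if isinstance(v, dict) and "__array__" in v:
            out[k] = np.asarray(v["__array__"], dtype=float)
        else:
            out[k] = v
    return out


# -- validation -----------------------------------------------------------


def _validate_factor(graph: FactorGraph, factor: FactorSpec) -> None:
    for vid in factor.neighbor_ids:
        if vid not in graph.variables:
            raise GraphError(
                f"factor {factor.id!r} references unknown variable {vid!r}"
            )
    if len(set(factor.neighbor_ids)) != len(factor.neighbor_ids):
        raise GraphError(f"factor {factor.id!r} lists a variable twice")
    cards = graph.neighbor_cards(factor)
    kind = factor.factor_kind
    if kind == "OR":
        if factor.arity < 2:
            raise GraphError(f"OR factor {factor.id!r} needs >= 1 child + output")
        if any(c != 2 for c in cards):
            raise GraphError(f"OR factor {factor.id!r}: all neighbors must be binary")
    elif kind == "POOL":
        if factor.arity < 2:
            raise GraphError(f"POOL factor {factor.id!r} needs pool var + >= 1 member")
        if any(c != 2 for c in cards):
            raise GraphError(f"POOL factor {factor.id!r}: all neighbors must be binary")
    elif kind == "EDGE_APPEARANCE":
        if factor.arity != 3:
            raise GraphError(f"EDGE_APPEARANCE factor {factor.id!r} needs (a, b, e)")
        if cards[0] != cards[1]:
            raise GraphError(
                f"EDGE_APPEARANCE factor {factor.id!r}: a and b cardinalities differ"
            )
        if cards[2] != 2:
            raise GraphError(f"EDGE_APPEARANCE factor {factor.id!r}: e must be binary")
        c_penalty = factor.params.get("c_penalty")
        if c_penalty is None or not c_penalty > 0:
            raise GraphError(
                f"EDGE_APPEARANCE factor {factor.id!r}: c_penalty must be > 0"
            )
    elif kind == "CHANNEL":
        if factor.arity != 2 or cards != (2, 2):
            raise GraphError(f"CHANNEL factor {factor.id!r} needs two binary neighbors")
        p = factor.params.get("precision")
        s = factor.params.get("sensitivity")
        if p is None or s is None or not (0 < p <= 1 and 0 <= s < 1 and p > s):
            raise GraphError(
                f"CHANNEL factor {factor.id!r}: need precision > sensitivity"
            )
    elif kind == "TABLE":
        table = np.asarray(factor.params.get("log_potential"), dtype=float)
        if table.shape != cards:
            raise GraphError(
                f"TABLE factor {factor.id!r}: table shape {table.shape} does not "
                f"match neighbor cardinalities {cards}"
            )
        if np.any(np.isposinf(table)) or np.any(np.isnan(table)):
            raise GraphError(f"TABLE factor {factor.id!r}: entries must be < +inf")
        factor.params["log_potential"] = table


def build_graph(
    variables: Iterable[VariableSpec], factors: Iterable[FactorSpec]
) -> FactorGraph:
    """Build and validate a factor graph.

    Raises :class:`GraphError` on duplicate ids, dangling neighbor
    references, arity mismatches, or TABLE shape mismatches.
    """
    graph = FactorGraph()
    for var in variables:
        graph.add_variable(var)
    for factor in factors:
        graph.add_factor(factor)
    return graph


# -- evidence -------------------------------------------------------------


def evidence_vector(graph: FactorGraph, vid: str, value) -> np.ndarray:
    """Expand an evidence entry to a full log-likelihood vector.

    A scalar on a binary variable is the log-likelihood ratio
    ``log L(x=1) - log L(x=0)`` and expands to ``(0, value)``.
    """
    card = graph.cardinality(vid)
    if np.isscalar(value):
        if card != 2:
            raise GraphError(
                f"scalar evidence on non-binary variable {vid!r} (cardinality {card})"
            )
        return np.array([0.0, float(value)])
    vec = np.asarray(value, dtype=float)
    if vec.shape != (card,):
        raise GraphError(
            f"evidence vector for {vid!r} has length {vec.shape}, "
            f"expected ({card},)"
        )
    return vec.copy()


def apply_evidence(
    graph: FactorGraph, evidence: Mapping[str, object], sentinel: float = SENTINEL
) -> list[FactorSpec]:
    """Attach each evidence entry as a unary TABLE factor on its variable.

    Evidence values: scalar log-likelihood ratio for binary variables or a
    full log-likelihood vector.  A value of 0 (or an all-zero vector) is
    uninformative; it is still attached, and is a no-op on all beliefs.
    Entries of -inf are replaced by the negative sentinel.  Returns the
    list of factors added (replacing any previous evidence on the same
    variable).
    """
    added = []
    for vid, value in evidence.items():
        if vid not in graph.variables:
            raise GraphError(f"evidence on unknown variable {vid!r}")
        vec = evidence_vector(graph, vid, value)
        vec = np.where(np.isneginf(vec), -sentinel, vec)
        fid = f"evidence:{vid}"
        if fid in graph.factors:
            graph.remove_factor(fid)
        factor = FactorSpec(fid, "TABLE", (vid,), {"log_potential": vec})
        graph.add_factor(factor)
        added.append(factor)
    return added


def clamp(
    graph: FactorGraph, clamps: Mapping[str, int], sentinel: float = SENTINEL
) -> FactorGraph:
    """Record clamped states on the graph (message overriding, not surgery).

    A clamped variable emits, on every outgoing edge, the message that is 0
    at the clamped state and -sentinel elsewhere; its incoming messages are
    ignored by the engine.  Clamping a state that the variable's own hard
    evidence already excludes is rejected.
    """
    for vid, state in clamps.items():
        if vid not in graph.variables:
            raise GraphError(f"clamp on unknown variable {vid!r}")
        card = graph.cardinality(vid)
        if not (0 <= int(state) < card):
            raise GraphError(
                f"clamp state {state} out of range for {vid!r} (cardinality {card})"
            )
        ev = graph.factors.get(f"evidence:{vid}")
        if ev is not None:
            vec = ev.params["log_potential"]
            if vec[int(state)] <= -sentinel:
                raise GraphError(
                    f"clamp of {vid!r} to state {state} contradicts hard evidence"
                )
        graph.clamps[vid] = int(state)
    return graph


def unclamp(graph: FactorGraph, vids: Iterable[str] | None = None) -> FactorGraph:
    """Remove clamps (all of them if ``vids`` is None)."""
    if vids is None:
        graph.clamps.clear()
    else:
        for vid in vids:
            graph.clamps.pop(vid, None)
    return graph


def clamp_message(card: int, state: int, sentinel: float = SENTINEL) -> np.ndarray:
    vec = np.full(card, -sentinel)
    vec[state] = 0.0
    return vec
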