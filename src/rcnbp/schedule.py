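"""The biologically scheduled parsing protocol.

Scene parsing runs max-product BP under a fixed stage schedule instead of
free-running updates:

1. evidence injection (pixel channels, priors) and one top-down sweep so
   that all parent-side messages start at their prior-OFF values;
2. a fast forward pass -- leaf OR interfaces, short-range lateral
   iterations, pools -- level by level up to the object features
   (``FWD_FEAT`` / ``FWD_LAT`` / ``FWD_POOL`` stages); because parents
   start OFF, the first sweep copies bottom-up evidence to all parents
   without feed-forward competition;
3. hypothesis selection (``SELECT``): the top-K object features by belief;
   positively supported ones receive a strong (not hard) top-down
   attention boost, or a hard clamp if configured;
4. backward passes: unpooling, longer-range lateral iterations, and OR
   interface updates where top-down context now gates the bottom-up flow
   (``BWD_UNPOOL`` / ``BWD_LAT`` / ``EXPLAIN_AWAY``), interleaved with
   fresh forward sweeps;
5. surface filling (``SURFACE_FILL``): lattice-edge contour variables and
   edge-appearance factors propagate appearance under the contour
   discontinuities the hierarchy settled on.

Each stage snapshot is recorded with an anatomical annotation (string
labels only).  The result is a MAP assignment, per-object segmentation
masks, and SUPPORTED/HALLUCINATED labels per ON contour unit: a unit is
HALLUCINATED when it is ON in the MAP while its bottom-up evidence
log-likelihood ratio is <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bp_engine import BeliefPropagation, BPSettings, Beliefs
from .factor_graph import FactorGraph, FactorSpec, apply_evidence
from .factors import MAX_PRODUCT
from .rcn_model import (
    ORIENTATIONS,
    RCNModel,
    clone_id,
    compile_model,
    leaf_id,
    pixel_id,
    patch_id,
)
from .stimuli import OIDX, UNOBSERVED, Stimulus

SUPPORTED = "SUPPORTED"
HALLUCINATED = "HALLUCINATED"

#: anatomical annotations for trace stages (labels only, no semantics)
ANATOMY = {
    "FWD_FEAT": "L4",
    "FWD_LAT": "L2/3",
    "FWD_POOL": "L2/3",
    "SELECT": "top-level",
    "BWD_UNPOOL": "L5",
    "BWD_LAT": "L5",
    "EXPLAIN_AWAY": "thalamus/TRN",
    "SURFACE_FILL": "blob (V1)",
}


@dataclass
class ProtocolSettings:
    """Pass-count configuration of the parsing schedule."""

    K: int = 3
    forward_lat_iters: int = 2
    backward_lat_iters: int = 8
    explain_away_sweeps: int = 3
    surface_iters: int = 12
    boost: float = 2.0
    hard_focus: bool = False  # clamp selected hypotheses instead of boosting
    appearance_llr: float = 4.0
    surface_interleaved: bool = False
    # staged directed sweeps are sequential; damping is for free-running
    # parallel schedules and would only attenuate one-shot stage messages
    bp: BPSettings = field(
        default_factory=lambda: BPSettings(temperature=MAX_PRODUCT, damping=0.0)
    )

    def __post_init__(self):
        if self.K < 1 or self.backward_lat_iters < 1 or self.explain_away_sweeps < 1:
            raise ValueError("counts must be >= 1 (forward laterals may be 0)")
        if self.forward_lat_iters < 0:
            raise ValueError("forward_lat_iters must be >= 0")


@dataclass
class StageRecord:
    name: str
    pass_index: int
    beliefs: dict[str, float]
    anatomy: str


@dataclass
class StageTrace:
    stages: list[StageRecord] = field(default_factory=list)

    def first_positive_stage(self, vid: str) -> int | None:
        """Index of the first recorded stage at which the unit's belief
        LLR is strictly positive."""
        for i, st in enumerate(self.stages):
            if st.beliefs.get(vid, 0.0) > 0:
                return i
        return None

    def to_jsonl(self) -> str:
        import json

        return "\n".join(
            json.dumps(
                {
                    "stage": s.name,
                    "pass": s.pass_index,
                    "anatomy": s.anatomy,
                    "beliefs": s.beliefs,
                }
            )
            for s in self.stages
        )


@dataclass
class ParseResult:
    assignment: dict[str, int]
    masks: dict[str, np.ndarray]           # object feature id -> bool (R, C)
    support: dict[str, str]                # ON leaf id -> SUPPORTED/HALLUCINATED
    hypotheses: list[tuple[str, float]]    # ranked (object id, belief LLR)
    trace: StageTrace
    converged: bool
    beliefs: Beliefs

    def on_leaves(self) -> list[str]:
        return sorted(self.support)

    def hallucinated(self) -> list[str]:
        return [v for v, s in self.support.items() if s == HALLUCINATED]


# -- the scene parser -----------------------------------------------------


class SceneParser:
    """Holds the compiled graph plus factor groupings for staged updates.

    Compile once, parse many stimuli: :meth:`parse` resets messages.
    """

    def __init__(
        self,
        model: RCNModel,
        settings: ProtocolSettings | None = None,
        graph: FactorGraph | None = None,
    ):
        self.model = model
        self.settings = settings or ProtocolSettings()
        self.base_graph = graph if graph is not None else compile_model(model)
        self._classify(self.base_graph)

    def _classify(self, g: FactorGraph) -> None:
        by = {
            "channel": [],
            "prior": [],
            "or_leaf": [],
            "or_f1": [],
            "or_f2": [],
            "pool1": [],
            "pool2": [],
            "pool3": [],
            "lateral": [],
            "surf_edge": [],
            "surf_or": [],
            "surf_pin": [],
        }
        for fid in g.factors:
            if fid.startswith("ch:"):
                by["channel"].append(fid)
            elif fid.startswith("prior:") or fid.startswith("shiftprior:"):
                by["prior"].append(fid)
            elif fid.startswith("for:lf:"):
                by["or_leaf"].append(fid)
            elif fid.startswith("for:f1:"):
                by["or_f1"].append(fid)
            elif fid.startswith("for:f2:"):
                by["or_f2"].append(fid)
            elif fid.startswith("fpool:p1:"):
                by["pool1"].append(fid)
            elif fid.startswith("fpool:p2:"):
                by["pool2"].append(fid)
            elif fid.startswith("fpool:p3:"):
                by["pool3"].append(fid)
            elif fid.startswith("lat:"):
                by["lateral"].append(fid)
            elif fid.startswith("fedge:"):
                by["surf_edge"].append(fid)
            elif fid.startswith("oredge:"):
                by["surf_or"].append(fid)
            elif fid.startswith("noedge:"):
                by["surf_pin"].append(fid)
        self.groups = by
        self.leaf_vars = [v for v, s in g.variables.items() if s.kind_label == "leaf"]
        self.object_vars = [
            f for f in self.model.features if self.model.features[f].level == 3
        ]

    # evidence

    def evidence_map(self, stimulus: Stimulus) -> dict:
        if tuple(stimulus.shape) != tuple(self.model.grid_shape):
            raise ValueError("stimulus grid does not match model grid")
        ev: dict[str, object] = {}
        for r, c, o in sorted(self.model.leaf_positions()):
            ev[pixel_id(r, c, o)] = stimulus.contour_at(r, c, o)
        if self.model.surface is not None:
            N = self.model.surface.appearance_n
            rows, cols = self.model.grid_shape
            for r in range(rows):
                for c in range(cols):
                    bin_ = int(stimulus.appearance[r, c])
                    if bin_ == UNOBSERVED:
                        continue
                    vec = np.zeros(N)
                    vec[bin_] = self.settings.appearance_llr
                    ev[patch_id(r, c)] = vec
        return ev

    # staged runs

    def _stage(
        self,
        engine: BeliefPropagation,
        name: str,
        pass_index: int,
        groups: Sequence[tuple[str, str | None]],
        iters: int,
        trace: StageTrace,
    ) -> None:
        for _ in range(max(iters, 0)):
            engine.step_group(list(groups))
        if iters > 0:
            trace.stages.append(
                StageRecord(
                    name,
                    pass_index,
                    {
                        v: float(
                            engine.store.belief_acc[v][1]
                            - engine.store.belief_acc[v][0]
                        )
                        for v in self.leaf_vars + self.object_vars
                    },
                    ANATOMY[name],
                )
            )

    @staticmethod
    def _all(fids: Sequence[str]) -> list[tuple[str, str | None]]:
        return [(f, None) for f in fids]

    def _targets(self, g, fids, pick) -> list[tuple[str, str | None]]:
        out = []
        for fid in fids:
            for vid in pick(g.factors[fid]):
                out.append((fid, vid))
        return out

    def forward_pass(
        self, engine: BeliefPropagation, trace: StageTrace, pass_index: int
    ) -> dict[str, float]:
        """One bottom-up sweep; returns top-level belief LLRs."""
        g = engine.graph
        by = self.groups
        st = self.settings
        # level 1: leaf interfaces -> clones, laterals, pools -> features
        self._stage(
            engine, "FWD_FEAT", pass_index,
            self._targets(g, by["or_leaf"], lambda f: f.neighbor_ids[:-1]),
            1, trace,
        )
        self._stage(
            engine, "FWD_LAT", pass_index, self._all(by["lateral"]),
            st.forward_lat_iters, trace,
        )
        self._stage(
            engine, "FWD_POOL", pass_index,
            self._targets(g, by["pool1"], lambda f: f.neighbor_ids[:1]),
            1, trace,
        )
        # level 2
        self._stage(
            engine, "FWD_FEAT", pass_index,
            self._targets(g, by["or_f1"], lambda f: f.neighbor_ids[:-1]),
            1, trace,
        )
        self._stage(
            engine, "FWD_POOL", pass_index,
            self._targets(g, by["pool2"], lambda f: f.neighbor_ids[:1]),
            1, trace,
        )
        # level 3
        self._stage(
            engine, "FWD_FEAT", pass_index,
            self._targets(g, by["or_f2"], lambda f: f.neighbor_ids[:-1]),
            1, trace,
        )
        self._stage(
            engine, "FWD_POOL", pass_index,
            self._targets(g, by["pool3"], lambda f: f.neighbor_ids[:1]),
            1, trace,
        )
        beliefs = engine.beliefs()
        return {v: beliefs.llr(v) for v in self.object_vars}

    def select_hypotheses(
        self, top_beliefs: dict[str, float], K: int | None = None
    ) -> list[tuple[str, float]]:
        """Top-K hypotheses by belief LLR; deterministic tie-break by id."""
        K = self.settings.K if K is None else K
        if K > len(top_beliefs):
            import warnings

            warnings.warn("K exceeds the number of top-level features; truncated")
            K = len(top_beliefs)
        ranked = sorted(top_beliefs.items(), key=lambda kv: (-kv[1], kv[0]))
        return ranked[:K]

    def backward_pass(
        self,
        engine: BeliefPropagation,
        trace: StageTrace,
        pass_index: int,
        leaf_output: bool = True,
    ) -> None:
        """Top-down sweep: unpool level by level, long-range laterals,
        and OR-interface updates implementing explaining away.

        With ``leaf_output=False`` the leaf OR interfaces update only
        their clone-side messages (used for the initial prior-OFF
        propagation, which must bias the interfaces without writing
        top-down beliefs onto the leaves before any evidence sweep).
        """
        g = engine.graph
        by = self.groups
        st = self.settings
        self._stage(
            engine, "BWD_UNPOOL", pass_index,
            self._targets(g, by["pool3"], lambda f: f.neighbor_ids[1:]),
            1, trace,
        )
        self._stage(
            engine, "EXPLAIN_AWAY", pass_index, self._all(by["or_f2"]), 1, trace
        )
        self._stage(
            engine, "BWD_UNPOOL", pass_index,
            self._targets(g, by["pool2"], lambda f: f.neighbor_ids[1:]),
            1, trace,
        )
        self._stage(
            engine, "EXPLAIN_AWAY", pass_index, self._all(by["or_f1"]), 1, trace
        )
        self._stage(
            engine, "BWD_UNPOOL", pass_index,
            self._targets(g, by["pool1"], lambda f: f.neighbor_ids[1:]),
            1, trace,
        )
        self._stage(
            engine, "BWD_LAT", pass_index, self._all(by["lateral"]),
            st.backward_lat_iters, trace,
        )
        leaf_or = (
            self._all(by["or_leaf"])
            if leaf_output
            else self._targets(g, by["or_leaf"], lambda f: f.neighbor_ids[:-1])
        )
        self._stage(engine, "EXPLAIN_AWAY", pass_index, leaf_or, 1, trace)

    def surface_fill(
        self,
        engine: BeliefPropagation,
        trace: StageTrace,
        pass_index: int,
        fill_hook=None,
    ) -> None:
        by = self.groups
        # contour support for the lattice edges first (parallel), then the
        # edge-appearance factors sequentially in raster order: propagation
        # is Gauss-Seidel, which fills smoothly instead of oscillating
        head = self._all(by["surf_or"]) + self._all(by["surf_pin"])
        edge_seq = [(f, None) for f in sorted(by["surf_edge"])]
        for it in range(self.settings.surface_iters):
            engine.step_group(head)
            for step in edge_seq:
                engine.step_group([step])
            trace.stages.append(
                StageRecord(
                    "SURFACE_FILL", pass_index, {}, ANATOMY["SURFACE_FILL"]
                )
            )
            if fill_hook is not None:
                fill_hook(it, engine)

    # orchestration

    def parse(self, stimulus: Stimulus, fill_hook=None) -> ParseResult:
        st = self.settings
        g = self.base_graph.copy()
        apply_evidence(g, self.evidence_map(stimulus))
        engine = BeliefPropagation(g, st.bp)
        trace = StageTrace()
        by = self.groups

        # inject evidence and priors, then one top-down sweep so parent->OR
        # messages start at their prior-OFF values
        engine.step_group(
            self._all([f for f in g.factors if f.startswith("evidence:")])
        )
        engine.step_group(self._all(by["channel"] + by["prior"]))
        # prior propagation, untraced; leaves see no top-down yet
        self.backward_pass(engine, StageTrace(), 0, leaf_output=False)

        top = self.forward_pass(engine, trace, 1)
        ranked = self.select_hypotheses(top)
        trace.stages.append(
            StageRecord("SELECT", 1, dict(ranked), ANATOMY["SELECT"])
        )
        focus = [fid for fid, llr in ranked if llr > 0]
        if st.hard_focus:
            from .factor_graph import clamp as _clamp

            _clamp(engine.graph, {fid: 1 for fid in focus})
        else:
            for fid in focus:
                engine.add_factor(
                    FactorSpec(
                        f"boost:{fid}",
                        "TABLE",
                        (fid,),
                        {"log_potential": np.array([0.0, st.boost])},
                    )
                )
        for sweep in range(1, st.explain_away_sweeps + 1):
            self.backward_pass(engine, trace, sweep)
            if st.surface_interleaved and self.model.surface is not None:
                self.surface_fill(engine, trace, sweep, fill_hook)
            self.forward_pass(engine, trace, sweep + 1)
        if self.model.surface is not None and not st.surface_interleaved:
            self.surface_fill(engine, trace, st.explain_away_sweeps, fill_hook)

        beliefs = engine.beliefs()
        assignment = engine.decode_map(beliefs)
        support = self._support_labels(stimulus, assignment)
        masks = self._attribute(engine.graph, assignment, ranked)
        converged = True  # fixed-pass protocol; convergence is not required
        return ParseResult(
            assignment, masks, support, ranked, trace, converged, beliefs
        )

    # labeling + attribution

    def _support_labels(self, stimulus, assignment) -> dict[str, str]:
        out = {}
        for r, c, o in sorted(self.model.leaf_positions()):
            lid = leaf_id(r, c, o)
            if assignment.get(lid) == 1:
                ev = stimulus.contour_at(r, c, o)
                out[lid] = SUPPORTED if ev > 0 else HALLUCINATED
        return out

    def _attribute(self, g, assignment, ranked) -> dict[str, np.ndarray]:
        """Assign each ON leaf to the single best-ranked object whose
        active pool chain reaches it; unreached ON leaves are background."""
        rows, cols = self.model.grid_shape
        masks: dict[str, np.ndarray] = {}
        claimed: set[str] = set()
        order = [fid for fid, _ in ranked] + [
            f for f in self.object_vars if f not in dict(ranked)
        ]
        for obj in order:
            if assignment.get(obj) != 1:
                continue
            mask = np.zeros((rows, cols), dtype=bool)
            for lid in self._active_leaves(g, assignment, obj):
                if lid in claimed:
                    continue
                claimed.add(lid)
                _, r, c, o = lid.split(":")
                mask[int(r), int(c)] = True
            masks[obj] = mask
        return masks

    def _active_leaves(self, g, assignment, obj: str) -> list[str]:
        model = self.model
        out = []
        stack = [obj]
        while stack:
            fid = stack.pop()
            if assignment.get(fid) != 1:
                continue
            for pid in model.features[fid].children:
                for unit, tag in model.pools[pid].members:
                    cid = clone_id(pid, tag)
                    if assignment.get(cid) != 1 or assignment.get(unit) != 1:
                        continue
                    if unit.startswith("lf:"):
                        out.append(unit)
                    else:
                        stack.append(unit)
        return out


def parse_scene(
    model: RCNModel,
    stimulus: Stimulus,
    settings: ProtocolSettings | None = None,
    graph: FactorGraph | None = None,
) -> ParseResult:
    """Compile (or reuse) the model graph and parse one stimulus."""
    return SceneParser(model, settings, graph).parse(stimulus)
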