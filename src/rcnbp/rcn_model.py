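"""Declarative recursive-cortical-network (RCN) architecture.

An RCN model is a three-level contour hierarchy over a pixel grid,
optionally coupled to a surface-appearance lattice:

- level 1: oriented-segment features anchored along each shape template's
  outline, each pooling over small perpendicular translations of a leaf
  contour unit (translation invariance);
- level 2: part features (corners / outline arcs), conjunctions of the
  level-1 segments in one contiguous arc of the outline;
- level 3: one object feature per template, a conjunction of its parts.

Adjacent level-1 pools along an outline are tied by lateral compatibility
factors (parent-specific clone variables) that keep the chosen
translations contour-continuous.  Every lower-level unit shared by one or
more parents is driven through a single OR interface block, which is where
explaining away between competing parents happens.  Each leaf contour unit
sees the image through a binary evidence CHANNEL (precision/sensitivity).

The surface lattice has one categorical appearance patch per grid cell and
one binary contour variable per 4-neighbor lattice edge; an
EDGE_APPEARANCE factor per edge enforces appearance continuity unless its
contour variable is ON.  Contour variables are OR-driven by the oriented
leaves that cross the edge; lattice edges no template can reach are pinned
OFF, so surfaces may only break along contours the hierarchy can explain.

Everything compiles to a plain :class:`~rcnbp.factor_graph.FactorGraph`
with a deterministic ``kind:coordinate`` id scheme.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .factor_graph import (
    FactorGraph,
    FactorSpec,
    GraphError,
    VariableSpec,
    build_graph,
)
from .factors import ChannelParams, make_channel_factor

MODEL_SCHEMA = "rcnbp-model"
MODEL_VERSION = 1

#: Contour orientations in degrees; the unit at (r, c, o) marks the
#: lattice discontinuity crossing cell (r, c): o=90 separates (r,c) from
#: (r,c+1) (the "right" edge), o=0 separates (r,c) from (r+1,c) (the
#: "down" edge), diagonals cross both.
ORIENTATIONS = (0, 45, 90, 135)

#: Pooling shift direction (perpendicular-ish) per orientation.
PERP = {0: (1, 0), 90: (0, 1), 45: (1, 1), 135: (1, -1)}


# -- ids ------------------------------------------------------------------


def leaf_id(r: int, c: int, o: int) -> str:
    return f"lf:{r}:{c}:{o}"


def pixel_id(r: int, c: int, o: int) -> str:
    return f"px:{r}:{c}:{o}"


def patch_id(r: int, c: int) -> str:
    return f"sp:{r}:{c}"


def edge_id(r: int, c: int, d: str) -> str:
    return f"ed:{r}:{c}:{d}"


# -- declarative pieces ---------------------------------------------------


@dataclass
class Stroke:
    """One ordered run of outline cells (r, c, orientation)."""

    cells: list[tuple[int, int, int]]
    closed: bool = False


@dataclass
class Template:
    """A named shape: outline strokes plus (optional) interior cells and an
    appearance color bin for the interior surface."""

    name: str
    strokes: list[Stroke]
    interior: list[tuple[int, int]] = field(default_factory=list)
    color_bin: int = 1

    def outline(self) -> list[tuple[int, int, int]]:
        return [cell for s in self.strokes for cell in s.cells]

    def footprint(self) -> set[tuple[int, int]]:
        return {(r, c) for r, c, _ in self.outline()} | set(self.interior)


@dataclass
class FeatureNode:
    id: str
    level: int
    children: list[str]  # pool ids one level down
    prior_llr: float = 0.0


@dataclass
class PoolSpec:
    id: str
    level: int
    center: tuple[int, int]
    # (lower-level unit id, transformation tag); tag is the signed shift
    members: list[tuple[str, int]]


@dataclass
class LateralSpec:
    """Contour-continuity compatibility between two adjacent pools.

    ``allowed`` lists (tag_i, tag_j) member pairs with log-weight 0; pairs
    not listed are forbidden (sentinel).  ``clone_tag`` labels the
    parent-specific copies the factor acts on.
    """

    pools: tuple[str, str]
    allowed: list[tuple[int, int]]
    clone_tag: str = ""


@dataclass
class SurfaceLattice:
    shape: tuple[int, int]
    appearance_n: int = 8
    c_penalty: float = 1.0


@dataclass
class ModelConfig:
    grid_shape: tuple[int, int] = (24, 24)
    pooling_radius: int = 1
    lateral_radius: int = 1
    appearance_n: int = 8
    c_penalty: float = 1.0
    channel: ChannelParams = field(default_factory=lambda: ChannelParams(0.9, 0.1))
    include_surface: bool = True
    n_parts: int = 4
    top_prior_llr: float | None = None  # default -log(n_objects) - 1
    lower_prior_llr: float = 0.0
    # weak canonical-transformation prior: shifted pool members pay
    # tie_epsilon * |shift|, so degenerate unpooling ties resolve to the
    # anchor position instead of leaving all members undecided
    tie_epsilon: float = 1e-3


@dataclass
class RCNModel:
    config: ModelConfig
    templates: dict[str, Template]
    features: dict[str, FeatureNode]
    pools: dict[str, PoolSpec]
    laterals: list[LateralSpec]
    surface: SurfaceLattice | None
    occluders: list[str] = field(default_factory=list)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return tuple(self.config.grid_shape)

    def object_ids(self, include_occluders: bool = True) -> list[str]:
        out = []
        for fid, f in self.features.items():
            if f.level == 3:
                name = fid.split(":", 1)[1]
                if include_occluders or name not in self.occluders:
                    out.append(fid)
        return out

    def leaf_positions(self) -> set[tuple[int, int, int]]:
        """All (r, c, o) leaf units any pool member can reach."""
        out = set()
        for pool in self.pools.values():
            if pool.level == 1:
                for unit, _tag in pool.members:
                    _, r, c, o = unit.split(":")
                    out.add((int(r), int(c), int(o)))
        return out


# -- template library -----------------------------------------------------


def square_template(
    name: str = "square",
    center: tuple[int, int] = (12, 12),
    half: int = 5,
    color_bin: int = 1,
) -> Template:
    """Closed square ring.  The outline cells sit just inside the contour
    they mark: the top side uses orientation 0 on the row above the
    interior, etc."""
    r0, c0 = center[0] - half, center[1] - half
    r1, c1 = center[0] + half, center[1] + half
    cells: list[tuple[int, int, int]] = []
    cells += [(r0 - 1, c, 0) for c in range(c0, c1 + 1)]           # top
    cells += [(r, c1, 90) for r in range(r0, r1 + 1)]              # right
    cells += [(r1, c, 0) for c in range(c1, c0 - 1, -1)]           # bottom
    cells += [(r, c0 - 1, 90) for r in range(r1, r0 - 1, -1)]      # left
    interior = [
        (r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)
    ]
    return Template(name, [Stroke(cells, closed=True)], interior, color_bin)


def diamond_template(
    name: str = "diamond",
    center: tuple[int, int] = (12, 12),
    half: int = 6,
    color_bin: int = 1,
) -> Template:
    """Closed diamond built from 45/135-degree segments."""
    cr, cc = center
    cells: list[tuple[int, int, int]] = []
    for k in range(half):                                  # NE side
        cells.append((cr - half + k, cc + k, 135))
    for k in range(half):                                  # SE side
        cells.append((cr + k, cc + half - k - 1, 45))
    for k in range(half):                                  # SW side
        cells.append((cr + half - k, cc - k - 1, 135))
    for k in range(half):                                  # NW side
        cells.append((cr - k, cc - half + k, 45))
    interior = [
        (r, c)
        for r in range(cr - half, cr + half + 1)
        for c in range(cc - half, cc + half + 1)
        if abs(r - cr) + abs(c - cc) < half
    ]
    return Template(name, [Stroke(cells, closed=True)], interior, color_bin)


def cross_template(
    name: str = "cross",
    center: tuple[int, int] = (12, 12),
    arm: int = 6,
    color_bin: int = 1,
) -> Template:
    """Plus sign: one horizontal and one vertical stroke."""
    cr, cc = center
    horiz = Stroke([(cr, c, 0) for c in range(cc - arm, cc + arm + 1)])
    vert = Stroke([(r, cc, 90) for r in range(cr - arm, cr + arm + 1)])
    return Template(name, [horiz, vert], [], color_bin)


def bar_template(
    name: str,
    col_left: int,
    width: int,
    rows: tuple[int, int],
    color_bin: int = 5,
) -> Template:
    """Vertical occluder bar spanning ``rows`` (inclusive), used to mask
    parts of other objects."""
    r0, r1 = rows
    c0, c1 = col_left, col_left + width - 1
    cells: list[tuple[int, int, int]] = []
    cells += [(r0 - 1, c, 0) for c in range(c0, c1 + 1)]
    cells += [(r, c1, 90) for r in range(r0, r1 + 1)]
    cells += [(r1, c, 0) for c in range(c1, c0 - 1, -1)]
    cells += [(r, c0 - 1, 90) for r in range(r1, r0 - 1, -1)]
    interior = [(r, c) for r in range(r0, r1 + 1) for c in range(c0, c1 + 1)]
    return Template(name, [Stroke(cells, closed=True)], interior, color_bin)


# -- model construction ---------------------------------------------------


def build_template_model(
    templates: Sequence[Template],
    config: ModelConfig | None = None,
    occluders: Sequence[str] = (),
) -> RCNModel:
    """Build the three-level hierarchy for a set of shape templates.

    Each outline cell becomes a level-1 segment anchor with a translation
    pool of radius ``config.pooling_radius`` (radius 0 gives a rigid
    template matcher); consecutive anchors within a stroke get
    contour-continuity laterals; the anchor sequence is split into
    ``config.n_parts`` contiguous arcs forming level-2 part features; one
    level-3 feature per template conjoins its parts.  Occluder templates
    are ordinary objects flagged by name.
    """
    config = config or ModelConfig()
    rows, cols = config.grid_shape
    if not templates:
        raise GraphError("need at least one template")
    n_objects = len(templates)
    top_prior = (
        config.top_prior_llr
        if config.top_prior_llr is not None
        else -math.log(n_objects) - 1.0
    )
    features: dict[str, FeatureNode] = {}
    pools: dict[str, PoolSpec] = {}
    laterals: list[LateralSpec] = []

    for tpl in templates:
        outline = tpl.outline()
        for r, c, o in outline:
            if not (0 <= r < rows and 0 <= c < cols):
                raise GraphError(
                    f"template {tpl.name!r}: outline cell {(r, c)} leaves the grid"
                )
        # level-1 anchors with translation pools over leaves
        anchor_pools: list[str] = []
        k = 0
        for stroke in tpl.strokes:
            stroke_pool_ids = []
            for r, c, o in stroke.cells:
                fid = f"f1:{tpl.name}:{k}"
                pid = f"p1:{tpl.name}:{k}"
                dr, dc = PERP[o]
                members = []
                for t in range(-config.pooling_radius, config.pooling_radius + 1):
                    rr, cc = r + dr * t, c + dc * t
                    if 0 <= rr < rows and 0 <= cc < cols:
                        members.append((leaf_id(rr, cc, o), t))
                if not members:
                    raise GraphError(
                        f"template {tpl.name!r}: empty pool at {(r, c, o)}"
                    )
                features[fid] = FeatureNode(fid, 1, [pid], config.lower_prior_llr)
                pools[pid] = PoolSpec(pid, 1, (r, c), members)
                stroke_pool_ids.append(pid)
                k += 1
            pairs = list(zip(stroke_pool_ids, stroke_pool_ids[1:]))
            if stroke.closed and len(stroke_pool_ids) > 2:
                pairs.append((stroke_pool_ids[-1], stroke_pool_ids[0]))
            for p, q in pairs:
                allowed = [
                    (ti, tj)
                    for _, ti in pools[p].members
                    for _, tj in pools[q].members
                    if abs(ti - tj) <= config.lateral_radius
                ]
                laterals.append(LateralSpec((p, q), allowed, clone_tag=tpl.name))
            anchor_pools.extend(stroke_pool_ids)

        # level-2 parts: contiguous arcs of the anchor sequence
        n_anchors = len(anchor_pools)
        n_parts = min(config.n_parts, n_anchors)
        bounds = np.linspace(0, n_anchors, n_parts + 1).astype(int)
        part_ids = []
        for q in range(n_parts):
            f2 = f"f2:{tpl.name}:{q}"
            child_pools = []
            for j, pi in enumerate(range(bounds[q], bounds[q + 1])):
                p2 = f"p2:{tpl.name}:{q}:{j}"
                f1 = f"f1:{tpl.name}:{pi}"
                pools[p2] = PoolSpec(p2, 2, pools[anchor_pools[pi]].center, [(f1, 0)])
                child_pools.append(p2)
            features[f2] = FeatureNode(f2, 2, child_pools, config.lower_prior_llr)
            part_ids.append(f2)

        # level-3 object
        f3 = f"f3:{tpl.name}"
        obj_pools = []
        for q, f2 in enumerate(part_ids):
            p3 = f"p3:{tpl.name}:{q}"
            pools[p3] = PoolSpec(p3, 3, pools[anchor_pools[0]].center, [(f2, 0)])
            obj_pools.append(p3)
        features[f3] = FeatureNode(f3, 3, obj_pools, top_prior)

    surface = (
        SurfaceLattice(tuple(config.grid_shape), config.appearance_n, config.c_penalty)
        if config.include_surface
        else None
    )
    return RCNModel(
        config=config,
        templates={t.name: t for t in templates},
        features=features,
        pools=pools,
        laterals=laterals,
        surface=surface,
        occluders=list(occluders),
    )


# -- compilation ----------------------------------------------------------


def clone_id(pool: str, tag: int) -> str:
    return f"cl:{pool}:{tag}"


def compile_model(model: RCNModel) -> FactorGraph:
    """Compile the declarative model to a factor graph.

    Emits: binary feature variables; clone variables (one per pool
    member); a POOL factor per pool whose pooling variable is the parent
    feature; pairwise TABLE laterals forbidding discontinuous clone pairs;
    one OR interface per referenced lower-level unit (all clones of the
    unit as children, the unit as output); a CHANNEL plus pixel variable
    per leaf; a unary prior per feature with nonzero prior; and, when the
    surface lattice is on, appearance patches, lattice-edge contour
    variables with their OR support and EDGE_APPEARANCE factors.
    """
    cfg = model.config
    rows, cols = model.grid_shape
    variables: list[VariableSpec] = []
    factors: list[FactorSpec] = []
    neg = -1e9

    for fid, feat in model.features.items():
        variables.append(VariableSpec(fid, 2, "feature"))
        if feat.prior_llr != 0.0:
            factors.append(
                FactorSpec(
                    f"prior:{fid}",
                    "TABLE",
                    (fid,),
                    {"log_potential": np.array([0.0, feat.prior_llr])},
                )
            )

    # clones + pool factors; collect clones per lower-level unit
    unit_clones: dict[str, list[str]] = {}
    for pid, pool in model.pools.items():
        parent = _pool_parent(model, pid)
        member_clones = []
        for unit, tag in pool.members:
            cid = clone_id(pid, tag)
            variables.append(VariableSpec(cid, 2, "clone"))
            member_clones.append(cid)
            unit_clones.setdefault(unit, []).append(cid)
            if tag != 0 and cfg.tie_epsilon > 0:
                factors.append(
                    FactorSpec(
                        f"shiftprior:{cid}",
                        "TABLE",
                        (cid,),
                        {
                            "log_potential": np.array(
                                [0.0, -cfg.tie_epsilon * abs(tag)]
                            )
                        },
                    )
                )
        factors.append(
            FactorSpec(f"fpool:{pid}", "POOL", (parent,) + tuple(member_clones))
        )

    # laterals: forbid member pairs not in the allowed set
    for li, lat in enumerate(model.laterals):
        p, q = lat.pools
        allowed = set(map(tuple, lat.allowed))
        for _, ti in model.pools[p].members:
            for _, tj in model.pools[q].members:
                if (ti, tj) not in allowed:
                    table = np.array([[0.0, 0.0], [0.0, neg]])
                    factors.append(
                        FactorSpec(
                            f"lat:{li}:{ti}:{tj}",
                            "TABLE",
                            (clone_id(p, ti), clone_id(q, tj)),
                            {"log_potential": table},
                        )
                    )

    # OR interfaces and leaf channels
    leaf_units = sorted(model.leaf_positions())
    for r, c, o in leaf_units:
        variables.append(VariableSpec(leaf_id(r, c, o), 2, "leaf"))
        variables.append(VariableSpec(pixel_id(r, c, o), 2, "pixel"))
        factors.append(
            make_channel_factor(
                cfg.channel, f"ch:{r}:{c}:{o}", leaf_id(r, c, o), pixel_id(r, c, o)
            )
        )
    for unit, clones in unit_clones.items():
        factors.append(
            FactorSpec(f"for:{unit}", "OR", tuple(clones) + (unit,))
        )

    # surface lattice
    if model.surface is not None:
        N = model.surface.appearance_n
        cpen = model.surface.c_penalty
        leaf_set = {(r, c, o) for r, c, o in leaf_units}
        for r in range(rows):
            for c in range(cols):
                variables.append(VariableSpec(patch_id(r, c), N, "surface-patch"))
        crossing = {"R": (90, 45, 135), "D": (0, 45, 135)}
        for r in range(rows):
            for c in range(cols):
                for d, (nr, nc) in (("R", (r, c + 1)), ("D", (r + 1, c))):
                    if not (nr < rows and nc < cols):
                        continue
                    eid = edge_id(r, c, d)
                    variables.append(VariableSpec(eid, 2, "edge"))
                    factors.append(
                        FactorSpec(
                            f"fedge:{r}:{c}:{d}",
                            "EDGE_APPEARANCE",
                            (patch_id(r, c), patch_id(nr, nc), eid),
                            {"c_penalty": cpen},
                        )
                    )
                    support = [
                        leaf_id(r, c, o) for o in crossing[d] if (r, c, o) in leaf_set
                    ]
                    if support:
                        factors.append(
                            FactorSpec(
                                f"oredge:{r}:{c}:{d}",
                                "OR",
                                tuple(support) + (eid,),
                            )
                        )
                    else:
                        # no template can explain a contour here: pin OFF
                        factors.append(
                            FactorSpec(
                                f"noedge:{r}:{c}:{d}",
                                "TABLE",
                                (eid,),
                                {"log_potential": np.array([0.0, neg])},
                            )
                        )
    return build_graph(variables, factors)


def _pool_parent(model: RCNModel, pid: str) -> str:
    for fid, feat in model.features.items():
        if pid in feat.children:
            return fid
    raise GraphError(f"pool {pid!r} has no parent feature")


# -- serialization --------------------------------------------------------


def save_model(model: RCNModel) -> str:
    doc = {
        "format": MODEL_SCHEMA,
        "version": MODEL_VERSION,
        "config": {
            **{k: v for k, v in asdict(model.config).items() if k != "channel"},
            "channel": {
                "precision": model.config.channel.precision,
                "sensitivity": model.config.channel.sensitivity,
            },
        },
        "templates": {
            name: {
                "strokes": [
                    {"cells": [list(c) for c in s.cells], "closed": s.closed}
                    for s in tpl.strokes
                ],
                "interior": [list(c) for c in tpl.interior],
                "color_bin": tpl.color_bin,
            }
            for name, tpl in model.templates.items()
        },
        "features": {
            fid: {"level": f.level, "children": f.children, "prior_llr": f.prior_llr}
            for fid, f in model.features.items()
        },
        "pools": {
            pid: {
                "level": p.level,
                "center": list(p.center),
                "members": [[u, t] for u, t in p.members],
            }
            for pid, p in model.pools.items()
        },
        "laterals": [
            {
                "pools": list(lat.pools),
                "allowed": [list(a) for a in lat.allowed],
                "clone_tag": lat.clone_tag,
            }
            for lat in model.laterals
        ],
        "surface": (
            None
            if model.surface is None
            else {
                "shape": list(model.surface.shape),
                "appearance_n": model.surface.appearance_n,
                "c_penalty": model.surface.c_penalty,
            }
        ),
        "occluders": model.occluders,
    }
    return json.dumps(doc, indent=1)


def load_model(text: str) -> RCNModel:
    doc = json.loads(text)
    if doc.get("format") != MODEL_SCHEMA:
        raise GraphError(f"not an {MODEL_SCHEMA} document")
    if doc.get("version") != MODEL_VERSION:
        raise GraphError(f"unsupported {MODEL_SCHEMA} version {doc.get('version')!r}")
    cfg_doc = dict(doc["config"])
    ch = cfg_doc.pop("channel")
    cfg = ModelConfig(**{**cfg_doc, "grid_shape": tuple(cfg_doc["grid_shape"])})
    cfg.channel = ChannelParams(ch["precision"], ch["sensitivity"])
    templates = {
        name: Template(
            name,
            [
                Stroke([tuple(c) for c in s["cells"]], s["closed"])
                for s in t["strokes"]
            ],
            [tuple(c) for c in t["interior"]],
            t["color_bin"],
        )
        for name, t in doc["templates"].items()
    }
    features = {
        fid: FeatureNode(fid, f["level"], list(f["children"]), f["prior_llr"])
        for fid, f in doc["features"].items()
    }
    pools = {}
    for pid, p in doc["pools"].items():
        members = [(u, int(t)) for u, t in p["members"]]
        for u, _ in members:
            if not (u.startswith("lf:") or u in features):
                raise GraphError(f"pools.{pid}: dangling member {u!r}")
        pools[pid] = PoolSpec(pid, p["level"], tuple(p["center"]), members)
    for fid, f in features.items():
        for pid in f.children:
            if pid not in pools:
                raise GraphError(f"features.{fid}: dangling child pool {pid!r}")
    laterals = []
    for i, lat in enumerate(doc["laterals"]):
        p, q = lat["pools"]
        if p not in pools or q not in pools:
            raise GraphError(f"laterals[{i}]: dangling pool reference")
        laterals.append(
            LateralSpec(
                (p, q), [tuple(a) for a in lat["allowed"]], lat.get("clone_tag", "")
            )
        )
    surface = None
    if doc.get("surface") is not None:
        s = doc["surface"]
        surface = SurfaceLattice(tuple(s["shape"]), s["appearance_n"], s["c_penalty"])
    return RCNModel(
        cfg, templates, features, pools, laterals, surface, list(doc["occluders"])
    )
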