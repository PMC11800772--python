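"""Synthetic stimulus generation.

A stimulus is a grid of idealized oriented-edge detector responses
(per-cell, per-orientation contour log-likelihood ratios, written straight
onto the model's pixel channels) plus a per-cell quantized appearance
observation (a color bin, or UNOBSERVED which contributes zero messages).
Generating evidence at the leaf-detector level rather than rendering and
filtering pixels keeps the occlusion/deletion semantics exact: deleted
object parts carry *negative* contour evidence (confident absence), while
parts covered by an occluder carry the occluder's own evidence and
*uncertain* (zero) evidence on the hidden channels.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .factor_graph import GraphError
from .rcn_model import ORIENTATIONS, RCNModel, Template

#: appearance value for cells with no appearance observation
UNOBSERVED = -1

OIDX = {o: i for i, o in enumerate(ORIENTATIONS)}


@dataclass
class Stimulus:
    """Evidence grids: ``contour[r, c, k]`` is the LLR for orientation
    ORIENTATIONS[k] at cell (r, c); ``appearance[r, c]`` is a color bin or
    UNOBSERVED."""

    contour: np.ndarray
    appearance: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.contour.shape[:2]

    def contour_at(self, r: int, c: int, o: int) -> float:
        return float(self.contour[r, c, OIDX[o]])

    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "rcnbp-stimulus",
                "version": 1,
                "contour": self.contour.tolist(),
                "appearance": self.appearance.tolist(),
                "provenance": self.provenance,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Stimulus":
        doc = json.loads(text)
        if doc.get("format") != "rcnbp-stimulus" or doc.get("version") != 1:
            raise GraphError("not a supported rcnbp-stimulus document")
        return cls(
            np.asarray(doc["contour"], dtype=float),
            np.asarray(doc["appearance"], dtype=int),
            doc.get("provenance", {}),
        )


@dataclass
class SceneSpec:
    """Reproducible scene description: template placements (name, (dr, dc)
    offset), evidence magnitude e0, Gaussian noise sigma on all contour
    channels, and the seed."""

    placements: list[tuple[str, tuple[int, int]]]
    e0: float = 3.0
    noise_sigma: float = 0.5
    seed: int = 0


def _blank(shape, e0: float, background_bin: int | None = 0):
    contour = np.full(shape + (len(ORIENTATIONS),), -e0, dtype=float)
    if background_bin is None:
        appearance = np.full(shape, UNOBSERVED, dtype=int)
    else:
        appearance = np.full(shape, background_bin, dtype=int)
    return contour, appearance


def _stamp(contour, appearance, tpl: Template, offset=(0, 0), e0=3.0):
    dr, dc = offset
    rows, cols = contour.shape[:2]
    for r, c, o in tpl.outline():
        rr, cc = r + dr, c + dc
        if not (0 <= rr < rows and 0 <= cc < cols):
            raise GraphError(f"placement of {tpl.name!r} leaves the grid")
        contour[rr, cc, OIDX[o]] = e0
    for r, c in tpl.interior:
        rr, cc = r + dr, c + dc
        if 0 <= rr < rows and 0 <= cc < cols:
            appearance[rr, cc] = tpl.color_bin


def render_scene(model: RCNModel, spec: SceneSpec) -> Stimulus:
    """Idealized rendering: +e0 contour evidence at the matching
    orientation on each placed outline cell, -e0 elsewhere, template color
    bins over interiors on a background-bin canvas, then seeded Gaussian
    noise on every contour channel."""
    shape = model.grid_shape
    contour, appearance = _blank(shape, spec.e0)
    for name, offset in spec.placements:
        if name not in model.templates:
            raise GraphError(f"unknown template {name!r}")
        _stamp(contour, appearance, model.templates[name], offset, spec.e0)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        contour = contour + rng.normal(0.0, spec.noise_sigma, contour.shape)
    return Stimulus(
        contour,
        appearance,
        {
            "kind": "scene",
            "placements": [[n, list(off)] for n, off in spec.placements],
            "e0": spec.e0,
            "noise_sigma": spec.noise_sigma,
            "seed": spec.seed,
        },
    )


# -- subjective contours --------------------------------------------------


@dataclass
class KanizsaConfig:
    """Four corner inducers on a square outline; the sides between them
    are blank (weakly negative evidence).  ``rotated`` flips each
    inducer's local orientations (the classic misaligned control)."""

    grid_shape: tuple[int, int] = (24, 24)
    center: tuple[int, int] = (12, 12)
    half: int = 5
    arm: int = 4
    e0: float = 3.0
    gap_llr: float = -0.5
    rotated: bool = False
    noise_sigma: float = 0.0
    seed: int = 0


def kanizsa(config: KanizsaConfig, square: Template) -> Stimulus:
    """Pac-man style inducer evidence at the four corners of ``square``'s
    outline; gap (mid-side) cells carry ``gap_llr``.  With ``rotated`` the
    inducer cells keep their positions but their orientations are rotated
    90 degrees, destroying the global square percept."""
    ring = square.outline()
    n = len(ring)
    if n % 4 != 0:
        raise GraphError("kanizsa expects a 4-side closed outline")
    side = n // 4
    contour, appearance = _blank(config.grid_shape, config.e0)
    rot = {0: 90, 90: 0, 45: 135, 135: 45}
    for i, (r, c, o) in enumerate(ring):
        pos = i % side
        near_corner = pos < config.arm or pos >= side - config.arm
        if near_corner:
            oo = rot[o] if config.rotated else o
            contour[r, c, OIDX[oo]] = config.e0
            if config.rotated:
                contour[r, c, OIDX[o]] = -config.e0
        else:
            contour[r, c, OIDX[o]] = config.gap_llr
    rng = np.random.default_rng(config.seed)
    if config.noise_sigma > 0:
        contour = contour + rng.normal(0.0, config.noise_sigma, contour.shape)
    return Stimulus(
        contour,
        appearance,
        {
            "kind": "kanizsa",
            "rotated": config.rotated,
            "arm": config.arm,
            "gap_llr": config.gap_llr,
            "seed": config.seed,
        },
    )


def kanizsa_gap_cells(config: KanizsaConfig, square: Template):
    """(r, c, o) outline cells in the illusory gaps (no inducer support)."""
    ring = square.outline()
    side = len(ring) // 4
    out = []
    for i, (r, c, o) in enumerate(ring):
        pos = i % side
        if config.arm <= pos < side - config.arm:
            out.append((r, c, o))
    return out


# -- neon-color spreading -------------------------------------------------


@dataclass
class NeonConfig:
    """Lattice of thin lines whose central portion (inside the illusory
    disk) is drawn in a different color.  Appearance is observed only on
    the lines; the rest of the canvas is UNOBSERVED and must be filled in
    by surface propagation."""

    grid_shape: tuple[int, int] = (24, 24)
    line_rows: tuple[int, ...] = (2, 6, 10, 14, 18, 22)
    line_cols: tuple[int, ...] = (2, 6, 10, 14, 18, 22)
    disk_center: tuple[int, int] = (12, 12)
    disk_half: int = 5
    line_bin: int = 1
    inducer_bin: int = 2
    e0: float = 3.0
    e_weak: float = 1.5
    gap_llr: float = 0.0


def neon_cross(config: NeonConfig, disk: Template) -> Stimulus:
    """Colored-segment lattice stimulus.

    Lines carry +e0 contour evidence along their own orientation and their
    color bin as appearance; line segments inside the disk footprint use
    the inducer color.  The disk outline carries weak positive evidence
    where a line crosses it (the physical color transition) and
    ``gap_llr`` elsewhere; the surrounding canvas carries -e0.
    """
    rows, cols = config.grid_shape
    contour, appearance = _blank(config.grid_shape, config.e0, background_bin=None)
    footprint = disk.footprint()
    for r in config.line_rows:
        for c in range(cols):
            contour[r, c, OIDX[0]] = config.e0
            appearance[r, c] = (
                config.inducer_bin if (r, c) in footprint else config.line_bin
            )
    for c in config.line_cols:
        for r in range(rows):
            contour[r, c, OIDX[90]] = config.e0
            appearance[r, c] = (
                config.inducer_bin if (r, c) in footprint else config.line_bin
            )
    for r, c, o in disk.outline():
        on_line = (o == 0 and c in config.line_cols) or (
            o == 90 and r in config.line_rows
        )
        val = config.e_weak if on_line else config.gap_llr
        contour[r, c, OIDX[o]] = max(contour[r, c, OIDX[o]], val)
    return Stimulus(
        contour,
        appearance,
        {
            "kind": "neon",
            "inducer_bin": config.inducer_bin,
            "disk_half": config.disk_half,
        },
    )


# -- occlusion vs. deletion -----------------------------------------------


def occlusion_deletion_pair(
    model: RCNModel,
    base_spec: SceneSpec,
    occluder_name: str | None,
    fraction: float,
) -> tuple[Stimulus, Stimulus]:
    """Matched stimulus pair with identical visible portions.

    The occluder template's footprint defines the mask.  In the occluded
    variant, masked cells carry *uncertain* (zero) contour evidence on all
    channels -- the region is covered, detectors cannot see behind it --
    except the occluder's own outline, which carries its positive
    evidence; masked appearance is the occluder's color.  In the deleted
    variant the masked region is background: confidently negative contour
    evidence everywhere and the background bin.  Both variants share one
    seeded noise field, so they are element-wise identical outside the
    mask.  ``fraction`` (0..1) is the intended masked share of the target
    outline; fraction 0 disables the occluder entirely and the two
    stimuli are identical.  The achieved fraction is recorded in
    provenance.
    """
    if not 0 <= fraction <= 1:
        raise GraphError("fraction must be in [0, 1]")
    shape = model.grid_shape
    e0 = base_spec.e0
    contour, appearance = _blank(shape, e0)
    target_outline: list[tuple[int, int]] = []
    for name, offset in base_spec.placements:
        tpl = model.templates[name]
        _stamp(contour, appearance, tpl, offset, e0)
        target_outline += [
            (r + offset[0], c + offset[1]) for r, c, _ in tpl.outline()
        ]

    if fraction == 0 or occluder_name is None:
        mask: set[tuple[int, int]] = set()
    else:
        occ = model.templates[occluder_name]
        mask = occ.footprint()

    occluded = contour.copy()
    occluded_app = appearance.copy()
    deleted = contour.copy()
    deleted_app = appearance.copy()
    covered = 0
    for r, c in mask:
        occluded[r, c, :] = 0.0
        deleted[r, c, :] = -e0
        deleted_app[r, c] = 0
    if mask:
        occ = model.templates[occluder_name]
        for r, c, o in occ.outline():
            occluded[r, c, OIDX[o]] = e0
        for r, c in mask:
            occluded_app[r, c] = occ.color_bin
        covered = sum((r, c) in mask for r, c in target_outline)
    achieved = covered / max(len(target_outline), 1)

    rng = np.random.default_rng(base_spec.seed)
    if base_spec.noise_sigma > 0:
        noise = rng.normal(0.0, base_spec.noise_sigma, contour.shape)
        occluded = occluded + noise
        deleted = deleted + noise
    prov = {
        "kind": "occlusion-deletion",
        "occluder": occluder_name if mask else None,
        "requested_fraction": fraction,
        "achieved_fraction": achieved,
        "seed": base_spec.seed,
    }
    return (
        Stimulus(occluded, occluded_app, {**prov, "condition": "occluded"}),
        Stimulus(deleted, deleted_app, {**prov, "condition": "deleted"}),
    )
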