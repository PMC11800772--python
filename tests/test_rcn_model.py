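import numpy as np
import pytest

from rcnbp.bp_engine import BPSettings, run
from rcnbp.factor_graph import GraphError
from rcnbp.factors import MAX_PRODUCT
from rcnbp.rcn_model import (
    ModelConfig,
    Stroke,
    Template,
    bar_template,
    build_template_model,
    compile_model,
    cross_template,
    diamond_template,
    leaf_id,
    load_model,
    save_model,
    square_template,
)


def small_config(**kw):
    defaults = dict(grid_shape=(24, 24), include_surface=False)
    defaults.update(kw)
    return ModelConfig(**defaults)


class TestBuildTemplateModel:
    def test_square_has_four_parts_and_tiled_pools(self, contour_model):
        parts = [f for f in contour_model.features if f.startswith("f2:square")]
        assert len(parts) == 4
        outline = contour_model.templates["square"].outline()
        pools = [p for p in contour_model.pools.values()
                 if p.level == 1 and "square" in p.id]
        assert len(pools) == len(outline)
        centers = {p.center for p in pools}
        assert centers == {(r, c) for r, c, _ in outline}

    def test_shared_leaf_feeds_both_templates_via_one_or_block(self):
        # two squares offset by one: their outlines overlap on shared leaves
        t1 = square_template("s1", center=(12, 12), half=4)
        t2 = Template(
            "s2",
            [Stroke(list(t1.strokes[0].cells), closed=True)],
            list(t1.interior),
            2,
        )
        model = build_template_model([t1, t2], small_config())
        g = compile_model(model)
        shared_or = [
            f for f in g.factors.values()
            if f.id.startswith("for:lf:") and f.arity >= 3
        ]
        assert shared_or  # identical outlines: every leaf OR has 2+ clones
        assert all(f.arity == 2 + 1 for f in shared_or)

    def test_pooling_radius_zero_is_rigid(self):
        model = build_template_model(
            [square_template()], small_config(pooling_radius=0)
        )
        assert all(
            len(p.members) == 1
            for p in model.pools.values()
            if p.level == 1
        )
        assert not any(
            len(lat.allowed) > 1 for lat in model.laterals
        )

    def test_outline_leaving_grid_rejected(self):
        with pytest.raises(GraphError, match="leaves the grid"):
            build_template_model(
                [square_template(center=(2, 2), half=5)], small_config()
            )

    def test_graph_size_scales_linearly_with_outline_and_pool(self):
        cfg = small_config()
        model = build_template_model([square_template()], cfg)
        g = compile_model(model)
        L = len(model.templates["square"].outline())
        pool = 2 * cfg.pooling_radius + 1
        # features + pools + clones + leaves + pixels, all O(L * pool)
        assert len(g.variables) <= 12 * L * pool
        assert len(g.factors) <= 12 * L * pool


class TestCompile:
    def test_compiled_graph_revalidates(self, contour_model):
        g = compile_model(contour_model)
        from rcnbp.factor_graph import build_graph

        g2 = build_graph(g.variables.values(), g.factors.values())
        assert len(g2.factors) == len(g.factors)

    def test_every_lattice_edge_has_one_edge_appearance_factor(self):
        model = build_template_model(
            [square_template()], small_config(include_surface=True)
        )
        g = compile_model(model)
        rows, cols = model.grid_shape
        expected = rows * (cols - 1) + (rows - 1) * cols
        fedges = [f for f in g.factors if f.startswith("fedge:")]
        assert len(fedges) == expected
        # each edge variable touched by exactly one EDGE_APPEARANCE factor
        from collections import Counter

        counts = Counter()
        for fid in fedges:
            counts[g.factors[fid].neighbor_ids[2]] += 1
        assert set(counts.values()) == {1}

    def test_rigid_single_object_no_laterals_is_tree(self):
        model = build_template_model(
            [square_template()],
            small_config(pooling_radius=0, tie_epsilon=0.0),
        )
        g = compile_model(model)
        assert g.is_tree()

    def test_all_off_map_without_evidence(self, contour_model):
        g = compile_model(contour_model)
        res = run(
            g,
            settings=BPSettings(temperature=MAX_PRODUCT, damping=0.5,
                                max_iterations=30),
            schedule=None if g.is_tree() else None,
        )
        dec = res.engine.decode_map()
        on = [v for v in contour_model.features if dec[v] == 1]
        assert on == []


class TestSerialization:
    def test_save_load_round_trip(self, contour_model):
        text = save_model(contour_model)
        model2 = load_model(text)
        assert set(model2.features) == set(contour_model.features)
        assert set(model2.pools) == set(contour_model.pools)
        assert len(model2.laterals) == len(contour_model.laterals)
        assert save_model(model2) == text

    def test_dangling_pool_member_named_in_error(self, contour_model):
        text = save_model(contour_model)
        import json

        doc = json.loads(text)
        pid = next(iter(doc["pools"]))
        doc["pools"][pid]["members"] = [["f1:nonexistent:99", 0]]
        with pytest.raises(GraphError, match="f1:nonexistent:99"):
            load_model(json.dumps(doc))

    def test_version_mismatch_rejected(self, contour_model):
        text = save_model(contour_model).replace('"version": 1', '"version": 2')
        with pytest.raises(GraphError, match="version"):
            load_model(text)


class TestGenerativeBehavior:
    def test_clamped_object_reconstructs_contour(self, contour_model, contour_parser):
        """Top-down generation: clamping one object ON with uncertain
        evidence reproduces its full outline on the lattice."""
        import rcnbp.schedule as sch
        from rcnbp.factor_graph import apply_evidence, clamp
        from rcnbp.bp_engine import BeliefPropagation
        from rcnbp.stimuli import Stimulus

        parser = contour_parser
        zero = Stimulus(
            np.zeros(contour_model.grid_shape + (4,)),
            np.zeros(contour_model.grid_shape, dtype=int),
        )
        g = parser.base_graph.copy()
        apply_evidence(g, parser.evidence_map(zero))
        clamp(g, {"f3:square": 1})
        engine = BeliefPropagation(g, parser.settings.bp)
        tr = sch.StageTrace()
        engine.step_group(
            parser._all([f for f in g.factors if f.startswith("evidence:")])
        )
        engine.step_group(parser._all(parser.groups["channel"]
                                      + parser.groups["prior"]))
        parser.backward_pass(engine, tr, 0)
        parser.forward_pass(engine, tr, 1)
        for i in range(2):
            parser.backward_pass(engine, tr, i + 1)
            parser.forward_pass(engine, tr, i + 2)
        dec = engine.decode_map()
        on = {v for v in g.variables if v.startswith("lf:") and dec[v] == 1}
        want = {
            leaf_id(r, c, o)
            for r, c, o in contour_model.templates["square"].outline()
        }
        assert on == want


def test_template_library_geometry():
    sq = square_template()
    assert len(sq.outline()) == 44
    assert sq.strokes[0].closed
    dm = diamond_template()
    assert all(o in (45, 135) for _, _, o in dm.outline())
    cr = cross_template()
    assert len(cr.strokes) == 2 and not cr.strokes[0].closed
    bar = bar_template("b", 5, 2, (1, 22))
    assert (1, 4, 90) in bar.outline()
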