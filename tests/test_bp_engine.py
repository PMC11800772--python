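import numpy as np
import pytest

from rcnbp.bp_engine import (
    BeliefPropagation,
    BPSettings,
    MessageStore,
    bethe_free_energy,
    factor_to_variable_generic,
    parallel_schedule,
    run,
    sequential_schedule,
    tree_schedule,
    variable_to_factor,
)
from rcnbp.factor_graph import FactorSpec, VariableSpec, apply_evidence, build_graph
from rcnbp.factors import MAX_PRODUCT
from rcnbp.oracle import (
    enumerate_factor_message,
    enumerate_log_partition,
    enumerate_map,
    enumerate_marginals,
    map_is_unique,
)

from conftest import normalize, random_loopy_graph, random_tree_graph


def unary(vid, values):
    return FactorSpec(
        f"u:{vid}", "TABLE", (vid,), {"log_potential": np.asarray(values, float)}
    )


class TestVariableToFactor:
    def test_sum_of_other_incoming(self):
        g = build_graph(
            [VariableSpec("x")],
            [unary("x", [0, 0]), FactorSpec("f2", "TABLE", ("x",),
                                            {"log_potential": np.zeros(2)}),
             FactorSpec("f3", "TABLE", ("x",), {"log_potential": np.zeros(2)})],
        )
        store = MessageStore(g)
        store.set_message("u:x", "x", np.array([0.0, 1.0]))
        store.set_message("f2", "x", np.array([0.0, -0.5]))
        store.set_message("f3", "x", np.array([0.0, 0.25]))
        out = variable_to_factor(store, g, "x", "u:x")
        assert out[1] - out[0] == pytest.approx(-0.25)

    def test_single_incident_factor_gives_zero(self):
        g = build_graph([VariableSpec("x")], [unary("x", [0, 2.0])])
        store = MessageStore(g)
        store.set_message("u:x", "x", np.array([0.0, 2.0]))
        out = variable_to_factor(store, g, "x", "u:x")
        assert np.allclose(out, 0.0)


class TestGenericFactorUpdate:
    def test_unary_factor_emits_own_potential(self):
        f = unary("x", [0.0, 1.5])
        out = factor_to_variable_generic(f, (2,), [np.zeros(2)], 0, 1.0)
        assert np.allclose(out, [0.0, 1.5])

    def test_pairwise_equality_copies_message(self):
        table = np.array([[0.0, -np.inf], [-np.inf, 0.0]])
        table = np.where(np.isneginf(table), -1e9, table)
        f = FactorSpec("f", "TABLE", ("a", "b"), {"log_potential": table})
        msg = np.array([0.0, 0.8])
        out = factor_to_variable_generic(f, (2, 2), [msg, np.zeros(2)], 1, MAX_PRODUCT)
        assert np.allclose(normalize(out), normalize(msg))

    @pytest.mark.parametrize("T", [1.0, 0.5])
    def test_random_table_matches_oracle(self, T):
        rng = np.random.default_rng(0)
        for _ in range(10):
            table = rng.normal(0, 1.5, (2, 2, 3))
            f = FactorSpec("f", "TABLE", ("a", "b", "c"), {"log_potential": table})
            incoming = [rng.normal(0, 1, k) for k in (2, 2, 3)]
            for t in range(3):
                got = factor_to_variable_generic(f, (2, 2, 3), incoming, t, T)
                want = enumerate_factor_message(f, (2, 2, 3), incoming, t, T)
                assert np.allclose(normalize(got), normalize(want), atol=1e-10)


class TestTreeExactness:
    def test_beliefs_equal_enumerated_marginals(self):
        rng = np.random.default_rng(42)
        for _ in range(15):
            g = random_tree_graph(rng, int(rng.integers(2, 13)))
            res = run(g, settings=BPSettings(temperature=1.0))
            assert res.converged
            marg = enumerate_marginals(g)
            for v in g.variables:
                assert np.allclose(res.beliefs.marginal(v), marg[v], atol=1e-9)

    def test_isolated_variable_belief_is_unary_llr(self):
        g = build_graph([VariableSpec("x")], [unary("x", [0.0, 0.7])])
        res = run(g, settings=BPSettings(temperature=1.0))
        assert res.beliefs.llr("x") == pytest.approx(0.7)

    def test_opposing_messages_cancel(self):
        g = build_graph(
            [VariableSpec("x")], [unary("x", [0, 1.0]),
                                  FactorSpec("d", "TABLE", ("x",),
                                             {"log_potential": np.array([0, -1.0])})],
        )
        res = run(g, settings=BPSettings(temperature=1.0))
        assert res.beliefs.llr("x") == pytest.approx(0.0, abs=1e-12)

    def test_damping_invariance_at_fixed_point(self):
        rng = np.random.default_rng(9)
        g = random_tree_graph(rng, 8)
        sched = tree_schedule(g)
        r0 = run(g, settings=BPSettings(temperature=1.0, damping=0.0),
                 schedule=sched)
        r5 = run(g, settings=BPSettings(temperature=1.0, damping=0.5,
                                        max_iterations=400), schedule=sched)
        for v in g.variables:
            assert np.allclose(
                r0.beliefs.marginal(v), r5.beliefs.marginal(v), atol=1e-6
            )

    def test_max_product_decode_equals_enumeration(self):
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 10:
            g = random_tree_graph(rng, int(rng.integers(2, 13)))
            if not map_is_unique(g):
                continue
            res = run(g, settings=BPSettings(temperature=MAX_PRODUCT))
            amap, _ = enumerate_map(g)
            assert res.engine.decode_map() == amap
            checked += 1


class TestBetheFreeEnergy:
    def test_uniform_binary_gives_log2(self):
        g = build_graph([VariableSpec("x")], [unary("x", [0.0, 0.0])])
        res = run(g, settings=BPSettings(temperature=1.0))
        assert res.engine.bethe_free_energy() == pytest.approx(-np.log(2), abs=1e-12)

    def test_unary_closed_form(self):
        g = build_graph([VariableSpec("x")], [unary("x", [0.0, 1.0])])
        res = run(g, settings=BPSettings(temperature=1.0))
        assert res.engine.bethe_free_energy() == pytest.approx(
            -np.log(1 + np.e), abs=1e-10
        )

    def test_tree_fixed_point_equals_minus_log_z(self):
        rng = np.random.default_rng(23)
        for _ in range(8):
            g = random_tree_graph(rng, int(rng.integers(3, 11)))
            res = run(g, settings=BPSettings(temperature=1.0))
            F = res.engine.bethe_free_energy()
            assert F == pytest.approx(-enumerate_log_partition(g), abs=1e-8)

    def test_reproducible_across_damping_on_loopy_graph(self):
        rng = np.random.default_rng(31)
        g = random_loopy_graph(rng, 8)
        Fs = []
        for d in (0.3, 0.6):
            res = run(g, settings=BPSettings(temperature=1.0, damping=d,
                                             max_iterations=500),
                      schedule=parallel_schedule(g))
            assert res.converged
            Fs.append(res.engine.bethe_free_energy())
        assert np.isfinite(Fs).all()
        assert Fs[0] == pytest.approx(Fs[1], abs=1e-4)


class TestDecode:
    def test_argmax_and_tie_rule(self):
        g = build_graph(
            [VariableSpec("a"), VariableSpec("b"), VariableSpec("t")],
            [unary("a", [0, 0.1]), unary("b", [0, -0.3]), unary("t", [0.0, 0.0])],
        )
        res = run(g, settings=BPSettings(temperature=MAX_PRODUCT))
        dec = res.engine.decode_map()
        assert dec == {"a": 1, "b": 0, "t": 0}  # exact tie -> state 0

    def test_clamps_copied_through(self):
        from rcnbp.factor_graph import clamp

        g = build_graph([VariableSpec("a")], [unary("a", [0, -5.0])])
        clamp(g, {"a": 1})
        res = run(g, settings=BPSettings(temperature=MAX_PRODUCT))
        assert res.engine.decode_map()["a"] == 1


class TestSchedulesAndDeterminism:
    def test_parallel_and_sequential_agree_on_tree(self):
        rng = np.random.default_rng(3)
        g = random_tree_graph(rng, 7)
        rp = run(g, settings=BPSettings(temperature=1.0, damping=0.5),
                 schedule=parallel_schedule(g))
        rs = run(g, settings=BPSettings(temperature=1.0),
                 schedule=sequential_schedule(g))
        for v in g.variables:
            assert np.allclose(rp.beliefs.marginal(v), rs.beliefs.marginal(v),
                               atol=1e-5)

    def test_identical_settings_give_bit_identical_messages(self):
        rng = np.random.default_rng(8)
        g = random_loopy_graph(rng, 8)
        st = BPSettings(temperature=MAX_PRODUCT, damping=0.5,
                        perturbation=1.0, seed=123)
        r1 = run(g, settings=st, schedule=parallel_schedule(g))
        r2 = run(g, settings=st, schedule=parallel_schedule(g))
        for key in r1.store.msg:
            assert np.array_equal(r1.store.msg[key], r2.store.msg[key])

    def test_trace_records_groups(self):
        rng = np.random.default_rng(1)
        g = random_tree_graph(rng, 5)
        res = run(g, settings=BPSettings(temperature=1.0), record=True,
                  snapshot_vars=list(g.variables)[:2])
        assert res.trace
        assert {"iteration", "group", "max_delta"} <= set(res.trace[0])

    def test_normalization_invariance_of_beliefs(self):
        """Shifting a stored message by a constant does not change any
        normalized belief."""
        rng = np.random.default_rng(5)
        g = random_tree_graph(rng, 6)
        res = run(g, settings=BPSettings(temperature=1.0))
        before = {v: res.beliefs.marginal(v) for v in g.variables}
        key = next(iter(res.store.msg))
        res.store.msg[key] = res.store.msg[key] + 3.7
        res.store.belief_acc[key[1]] = res.store.belief_acc[key[1]] + 3.7
        after = res.engine.beliefs()
        for v in g.variables:
            assert np.allclose(after.marginal(v), before[v], atol=1e-12)
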