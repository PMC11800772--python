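import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rcnbp.bp_engine import run, BPSettings
from rcnbp.factor_graph import FactorSpec, VariableSpec, build_graph, apply_evidence
from rcnbp.factors import (
    MAX_PRODUCT,
    ChannelParams,
    EdgeAppearanceParams,
    ORFactorParams,
    PoolFactorParams,
    channel_llr,
    edge_appearance_messages,
    make_channel_factor,
    or_messages,
    pool_messages,
    pool_messages_checked,
)
from rcnbp.oracle import enumerate_factor_message

from conftest import normalize

TEMPERATURES = [1.0, 0.5, 0.25, MAX_PRODUCT]


def or_factor(M):
    return FactorSpec("f", "OR", tuple(f"v{i}" for i in range(M + 1)))


def pool_factor(M):
    return FactorSpec("f", "POOL", tuple(f"v{i}" for i in range(M + 1)))


def edge_factor(c):
    return FactorSpec("f", "EDGE_APPEARANCE", ("a", "b", "e"), {"c_penalty": c})


class TestORMessages:
    @pytest.mark.parametrize("T", TEMPERATURES)
    @pytest.mark.parametrize("M", [2, 3, 5, 8])
    def test_matches_enumeration(self, M, T):
        rng = np.random.default_rng(M * 10 + hash(str(T)) % 97)
        for _ in range(10):
            inc = rng.normal(0, 2, M + 1)
            res = or_messages(ORFactorParams(M), inc, T)
            vecs = [np.array([0.0, s]) for s in inc]
            for t in range(M + 1):
                want = enumerate_factor_message(
                    or_factor(M), (2,) * (M + 1), vecs, t, T
                )
                assert np.allclose(
                    normalize([0.0, res[t]]), normalize(want), atol=1e-9
                )

    @pytest.mark.parametrize("T", TEMPERATURES)
    def test_single_input_identity_exact(self, T):
        """OR of one input passes messages through unchanged, at machine
        precision (closed-form cancellation)."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            c_in, e_in = rng.normal(0, 3, 2)
            to_c, to_e = or_messages(ORFactorParams(1), [c_in, e_in], T)
            assert to_c == e_in
            assert to_e == c_in

    def test_uninformative_children_count_configurations(self):
        # two children at 0: three of four input configurations give e=1
        res = or_messages(ORFactorParams(2), [0.0, 0.0, 0.0], 1.0)
        assert res[2] == pytest.approx(np.log(3), abs=1e-12)

    def test_explaining_away_blocks_evidence(self):
        # sibling certainly ON: the full child evidence is explained away
        res = or_messages(ORFactorParams(2), [0.0, 50.0, 4.0], MAX_PRODUCT)
        assert res[0] == pytest.approx(0.0, abs=1e-12)



class TestPoolMessages:
    @pytest.mark.parametrize("M", [1, 2, 3, 5, 8])
    def test_matches_enumeration(self, M):
        rng = np.random.default_rng(M)
        for _ in range(10):
            inc = rng.normal(0, 2, M + 1)
            res = pool_messages(PoolFactorParams(M), inc)
            vecs = [np.array([0.0, s]) for s in inc]
            for t in range(M + 1):
                want = enumerate_factor_message(
                    pool_factor(M), (2,) * (M + 1), vecs, t, MAX_PRODUCT
                )
                assert np.allclose(
                    normalize([0.0, res[t]]), normalize(want), atol=1e-9
                )

    def test_single_member_identity_exact(self):
        to_a, to_b = pool_messages(PoolFactorParams(1), [0.7, -1.3])
        assert to_a == -1.3 and to_b == 0.7

    def test_sum_product_refused(self):
        with pytest.raises(ValueError, match="MAX_PRODUCT"):
            pool_messages_checked(PoolFactorParams(2), [0.0, 0.0, 0.0], 1.0)

    def test_mutual_exclusivity_under_clamp(self):
        """Clamping one member ON forces the siblings OFF in the decode."""
        variables = [VariableSpec(v) for v in ("a", "b1", "b2", "b3")]
        factors = [FactorSpec("f", "POOL", ("a", "b1", "b2", "b3"))]
        g = build_graph(variables, factors)
        apply_evidence(g, {"a": 0.0, "b1": 0.5, "b2": 0.5, "b3": 0.5})
        from rcnbp.factor_graph import clamp

        clamp(g, {"b1": 1})
        res = run(g, settings=BPSettings(temperature=MAX_PRODUCT, damping=0.5))
        dec = res.engine.decode_map()
        assert dec["b1"] == 1 and dec["b2"] == 0 and dec["b3"] == 0
        assert dec["a"] == 1


class TestEdgeAppearanceMessages:
    @pytest.mark.parametrize("T", TEMPERATURES)
    @pytest.mark.parametrize("N", [2, 3, 5, 6])
    def test_matches_enumeration(self, N, T):
        rng = np.random.default_rng(N * 7 + hash(str(T)) % 31)
        for _ in range(10):
            a, b = rng.normal(0, 2, (2, N))
            e = float(rng.normal(0, 2))
            c = float(rng.uniform(0.2, 3.0))
            to_a, to_b, to_e = edge_appearance_messages(
                EdgeAppearanceParams(N, c), a, b, e, T
            )
            vecs = [a, b, np.array([0.0, e])]
            for t, got in ((0, to_a), (1, to_b), (2, np.array([0.0, to_e]))):
                want = enumerate_factor_message(edge_factor(c), (N, N, 2), vecs, t, T)
                assert np.allclose(normalize(got), normalize(want), atol=1e-9)

    def test_configuration_count_all_zero(self):
        # N(N-1) discontinuous vs N continuous configurations
        _, _, to_e = edge_appearance_messages(
            EdgeAppearanceParams(4, 1.0), np.zeros(4), np.zeros(4), 0.0, 1.0
        )
        assert to_e == pytest.approx(np.log(3) - 1.0, abs=1e-12)

    @pytest.mark.parametrize("T", TEMPERATURES)
    def test_edge_absent_acts_as_equality(self, T):
        """With the contour certainly absent the factor copies the
        opposite side's message (pure continuity), at machine precision."""
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 2, (2, 5))
        to_a, to_b, _ = edge_appearance_messages(
            EdgeAppearanceParams(5, 1.0), a, b, -1e9, T
        )
        assert np.array_equal(to_a, b)
        assert np.array_equal(to_b, a)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        shift=st.floats(-4, 4),
        seed=st.integers(0, 10**6),
        T=st.sampled_from(TEMPERATURES),
    )
    def test_constant_shift_invariance(self, shift, seed, T):
        """Adding a constant to one incoming appearance message shifts
        every output by (at most) a constant: normalized messages are
        unchanged."""
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 2, (2, 4))
        e = float(rng.normal(0, 2))
        p = EdgeAppearanceParams(4, 1.0)
        to_a, to_b, to_e = edge_appearance_messages(p, a, b, e, T)
        sh_a, sh_b, sh_e = edge_appearance_messages(p, a + shift, b, e, T)
        assert np.allclose(normalize(sh_a), normalize(to_a), atol=1e-8)
        assert np.allclose(normalize(sh_b), normalize(to_b), atol=1e-8)
        # the scalar e-message is already normalized and shifts cancel
        assert sh_e == pytest.approx(to_e, abs=1e-8)

    def test_ab_exchange_symmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 2, (2, 4))
        e, c = 0.7, 1.3
        p = EdgeAppearanceParams(4, c)
        to_a, to_b, to_e = edge_appearance_messages(p, a, b, e, 0.5)
        sw_a, sw_b, sw_e = edge_appearance_messages(p, b, a, e, 0.5)
        assert np.allclose(to_a, sw_b, atol=1e-12)
        assert np.allclose(to_b, sw_a, atol=1e-12)
        assert to_e == pytest.approx(sw_e, abs=1e-12)


class TestChannel:
    def test_deterministic_channel_passes_llr(self):
        f = make_channel_factor(ChannelParams(1.0, 0.0), "ch", "s", "p")
        assert f.factor_kind == "CHANNEL"
        assert channel_llr(ChannelParams(1.0, 0.0), 2.5) == pytest.approx(2.5)

    def test_observed_on_gives_likelihood_ratio(self):
        # precision .9 / sensitivity .1, pixel certainly ON -> log 9
        assert channel_llr(ChannelParams(0.9, 0.1), 50.0) == pytest.approx(
            np.log(9.0), abs=1e-9
        )

    def test_unobserved_pixel_is_uninformative(self):
        for p, s in [(0.9, 0.1), (0.7, 0.2), (1.0, 0.0)]:
            assert channel_llr(ChannelParams(p, s), 0.0) == pytest.approx(
                0.0, abs=1e-12
            )
        # full composition: pixel evidence 0 -> message into source = 0
        g = build_graph(
            [VariableSpec("s"), VariableSpec("p")],
            [make_channel_factor(ChannelParams(0.9, 0.1), "ch", "s", "p")],
        )
        apply_evidence(g, {"p": 0.0})
        res = run(g, settings=BPSettings(temperature=1.0))
        assert res.beliefs.llr("s") == pytest.approx(0.0, abs=1e-12)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ChannelParams(0.5, 0.5)
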