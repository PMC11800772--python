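import numpy as np
import pytest

from rcnbp.factor_graph import FactorSpec, VariableSpec, build_graph
from rcnbp.rcn_model import (
    ModelConfig,
    build_template_model,
    cross_template,
    diamond_template,
    square_template,
)


def normalize(vec):
    """Module-boundary message normalization used when comparing against
    the enumeration oracle."""
    vec = np.asarray(vec, dtype=float)
    if len(vec) == 2:
        return vec - vec[0]
    return vec - vec.max()


def random_tree_graph(rng, n, cards=(2, 3, 4), unary_p=0.7):
    """Random tree-structured factor graph with mixed cardinalities."""
    variables = []
    total_states = 1
    for i in range(n):
        card = int(rng.choice(cards))
        if total_states * card > 2**18:  # keep enumeration affordable
            break
        total_states *= card
        variables.append(VariableSpec(f"v{i}", card))
    n = len(variables)
    factors = []
    for i in range(1, n):
        j = int(rng.integers(0, i))
        table = rng.normal(0, 1.5, (variables[j].cardinality, variables[i].cardinality))
        factors.append(
            FactorSpec(f"p{i}", "TABLE", (f"v{j}", f"v{i}"), {"log_potential": table})
        )
    for i in range(n):
        if rng.random() < unary_p:
            factors.append(
                FactorSpec(
                    f"u{i}",
                    "TABLE",
                    (f"v{i}",),
                    {"log_potential": rng.normal(0, 1, variables[i].cardinality)},
                )
            )
    return build_graph(variables, factors)


def random_loopy_graph(rng, n, extra_edges=1.3):
    """Random binary pairwise graph with ~extra_edges * n pair factors."""
    variables = [VariableSpec(f"v{i}", 2) for i in range(n)]
    factors = [
        FactorSpec(
            f"u{i}", "TABLE", (f"v{i}",), {"log_potential": rng.normal(0, 1, 2)}
        )
        for i in range(n)
    ]
    for k in range(int(extra_edges * n)):
        i, j = rng.choice(n, 2, replace=False)
        factors.append(
            FactorSpec(
                f"p{k}",
                "TABLE",
                (f"v{int(i)}", f"v{int(j)}"),
                {"log_potential": rng.normal(0, 1, (2, 2))},
            )
        )
    return build_graph(variables, factors)


@pytest.fixture(scope="session")
def contour_model():
    """Shared contour-only model (square + diamond + cross on 24x24)."""
    cfg = ModelConfig(include_surface=False)
    return build_template_model(
        [square_template(), diamond_template(), cross_template()], cfg
    )


@pytest.fixture(scope="session")
def contour_parser(contour_model):
    from rcnbp.schedule import SceneParser

    return SceneParser(contour_model)
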