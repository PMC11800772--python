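"""Closed-form message updates for the specialized factor families.

Three factor families carry the model's structure:

- OR: a binary output ``e`` is constrained to be the logical OR of M binary
  children; multi-parent interactions through shared children produce
  explaining away.
- POOL: a binary pooling variable ``a`` licenses exactly one of M mutually
  exclusive binary members, each with uniform probability 1/M (max-product
  only).
- EDGE_APPEARANCE: two categorical appearance variables ``a``, ``b`` on the
  two sides of a lattice edge and a binary contour variable ``e``; the
  absence of the contour forces appearance continuity, its presence forces
  a discontinuity at penalty ``c``.

Each update is an O(M) / O(N) reparameterization of the generic tempered
factor-to-variable update and is verified against brute-force enumeration
in the test suite.  Messages for binary variables are single scalars
(``m = m(1) - m(0)``); categorical messages are vectors.

The temperature argument is a real in (0, 1] or the token
:data:`MAX_PRODUCT`, which selects exact (max, +) algebra rather than a
small-temperature numeric limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .factor_graph import SENTINEL, FactorSpec

#: Token selecting exact (max, +) message algebra.
MAX_PRODUCT = "max_product"


def _check_temperature(T) -> None:
    if T == MAX_PRODUCT:
        return
    if not (0 < float(T) <= 1):
        raise ValueError(f"temperature must be in (0, 1] or MAX_PRODUCT, got {T!r}")


def _clip(x):
    return np.clip(x, -SENTINEL, SENTINEL)


def log_expm1(x: np.ndarray) -> np.ndarray:
    """log(exp(x) - 1), elementwise, stable for both small and large x.

    For x <= 0 the true value is -inf (or undefined); the sentinel is
    returned.  This is the stable evaluation of the g(x) = log(1 - e^-x)
    identity shifted by x: log(e^x - 1) = x + g(x).
    """
    scalar = np.isscalar(x) or np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.full_like(x, -SENTINEL)
    big = x > 30.0
    out[big] = x[big]
    mid = (x > 0) & ~big
    with np.errstate(divide="ignore"):
        out[mid] = np.log(np.expm1(x[mid]))
    return float(out[0]) if scalar else out


# -- parameter records ----------------------------------------------------


@dataclass(frozen=True)
class ORFactorParams:
    """M binary children (c1..cM) feeding a binary OR output e."""

    M: int

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("OR factor needs M >= 1 children")


@dataclass(frozen=True)
class PoolFactorParams:
    """Binary pooling variable a with M mutually exclusive members b1..bM."""

    M: int

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("POOL factor needs M >= 1 members")


@dataclass(frozen=True)
class EdgeAppearanceParams:
    """Shared appearance cardinality N and discontinuity penalty c > 0."""

    N: int
    c_penalty: float

    def __post_init__(self):
        if self.N < 2:
            raise ValueError("appearance cardinality must be >= 2")
        if not self.c_penalty > 0:
            raise ValueError("c_penalty must be > 0")


@dataclass(frozen=True)
class ChannelParams:
    """Leaf evidence channel: P(pixel ON | source ON) = precision,
    P(pixel ON | source OFF) = sensitivity."""

    precision: float
    sensitivity: float

    def __post_init__(self):
        if not (0 < self.precision <= 1):
            raise ValueError("precision must be in (0, 1]")
        if not (0 <= self.sensitivity < 1):
            raise ValueError("sensitivity must be in [0, 1)")
        if not self.precision > self.sensitivity:
            raise ValueError("need precision > sensitivity")


# -- OR factor ------------------------------------------------------------


def or_messages(params: ORFactorParams, incoming, T=1.0) -> list[float]:
    """All M+1 outgoing messages of an OR factor.

    ``incoming`` is the ordered sequence of scalar messages
    ``(m_{c1->f}, ..., m_{cM->f}, m_{e->f})``.  Returns messages in the
    same role order ``(to c1, ..., to cM, to e)``.

    For tempered sum-product the update uses the intermediates
    ``z_m = T softplus(m_{cm->f}/T)`` and
    ``h_m = S_m + T g(S_m/T)`` with ``S_m = sum_{j != m} z_j`` and
    ``g(x) = log(1 - e^-x)``; for MAX_PRODUCT it is exact (max, +)
    enumeration over the two output states, O(M) via prefix sums.
    """
    _check_temperature(T)
    incoming = np.asarray(incoming, dtype=float)
    M = params.M
    if incoming.shape != (M + 1,):
        raise ValueError(f"OR factor expects {M + 1} incoming messages")
    u = incoming[:M]
    e_in = incoming[M]

    if M == 1:
        # OR of one input is the identity; exact closed-form cancellation.
        return [float(e_in), float(u[0])]

    if T == MAX_PRODUCT:
        return _or_messages_maxprod(u, e_in)

    T = float(T)
    z = T * np.logaddexp(0.0, u / T)          # z_m >= 0
    S = float(np.sum(z))
    # message to e (scalar convention): sum z + T g(sum z / T) = T log(e^{S/T}-1)
    to_e = float(_clip(T * log_expm1(S / T)))

    S_minus = S - z
    # h_m = S_minus + T g(S_minus/T) = T * log_expm1(S_minus/T)
    h = T * log_expm1(S_minus / T)
    a = h / T
    b = e_in / T
    # m_{f->cm} = T [ logaddexp(0, -a) - logaddexp(0, -a - b) ]
    to_c = T * (np.logaddexp(0.0, -a) - np.logaddexp(0.0, -a - b))
    return [float(v) for v in _clip(to_c)] + [float(to_e)]


def _or_messages_maxprod(u: np.ndarray, e_in: float) -> list[float]:
    M = len(u)
    pos = np.maximum(u, 0.0)
    P = float(np.sum(pos))
    n_pos = int(np.sum(u > 0))
    # leave-one-out maxima of u via top-2
    order = np.argsort(u)
    i_max, i_2nd = order[-1], order[-2]
    to_c = np.empty(M)
    for m in range(M):
        P_m = P - pos[m]
        n_pos_m = n_pos - (1 if u[m] > 0 else 0)
        if n_pos_m > 0:
            Q_m = P_m
        else:
            Q_m = u[i_2nd] if m == i_max else u[i_max]
        m1 = e_in + P_m                      # cm = 1 forces e = 1
        m0 = max(0.0, e_in + Q_m)            # cm = 0: all-off or sibling on
        to_c[m] = m1 - m0
    best_on = P if n_pos > 0 else float(u[i_max])
    to_e = best_on                            # minus the all-off score 0
    return [float(v) for v in _clip(to_c)] + [float(_clip(to_e))]


# -- POOL factor ----------------------------------------------------------


def pool_messages(params: PoolFactorParams, incoming) -> list[float]:
    """All M+1 outgoing messages of a POOL factor (max-product only).

    ``incoming`` is ``(m_{a->f}, m_{b1->f}, ..., m_{bM->f})``; the return
    order is ``(to a, to b1, ..., to bM)``.  Closed forms:

    - ``m_{f->a}  = max_m m_{bm->f} - log M``
    - ``m_{f->bm} = min[m_{a->f} - log M, -max_{j != m} m_{bj->f}]``

    Sum-product updates are not provided; expand the factor to a TABLE if a
    tempered marginalization over a POOL is required.
    """
    incoming = np.asarray(incoming, dtype=float)
    M = params.M
    if incoming.shape != (M + 1,):
        raise ValueError(f"POOL factor expects {M + 1} incoming messages")
    v = incoming[0]
    u = incoming[1:]
    logM = float(np.log(M))

    to_a = float(np.max(u)) - logM
    if M == 1:
        return [float(_clip(to_a)), float(_clip(v - logM))]

    order = np.argsort(u)
    i_max, i_2nd = order[-1], order[-2]
    to_b = np.empty(M)
    for m in range(M):
        loo = u[i_2nd] if m == i_max else u[i_max]
        to_b[m] = min(v - logM, -loo)
    return [float(_clip(to_a))] + [float(x) for x in _clip(to_b)]


def pool_messages_checked(params: PoolFactorParams, incoming, T) -> list[float]:
    if T != MAX_PRODUCT:
        raise ValueError(
            "POOL factors support MAX_PRODUCT only; expand to a TABLE factor "
            "for tempered sum-product"
        )
    return pool_messages(params, incoming)


# -- edge-appearance factor -----------------------------------------------


def edge_appearance_messages(
    params: EdgeAppearanceParams, a_in, b_in, e_in: float, T=1.0
):
    """Messages of the contour-surface factor, O(N) per update.

    ``a_in``/``b_in`` are length-N log-message vectors from the two
    appearance variables, ``e_in`` the scalar message from the contour
    variable.  Returns ``(to_a, to_b, to_e)`` with vectors for a and b and
    a scalar for e.

    Tempered sum-product uses the intermediates

    - ``s_a = T lse(a/T)``, ``s_b = T lse(b/T)``, ``s_d = T lse((a+b)/T)``

    giving ``m_{f->a}(i) = b_i + T log[1 + e^{(m_e - c)/T}(e^{(s_b-b_i)/T}-1)]``
    (and symmetrically for b) and
    ``m_{f->e} = T log[e^{(s_a+s_b-s_d)/T} - 1] - c`` in the binary scalar
    convention.  MAX_PRODUCT uses the (max, +) analogues with leave-one-out
    maxima from the top-2 entries.
    """
    _check_temperature(T)
    a_in = np.asarray(a_in, dtype=float)
    b_in = np.asarray(b_in, dtype=float)
    N, c = params.N, float(params.c_penalty)
    if a_in.shape != (N,) or b_in.shape != (N,):
        raise ValueError(f"appearance messages must have length {N}")

    if T == MAX_PRODUCT:
        return _edge_appearance_maxprod(a_in, b_in, float(e_in), c)

    T = float(T)
    sa = T * _lse(a_in / T)
    sb = T * _lse(b_in / T)
    sd = T * _lse((a_in + b_in) / T)
    w = (float(e_in) - c) / T
    # log[1 + e^w (e^d - 1)] = logaddexp(0, w + log_expm1(d)), d >= 0
    to_a = b_in + T * np.logaddexp(0.0, w + log_expm1((sb - b_in) / T))
    to_b = a_in + T * np.logaddexp(0.0, w + log_expm1((sa - a_in) / T))
    to_e = T * log_expm1((sa + sb - sd) / T) - c
    return _clip(to_a), _clip(to_b), float(_clip(to_e))


def _edge_appearance_maxprod(a_in, b_in, e_in, c):
    N = len(a_in)
    def loo_max(x):
        order = np.argsort(x)
        i_max, i_2nd = order[-1], order[-2]
        out = np.full(N, x[i_max])
        out[i_max] = x[i_2nd]
        return out

    loo_b = loo_max(b_in)
    loo_a = loo_max(a_in)
    to_a = np.maximum(b_in, e_in - c + loo_b)
    to_b = np.maximum(a_in, e_in - c + loo_a)
    sd = float(np.max(a_in + b_in))
    best_mismatch = float(np.max(a_in + loo_b))
    to_e = best_mismatch - c - sd
    return _clip(to_a), _clip(to_b), float(_clip(to_e))


def _lse(x: np.ndarray) -> float:
    m = float(np.max(x))
    return m + float(np.log(np.sum(np.exp(x - m))))


# -- evidence channel -----------------------------------------------------


def make_channel_factor(
    params: ChannelParams, factor_id: str, source_id: str, pixel_id: str
) -> FactorSpec:
    """Build the 2x2 conditional table factor ``log P(pixel | source)``.

    Rows index the source state (OFF, ON), columns the pixel state.
    Composed with a hard OR over parent features this realizes the
    Noisy-OR leaf: the precision parameter sets how likely the pixel is ON
    given the source is ON, the sensitivity how likely it is ON by noise
    when the source is OFF.  precision=1, sensitivity=0 is a deterministic
    (equality) channel.
    """
    p, s = params.precision, params.sensitivity

    def safe_log(x):
        return float(np.log(x)) if x > 0 else -SENTINEL

    table = np.array(
        [
            [safe_log(1 - s), safe_log(s)],
            [safe_log(1 - p), safe_log(p)],
        ]
    )
    return FactorSpec(
        factor_id,
        "CHANNEL",
        (source_id, pixel_id),
        {
            "precision": p,
            "sensitivity": s,
            "log_potential": table,
        },
    )


def channel_llr(params: ChannelParams, pixel_llr: float, T=1.0) -> float:
    """Scalar message into the source when the pixel carries evidence
    ``pixel_llr`` and no other factor touches the pixel.

    This is the one-step collapse of pixel -> CHANNEL -> source and is used
    to inject stimulus evidence efficiently.
    """
    p, s = params.precision, params.sensitivity
    tbl = np.array(
        [[np.log(max(1 - s, 1e-300)), np.log(max(s, 1e-300))],
         [np.log(max(1 - p, 1e-300)), np.log(max(p, 1e-300))]]
    )
    m_pix = np.array([0.0, float(pixel_llr)])
    if T == MAX_PRODUCT:
        vals = tbl + m_pix
        out = vals.max(axis=1)
    else:
        T = float(T)
        out = T * np.array([_lse((tbl[i] + m_pix) / T) for i in range(2)])
    return float(_clip(out[1] - out[0]))


# -- dense tables (shared with the enumeration oracle) --------------------


def dense_log_potential(factor: FactorSpec, cards: tuple[int, ...]) -> np.ndarray:
    """Materialize any factor kind as a dense log-potential array.

    -inf entries are represented by the negative sentinel.  This is the
    single authoritative definition of each factor's semantics; both the
    enumeration oracle and the generic TABLE update consume it.
    """
    kind = factor.factor_kind
    if kind in ("TABLE", "CHANNEL"):
        table = np.asarray(factor.params["log_potential"], dtype=float)
        return np.where(np.isneginf(table), -SENTINEL, table)
    if kind == "OR":
        M = factor.arity - 1
        table = np.full((2,) * (M + 1), -SENTINEL)
        for idx in np.ndindex(*(2,) * M):
            e = 1 if any(idx) else 0
            table[idx + (e,)] = 0.0
        return table
    if kind == "POOL":
        M = factor.arity - 1
        table = np.full((2,) * (M + 1), -SENTINEL)
        table[(0,) + (0,) * M] = 0.0
        for m in range(M):
            idx = [0] * M
            idx[m] = 1
            table[(1,) + tuple(idx)] = -np.log(M)
        return table
    if kind == "EDGE_APPEARANCE":
        N = cards[0]
        c = float(factor.params["c_penalty"])
        table = np.full((N, N, 2), -SENTINEL)
        for i in range(N):
            table[i, i, 0] = 0.0
            for j in range(N):
                if i != j:
                    table[i, j, 1] = -c
        return table
    raise ValueError(f"unknown factor kind {kind!r}")
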