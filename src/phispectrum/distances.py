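"""Earth Mover's Distance on the Hamming metric, and its extension to
cause-effect structures.

The repertoire-level EMD is the minimum-cost transport between two
distributions over joint binary states, with ground distance the Hamming
distance between state codes.  The constellation-level ("extended") EMD moves
phi^Max mass between concepts, with ground distance the summed cause+effect
EMD between concepts; surplus mass is transported to the null concept of the
concept's own subsystem.

All transport problems are solved exactly as integer minimum-cost flows
(rational mode: common-denominator scaling; float mode: 1e-9 quantization of
mass, 1e-6 quantization of ground costs, matching the engine's 6-decimal
comparison precision).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Tuple

import networkx as nx

from ._num import common_denominator, quantize
from .errors import StateError

__all__ = ["emd", "emd_plan", "TransportPlan", "hamming", "transport_cost",
           "concept_distance", "emd_call_count", "reset_emd_call_count"]

#: diagnostic counter of elementary repertoire-level EMD evaluations
_EMD_CALLS = 0

_MASS_SCALE = 10 ** 9
_COST_SCALE = 10 ** 9


def emd_call_count() -> int:
    return _EMD_CALLS


def reset_emd_call_count():
    global _EMD_CALLS
    _EMD_CALLS = 0


def hamming(a: int, b: int) -> int:
    return (a ^ b).bit_count()


def _min_cost_transport_int(supply, demand, cost):
    """Exact min-cost transport with integer masses and integer arc costs."""
    total_s = sum(supply)
    total_d = sum(demand)
    if total_s != total_d:
        raise StateError(f"unbalanced transport problem ({total_s} vs {total_d})")
    if total_s == 0:
        return 0
    si = [i for i, s in enumerate(supply) if s]
    di = [j for j, d in enumerate(demand) if d]
    # closed forms for the ubiquitous tiny cases
    if len(si) == 1:
        i = si[0]
        return sum(demand[j] * cost[i][j] for j in di)
    if len(di) == 1:
        j = di[0]
        return sum(supply[i] * cost[i][j] for i in si)
    if len(si) == 2 and len(di) == 2:
        (a, b), (u, v) = si, di
        # one degree of freedom: flow x on arc a->u; cost is linear in x
        lo = max(0, supply[a] - demand[v])
        hi = min(supply[a], demand[u])
        slope = cost[a][u] - cost[a][v] - cost[b][u] + cost[b][v]
        x = lo if slope > 0 else hi
        return (cost[a][u] * x + cost[a][v] * (supply[a] - x)
                + cost[b][u] * (demand[u] - x)
                + cost[b][v] * (supply[b] - demand[u] + x))
    G = nx.DiGraph()
    for i, s in enumerate(supply):
        if s:
            G.add_node(("s", i), demand=-s)
    for j, d in enumerate(demand):
        if d:
            G.add_node(("d", j), demand=d)
    for i, s in enumerate(supply):
        if not s:
            continue
        for j, d in enumerate(demand):
            if not d:
                continue
            G.add_edge(("s", i), ("d", j), weight=cost[i][j])
    return nx.min_cost_flow_cost(G)


def transport_cost(supply, demand, cost, exact: bool):
    """Minimum transport cost between two equal-mass non-negative vectors.

    ``cost[i][j]`` is the ground distance; entries may be ints, Fractions or
    floats.  Exact mode requires Fraction/int inputs.
    """
    if exact:
        dm = common_denominator(list(supply) + list(demand))
        sup = [int(Fraction(x) * dm) for x in supply]
        dem = [int(Fraction(x) * dm) for x in demand]
        dc = common_denominator([c for row in cost for c in row])
        ic = [[int(Fraction(c) * dc) for c in row] for row in cost]
        return Fraction(_min_cost_transport_int(sup, dem, ic), dm * dc)
    sup = quantize(supply, _MASS_SCALE)
    dem = quantize(demand, _MASS_SCALE)
    ic = [[int(round(float(c) * _COST_SCALE)) for c in row] for row in cost]
    return _min_cost_transport_int(sup, dem, ic) / (_MASS_SCALE * _COST_SCALE)


def emd(p, q, exact: bool = None):
    """Exact EMD between two distributions over the same binary state space."""
    global _EMD_CALLS
    _EMD_CALLS += 1
    if len(p) != len(q):
        raise StateError(f"mismatched supports ({len(p)} vs {len(q)} states)")
    n_states = len(p)
    if n_states & (n_states - 1):
        raise StateError("support size must be a power of two (joint binary states)")
    if exact is None:
        exact = isinstance(p[0], (Fraction, int)) and isinstance(q[0], (Fraction, int))
    tol = 0 if exact else 1e-6
    if abs(float(sum(p)) - 1.0) > tol or abs(float(sum(q)) - 1.0) > tol:
        raise StateError("EMD inputs must be normalized distributions")
    if tuple(p) == tuple(q):
        return Fraction(0) if exact else 0.0
    if n_states == 2:  # single node: cost is |p1 - q1|
        d = p[1] - q[1]
        return abs(d)
    # net supplies only: transport surplus to deficit
    diff = [pi - qi for pi, qi in zip(p, q)]
    surplus_idx = [i for i, d in enumerate(diff) if d > 0]
    deficit_idx = [i for i, d in enumerate(diff) if d < 0]
    if not surplus_idx:
        return Fraction(0) if exact else 0.0
    supply = [diff[i] for i in surplus_idx]
    demand = [-diff[j] for j in deficit_idx]
    cost = [[hamming(i, j) for j in deficit_idx] for i in surplus_idx]
    return transport_cost(supply, demand, cost, exact)


@dataclass(frozen=True)
class TransportPlan:
    """An optimal flow between two distributions (debugging aid).

    ``flows[(i, j)]`` is the mass moved from state ``i`` to state ``j``;
    marginals match the source/target distributions and
    ``cost == sum(flow * hamming)``.
    """

    source: tuple
    target: tuple
    flows: Dict[Tuple[int, int], object]
    cost: object


def emd_plan(p, q, exact: bool = None) -> TransportPlan:
    """Like :func:`emd` but also returns one optimal transport plan."""
    if exact is None:
        exact = isinstance(p[0], (Fraction, int)) and isinstance(q[0], (Fraction, int))
    diff = [pi - qi for pi, qi in zip(p, q)]
    surplus = {i: d for i, d in enumerate(diff) if d > 0}
    deficit = {j: -d for j, d in enumerate(diff) if d < 0}
    flows = {(i, i): min(pi, qi) for i, (pi, qi) in enumerate(zip(p, q)) if min(pi, qi) > 0}
    if not surplus:
        return TransportPlan(tuple(p), tuple(q), flows, Fraction(0) if exact else 0.0)
    if exact:
        dm = common_denominator(list(surplus.values()) + list(deficit.values()))
        scale = dm
    else:
        scale = 10 ** 9
    G = nx.DiGraph()
    for i, s in surplus.items():
        G.add_node(("s", i), demand=-int(round(float(s) * scale)) if not exact
                   else -int(Fraction(s) * scale))
    for j, d in deficit.items():
        G.add_node(("d", j), demand=int(round(float(d) * scale)) if not exact
                   else int(Fraction(d) * scale))
    drift = -sum(G.nodes[n]["demand"] for n in G.nodes)
    if drift:  # float quantization imbalance absorbed by largest deficit
        jmax = max(deficit, key=deficit.get)
        G.nodes[("d", jmax)]["demand"] += drift
    for i in surplus:
        for j in deficit:
            G.add_edge(("s", i), ("d", j), weight=hamming(i, j))
    flow = nx.min_cost_flow(G)
    cost = 0
    for (_, i), targets in flow.items():
        for (_, j), f in targets.items():
            if f:
                amt = Fraction(f, scale) if exact else f / scale
                flows[(i, j)] = flows.get((i, j), 0) + amt
                cost += amt * hamming(i, j)
    return TransportPlan(tuple(p), tuple(q), flows, cost)


# ---------------------------------------------------------------------------
# concept-level distances
# ---------------------------------------------------------------------------


def concept_distance(c1, c2):
    """Sum of cause-side and effect-side EMDs between two concepts.

    Each side is expanded over the union of the two concepts' purviews,
    with missing elements filled from each concept's own subsystem's
    unconstrained repertoire (uniform on the cause side, the noised gate
    bias on the effect side).
    """
    from .repertoires import FUTURE, PAST
    exact = c1.subsystem.exact
    cp = tuple(sorted(set(c1.cause.purview) | set(c2.cause.purview)))
    ep = tuple(sorted(set(c1.effect.purview) | set(c2.effect.purview)))
    d = emd(c1.expanded(PAST, cp), c2.expanded(PAST, cp), exact) + \
        emd(c1.expanded(FUTURE, ep), c2.expanded(FUTURE, ep), exact)
    return d if exact else float(d)
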