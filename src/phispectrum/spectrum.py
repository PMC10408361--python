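"""System-level integrated information: cuts, constellations, the extended
EMD between constellations, and the spectrum of valid Phi^MIP values.

The spectrum enumeration forks the computation at every degenerate core
cause/effect: each concept-bearing mechanism contributes its full set of
concept variants, constellations are the Cartesian product of one variant per
mechanism, and every (original constellation, cut constellation) pair yields
a candidate Phi value for that cut.  The set of *valid* Phi^MIP values is
then derived from the per-cut value sets: the lower bound is the global
minimum over cuts, the upper bound is the smallest per-cut maximum among the
cuts attaining that minimum, and every observed value inside the interval is
valid (it is the minimum of some selection of per-cut values).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Dict, List, Optional, Tuple

from ._num import num_eq, phi_round
from .concepts import Concept, concept_variants, null_concept, powerset_purviews
from .distances import emd, transport_cost
from .errors import CombinatorialGuardError, StateError
from .subsystem import Cut, Subsystem

__all__ = ["Constellation", "PhiSpectrum", "unidirectional_cuts",
           "enumerate_constellations", "ces_distance", "phi_spectrum",
           "phi_mip_set", "phi_max_over_subsystems", "DEFAULT_CAP"]

DEFAULT_CAP = 10 ** 6


@dataclass(frozen=True)
class Constellation:
    """One cause-effect structure: at most one concept variant per mechanism."""

    concepts: Tuple[Concept, ...]
    subsystem: Subsystem

    def key(self):
        return tuple(c.key() for c in self.concepts)

    @property
    def provenance(self):
        """Which (cause purview, effect purview) variant was chosen per mechanism."""
        return {c.mechanism: (c.cause.purview, c.effect.purview) for c in self.concepts}


def unidirectional_cuts(sub: Subsystem) -> List[Cut]:
    """All 2*S(n,2) unidirectional bipartition cuts of the subsystem."""
    if sub.k < 2:
        raise StateError("cuts require a subsystem of at least two nodes")
    cuts = []
    for mask in range(1, (1 << sub.k) - 1):
        src = tuple(sub.nodes[p] for p in range(sub.k) if (mask >> p) & 1)
        tgt = tuple(sub.nodes[p] for p in range(sub.k) if not (mask >> p) & 1)
        cuts.append(Cut(src, tgt))
    return cuts


def enumerate_constellations(sub: Subsystem, strategy=None,
                             cap: int = DEFAULT_CAP) -> List[Constellation]:
    """All non-unique constellations of a subsystem (duplicates collapsed).

    ``strategy`` optionally filters each mechanism's variants before the
    product is taken (see :mod:`phispectrum.resolutions`).
    """
    per_mech = []
    for mech in powerset_purviews(sub):
        variants = concept_variants(sub, mech)
        if strategy is not None:
            variants = strategy(variants)
        if variants:
            per_mech.append(variants)
    count = 1
    for v in per_mech:
        count *= len(v)
        if count > cap:
            raise CombinatorialGuardError(
                f"constellation count exceeds cap ({count} > {cap})")
    seen = set()
    out = []
    for combo in product(*per_mech):
        ces = Constellation(tuple(combo), sub)
        k = ces.key()
        if k not in seen:
            seen.add(k)
            out.append(ces)
    return out


# ---------------------------------------------------------------------------
# extended EMD between constellations
# ---------------------------------------------------------------------------


class _DistanceCache:
    """Memoizes concept-pair distances and constellation-pair distances."""

    def __init__(self, exact: bool):
        self.exact = exact
        self.concept_pair: Dict[tuple, object] = {}
        self.to_null: Dict[tuple, object] = {}
        self.ces_pair: Dict[tuple, object] = {}

    def concept_distance(self, c1: Concept, c2: Concept):
        # Repertoires are expanded over the union of the two purviews (not
        # the whole subsystem), each filled from its own subsystem's
        # unconstrained repertoire -- the reference-implementation contract.
        key = (c1.key(), c2.key())
        if key not in self.concept_pair:
            cp = tuple(sorted(set(c1.cause.purview) | set(c2.cause.purview)))
            ep = tuple(sorted(set(c1.effect.purview) | set(c2.effect.purview)))
            from .repertoires import FUTURE, PAST
            d = emd(c1.expanded(PAST, cp), c2.expanded(PAST, cp), self.exact) + \
                emd(c1.expanded(FUTURE, ep), c2.expanded(FUTURE, ep), self.exact)
            self.concept_pair[key] = d
            self.concept_pair[(key[1], key[0])] = d
        return self.concept_pair[key]

    def null_distance(self, c: Concept, null: Concept):
        key = c.key()
        if key not in self.to_null:
            self.to_null[key] = self.concept_distance(c, null)
        return self.to_null[key]


def ces_distance(C1: Constellation, C2: Constellation,
                 cache: Optional[_DistanceCache] = None,
                 null1: Optional[Concept] = None,
                 null2: Optional[Concept] = None):
    """Extended EMD between two constellations of the same subsystem.

    Concepts present (EMD-identically) in both constellations cost nothing
    and are removed.  If the remaining difference is only disappearing
    concepts, each moves its phi mass to the null concept of its own
    (sub)system; otherwise a transportation problem is solved between the two
    remainders, with the null concept absorbing the surplus phi mass.
    """
    exact = C1.subsystem.exact
    if cache is None:
        cache = _DistanceCache(exact)
    if null1 is None:
        null1 = null_concept(C1.subsystem)
    if null2 is None:
        null2 = null_concept(C2.subsystem)

    matched2 = set()
    only1 = []
    for c1 in C1.concepts:
        m = c1.match_key()
        hit = next((i for i, c2 in enumerate(C2.concepts)
                    if i not in matched2 and c2.match_key() == m), None)
        if hit is None:
            only1.append(c1)
        else:
            matched2.add(hit)
    only2 = [c2 for i, c2 in enumerate(C2.concepts) if i not in matched2]

    key = (tuple(c.key() for c in only1), tuple(c.key() for c in only2))
    if key in cache.ces_pair:
        return cache.ces_pair[key]

    if not only2:
        total = sum((c.phi * cache.null_distance(c, null1) for c in only1),
                    0 if exact else 0.0)
        result = phi_round(total, exact)
    elif not only1:
        total = sum((c.phi * cache.null_distance(c, null2) for c in only2),
                    0 if exact else 0.0)
        result = phi_round(total, exact)
    else:
        supply = [c.phi for c in only1]
        demand = [c.phi for c in only2]
        residual = sum(supply) - sum(demand)
        # null node on the deficient side absorbs/provides the residual mass
        supply = supply + [(-residual) if residual < 0 else (0 if exact else 0.0)]
        demand = demand + [residual if residual > 0 else (0 if exact else 0.0)]
        cost = []
        for c1 in only1:
            row = [cache.concept_distance(c1, c2) for c2 in only2]
            row.append(cache.null_distance(c1, null1))
            cost.append(row)
        null_row = [cache.null_distance(c2, null2) for c2 in only2]
        null_row.append(0 if exact else 0.0)
        cost.append(null_row)
        result = phi_round(transport_cost(supply, demand, cost, exact), exact)
    cache.ces_pair[key] = result
    return result


# ---------------------------------------------------------------------------
# the spectrum
# ---------------------------------------------------------------------------


@dataclass
class PhiSpectrum:
    """Per-cut Phi value sets and the derived set of valid Phi^MIP values."""

    subsystem: Subsystem
    cuts: List[Cut]
    values_per_cut: List[tuple]
    n_constellations: int
    n_constellations_per_cut: List[int]
    empty_original: bool = False

    @property
    def valid_phi_mip(self):
        return phi_mip_set(self.values_per_cut, exact=self.subsystem.exact)

    def to_json(self):
        return {"nodes": list(self.subsystem.nodes),
                "state": "".join(map(str, self.subsystem.state)),
                "cuts": [str(c) for c in self.cuts],
                "values_per_cut": [[float(v) for v in vs] for vs in self.values_per_cut],
                "n_constellations": self.n_constellations,
                "n_constellations_per_cut": list(self.n_constellations_per_cut),
                "valid_phi_mip": [float(v) for v in self.valid_phi_mip],
                "empty_original": self.empty_original}


def _unique_sorted(values, exact):
    out = []
    for v in sorted(values):
        if not out or not num_eq(v, out[-1], exact):
            out.append(v)
    return tuple(out)


def phi_spectrum(sub: Subsystem, strategy=None, cap: int = DEFAULT_CAP) -> PhiSpectrum:
    """Every valid Phi value per unidirectional cut, all variants carried."""
    exact = sub.exact
    originals = enumerate_constellations(sub, strategy, cap)
    cache = _DistanceCache(exact)
    null1 = null_concept(sub)
    cuts = unidirectional_cuts(sub)
    values_per_cut = []
    n_per_cut = []
    for cut in cuts:
        cut_sub = sub.apply_cut(cut)
        cut_cess = enumerate_constellations(cut_sub, strategy, cap)
        null2 = null_concept(cut_sub)
        vals = set()
        for orig in originals:
            for new in cut_cess:
                vals.add(ces_distance(orig, new, cache, null1, null2))
        values_per_cut.append(_unique_sorted(vals, exact))
        n_per_cut.append(len(cut_cess))
    empty = all(not c.concepts for c in originals)
    return PhiSpectrum(sub, cuts, values_per_cut, len(originals), n_per_cut,
                       empty_original=empty)


def phi_mip_set(values_per_cut, *, exact: bool = False, strict: bool = False):
    """Valid Phi^MIP values from per-cut value sets.

    The default follows the published selection rule literally: the upper
    bound starts from the first cut's maximum and is lowered by the maxima of
    the cuts attaining the global minimum.  ``strict=True`` instead uses
    exactly the minimum of the candidate-MIP cuts' maxima.
    """
    if not values_per_cut or any(not v for v in values_per_cut):
        raise StateError("empty spectrum")
    mins = [min(v) for v in values_per_cut]
    phi_min = min(mins)
    possible = [v for v, m in zip(values_per_cut, mins) if num_eq(m, phi_min, exact)]
    if strict:
        phi_max = min(max(v) for v in possible)
    else:
        phi_max = max(values_per_cut[0])
        for v in possible:
            if max(v) < phi_max:
                phi_max = max(v)
    valid = [phi for vs in values_per_cut for phi in vs
             if (phi >= phi_min or num_eq(phi, phi_min, exact))
             and (phi <= phi_max or num_eq(phi, phi_max, exact))]
    return _unique_sorted(valid, exact)


def phi_max_over_subsystems(network, state, *, guard: int = 4,
                            strategy=None, cap: int = DEFAULT_CAP):
    """Valid Phi^MIP sets for every subsystem in the powerset of nodes.

    Single-node subsystems admit no cut and contribute Phi = 0.  Returns
    ``(best_nodes, best_set, per_subsystem)`` where the best subsystem
    maximizes the largest member of its valid set.
    """
    if network.n > guard:
        raise CombinatorialGuardError(
            f"subsystem sweep guarded at n <= {guard} (network has {network.n})")
    zero = 0 if network.exact else 0.0
    per_subsystem = {}
    for mask in range(1, 1 << network.n):
        nodes = tuple(i for i in range(network.n) if (mask >> i) & 1)
        if len(nodes) < 2:
            per_subsystem[nodes] = (zero,)
            continue
        sub = Subsystem(network, state, nodes)
        per_subsystem[nodes] = phi_spectrum(sub, strategy, cap).valid_phi_mip
    best = max(per_subsystem, key=lambda k: max(per_subsystem[k]))
    return best, per_subsystem[best], per_subsystem
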