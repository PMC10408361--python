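"""Mechanism-level integrated information: phi^MIP, tied core causes/effects,
and concept variants.

For a mechanism ``m`` and purview ``z``, ``phi^MIP(m, z)`` is the EMD between
the unpartitioned repertoire and the closest repertoire obtainable from a
bipartition of ``(m, z)``.  The *core* cause (effect) of a mechanism is the
purview maximizing ``phi^MIP`` over the non-empty powerset of subsystem
nodes; when several purviews attain the maximum the core is degenerate, and
every tied alternative is retained.  A mechanism with
``phi^Max = min(phi_cause^Max, phi_effect^Max) > 0`` yields one concept
*variant* per (tied cause, tied effect) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Tuple

from ._num import dist_key, num_eq, phi_round
from .distances import emd
from .errors import StateError
from .repertoires import (FUTURE, PAST, MechanismPartition, Repertoire,
                          cause_repertoire, effect_repertoire, expand_dist,
                          partitioned_repertoire, unconstrained_repertoire)
from .subsystem import Subsystem

__all__ = ["PurviewResult", "Concept", "enumerate_partitions", "phi_mip",
           "core_candidates", "concept_variants", "null_concept",
           "powerset_purviews"]


def _subsets(items):
    for r in range(len(items) + 1):
        yield from combinations(items, r)


def powerset_purviews(sub: Subsystem):
    """Non-empty subsets of subsystem positions, in (size, lexicographic) order."""
    return [s for s in _subsets(sub.positions) if s]


def enumerate_partitions(mechanism, purview) -> List[MechanismPartition]:
    """All bipartitions of (mechanism, purview) into two (mech, purview) parts.

    Empty parts are allowed on either side of a part, the trivial partition
    (everything vs nothing) is excluded, and the unordered pair is emitted
    once, in a deterministic order.
    """
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    if not purview:
        raise StateError("purview must be non-empty")
    seen = set()
    out = []
    for m1 in _subsets(mechanism):
        m2 = tuple(x for x in mechanism if x not in m1)
        for z1 in _subsets(purview):
            z2 = tuple(x for x in purview if x not in z1)
            if (not m1 and not z1) or (not m2 and not z2):
                continue
            key = frozenset(((m1, z1), (m2, z2)))
            if key in seen:
                continue
            seen.add(key)
            out.append(MechanismPartition((m1, z1), (m2, z2)))
    return out


@dataclass(frozen=True)
class PurviewResult:
    """phi^MIP of one mechanism/purview pair, with all minimizing partitions."""

    purview: Tuple[int, ...]
    direction: str
    phi: object
    mips: tuple
    repertoire: Repertoire


def phi_mip(sub: Subsystem, mechanism, purview, direction) -> PurviewResult:
    """Minimum-information-partition phi for one mechanism/purview pair."""
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    rep = (cause_repertoire if direction == PAST else effect_repertoire)(
        sub, mechanism, purview)
    best = None
    mips = []
    for part in enumerate_partitions(mechanism, purview):
        pr = partitioned_repertoire(sub, part, direction)
        d = emd(rep.dist, pr.dist, sub.exact)
        if best is None or d < best:
            best, mips = d, [part]
        elif num_eq(d, best, sub.exact):
            mips.append(part)
    return PurviewResult(purview, direction, best, tuple(mips), rep)


def core_candidates(sub: Subsystem, mechanism, direction):
    """All purviews attaining the maximal phi^MIP for a mechanism.

    Returns ``(phi_max, [PurviewResult, ...])`` with the tied purview results
    in canonical (size, lexicographic) order.
    """
    mechanism = tuple(sorted(mechanism))
    if not mechanism:
        raise StateError("mechanism must be non-empty")
    best = None
    tied = []
    for purview in powerset_purviews(sub):
        res = phi_mip(sub, mechanism, purview, direction)
        if best is None or (res.phi > best and not num_eq(res.phi, best, sub.exact)):
            best, tied = res.phi, [res]
        elif num_eq(res.phi, best, sub.exact):
            tied.append(res)
    return best, tied


class Concept:
    """A mechanism's (phi^Max, core cause, core effect) tuple -- one variant.

    ``tied_causes``/``tied_effects`` carry the full degenerate sets the
    variant was drawn from.
    """

    __slots__ = ("subsystem", "mechanism", "phi", "cause", "effect",
                 "tied_causes", "tied_effects", "_expansions", "_key")

    def __init__(self, subsystem, mechanism, phi, cause, effect,
                 tied_causes=(), tied_effects=()):
        self.subsystem = subsystem
        self.mechanism = tuple(sorted(mechanism))
        self.phi = phi
        self.cause = cause
        self.effect = effect
        self.tied_causes = tuple(tied_causes)
        self.tied_effects = tuple(tied_effects)
        self._expansions = {}
        self._key = None

    def expanded(self, direction, target=None):
        """A repertoire expanded over ``target`` (default: full subsystem).

        Missing elements are filled with this concept's own subsystem's
        unconstrained repertoire (uniform for causes, gate bias for effects).
        """
        if target is None:
            target = self.subsystem.positions
        target = tuple(sorted(target))
        key = (direction, target)
        if key not in self._expansions:
            pr = self.cause if direction == PAST else self.effect
            self._expansions[key] = expand_dist(
                self.subsystem, pr.repertoire.dist, pr.purview, target, direction)
        return self._expansions[key]

    @property
    def expanded_cause(self):
        """Cause repertoire expanded over the full subsystem (uniform fill)."""
        return self.expanded(PAST)

    @property
    def expanded_effect(self):
        """Effect repertoire expanded over the full subsystem (unconstrained fill)."""
        return self.expanded(FUTURE)

    def match_key(self):
        """Key for EMD-equality: mechanism, phi and raw repertoires."""
        exact = self.subsystem.exact
        return (self.mechanism, phi_round(self.phi, exact),
                self.cause.purview, dist_key(self.cause.repertoire.dist, exact),
                self.effect.purview, dist_key(self.effect.repertoire.dist, exact))

    def key(self):
        """Identity key including the expansion context (for caching/dedup)."""
        if self._key is None:
            exact = self.subsystem.exact
            cut = self.subsystem.cut
            ctx = (cut.severed_from, cut.severed_to) if cut is not None else None
            self._key = (ctx, self.mechanism, phi_round(self.phi, exact),
                         self.cause.purview, dist_key(self.cause.repertoire.dist, exact),
                         self.effect.purview, dist_key(self.effect.repertoire.dist, exact))
        return self._key

    def to_json(self):
        return {"mechanism": list(self.mechanism),
                "phi": float(self.phi),
                "cause": {"purview": list(self.cause.purview),
                          "dist": [float(p) for p in self.cause.repertoire.dist]},
                "effect": {"purview": list(self.effect.purview),
                           "dist": [float(p) for p in self.effect.repertoire.dist]},
                "n_tied_causes": len(self.tied_causes),
                "n_tied_effects": len(self.tied_effects)}

    def __repr__(self):
        return (f"<Concept m={self.mechanism} phi={float(self.phi):.6f} "
                f"cause={self.cause.purview} effect={self.effect.purview}>")


def null_concept(sub: Subsystem) -> Concept:
    """The concept-shaped object built from unconstrained repertoires, phi=0."""
    full = sub.positions
    cr = unconstrained_repertoire(sub, full, PAST)
    er = unconstrained_repertoire(sub, full, FUTURE)
    zero = 0 if sub.exact else 0.0
    cause = PurviewResult(full, PAST, zero, (), cr)
    effect = PurviewResult(full, FUTURE, zero, (), er)
    return Concept(sub, (), zero, cause, effect)


def concept_variants(sub: Subsystem, mechanism) -> List[Concept]:
    """Every (tied cause) x (tied effect) concept variant of a mechanism.

    Empty when phi^Max is zero (the mechanism yields no concept).
    """
    phi_c, tied_c = core_candidates(sub, mechanism, PAST)
    phi_e, tied_e = core_candidates(sub, mechanism, FUTURE)
    phi = min(phi_c, phi_e)
    if num_eq(phi, 0, sub.exact):
        return []
    return [Concept(sub, mechanism, phi, c, e, tied_c, tied_e)
            for c in tied_c for e in tied_e]
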