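"""Cause and effect repertoires.

A repertoire is the probability distribution over the past (*cause*) or
future (*effect*) states of a purview ``z`` induced by clamping a mechanism
``m`` to its current state while every other input is perturbed with
independent maximum-entropy noise.

* Cause side: Bayesian inversion of the TPM under a uniform prior over past
  states.  Multi-node mechanisms combine per-node constraints as a normalized
  product of single-node cause repertoires (the virtual-element
  factorization), which reproduces the published worked values.
* Effect side: a product over purview nodes of each node's next-state
  distribution given the mechanism, with all non-mechanism inputs noised
  independently per target (avoiding correlated input).

Mechanisms and purviews are tuples of within-subsystem *positions*; joint
purview states are coded with the first purview position as the
least-significant bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Tuple

from .errors import StateError
from .subsystem import Subsystem

__all__ = [
    "PAST", "FUTURE", "Repertoire", "MechanismPartition",
    "cause_repertoire", "effect_repertoire", "unconstrained_repertoire",
    "partitioned_repertoire", "expand_dist", "marginalize_dist",
]

PAST = "past"
FUTURE = "future"


@dataclass(frozen=True)
class Repertoire:
    """A probability distribution over joint purview states."""

    direction: str
    mechanism: Tuple[int, ...]
    purview: Tuple[int, ...]
    dist: tuple

    def __post_init__(self):
        if self.direction not in (PAST, FUTURE):
            raise StateError(f"direction must be {PAST!r} or {FUTURE!r}")
        if len(self.dist) != 1 << len(self.purview):
            raise StateError("distribution size does not match purview")

    def to_json(self):
        return {"direction": self.direction,
                "mechanism": list(self.mechanism),
                "purview": list(self.purview),
                "dist": [float(p) for p in self.dist]}


@dataclass(frozen=True)
class MechanismPartition:
    """An unordered bipartition of a (mechanism, purview) pair.

    Each part is a ``(mechanism_subset, purview_subset)`` pair; the two parts
    are disjoint and jointly cover the original pair.  A part may be empty on
    either side, but no part may be empty on both (which excludes the trivial
    partition).
    """

    part1: Tuple[Tuple[int, ...], Tuple[int, ...]]
    part2: Tuple[Tuple[int, ...], Tuple[int, ...]]

    def __post_init__(self):
        (m1, z1), (m2, z2) = self.part1, self.part2
        if (not m1 and not z1) or (not m2 and not z2):
            raise StateError("a partition part may not be empty on both sides")
        if set(m1) & set(m2) or set(z1) & set(z2):
            raise StateError("partition parts overlap")

    def __str__(self):
        def half(part):
            m, z = part
            return f"{','.join(map(str, m)) or '[]'}/{','.join(map(str, z)) or '[]'}"
        return f"({half(self.part1)} x {half(self.part2)})"


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _substate(code: int, positions, subset) -> int:
    """Extract the joint code of ``subset`` (ordered) from a code over ``positions``."""
    idx = {p: i for i, p in enumerate(positions)}
    out = 0
    for b, p in enumerate(subset):
        if (code >> idx[p]) & 1:
            out |= 1 << b
    return out


def combine_dists(parts, purview):
    """Tensor-combine part distributions into canonical order over ``purview``.

    ``parts`` is a list of ``(subset, dist)`` with disjoint subsets whose
    union is ``purview`` (sorted).
    """
    k = len(purview)
    out = []
    for code in range(1 << k):
        p = None
        for subset, dist in parts:
            sub = _substate(code, purview, subset)
            p = dist[sub] if p is None else p * dist[sub]
        out.append(p if p is not None else 1)
    return tuple(out)


def marginalize_dist(dist, purview, keep):
    """Marginal of a purview distribution over the sub-purview ``keep``."""
    out = [0] * (1 << len(keep))
    for code, p in enumerate(dist):
        out[_substate(code, purview, keep)] += p
    return tuple(out)


# ---------------------------------------------------------------------------
# repertoires
# ---------------------------------------------------------------------------


def _check_pos(sub: Subsystem, positions):
    for p in positions:
        if not 0 <= p < sub.k:
            raise StateError(f"position {p} outside subsystem of size {sub.k}")


def _one(sub: Subsystem):
    return Fraction(1) if sub.exact else 1.0


def cause_repertoire(sub: Subsystem, mechanism, purview) -> Repertoire:
    """p(purview at t-1 | mechanism = its current state), uniform prior."""
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    _check_pos(sub, mechanism + purview)
    kz = len(purview)
    if kz == 0:
        return Repertoire(PAST, mechanism, purview, (_one(sub),))
    size = 1 << kz
    uniform = tuple([_one(sub) / size] * size)
    if not mechanism:
        return Repertoire(PAST, mechanism, purview, uniform)
    rest = [p for p in range(sub.k) if p not in purview]
    joint = [_one(sub)] * size
    for i in mechanism:
        s_i = sub.node_state(i)
        vec = [0] * size
        for u in range(size):
            total = 0
            for w in range(1 << len(rest)):
                code = 0
                for b, p in enumerate(purview):
                    if (u >> b) & 1:
                        code |= 1 << p
                for b, p in enumerate(rest):
                    if (w >> b) & 1:
                        code |= 1 << p
                pr = sub.prob_on(i, code)
                total += pr if s_i else (1 - pr)
            vec[u] = total
        for u in range(size):
            joint[u] = joint[u] * vec[u]
    total = sum(joint)
    if total == 0:
        # Mechanism state has zero prior probability: degenerate-input rule --
        # fall back to the unconstrained repertoire (phi is forced to 0 for
        # such mechanisms downstream).
        return Repertoire(PAST, mechanism, purview, uniform)
    return Repertoire(PAST, mechanism, purview, tuple(p / total for p in joint))


def effect_repertoire(sub: Subsystem, mechanism, purview) -> Repertoire:
    """p(purview at t+1 | mechanism = its current state), inputs noised."""
    mechanism = tuple(sorted(mechanism))
    purview = tuple(sorted(purview))
    _check_pos(sub, mechanism + purview)
    if not purview:
        return Repertoire(FUTURE, mechanism, purview, (_one(sub),))
    free = [p for p in range(sub.k) if p not in mechanism]
    mech_code = 0
    for i in mechanism:
        if sub.node_state(i):
            mech_code |= 1 << i
    norm = _one(sub) / (1 << len(free))
    parts = []
    for j in purview:
        total = 0
        for v in range(1 << len(free)):
            code = mech_code
            for b, p in enumerate(free):
                if (v >> b) & 1:
                    code |= 1 << p
            total += sub.prob_on(j, code)
        p1 = total * norm
        parts.append(((j,), (1 - p1, p1)))
    return Repertoire(FUTURE, mechanism, purview, combine_dists(parts, purview))


def unconstrained_repertoire(sub: Subsystem, purview, direction) -> Repertoire:
    """Repertoire with an empty mechanism (uniform past; gate-biased future)."""
    if direction == PAST:
        return cause_repertoire(sub, (), purview)
    return effect_repertoire(sub, (), purview)


def partitioned_repertoire(sub: Subsystem, partition: MechanismPartition,
                           direction) -> Repertoire:
    """Product of the two part repertoires over the full purview."""
    rep = cause_repertoire if direction == PAST else effect_repertoire
    (m1, z1), (m2, z2) = partition.part1, partition.part2
    purview = tuple(sorted(z1 + z2))
    mechanism = tuple(sorted(m1 + m2))
    parts = []
    for m, z in ((m1, z1), (m2, z2)):
        if z:
            parts.append((tuple(sorted(z)), rep(sub, m, z).dist))
    if not parts:
        raise StateError("partitioned repertoire needs a non-empty purview")
    return Repertoire(direction, mechanism, purview, combine_dists(parts, purview))


def expand_dist(sub: Subsystem, dist, purview, target, direction):
    """Expand a purview distribution over ``target`` (a superset).

    Missing elements are filled with the unconstrained repertoire in the given
    direction: uniform for causes, the noised gate bias for effects.
    """
    purview = tuple(sorted(purview))
    target = tuple(sorted(target))
    missing = tuple(p for p in target if p not in purview)
    if not set(purview) <= set(target):
        raise StateError("expansion target must contain the purview")
    if not missing:
        return combine_dists([(purview, dist)], target)
    fill = unconstrained_repertoire(sub, missing, direction).dist
    return combine_dists([(purview, dist), (missing, fill)], target)
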