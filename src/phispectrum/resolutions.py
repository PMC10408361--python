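"""The four published tie-resolution strategies, plus the reference
implementation's default.

* ``biggest`` -- keep only the largest tied purviews (ties of equal size
  survive and are reported as residual degeneracy).
* ``smallest`` -- keep only the smallest tied purviews (likewise).
* ``moon`` -- a mechanism with any degenerate core cause or effect
  contributes no concept at all ("differences that make a difference").
* ``ko17_sum`` -- replace selection by summation: the mechanism's phi is the
  sum of the degenerate phi values per side, and the repertoires carried
  forward are the unconstrained ones (the shape of the distribution is
  deliberately discarded).  This is a reinterpretation of the cited
  definition; outputs are flagged accordingly.
* ``pyphi_default`` -- biggest, then first in canonical (lexicographic by
  node index) order, emulating the reference implementation.

None of these silently manufacture uniqueness: residual ties under
``biggest``/``smallest`` are surfaced as multiple surviving Phi values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from ._num import phi_round
from .concepts import Concept, PurviewResult, concept_variants, powerset_purviews
from .errors import StateError
from .repertoires import FUTURE, PAST, unconstrained_repertoire
from .spectrum import DEFAULT_CAP, PhiSpectrum, phi_spectrum
from .subsystem import Subsystem

__all__ = ["STRATEGIES", "resolve_concept", "variant_filter", "resolve_phi",
           "ResolutionResult"]

STRATEGIES = ("biggest", "smallest", "moon", "ko17_sum", "pyphi_default")


def _filter_by_size(results, pick):
    target = pick(len(r.purview) for r in results)
    return [r for r in results if len(r.purview) == target]


def resolve_concept(variants: List[Concept], strategy: str) -> List[Concept]:
    """Apply a tie-resolution strategy to one mechanism's concept variants."""
    if strategy not in STRATEGIES:
        raise StateError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    if not variants:
        return []
    tied_c, tied_e = variants[0].tied_causes, variants[0].tied_effects

    if strategy == "moon":
        return list(variants) if len(tied_c) == 1 and len(tied_e) == 1 else []

    if strategy == "ko17_sum":
        sub = variants[0].subsystem
        phi_c = sum(r.phi for r in tied_c)
        phi_e = sum(r.phi for r in tied_e)
        phi = phi_round(min(phi_c, phi_e), sub.exact)
        full = sub.positions
        cause = PurviewResult(full, PAST, phi_c, (),
                              unconstrained_repertoire(sub, full, PAST))
        effect = PurviewResult(full, FUTURE, phi_e, (),
                               unconstrained_repertoire(sub, full, FUTURE))
        return [Concept(sub, variants[0].mechanism, phi, cause, effect,
                        (cause,), (effect,))]

    pick = max if strategy in ("biggest", "pyphi_default") else min
    keep_c = _filter_by_size(tied_c, pick)
    keep_e = _filter_by_size(tied_e, pick)
    if strategy == "pyphi_default":
        keep_c = [min(keep_c, key=lambda r: r.purview)]
        keep_e = [min(keep_e, key=lambda r: r.purview)]
    cp = {r.purview for r in keep_c}
    ep = {r.purview for r in keep_e}
    return [v for v in variants if v.cause.purview in cp and v.effect.purview in ep]


def variant_filter(strategy: Optional[str]):
    """A per-mechanism filter usable by the constellation enumerator."""
    if strategy is None or strategy == "all":
        return None
    return lambda variants: resolve_concept(variants, strategy)


@dataclass
class ResolutionResult:
    """Phi value(s) of a subsystem under one tie-resolution strategy."""

    strategy: str
    values: Tuple
    residual_ties: Dict[tuple, int]
    spectrum: PhiSpectrum
    reinterpreted: bool = False

    @property
    def unique(self) -> bool:
        return len(self.values) == 1

    def to_json(self):
        return {"strategy": self.strategy,
                "values": [float(v) for v in self.values],
                "unique": self.unique,
                "residual_ties": {"".join(map(str, k)): v
                                  for k, v in self.residual_ties.items()},
                "reinterpreted": self.reinterpreted}


def resolve_phi(sub: Subsystem, strategy: str, cap: int = DEFAULT_CAP) -> ResolutionResult:
    """Phi^MIP of a subsystem with per-mechanism resolution applied first.

    Strategies that fail to break every tie (``biggest``/``smallest``) return
    the full residual set of valid Phi^MIP values rather than an arbitrary
    single member.
    """
    if strategy not in STRATEGIES:
        raise StateError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    residual = {}
    for mech in powerset_purviews(sub):
        variants = concept_variants(sub, mech)
        if not variants:
            continue
        surviving = resolve_concept(variants, strategy)
        if len(surviving) > 1:
            residual[mech] = len(surviving)
    spec = phi_spectrum(sub, strategy=variant_filter(strategy), cap=cap)
    values = spec.valid_phi_mip
    return ResolutionResult(strategy, values, residual, spec,
                            reinterpreted=(strategy == "ko17_sum"))
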