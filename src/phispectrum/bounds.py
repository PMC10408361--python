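"""Analytic and numerical upper bounds on Phi, operation-count bookkeeping,
and the degeneracy-scaling measure.

The loose analytic bound follows from moving each mechanism's maximal
phi^Max (bounded by the maximal Hamming EMD, ``m`` for an ``m``-bit
mechanism) the maximal conceptual distance (again ``m``):

    Phi(n) <= sum_{m=1..n} C(n,m) m^2 = 2^(n-2) n (n+1).

Refinements divide by 2 when cut concepts land on the null concept
(``D^Max = n/2``) and, conjecturally, by 2 again on the phi^Max side.  The
numerical bound for two-node systems comes from exhaustively evaluating all
256 deterministic Boolean TPMs in all 4 initial states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import comb, factorial
from typing import List, Optional

from .errors import StateError
from .network import Network
from .spectrum import phi_spectrum
from .subsystem import Subsystem

__all__ = ["analytic_bound", "refined_bound", "conjectured_bound",
           "binomial_sum_bound", "BoundReport", "exhaustive_two_node_scan",
           "stirling2", "op_counts", "degeneracy_scaling"]


def _closed_form(n: int, shift: int) -> Fraction:
    if n < 1:
        raise StateError("bound requires n >= 1")
    return Fraction(2) ** (n - shift) * n * (n + 1)


def analytic_bound(n: int) -> Fraction:
    """Closed-form loose bound 2^(n-2) n (n+1), in bits."""
    return _closed_form(n, 2)


def refined_bound(n: int) -> Fraction:
    """Bound with concepts moving at most n/2 (to the null concept)."""
    return _closed_form(n, 3)


def conjectured_bound(n: int) -> Fraction:
    """Conjectured tight-by-a-further-half bound 2^(n-4) n (n+1)."""
    return _closed_form(n, 4)


def binomial_sum_bound(n: int) -> int:
    """Direct evaluation of sum_m C(n,m) m^2 (equals the closed form)."""
    if n < 1:
        raise StateError("bound requires n >= 1")
    return sum(comb(n, m) * m * m for m in range(1, n + 1))


@dataclass
class BoundReport:
    n: int
    analytic: Fraction
    refined: Fraction
    conjectured: Fraction
    numeric_max: Optional[float] = None
    witnesses: List[tuple] = field(default_factory=list)
    scanned: int = 0

    def to_json(self):
        return {"n": self.n,
                "analytic_bound": float(self.analytic),
                "refined_bound": float(self.refined),
                "conjectured_bound": float(self.conjectured),
                "numeric_max": self.numeric_max,
                "witnesses": [{"tpm": list(t), "state": s} for t, s in self.witnesses],
                "scanned": self.scanned}


def exhaustive_two_node_scan(full_spectrum: bool = True, progress=None) -> BoundReport:
    """Max Phi^MIP over all 256 deterministic two-node TPMs x 4 initial states.

    ``full_spectrum=False`` restricts each run to the reference-default
    single constellation (faster smoke-test mode); the bound itself is
    defined over the full valid value sets.
    """
    from .resolutions import variant_filter
    strategy = None if full_spectrum else variant_filter("pyphi_default")
    report = BoundReport(2, analytic_bound(2), refined_bound(2), conjectured_bound(2))
    best = 0.0
    witnesses = []
    for fa in range(16):
        for fb in range(16):
            nxt = [((fa >> row) & 1) | (((fb >> row) & 1) << 1) for row in range(4)]
            net = Network.from_transitions(nxt, ("A", "B"), exact=False)
            for state_idx in range(4):
                state = ((state_idx >> 0) & 1, (state_idx >> 1) & 1)
                spec = phi_spectrum(Subsystem(net, state), strategy=strategy)
                top = max(spec.valid_phi_mip)
                report.scanned += 1
                if top > best + 1e-9:
                    best, witnesses = top, [(tuple(nxt), "".join(map(str, state)))]
                elif abs(top - best) <= 1e-9:
                    witnesses.append((tuple(nxt), "".join(map(str, state))))
            if progress is not None:
                progress(fa * 16 + fb + 1)
    report.numeric_max = best
    report.witnesses = witnesses
    return report


def stirling2(n: int, k: int) -> int:
    """Stirling number of the second kind."""
    if k == 0:
        return int(n == 0)
    return sum((-1) ** j * comb(k, j) * (k - j) ** n for j in range(k + 1)) // factorial(k)


def op_counts(n: int, m: Optional[int] = None) -> dict:
    """Operation-count bookkeeping for a subsystem of size n (system size m).

    Reports both the printed closed forms and their exact direct-sum
    evaluations; the engine itself never relies on these formulas.
    ``per_ces_emds_exact`` is the exact value of ``2 sum_k C(n,k) S(k,2)``,
    which evaluates to ``3^n + 1 - 2^(n+1)`` -- the printed shorthand
    ``2*3^n`` overcounts it (asymptotically by a factor of 2).
    """
    if n < 1 or (m is not None and m < 1):
        raise StateError("op_counts requires n, m >= 1")
    exact_sum = 2 * sum(comb(n, k) * stirling2(k, 2) for k in range(n + 1))
    counts = {
        "cuts_including_unpartitioned": 2 * stirling2(n, 2) + 1,
        "mechanisms": 2 ** n - 1,
        "per_ces_emds_exact": exact_sum,
        "per_ces_emds_printed": 2 * 3 ** n,
        "per_ces_emds_identity": 3 ** n + 1 - 2 ** (n + 1),
        "per_subsystem_approx": 12 ** n,
    }
    if m is not None:
        counts["global_exact_sum"] = sum(comb(m, k) * 12 ** k for k in range(m + 1))
        counts["global_printed"] = 13 ** m
    return counts


def degeneracy_scaling(n: int) -> Fraction:
    """Degeneracy measure L = n! / |phi| with the |phi| <= n^4 cap.

    Here ``n`` counts system states (deterministic TPMs quantize probability
    in units of 1/n); L tracks how many degenerate phi values fall on each
    purview element on average, and grows without bound.
    """
    if n < 1:
        raise StateError("degeneracy scaling requires n >= 1")
    return Fraction(factorial(n), n ** 4)
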