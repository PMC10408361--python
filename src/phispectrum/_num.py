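"""Numeric-mode helpers.

The engine runs in one of two arithmetic modes:

* exact mode -- probabilities and phi values are :class:`fractions.Fraction`
  instances and equality is literal.  This is the default for deterministic
  transition tables, where every repertoire entry is a rational number.
* float mode -- IEEE doubles, with phi-style quantities rounded to
  ``PRECISION`` decimals before any comparison (mirroring the 6-decimal
  precision of the reference implementation).  Tie detection, value
  deduplication and spectrum membership all share this single comparator.
"""

from __future__ import annotations

from fractions import Fraction
from math import lcm

#: Decimal precision used for phi/Phi comparisons in float mode.
PRECISION = 6

#: Absolute tolerance implied by PRECISION.
TOL = 10.0 ** (-PRECISION)


def phi_round(x, exact: bool):
    """Round a phi-like scalar for storage/comparison (identity in exact mode)."""
    if exact:
        return x
    return round(float(x), PRECISION)


def num_eq(a, b, exact: bool) -> bool:
    """Equality under the mode's comparator."""
    if exact:
        return a == b
    return abs(float(a) - float(b)) <= TOL


def dist_key(dist, exact: bool):
    """Hashable canonical form of a probability vector."""
    if exact:
        return tuple(dist)
    return tuple(round(float(p), PRECISION + 3) for p in dist)


def quantize(values, scale: int):
    """Scale non-negative reals to integers summing to ``round(sum*scale)``.

    Drift from rounding is absorbed by the largest entry so that two vectors
    with equal mass stay balanced after quantization.
    """
    scaled = [int(round(float(v) * scale)) for v in values]
    target = int(round(float(sum(values)) * scale))
    drift = target - sum(scaled)
    if drift:
        i = max(range(len(scaled)), key=lambda j: scaled[j])
        scaled[i] += drift
    return scaled


def common_denominator(fracs) -> int:
    d = 1
    for f in fracs:
        d = lcm(d, Fraction(f).denominator)
    return d
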