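# phispectrum

Exhaustive integrated-information (Φ) spectra for small discrete networks.

## The problem

Integrated Information Theory (IIT 3.0) assigns a scalar Φ to a set of
interacting binary elements: the irreducibility of the system's cause–effect
structure under its minimum-information partition.  The calculus is a nested
stack of optimizations.  For every mechanism *m* (a subset of nodes in its
current state) and every purview *z*, the mechanism-level integrated
information is

    φ^MIP(m, z) = D[ p(z | m = s₀) ‖ p(z | m = s₀ / MIP) ],

the Earth Mover's Distance (Hamming ground metric) between the constrained
repertoire and its best bipartition.  The core cause/effect of *m* is the
purview maximizing φ^MIP, with φ^Max = min(φ^Max_cause, φ^Max_effect); the
concepts of all mechanisms form a cause–effect structure (constellation) C;
and the system-level value is

    Φ = D(C ‖ C′),     Φ^MIP = min over unidirectional cuts,

where D is the extended EMD that moves φ^Max mass between concepts.

The inner maximizations are not guaranteed unique: several purviews
routinely tie at φ^Max ("tied purviews"), each carrying a *different*
repertoire, and the choice propagates to Φ.  This package computes the whole
calculus and, instead of picking one winner, forks the computation at every
tie and enumerates **every valid Φ^MIP value** — the Φ spectrum — together
with the four published tie-resolution strategies (biggest / smallest
purview, the summation rule, the "differences that make a difference" rule)
and an emulation of the reference implementation's default.  It is aimed at
researchers auditing published Φ values for Boolean network models
(gene-regulatory circuits, logic-gate toys) and at anyone studying the
non-uniqueness problem itself.

All ten published case-study systems — from the two-gate photodiode to the
nine-node fission yeast cell-cycle model — are built in as programmatic
fixtures, plus the three-majority-gate demonstration system.

## Worked example

The fully connected AND+OR pair in state 00:

```python
>>> import phispectrum as ps
>>> sub = ps.get_subsystem("and_or")          # exact rational mode
>>> ps.cause_repertoire(sub, (0,), (0, 1)).dist
(Fraction(1, 3), Fraction(1, 3), Fraction(1, 3), Fraction(0, 1))
>>> spec = ps.phi_spectrum(sub)
>>> len(spec.valid_phi_mip)
63
>>> float(min(spec.valid_phi_mip)), float(max(spec.valid_phi_mip))
(0.0, 0.5138888888888888)
>>> [float(v) for v in ps.resolve_phi(sub, "pyphi_default").values]
[0.090278]
>>> [float(v) for v in ps.resolve_phi(sub, "moon").values]
[0.0]
```

The mechanism A (the AND gate) has three tied core causes and three tied
core effects at φ^Max = 1/6; carried through both unidirectional cuts, the
81 resulting constellations produce 63 distinct valid Φ^MIP values, ranging
from 0 to 37/72 bits.  The spectrum contains both Φ = 0 and Φ > 0: whether
the pair is "integrated" depends entirely on which tied purview is selected.
The reference default picks the largest purview and reports the single value
13/144 ≈ 0.0903 bits, while the "differences that make a difference" rule
discards every tied mechanism and yields Φ = 0.

The same machinery runs from the shell:

```
phispectrum spectrum --network and_or --out report.json
phispectrum resolve --mode biggest --network majority --float
phispectrum corpus --float
phispectrum bounds --n 2
```

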