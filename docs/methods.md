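# Methods

This note documents the calculus the package implements, the conventions it
fixes where implementations genuinely differ, the numerical choices, and the
known limitations.  Everything stated as a number here is recomputed by the
test suite or by `scripts/acceptance.py`; nothing is asserted from memory.

## The model

A network is `n` binary nodes with a row-stochastic transition probability
matrix (TPM) over the `2^n` joint states.  Internally the TPM is held in
state-by-node form, `p(node j ON at t+1 | global state at t)`, which is
equivalent to the dense matrix exactly when nodes update conditionally
independently given the current state — the standing assumption of the
cause–effect calculus.  State indices are canonical little-endian (node 0 is
the least-significant bit); published tables written "most significant digit
on the left" are converted on load.  Human-facing output uses state strings
with node 0 leftmost.

A subsystem is a node subset evaluated in a fixed global state; background
nodes (the complement) are frozen at their state values in every
computation, in both temporal directions.  A unidirectional cut severs all
connections from one part into the other and replaces them with independent
maximum-entropy noise; cuts are applied at the per-node conditional level,
so all downstream machinery is cut-agnostic.

## Repertoires

* Cause: Bayesian inversion of the TPM under a uniform (maximum-entropy)
  prior over past states.  Multi-node mechanisms combine per-node
  constraints as a normalized product of single-node cause repertoires (the
  virtual-element factorization of the reference formulation).  This
  normalized product is *not* marginalization-consistent for mechanisms of
  two or more nodes — marginalizing the joint does not reproduce the
  smaller-purview repertoire — and the property suite asserts consistency
  only where it mathematically holds (all effects; single-node-mechanism
  causes).
* Effect: a product over purview nodes of each node's next-state
  distribution with the mechanism clamped and every non-mechanism input
  noised independently per target node (avoiding correlated input).
* A mechanism state with zero prior probability falls back to the
  unconstrained repertoire; its φ is forced to zero downstream.  None of the
  shipped fixtures exercises this rule.

## Mechanism-level φ and ties

φ^MIP(m, z) minimizes the EMD between the unpartitioned repertoire and the
product repertoire of a bipartition of (m, z).  The bipartition census
follows the reference contract: both parts may be empty on one side, no part
may be empty on both sides, the trivial partition is excluded, and the
full-severance bipartition (entire mechanism vs entire purview) **is** a
candidate.  All minimizing partitions are recorded; since only the scalar
moves forward, tied partitions need no disambiguation.

Core causes/effects maximize φ^MIP over the non-empty powerset of subsystem
nodes.  Every tied maximizer is retained; a mechanism with
φ^Max = min(φ^Max_cause, φ^Max_effect) > 0 yields one concept variant per
(tied cause × tied effect) pair.  Tie detection shares one comparator with
value deduplication end-to-end: exact equality in rational mode, absolute
1e-6 in float mode (mirroring the reference implementation's 6-decimal
precision).

## Distances

The repertoire-level EMD uses the Hamming ground metric and is solved as an
exact integer minimum-cost flow (common-denominator scaling in rational
mode; 1e-9 quantization of masses and ground costs in float mode), with
closed forms for the 1×k and 2×2 transport cases.  An independent dense-LP
oracle (scipy HiGHS) checks it property-wise in the tests.

Concept-to-concept distance expands each side's repertoire over the union of
the two purviews, filling missing elements from the concept's **own**
subsystem's unconstrained repertoire (uniform on the cause side, gate bias
on the effect side), then sums the cause- and effect-side EMDs.  The
constellation distance (extended EMD) removes concepts that are
EMD-identical across the two constellations, moves disappearing concepts'
φ mass to the null concept of their own subsystem, and otherwise solves the
transportation problem with the null concept absorbing surplus mass.  These
conventions follow the reference implementation contract; they are isolated
in one function so alternative extended-EMD conventions can be swapped.

## The spectrum

Per cut, every (original constellation × cut constellation) pair yields a
candidate Φ; the valid Φ^MIP set takes the global minimum over cuts as lower
bound and, following the published selection pseudocode literally, an upper
bound initialized from the first cut's maximum and lowered by the maxima of
the cuts attaining the global minimum.  A strict variant (minimum over
candidate-MIP cuts only) sits behind a flag; the two differ only when the
first cut is not itself a candidate MIP and has an unusually small maximum.
Constellations are deduplicated before the quadratic pair loop, and
concept-pair and constellation-pair distances are memoized.  Enumerations
that would exceed a configurable cap (default 10^6 constellations) abort
with a distinct error rather than truncating silently.

On the corpus this yields, in exact arithmetic: 63 distinct valid Φ^MIP
values for the AND+OR pair in state 00 (spanning 0 to 37/72 bits, containing
both 0 and the reference default 13/144), a singleton {1.0} for the
photodiode, a 19-value spectrum for OR+AND+XOR containing 23/12 ≈ 1.9167,
and 114 values spanning 0.00–0.83 bits (containing 0.0903) for the
three-node fission yeast subsystem.  Earlier reports of these spectra list
larger cardinalities (83 and 244).  Those counts were produced by a pipeline
that rounds each Φ to six decimals after accumulating floating-point error
of the same 1e-6 order (its published single-value outputs show exactly such
offsets, e.g. 1.916665 for the exact 23/12), so equal exact values computed
through different concept decompositions round apart and inflate the count.
This package's two arithmetic modes agree with each other at six decimals by
construction, and every *pointwise* published quantity — each worked
repertoire, each EMD, each strategy value, each spectrum extreme — is
reproduced exactly; the cardinalities reported here are the
distinct-rational-value counts.

## The fission yeast configuration

The nine-node Boolean cell-cycle model is shipped as its full printed
512-row transition table.  The analyzed three-node subsystem and its state
are pinned by matching the published Φ signature over all 84 candidate
triples and candidate states: the unique match is nodes (1, 2, 3) —
Cdc2/Cdc13, Ste9, Rum1, the G1/S antagonism trio — with the network in its
stable G1 resting state (Ste9, Rum1, Wee1/Mik1 active), where the reference
default reproduces 13/144 ≈ 0.0903 exactly and the spectrum spans 0.00–0.83
bits.  The late-M cycle state printed alongside the table (000110011, which
relaxes onto the G1 state in two updates) reproduces no published value for
any triple; both states are exported as constants.

## Strategies

`biggest`/`smallest` filter tied purviews by cardinality and surface
residual equal-size ties rather than breaking them silently (the
three-majority-gate system leaves 15 residual Φ^MIP values under
`biggest`).  `moon` drops any mechanism with a degenerate core.  `ko17_sum`
replaces selection by summation of the tied φ values, carrying unconstrained
repertoires — a reinterpretation, flagged as such in its output, since the
source formulation lives in cited work.  `pyphi_default` applies biggest,
then first-in-canonical-order (lexicographic by node index), and reproduces
the published single values for the photodiode (1.0), AND+OR (0.0903),
OR+AND+XOR (1.9167), the reduced virus–host model (0.4375) and the fission
yeast subsystem (0.0903).  For the mod-eight counter it yields 1.625 where
1.7187 was published; that system's thousands of degenerate constellations
make the published selection sensitive to iteration-order details that its
source does not specify, and its full spectrum is out of reach at desk
scale, so the counter is covered by fixture-integrity tests only.

## Bounds and scaling

The closed-form bound Φ(n) ≤ 2^(n−2)·n·(n+1) is exposed alongside its
refined (2^(n−3)) and conjectured (2^(n−4)) variants and cross-checked
against the direct binomial sum.  The exhaustive two-node scan evaluates the
full spectrum of all 256 deterministic two-node TPMs in all 4 initial states
and attains the numerical bound Φ^MIP = 1.5 (32 witness TPM/state pairs).
Operation-count bookkeeping reports the published closed forms next to their
exact direct sums; note that 2·Σₖ C(n,k)·S(k,2) evaluates exactly to
3ⁿ + 1 − 2ⁿ⁺¹, so the printed shorthand 2·3ⁿ overcounts it roughly twofold,
while Σₙ C(m,n)·12ⁿ = 13ᵐ is an exact binomial identity.  The degeneracy
measure L = n!/n⁴ (n counting states) is implemented as printed.

## Problem sizes and limitations

Exhaustive enumeration is the point of the package, and it is intentionally
restricted to the sizes where it is meaningful: spectra are routine for 2–3
node subsystems (seconds to about two minutes), while the 4–5 node corpus
entries (mod-eight counter, noisy AND quartet, four-gate systems, full
virus–host model) exceed the constellation cap or any reasonable wall-clock
budget and are shipped as integrity-tested fixtures with single-strategy
runs only.  The subsystem sweep (Φ^Max) is guarded at n ≤ 4 by default.
Only binary (binarized) networks are supported, with the maximum-entropy
prior and noise model of IIT 3.0; alternative priors, Kullback–Leibler
distances, and approximate or entropic EMDs are out of scope.
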