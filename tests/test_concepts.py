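"""Mechanism-level phi: partition census, phi^MIP, tied maximizers, variants."""

from fractions import Fraction as F
from itertools import combinations

import pytest

import phispectrum as ps
from phispectrum.bounds import stirling2
from phispectrum.concepts import (concept_variants, core_candidates,
                                  enumerate_partitions, null_concept, phi_mip)
from phispectrum.errors import StateError
from phispectrum.network import reorder_to_paper

A, B = 0, 1


class TestPartitionCensus:
    def test_single_mechanism_two_node_purview(self):
        parts = enumerate_partitions((A,), (A, B))
        keys = {frozenset((p.part1, p.part2)) for p in parts}
        assert keys == {
            frozenset((((A,), (A,)), ((), (B,)))),        # A/A x []/B
            frozenset((((A,), (B,)), ((), (A,)))),        # A/B x []/A
            frozenset((((A,), ()), ((), (A, B)))),        # A/[] x []/AB (full severance)
        }

    def test_single_node_pair_has_single_severing_partition(self):
        parts = enumerate_partitions((A,), (A,))
        assert len(parts) == 1
        assert frozenset((parts[0].part1, parts[0].part2)) == \
            frozenset((((A,), ()), ((), (A,))))

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_nonempty_purview_splits_count_twice_stirling(self, k):
        # bipartitions of a single-node mechanism over a k-node purview with
        # both purview parts non-empty number 2*S(k,2)
        purview = tuple(range(1, k + 1))
        parts = enumerate_partitions((0,), purview)
        both_nonempty = [p for p in parts if p.part1[1] and p.part2[1]]
        assert len(both_nonempty) == 2 * stirling2(k, 2)

    def test_empty_purview_rejected(self):
        with pytest.raises(StateError):
            enumerate_partitions((A,), ())


class TestPhiMip:
    def test_and_gate_cause_over_both_nodes(self, and_or):
        res = phi_mip(and_or, (A,), (A, B), ps.PAST)
        assert res.phi == F(1, 6)
        assert reorder_to_paper(res.repertoire.dist, 2) == (F(1, 3), F(1, 3), F(1, 3), 0)

    def test_and_gate_cause_over_itself(self, and_or):
        # single partition: EMD([2/3,1/3]x..., unconstrained) = 1/6
        assert phi_mip(and_or, (A,), (A,), ps.PAST).phi == F(1, 6)

    def test_disconnected_purview_gives_zero(self):
        net = ps.build_network([ps.GateSpec("COPY", (0,)), ps.GateSpec("COPY", (1,))],
                               ("A", "B"))
        sub = ps.Subsystem(net, (0, 0))
        assert phi_mip(sub, (A,), (B,), ps.PAST).phi == 0
        assert phi_mip(sub, (A,), (B,), ps.FUTURE).phi == 0

    def test_all_minimizing_partitions_recorded(self, and_or):
        res = phi_mip(and_or, (A,), (A, B), ps.PAST)
        assert len(res.mips) >= 1
        for part in res.mips:
            pr = ps.partitioned_repertoire(and_or, part, ps.PAST)
            assert ps.emd(res.repertoire.dist, pr.dist) == res.phi


class TestCoreCandidates:
    def test_and_gate_past_ties_all_three_purviews(self, and_or):
        phi, tied = core_candidates(and_or, (A,), ps.PAST)
        assert phi == F(1, 6)
        assert [t.purview for t in tied] == [(A,), (B,), (A, B)]

    def test_zero_phi_mechanism_ties_everything_and_bears_no_concept(self, and_or):
        phi, tied = core_candidates(and_or, (A, B), ps.PAST)
        assert phi == 0
        assert len(tied) == 3  # the full non-empty purview powerset stays tied at zero
        assert concept_variants(and_or, (A, B)) == []

    def test_exhaustive_recomputation_agrees(self, or_and_xor):
        # independent brute-force: recompute max phi by direct enumeration
        for mech_size in (1, 2):
            for mech in combinations(range(3), mech_size):
                for direction in (ps.PAST, ps.FUTURE):
                    phi, tied = core_candidates(or_and_xor, mech, direction)
                    best = max(phi_mip(or_and_xor, mech, z, direction).phi
                               for k in (1, 2, 3)
                               for z in combinations(range(3), k))
                    assert phi == best
                    recomputed = [z for k in (1, 2, 3)
                                  for z in combinations(range(3), k)
                                  if phi_mip(or_and_xor, mech, z, direction).phi == best]
                    assert [t.purview for t in tied] == recomputed


class TestConceptVariants:
    def test_published_variant_tuples(self, and_or):
        variants = concept_variants(and_or, (A,))
        assert len(variants) == 9
        assert len({v.phi for v in variants}) == 1 and variants[0].phi == F(1, 6)
        by_purviews = {(v.cause.purview, v.effect.purview): v for v in variants}
        big = by_purviews[((A, B), (A, B))]
        assert reorder_to_paper(big.cause.repertoire.dist, 2) == (F(1, 3), F(1, 3), F(1, 3), 0)
        assert reorder_to_paper(big.effect.repertoire.dist, 2) == (F(1, 2), F(1, 2), 0, 0)
        small = by_purviews[((A,), (A,))]
        assert reorder_to_paper(small.expanded_cause, 2) == (F(1, 3), F(1, 3), F(1, 6), F(1, 6))
        assert reorder_to_paper(small.expanded_effect, 2) == (F(1, 4), F(3, 4), 0, 0)

    def test_null_concept_carries_unconstrained_repertoires(self, and_or):
        nc = null_concept(and_or)
        assert nc.phi == 0
        assert nc.cause.repertoire.dist == (F(1, 4),) * 4
        assert reorder_to_paper(nc.effect.repertoire.dist, 2) == \
            (F(3, 16), F(9, 16), F(1, 16), F(3, 16))

    def test_variant_count_stable_across_numeric_modes(self, and_or, and_or_float):
        for mech in ((A,), (B,), (A, B)):
            assert len(concept_variants(and_or, mech)) == \
                len(concept_variants(and_or_float, mech))


class TestConceptDistances:
    def test_big_concept_vs_null(self, and_or):
        variants = concept_variants(and_or, (A,))
        big = next(v for v in variants
                   if (v.cause.purview, v.effect.purview) == ((A, B), (A, B)))
        nc = null_concept(and_or)
        assert ps.concept_distance(big, nc) == F(1, 3) + F(1, 2)
        assert ps.concept_distance(big, big) == 0

    def test_small_concept_vs_null(self, and_or):
        variants = concept_variants(and_or, (A,))
        small = next(v for v in variants
                     if (v.cause.purview, v.effect.purview) == ((A,), (A,)))
        assert ps.concept_distance(small, null_concept(and_or)) == F(1, 6) + F(1, 4)
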