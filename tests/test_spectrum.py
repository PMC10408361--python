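"""System-level machinery: cuts, constellations, extended EMD, Phi spectra."""

from fractions import Fraction as F

import pytest

import phispectrum as ps
from phispectrum.bounds import analytic_bound, stirling2
from phispectrum.concepts import concept_variants, null_concept, powerset_purviews
from phispectrum.errors import CombinatorialGuardError, StateError
from phispectrum.spectrum import (Constellation, enumerate_constellations,
                                  phi_mip_set, unidirectional_cuts)

A, B = 0, 1


class TestCuts:
    def test_two_node_system_has_two_cuts(self, and_or):
        cuts = unidirectional_cuts(and_or)
        assert [(c.severed_from, c.severed_to) for c in cuts] == \
            [((0,), (1,)), ((1,), (0,))]

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_cut_count_is_twice_stirling(self, n):
        net = ps.build_network([ps.GateSpec("COPY", ((i + 1) % n,)) for i in range(n)])
        cuts = unidirectional_cuts(ps.Subsystem(net, (0,) * n))
        assert len(cuts) == 2 * stirling2(n, 2)
        for c in cuts:
            assert c.severed_from and c.severed_to
            assert not set(c.severed_from) & set(c.severed_to)
            assert set(c.severed_from) | set(c.severed_to) == set(range(n))

    def test_single_node_subsystem_admits_no_cut(self):
        net = ps.get_network("and_or")
        with pytest.raises(StateError):
            unidirectional_cuts(ps.Subsystem(net, (0, 0), (0,)))

    def test_cutting_only_input_of_copy_gate_makes_effect_uniform(self):
        net = ps.build_network([ps.GateSpec("COPY", (1,)), ps.GateSpec("COPY", (0,))])
        sub = ps.Subsystem(net, (1, 0))
        cut = sub.apply_cut(ps.Cut((1,), (0,)))
        assert ps.effect_repertoire(cut, (1,), (0,)).dist == (F(1, 2), F(1, 2))
        # the unsevered direction is untouched
        assert ps.effect_repertoire(cut, (0,), (1,)).dist == \
            ps.effect_repertoire(sub, (0,), (1,)).dist

    def test_cutting_absent_connection_is_a_noop(self):
        # A and B are self-loops only; severing A->B changes nothing
        net = ps.build_network([ps.GateSpec("COPY", (0,)), ps.GateSpec("COPY", (1,))])
        sub = ps.Subsystem(net, (1, 1))
        cut = sub.apply_cut(ps.Cut((0,), (1,)))
        for mech in ((), (0,), (1,), (0, 1)):
            for z in ((0,), (1,), (0, 1)):
                assert ps.cause_repertoire(cut, mech, z).dist == \
                    ps.cause_repertoire(sub, mech, z).dist
                assert ps.effect_repertoire(cut, mech, z).dist == \
                    ps.effect_repertoire(sub, mech, z).dist

    def test_cut_against_brute_force_conditional(self, and_or):
        # severing A->B leaves B' = OR(noise, B): ON w.p. 1/2 when B=0
        cut = and_or.apply_cut(ps.Cut((0,), (1,)))
        assert ps.effect_repertoire(cut, (1,), (1,)).dist == (F(1, 2), F(1, 2))


class TestConstellations:
    def test_and_or_is_non_unique(self, and_or):
        cess = enumerate_constellations(and_or)
        assert len(cess) > 1
        assert len(cess) == 81  # 9 variants for each of the two concept-bearing mechanisms

    def test_photodiode_is_unique(self, photodiode):
        assert len(enumerate_constellations(photodiode)) == 1

    def test_variant_counts_multiply_into_constellation_count(self, and_or):
        per_mech = [len(concept_variants(and_or, m)) for m in powerset_purviews(and_or)]
        product = 1
        for c in per_mech:
            if c:
                product *= c
        assert len(enumerate_constellations(and_or)) <= product

    def test_combinatorial_guard_raises_instead_of_truncating(self, and_or):
        with pytest.raises(CombinatorialGuardError):
            enumerate_constellations(and_or, cap=10)


class TestCesDistance:
    def test_single_concept_vs_null_constellation(self, and_or):
        variants = concept_variants(and_or, (A,))
        nc = null_concept(and_or)
        empty = Constellation((), and_or)
        big = next(v for v in variants
                   if (v.cause.purview, v.effect.purview) == ((A, B), (A, B)))
        small = next(v for v in variants
                     if (v.cause.purview, v.effect.purview) == ((A,), (A,)))
        assert ps.ces_distance(Constellation((big,), and_or), empty) == F(5, 36)
        assert ps.ces_distance(Constellation((small,), and_or), empty) == F(5, 72)

    def test_distance_to_self_is_zero(self, and_or):
        cess = enumerate_constellations(and_or)
        for ces in cess[:5]:
            assert ps.ces_distance(ces, ces) == 0

    def test_zero_iff_matched_concepts_identical(self, and_or):
        cess = enumerate_constellations(and_or)
        for c1 in cess[:6]:
            for c2 in cess[:6]:
                d = ps.ces_distance(c1, c2)
                if c1.key() == c2.key():
                    assert d == 0
                else:
                    assert d > 0


class TestPhiSpectrum:
    def test_and_or_spectrum_shape(self, and_or_spectrum):
        valid = and_or_spectrum.valid_phi_mip
        assert min(valid) == 0
        assert max(valid) == F(37, 72)
        assert F(5, 36) in valid and F(5, 72) in valid
        assert F(13, 144) in valid  # the reference implementation's selection
        assert len(valid) == 63

    def test_photodiode_spectrum_is_singleton_one_bit(self, photodiode):
        spec = ps.phi_spectrum(photodiode)
        assert all(vs == (1,) for vs in spec.values_per_cut)
        assert spec.valid_phi_mip == (1,)

    def test_disconnected_self_loop_pair_has_all_zero_spectrum(self):
        net = ps.build_network([ps.GateSpec("COPY", (0,)), ps.GateSpec("COPY", (1,))])
        spec = ps.phi_spectrum(ps.Subsystem(net, (1, 1)))
        assert spec.valid_phi_mip == (0,)

    def test_rational_and_float_spectra_agree_at_six_decimals(self, and_or_spectrum,
                                                              and_or_float):
        fspec = ps.phi_spectrum(and_or_float)
        for ev, fv in zip(and_or_spectrum.values_per_cut, fspec.values_per_cut):
            assert [round(float(x), 6) for x in ev] == [round(x, 6) for x in fv]

    def test_spectrum_respects_analytic_bound(self, and_or_spectrum, or_and_xor):
        assert max(and_or_spectrum.valid_phi_mip) <= analytic_bound(2)
        oax = ps.phi_spectrum(or_and_xor)
        assert max(oax.valid_phi_mip) <= analytic_bound(3)

    def test_or_and_xor_spectrum_contains_published_value(self, or_and_xor):
        valid = ps.phi_spectrum(or_and_xor).valid_phi_mip
        assert F(23, 12) in valid  # 1.916667 at the printed precision


class TestPhiMipSet:
    def test_worked_selection_rule_example(self):
        # per-cut values [0,1,2] and [1,2,3]: only 3 is excluded
        assert phi_mip_set([(0, 1, 2), (1, 2, 3)]) == (0, 1, 2)

    def test_identical_singletons(self):
        assert phi_mip_set([(5,), (5,)]) == (5,)

    def test_strict_variant_bounds_by_candidate_mips_only(self):
        # cut 0 attains the global minimum with a small max; a non-MIP cut's
        # larger values are excluded either way
        values = [(0, 1), (2, 3)]
        assert phi_mip_set(values) == (0, 1)
        assert phi_mip_set(values, strict=True) == (0, 1)

    def test_empty_spectrum_rejected(self):
        with pytest.raises(StateError):
            phi_mip_set([])


class TestPhiMaxOverSubsystems:
    def test_two_node_system_equals_single_subsystem_result(self, and_or):
        best, best_set, per_sub = ps.phi_max_over_subsystems(
            and_or.network, and_or.state)
        assert per_sub[(0, 1)] == ps.phi_spectrum(and_or).valid_phi_mip
        assert per_sub[(0,)] == (0,) and per_sub[(1,)] == (0,)
        assert best == (0, 1)

    def test_three_node_census_matches_direct_recomputation(self, or_and_xor):
        net = or_and_xor.network
        best, _, per_sub = ps.phi_max_over_subsystems(net, or_and_xor.state)
        for nodes in [(0, 1), (0, 2), (1, 2), (0, 1, 2)]:
            direct = ps.phi_spectrum(ps.Subsystem(net, or_and_xor.state, nodes))
            assert per_sub[nodes] == direct.valid_phi_mip

    def test_guard_on_large_networks(self):
        net = ps.get_network("fission_yeast")
        with pytest.raises(CombinatorialGuardError):
            ps.phi_max_over_subsystems(net, (0,) * 9)
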