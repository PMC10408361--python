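"""Network model: state conventions, gate construction, fixture integrity, I/O."""

from fractions import Fraction

import pytest

import phispectrum as ps
from phispectrum.errors import FormatError, StateError
from phispectrum.fixtures import FIXTURES, get_fixture, _pairs
from phispectrum.network import (GateSpec, Network, build_network,
                                 index_to_state, network_from_transition_pairs,
                                 parse_state, state_to_index, write_tpm)


class TestStateIndexing:
    def test_positional_encoding(self):
        # "10" = first node ON: MSB-left display code 2, canonical code 1
        assert state_to_index((1, 0), "big_endian_string") == 2
        assert state_to_index((1, 0), "little_endian_int") == 1

    def test_all_zero_state_is_zero_in_both_conventions(self):
        for conv in ("big_endian_string", "little_endian_int"):
            assert state_to_index((0,) * 5, conv) == 0

    @pytest.mark.parametrize("conv", ["big_endian_string", "little_endian_int"])
    def test_round_trip_is_identity_on_nine_node_space(self, conv):
        for i in range(512):
            assert state_to_index(index_to_state(i, 9, conv), conv) == i

    def test_non_binary_state_rejected(self):
        with pytest.raises(StateError):
            state_to_index((0, 2), "little_endian_int")
        with pytest.raises(StateError):
            parse_state("0x1")


class TestGateConstruction:
    def test_and_or_gates_reproduce_printed_table(self):
        fx = get_fixture("and_or")
        assert fx.build().next_states == network_from_transition_pairs(
            _pairs(fx.table)).next_states

    def test_three_majority_gates_reproduce_printed_table(self):
        fx = get_fixture("majority")
        assert fx.build().next_states == network_from_transition_pairs(
            _pairs(fx.table)).next_states

    def test_mutual_copy_gates_reproduce_photodiode_table(self):
        fx = get_fixture("photodiode")
        net = build_network(fx.gates, fx.labels)
        assert net.next_states == network_from_transition_pairs(_pairs(fx.table)).next_states

    def test_or_and_xor_gates_reproduce_printed_table(self):
        fx = get_fixture("or_and_xor")
        assert build_network(fx.gates).next_states == \
            network_from_transition_pairs(_pairs(fx.table)).next_states

    def test_noisy_and_quartet_matches_published_rows_at_two_decimals(self):
        # published dense TPM is printed at 2-decimal precision
        net = get_fixture("hoel_noisy_and").build(exact=True)
        rows = net.dense_tpm()
        assert all(sum(r) == 1 for r in rows)
        expected_row0 = [Fraction(7, 10) ** (4 - b.bit_count()) * Fraction(3, 10) ** b.bit_count()
                        for b in range(16)]
        assert rows[0] == expected_row0
        printed0 = [0.24, 0.10, 0.10, 0.04, 0.10, 0.04, 0.04, 0.02,
                    0.10, 0.04, 0.04, 0.02, 0.04, 0.02, 0.02, 0.01]
        assert [round(float(x), 2) for x in rows[0]] == printed0
        # a both-gates-on row: targets deterministic, sources noisy
        row3 = rows[3]  # nodes 0,1 ON
        assert [round(float(x), 2) for x in row3[12:]] == [0.49, 0.21, 0.21, 0.09]
        assert sum(row3[:12]) == 0

    def test_unknown_gate_kind_rejected(self):
        with pytest.raises(FormatError):
            GateSpec("NAND", (0, 1))


class TestFixtureIntegrity:
    @pytest.mark.parametrize("name", [n for n, f in FIXTURES.items()
                                      if f.table is not None and f.gates is not None])
    def test_gate_specs_match_printed_tables(self, name):
        fx = get_fixture(name)
        assert build_network(fx.gates, fx.labels).next_states == \
            network_from_transition_pairs(_pairs(fx.table)).next_states

    @pytest.mark.parametrize("name", [n for n, f in FIXTURES.items() if f.table])
    def test_printed_tables_are_deterministic_permutation_free_tpms(self, name):
        net = get_fixture(name).build()
        assert net.deterministic
        assert len(net.next_states) == 2 ** net.n
        assert all(0 <= s < 2 ** net.n for s in net.next_states)

    def test_fission_yeast_relaxes_to_its_g1_resting_state(self):
        from phispectrum.fixtures import FISSION_YEAST_G1, FISSION_YEAST_LATE_M
        net = get_fixture("fission_yeast").build(exact=False)
        g1 = ps.state_to_index(parse_state(FISSION_YEAST_G1))
        assert net.next_states[g1] == g1  # G1 is a fixed point
        s = ps.state_to_index(parse_state(FISSION_YEAST_LATE_M))
        s = net.next_states[net.next_states[s]]
        assert s == g1  # the late-M cycle state relaxes onto it in two updates

    def test_initial_states_consistent_with_network_sizes(self):
        for fx in FIXTURES.values():
            assert len(fx.initial_state) == fx.size
            assert set(fx.initial_state) <= {"0", "1"}


class TestIO:
    @pytest.mark.parametrize("dialect", ["transition_table_binary",
                                         "transition_table_int", "dense_matrix"])
    def test_round_trip_identity(self, tmp_path, dialect):
        net = get_fixture("or_and_xor").build(exact=(dialect != "dense_matrix"))
        path = tmp_path / "tpm.tsv"
        write_tpm(net, path, dialect)
        back = ps.load_tpm(path, dialect, exact=net.exact)
        assert back.node_probs == net.node_probs

    def test_and_or_table_loads_as_permutation_like_matrix(self, tmp_path):
        path = tmp_path / "and_or.tsv"
        path.write_text("00\t00\n10\t01\n01\t01\n11\t11\n")
        net = ps.load_tpm(path, "transition_table_binary")
        assert net.next_states == (0, 2, 2, 3)
        dense = net.dense_tpm()
        assert all(sorted(row, reverse=True)[0] == 1 for row in dense)

    def test_non_stochastic_dense_row_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("0.4,0.5\n0.5,0.5\n")
        with pytest.raises(FormatError):
            ps.load_tpm(path, "dense_matrix")

    def test_ragged_table_rejected(self, tmp_path):
        path = tmp_path / "ragged.tsv"
        path.write_text("00\t00\n10\t01\n11\t11\n")
        with pytest.raises(FormatError):
            ps.load_tpm(path, "transition_table_binary")

    def test_state_width_mismatch_rejected(self, tmp_path):
        path = tmp_path / "widths.tsv"
        path.write_text("00\t00\n100\t01\n")
        with pytest.raises(FormatError):
            ps.load_tpm(path, "transition_table_binary")


class TestConnectivityAndConditioning:
    def test_connectivity_derived_from_tpm(self):
        net = get_fixture("or_and_xor").build()
        # A=OR(B,C): B,C -> A; B=AND(A,C): A,C -> B; C=XOR(A,B): A,B -> C
        cm = net.connectivity
        assert [cm[i][0] for i in range(3)] == [False, True, True]
        assert [cm[i][1] for i in range(3)] == [True, False, True]
        assert [cm[i][2] for i in range(3)] == [True, True, False]

    def test_full_system_subsystem_matches_unconditioned_network(self, and_or):
        full = ps.condition_on_background(and_or.network, (0, 1), and_or.state)
        for mech in ((0,), (1,), (0, 1)):
            for z in ((0,), (1,), (0, 1)):
                assert ps.cause_repertoire(full, mech, z).dist == \
                    ps.cause_repertoire(and_or, mech, z).dist

    def test_frozen_background_turns_and_gate_into_copy(self):
        net = build_network([GateSpec("COPY", (0,)), GateSpec("COPY", (1,)),
                             GateSpec("AND", (0, 1))], ("A", "B", "C"))
        on = ps.Subsystem(net, (1, 1, 0), (0, 2))
        off = ps.Subsystem(net, (1, 0, 0), (0, 2))
        assert ps.effect_repertoire(on, (0,), (1,)).dist == (0, 1)   # copies A=1
        assert ps.effect_repertoire(off, (0,), (1,)).dist == (1, 0)  # stuck off

    def test_empty_subsystem_rejected(self):
        net = get_fixture("and_or").build()
        with pytest.raises(StateError):
            ps.Subsystem(net, (0, 0), ())
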