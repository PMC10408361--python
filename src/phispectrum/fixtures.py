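"""Programmatic construction of the ten published case-study systems.

Each fixture records the transition table exactly as published (binary-string
tables are big-endian: leftmost character = first listed node; the fission
yeast table is integer-coded little-endian), the published initial state, the
published Phi value, and -- where the wiring is unambiguous -- an equivalent
gate specification.  Everything is built in memory; nothing is downloaded.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Tuple

from .errors import StateError
from .network import (GateSpec, Network, build_network,
                      network_from_transition_pairs, parse_state)
from .subsystem import Subsystem

__all__ = ["Fixture", "FIXTURES", "get_fixture", "get_network", "get_subsystem",
           "fixture_names"]


def _pairs(table: str):
    rows = [ln.split() for ln in table.strip().splitlines()]
    return [(a, b) for a, b in rows]


# --- deterministic transition tables, as published (big-endian strings) ----

_PHOTODIODE = """
00 00
10 01
01 10
11 11
"""

_AND_OR = """
00 00
10 01
01 01
11 11
"""

_COUNTER = """
000 110
100 000
010 101
110 010
001 100
101 111
011 001
111 011
"""

_MAJ3 = """
000 000
100 000
010 000
110 111
001 000
101 111
011 111
111 111
"""

_P53_MDM2 = """
0000 1101
1000 1100
0100 1100
1100 1110
0010 1101
1010 1101
0110 1101
1110 1111
0001 0001
1001 0000
0101 0000
1101 0010
0011 0001
1011 0001
0111 0001
1111 0011
"""

_VIRUS_HOST_FULL = """
00000 00000
10000 00000
01000 10000
11000 10000
00100 01000
10100 01000
01100 11000
11100 11000
00010 00100
10010 00101
01010 10100
11010 10101
00110 01100
10110 01101
01110 11100
11110 11101
00001 00000
10001 00000
01001 10010
11001 10010
00101 01000
10101 01000
01101 11010
11101 11010
00011 00100
10011 00101
01011 10110
11011 10111
00111 01100
10111 01101
01111 11110
11111 11111
"""

_VIRUS_HOST_REDUCED = """
000 000
100 000
010 100
110 101
001 010
101 010
011 110
111 111
"""

_OR_AND_XOR = """
000 000
100 001
010 101
110 100
001 100
101 111
011 101
111 110
"""

_MAJ_OR_AND_AND = """
0000 0000
1000 0100
0100 0000
1100 1110
0010 0000
1010 1100
0110 1000
1110 1110
0001 0100
1001 0100
0101 0100
1101 1110
0011 0101
1011 1101
0111 1101
1111 1111
"""

# Nine-node fission yeast cell-cycle model; integer-coded little-endian
# (node 0 = least-significant bit), rows 0..511 in order.
_FISSION_YEAST_NEXT = tuple(int(x) for x in """
2 2 130 130 4 0 128 128 8 0 128 128 12 0 128 128 256 256 384 384 260 256 384
384 264 256 384 384 268 256 384 384 18 18 146 146 16 16 144 144 16 16 144 144
16 16 144 144 272 272 400 400 272 272 400 400 272 272 400 400 272 272 400 400
66 66 130 130 68 64 128 128 72 64 128 128 76 64 128 128 320 320 384 384 324
320 384 384 328 320 384 384 332 320 384 384 82 82 146 146 80 80 144 144 80 80
144 144 80 80 144 144 336 336 400 400 336 336 400 400 336 336 400 400 336 336
400 400 162 162 162 162 132 128 128 128 136 128 128 128 140 128 128 128 384
384 384 384 388 384 384 384 392 384 384 384 396 384 384 384 178 178 178 178
144 144 144 144 144 144 144 144 144 144 144 144 400 400 400 400 400 400 400
400 400 400 400 400 400 400 400 400 194 194 130 130 196 192 128 128 200 192
128 128 204 192 128 128 448 448 384 384 452 448 384 384 456 448 384 384 460
448 384 384 210 210 146 146 208 208 144 144 208 208 144 144 208 208 144 144
464 464 400 400 464 464 400 400 464 464 400 400 464 464 400 400 78 66 2 2 76
68 4 0 76 72 8 0 76 76 12 0 332 320 256 256 332 324 260 256 332 328 264 256
332 332 268 256 82 82 18 18 84 80 16 16 88 80 16 16 92 80 16 16 336 336 272
272 340 336 272 272 344 336 272 272 348 336 272 272 78 66 66 66 76 68 68 64 76
72 72 64 76 76 76 64 332 320 320 320 332 324 324 320 332 328 328 320 332 332
332 320 82 82 82 82 84 80 80 80 88 80 80 80 92 80 80 80 336 336 336 336 340
336 336 336 344 336 336 336 348 336 336 336 110 98 162 162 76 68 132 128 76 72
136 128 76 76 140 128 332 320 384 384 332 324 388 384 332 328 392 384 332 332
396 384 114 114 178 178 84 80 144 144 88 80 144 144 92 80 144 144 336 336 400
400 340 336 400 400 344 336 400 400 348 336 400 400 78 66 194 194 76 68 196
192 76 72 200 192 76 76 204 192 332 320 448 448 332 324 452 448 332 328 456
448 332 332 460 448 82 82 210 210 84 80 208 208 88 80 208 208 92 80 208 208
336 336 464 464 340 336 464 464 344 336 464 464 348 336 464 464
""".split())

_YEAST_LABELS = ("SK", "Cdc2/Cdc13", "Ste9", "Rum1", "Slp1",
                 "Cdc2/Cdc13*", "Wee1/Mik1", "Cdc25", "PP")

#: Three-node subsystem of the fission yeast network whose Phi spectrum is
#: analyzed, identified by matching the published Phi signature over all
#: candidate triples of the nine-node TPM: nodes 1, 2, 3 (Cdc2/Cdc13, Ste9,
#: Rum1 -- the G1/S antagonism trio).
FISSION_YEAST_SUBSYSTEM: Tuple[int, ...] = (1, 2, 3)

#: Analysis state: the model's stable G1 resting state (Ste9, Rum1 and
#: Wee1/Mik1 active).  The late-M cycle state 000110011 relaxes onto it in
#: two updates; only the resting state reproduces the published Phi value of
#: the three-node subsystem.
FISSION_YEAST_G1 = "001100100"
FISSION_YEAST_LATE_M = "000110011"


@dataclass(frozen=True)
class Fixture:
    """A published case-study system and the details needed to rerun it."""

    name: str
    description: str
    size: int
    initial_state: str           # big-endian string, leftmost char = node 0
    published_phi: Optional[float]
    dialect: str
    table: Optional[str] = None
    gates: Optional[tuple] = None
    labels: Optional[tuple] = None
    subsystem_nodes: Optional[tuple] = None
    tractable_spectrum: bool = True

    def build(self, exact: bool = True) -> Network:
        if self.name == "fission_yeast":
            return Network.from_transitions(_FISSION_YEAST_NEXT, self.labels,
                                            exact=exact)
        if self.table is not None:
            return network_from_transition_pairs(_pairs(self.table), self.labels,
                                                 binary=True, exact=exact)
        return build_network(self.gates, self.labels, exact=exact)

    def to_json(self):
        return {"name": self.name, "description": self.description,
                "size": self.size, "initial_state": self.initial_state,
                "published_phi": self.published_phi,
                "subsystem_nodes": list(self.subsystem_nodes) if self.subsystem_nodes else None,
                "tractable_spectrum": self.tractable_spectrum}


_HOEL_GATES = (
    GateSpec("NOISY_AND", (2, 3), Fraction(3, 10)),
    GateSpec("NOISY_AND", (2, 3), Fraction(3, 10)),
    GateSpec("NOISY_AND", (0, 1), Fraction(3, 10)),
    GateSpec("NOISY_AND", (0, 1), Fraction(3, 10)),
)

FIXTURES = {f.name: f for f in (
    Fixture("photodiode", "COPY+COPY photodiode", 2, "10", 1.0000,
            "transition_table_binary", table=_PHOTODIODE, labels=("A", "B"),
            gates=(GateSpec("COPY", (1,)), GateSpec("COPY", (0,)))),
    Fixture("and_or", "fully connected AND+OR pair", 2, "00", 0.0903,
            "transition_table_binary", table=_AND_OR, labels=("A", "B"),
            gates=(GateSpec("AND", (0, 1)), GateSpec("OR", (0, 1)))),
    Fixture("counter", "mod-eight digital counter", 3, "101", 1.7187,
            "transition_table_binary", table=_COUNTER, labels=("A", "B", "C"),
            tractable_spectrum=False),
    Fixture("majority", "three fully connected majority gates", 3, "000", None,
            "transition_table_binary", table=_MAJ3, labels=("A", "B", "C"),
            gates=(GateSpec("MAJ", (0, 1, 2)), GateSpec("MAJ", (0, 1, 2)),
                   GateSpec("MAJ", (0, 1, 2)))),
    Fixture("p53_mdm2", "binarized p53-Mdm2 regulatory network", 4, "0001", 0.2153,
            "transition_table_binary", table=_P53_MDM2,
            labels=("P", "Mn", "Mc", "Dam"), tractable_spectrum=False),
    Fixture("virus_host_full", "virus-host Boolean network (full, 5 nodes)", 5,
            "11111", 0.3125, "transition_table_binary", table=_VIRUS_HOST_FULL,
            labels=("V", "X1", "X2", "X3", "X4"), tractable_spectrum=False),
    Fixture("virus_host_reduced", "virus-host Boolean network (reduced, 3 nodes)",
            3, "111", 0.4375, "transition_table_binary",
            table=_VIRUS_HOST_REDUCED, labels=("V", "X1", "X2")),
    Fixture("or_and_xor", "canonical OR+AND+XOR demonstration system", 3, "100",
            1.9167, "transition_table_binary", table=_OR_AND_XOR,
            labels=("A", "B", "C"),
            gates=(GateSpec("OR", (1, 2)), GateSpec("AND", (0, 2)),
                   GateSpec("XOR", (0, 1)))),
    Fixture("maj_or_and_and", "MAJORITY+OR+AND+AND system", 4, "1110", 0.6597,
            "transition_table_binary", table=_MAJ_OR_AND_AND,
            labels=("A", "B", "C", "D"), tractable_spectrum=False),
    Fixture("hoel_noisy_and", "four interconnected AND gates with noisy input",
            4, "0000", 0.1139, "dense_matrix", gates=_HOEL_GATES,
            labels=("A", "B", "C", "D"), tractable_spectrum=False),
    Fixture("fission_yeast", "nine-node fission yeast cell-cycle model "
            "(three-node subsystem analyzed in the G1 resting state)", 9,
            FISSION_YEAST_G1, 0.0903, "transition_table_int",
            labels=_YEAST_LABELS, subsystem_nodes=FISSION_YEAST_SUBSYSTEM),
)}


def fixture_names():
    return tuple(FIXTURES)


def get_fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]
    except KeyError:
        raise StateError(f"unknown fixture {name!r}; known: {fixture_names()}")


def get_network(name: str, exact: bool = True) -> Network:
    return get_fixture(name).build(exact=exact)


def get_subsystem(name: str, exact: bool = True) -> Subsystem:
    """The fixture's analyzed subsystem in its published initial state."""
    fx = get_fixture(name)
    net = fx.build(exact=exact)
    state = parse_state(fx.initial_state)
    return Subsystem(net, state, fx.subsystem_nodes)
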