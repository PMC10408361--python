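"""Candidate subsystems: background conditioning and unidirectional cuts.

A :class:`Subsystem` is a subset of network nodes evaluated in a fixed global
state.  Nodes outside the subset (the *background*) are frozen at their state
values during every repertoire computation.  A unidirectional :class:`Cut`
severs all connections from one part of the subsystem into the other,
replacing the severed inputs with independent maximum-entropy noise.

All downstream machinery (repertoires, concepts, constellations) reads the
system exclusively through :meth:`Subsystem.prob_on`, the per-node activation
table over joint subsystem states, so cuts and background freezing compose
transparently.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Tuple

from .errors import StateError
from .network import Network, parse_state

__all__ = ["Cut", "Subsystem", "condition_on_background"]


@dataclass(frozen=True)
class Cut:
    """Sever connections from ``severed_from`` into ``severed_to`` (network indices)."""

    severed_from: tuple
    severed_to: tuple

    def __post_init__(self):
        object.__setattr__(self, "severed_from", tuple(sorted(self.severed_from)))
        object.__setattr__(self, "severed_to", tuple(sorted(self.severed_to)))
        if not self.severed_from or not self.severed_to:
            raise StateError("cut parts must be non-empty")
        if set(self.severed_from) & set(self.severed_to):
            raise StateError("cut parts must be disjoint")

    def __str__(self):
        return f"{self.severed_from} --/--> {self.severed_to}"


class Subsystem:
    """A candidate set of nodes in a fixed state, with optional cut applied."""

    def __init__(self, network: Network, state, nodes: Optional[Sequence[int]] = None,
                 cut: Optional[Cut] = None):
        if isinstance(state, str):
            state = parse_state(state)
        state = tuple(state)
        if len(state) != network.n or any(v not in (0, 1) for v in state):
            raise StateError(f"state {state!r} inconsistent with network of size {network.n}")
        if nodes is None:
            nodes = tuple(range(network.n))
        nodes = tuple(sorted(set(nodes)))
        if not nodes:
            raise StateError("subsystem node set must be non-empty")
        if any(not 0 <= i < network.n for i in nodes):
            raise StateError(f"subsystem nodes {nodes} not all in network")
        if cut is not None:
            allnodes = set(cut.severed_from) | set(cut.severed_to)
            if not allnodes <= set(nodes):
                raise StateError("cut refers to nodes outside the subsystem")
        self.network = network
        self.state = state
        self.nodes = nodes
        self.cut = cut
        self.exact = network.exact
        self.k = len(nodes)
        self._tables = self._build_tables()

    # ------------------------------------------------------------------

    def _row_index(self, sub_state: int) -> int:
        """Canonical full-network row for a joint subsystem state code."""
        row = 0
        for pos, j in enumerate(self.nodes):
            if (sub_state >> pos) & 1:
                row |= 1 << j
        for j in range(self.network.n):
            if j not in self._node_set and self.state[j]:
                row |= 1 << j
        return row

    def _build_tables(self):
        self._node_set = set(self.nodes)
        size = 1 << self.k
        raw = []
        for pos, j in enumerate(self.nodes):
            tab = [self.network.node_probs[j][self._row_index(s)] for s in range(size)]
            raw.append(tab)
        if self.cut is None:
            return raw
        # Noise severed inputs: average each target's table over the severed
        # source bits, uniformly and independently of their actual values.
        src_pos = [self.nodes.index(i) for i in self.cut.severed_from]
        tgt_pos = {self.nodes.index(i) for i in self.cut.severed_to}
        tables = []
        norm = Fraction(1, 1 << len(src_pos)) if self.exact else 1.0 / (1 << len(src_pos))
        for pos in range(self.k):
            if pos not in tgt_pos:
                tables.append(raw[pos])
                continue
            tab = []
            for s in range(size):
                total = 0
                for assign in range(1 << len(src_pos)):
                    s2 = s
                    for b, sp in enumerate(src_pos):
                        if (assign >> b) & 1:
                            s2 |= 1 << sp
                        else:
                            s2 &= ~(1 << sp)
                    total += raw[pos][s2]
                tab.append(total * norm)
            tables.append(tab)
        return tables

    # ------------------------------------------------------------------

    def prob_on(self, pos: int, sub_state: int):
        """p(subsystem node at position ``pos`` is ON at t+1 | joint state code)."""
        return self._tables[pos][sub_state]

    def node_state(self, pos: int) -> int:
        """Current state of the subsystem node at position ``pos``."""
        return self.state[self.nodes[pos]]

    @property
    def positions(self) -> Tuple[int, ...]:
        """Within-subsystem positions ``0..k-1`` (mechanisms/purviews use these)."""
        return tuple(range(self.k))

    def labels(self, positions) -> tuple:
        return tuple(self.network.node_labels[self.nodes[p]] for p in positions)

    def apply_cut(self, cut: Cut) -> "Subsystem":
        return Subsystem(self.network, self.state, self.nodes, cut=cut)

    def __repr__(self):
        lbl = ",".join(self.labels(self.positions))
        cut = f" cut={self.cut}" if self.cut else ""
        return f"<Subsystem [{lbl}] state={''.join(map(str, self.state))}{cut}>"


def condition_on_background(network: Network, nodes, state) -> Subsystem:
    """Freeze the complement of ``nodes`` at its values in ``state``."""
    return Subsystem(network, state, nodes)
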