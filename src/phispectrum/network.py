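"""Discrete networks: TPMs, state-index conventions, gate-based construction, I/O.

A :class:`Network` holds a row-stochastic transition probability matrix (TPM)
over the ``2**n`` joint states of ``n`` binary nodes.  Internally the TPM is
kept in *state-by-node* form: for every node ``j`` and every current global
state we store ``p(j = 1 at t+1)``.  This form is exactly equivalent to the
dense ``2**n x 2**n`` matrix whenever nodes update conditionally independently
given the current state -- the standing assumption of the causal calculus
implemented here -- and it is the natural substrate for mechanism clamping,
input noising and unidirectional cuts.

State conventions
-----------------
* A *state* is a tuple of 0/1 values aligned with ``node_labels`` (node 0
  first).  State *strings* are written with node 0 as the leftmost character.
* The canonical integer index of a state puts node 0 in the least-significant
  bit (``little_endian_int``).  Published tables that order states "with the
  most significant digit on the left" are big-endian in this vocabulary and
  are converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence

from .errors import FormatError, StateError

__all__ = [
    "state_to_index",
    "index_to_state",
    "parse_state",
    "state_string",
    "Network",
    "GateSpec",
    "build_network",
    "load_tpm",
    "write_tpm",
]


# ---------------------------------------------------------------------------
# state/index conversions
# ---------------------------------------------------------------------------

_CONVENTIONS = ("little_endian_int", "big_endian_string")


def _check_state(state: Sequence[int]) -> tuple:
    state = tuple(state)
    if not all(v in (0, 1) for v in state):
        raise StateError(f"non-binary state values: {state!r}")
    return state


def state_to_index(state: Sequence[int], convention: str = "little_endian_int") -> int:
    """Integer code of a node-state tuple under the named convention.

    ``little_endian_int`` (canonical): node 0 is the least-significant bit.
    ``big_endian_string``: node 0 is the most-significant digit, as in
    published tables that list states ``00, 01, 10, 11``.
    """
    state = _check_state(state)
    if convention == "little_endian_int":
        return sum(v << i for i, v in enumerate(state))
    if convention == "big_endian_string":
        n = len(state)
        return sum(v << (n - 1 - i) for i, v in enumerate(state))
    raise ValueError(f"unknown convention {convention!r}; expected one of {_CONVENTIONS}")


def index_to_state(index: int, n: int, convention: str = "little_endian_int") -> tuple:
    """Inverse of :func:`state_to_index`."""
    if not 0 <= index < (1 << n):
        raise StateError(f"index {index} out of range for {n} nodes")
    bits = [(index >> i) & 1 for i in range(n)]
    if convention == "little_endian_int":
        return tuple(bits)
    if convention == "big_endian_string":
        return tuple(reversed(bits))
    raise ValueError(f"unknown convention {convention!r}; expected one of {_CONVENTIONS}")


def parse_state(s: str) -> tuple:
    """Parse a state string (leftmost character = node 0) into a tuple."""
    if not s or any(c not in "01" for c in s):
        raise StateError(f"invalid state string {s!r}")
    return tuple(int(c) for c in s)


def state_string(state: Sequence[int]) -> str:
    return "".join(str(v) for v in _check_state(state))


def _to_paper_index(i: int, n: int) -> int:
    """Map a canonical index to the big-endian display index (bit reversal)."""
    return state_to_index(index_to_state(i, n), "big_endian_string")


def reorder_to_paper(dist: Sequence, n: int) -> tuple:
    """Reorder a canonical-order distribution into big-endian display order."""
    out = [None] * len(dist)
    for i, p in enumerate(dist):
        out[_to_paper_index(i, n)] = p
    return tuple(out)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class Network:
    """A discrete network of binary nodes with a row-stochastic TPM.

    Parameters
    ----------
    node_probs : per-node activation tables, ``node_probs[j][row]`` giving
        ``p(node j is ON at t+1 | canonical state index row)``.
    node_labels : ordered node symbols.
    exact : if True the tables hold :class:`fractions.Fraction` entries.
    next_states : canonical next-state index per row, for deterministic nets.
    """

    def __init__(self, node_probs, node_labels=None, *, exact=True,
                 next_states=None, connectivity=None):
        self.n = len(node_probs)
        size = 1 << self.n
        for j, tab in enumerate(node_probs):
            if len(tab) != size:
                raise FormatError(f"node {j} table has {len(tab)} rows, expected {size}")
        self.exact = bool(exact)
        conv = (lambda x: Fraction(x)) if self.exact else float
        self.node_probs = [tuple(conv(p) for p in tab) for tab in node_probs]
        self.node_labels = tuple(node_labels) if node_labels else tuple(
            chr(ord("A") + j) if self.n <= 26 else f"n{j}" for j in range(self.n))
        if len(self.node_labels) != self.n:
            raise FormatError("node_labels length does not match number of nodes")
        self.next_states = tuple(next_states) if next_states is not None else None
        self._connectivity = connectivity

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_transitions(cls, next_states: Sequence[int], node_labels=None, *, exact=True):
        """Deterministic network from a canonical next-state array."""
        size = len(next_states)
        n = size.bit_length() - 1
        if 1 << n != size:
            raise FormatError(f"transition array length {size} is not a power of two")
        for row, nxt in enumerate(next_states):
            if not 0 <= nxt < size:
                raise FormatError(f"row {row}: next state {nxt} out of range")
        node_probs = [[(next_states[row] >> j) & 1 for row in range(size)]
                      for j in range(n)]
        return cls(node_probs, node_labels, exact=exact, next_states=next_states)

    @classmethod
    def from_dense(cls, rows, node_labels=None, *, exact=False, atol=1e-6):
        """Network from a dense ``2**n x 2**n`` row-stochastic matrix.

        Rows/columns are indexed canonically (node 0 = least-significant bit).
        """
        size = len(rows)
        n = size.bit_length() - 1
        if 1 << n != size:
            raise FormatError(f"dense TPM has {size} rows; not a power of two")
        node_probs = [[None] * size for _ in range(n)]
        deterministic = True
        next_states = []
        for r, row in enumerate(rows):
            if len(row) != size:
                raise FormatError(f"row {r} has {len(row)} entries, expected {size}")
            row = [Fraction(x) if exact else float(x) for x in row]
            total = sum(row)
            if exact:
                if total != 1:
                    raise FormatError(f"row {r} sums to {total}, not 1")
            elif abs(total - 1.0) > atol:
                raise FormatError(f"row {r} sums to {total:.6g}, not 1")
            if any((x < 0) or (x > 1) for x in row):
                raise FormatError(f"row {r} has probabilities outside [0,1]")
            ones = [c for c, x in enumerate(row) if x == 1]
            if len(ones) == 1 and sum(row) == 1:
                next_states.append(ones[0])
            else:
                deterministic = False
            for j in range(n):
                node_probs[j][r] = sum(x for c, x in enumerate(row) if (c >> j) & 1)
        return cls(node_probs, node_labels, exact=exact,
                   next_states=next_states if deterministic else None)

    # -- basic properties ---------------------------------------------------

    @property
    def size(self) -> int:
        return 1 << self.n

    @property
    def deterministic(self) -> bool:
        return self.next_states is not None or all(
            p in (0, 1) for tab in self.node_probs for p in tab)

    def dense_tpm(self):
        """Dense TPM rows (product of per-node marginals)."""
        size = self.size
        one = Fraction(1) if self.exact else 1.0
        rows = []
        for r in range(size):
            row = []
            for c in range(size):
                p = one
                for j in range(self.n):
                    pj = self.node_probs[j][r]
                    p *= pj if (c >> j) & 1 else (one - pj)
                row.append(p)
            rows.append(row)
        return rows

    @property
    def connectivity(self):
        """Boolean matrix: entry (i, j) is True iff node i influences node j.

        Derived from the TPM when not supplied: j depends on i iff flipping i
        in some state changes j's activation probability.
        """
        if self._connectivity is None:
            cm = [[False] * self.n for _ in range(self.n)]
            for i in range(self.n):
                bit = 1 << i
                for j in range(self.n):
                    tab = self.node_probs[j]
                    if any(tab[r] != tab[r | bit] for r in range(self.size)
                           if not r & bit):
                        cm[i][j] = True
            self._connectivity = cm
        return self._connectivity

    def to_mode(self, exact: bool) -> "Network":
        """Return this network converted to the requested arithmetic mode."""
        if exact == self.exact:
            return self
        return Network(self.node_probs, self.node_labels, exact=exact,
                       next_states=self.next_states)

    def __repr__(self):
        kind = "deterministic" if self.deterministic else "stochastic"
        return f"<Network n={self.n} labels={self.node_labels} {kind}>"


# ---------------------------------------------------------------------------
# Gate-based construction
# ---------------------------------------------------------------------------

_GATES = ("AND", "OR", "XOR", "COPY", "MAJ", "NOISY_AND")


@dataclass(frozen=True)
class GateSpec:
    """Update rule for one node: a named gate reading a list of input nodes.

    ``NOISY_AND`` fires with certainty when all inputs are ON and with
    probability ``noise`` otherwise (asymmetric input noise).
    """

    kind: str
    inputs: tuple
    noise: Optional[Fraction] = None

    def __post_init__(self):
        if self.kind not in _GATES:
            raise FormatError(f"unknown gate kind {self.kind!r}; expected one of {_GATES}")
        object.__setattr__(self, "inputs", tuple(self.inputs))

    def activation(self, state: Sequence[int]):
        """p(node ON at t+1 | global state), as an int or Fraction."""
        vals = [state[i] for i in self.inputs]
        if self.kind == "AND":
            return int(all(vals))
        if self.kind == "OR":
            return int(any(vals))
        if self.kind == "XOR":
            return sum(vals) % 2
        if self.kind == "COPY":
            if len(vals) != 1:
                raise FormatError("COPY gate takes exactly one input")
            return vals[0]
        if self.kind == "MAJ":
            return int(2 * sum(vals) > len(vals))
        # NOISY_AND
        p = Fraction(self.noise) if self.noise is not None else Fraction(0)
        return 1 if all(vals) else p


def build_network(specs: Sequence[GateSpec], node_labels=None, *, exact=True) -> Network:
    """Evaluate one gate per node on every global state to produce the TPM."""
    n = len(specs)
    for spec in specs:
        for i in spec.inputs:
            if not 0 <= i < n:
                raise FormatError(f"gate input {i} does not exist (n={n})")
    size = 1 << n
    node_probs = []
    for spec in specs:
        tab = []
        for r in range(size):
            state = index_to_state(r, n)
            p = spec.activation(state)
            tab.append(p if exact else float(p))
        node_probs.append(tab)
    net = Network(node_probs, node_labels, exact=exact)
    if net.deterministic:
        nxt = []
        for r in range(size):
            nxt.append(sum((1 << j) for j in range(n) if net.node_probs[j][r] == 1))
        net.next_states = tuple(nxt)
    return net


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("transition_table_binary", "transition_table_int", "dense_matrix")


def _split_row(line: str):
    line = line.strip()
    if not line:
        return None
    for sep in ("\t", ","):
        if sep in line:
            return [f.strip() for f in line.split(sep)]
    return line.split()


def network_from_transition_pairs(pairs, node_labels=None, *, binary=True, exact=True,
                                  n=None) -> Network:
    """Build a deterministic Network from (s(t), s(t+1)) pairs.

    ``binary=True``: states are strings, leftmost character = node 0.
    ``binary=False``: states are canonical little-endian integers and ``n``
    must be given (or is inferred from the largest index).
    """
    if binary:
        widths = {len(str(a)) for a, _ in pairs} | {len(str(b)) for _, b in pairs}
        if len(widths) != 1:
            raise FormatError(f"state-width mismatch across rows: widths {sorted(widths)}")
        n = widths.pop()
        coded = [(state_to_index(parse_state(str(a))), state_to_index(parse_state(str(b))))
                 for a, b in pairs]
    else:
        coded = [(int(a), int(b)) for a, b in pairs]
        if n is None:
            n = max(max(a, b) for a, b in coded).bit_length()
    size = 1 << n
    nxt = [None] * size
    for row, (a, b) in enumerate(coded):
        if not (0 <= a < size and 0 <= b < size):
            raise FormatError(f"row {row}: state out of range for n={n}")
        if nxt[a] is not None and nxt[a] != b:
            raise FormatError(f"row {row}: duplicate source state {a} with conflicting target")
        nxt[a] = b
    missing = [i for i, v in enumerate(nxt) if v is None]
    if missing:
        raise FormatError(f"transition table is ragged: missing source states {missing[:5]}")
    return Network.from_transitions(nxt, node_labels, exact=exact)


def load_tpm(path, dialect: str, node_labels=None, *, exact=None) -> Network:
    """Read a TPM file under the declared dialect and return a Network."""
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    with open(path) as fh:
        rows = [r for r in (_split_row(line) for line in fh) if r]
    if rows and not rows[0][0].lstrip("-").replace(".", "").isdigit() \
            and dialect == "dense_matrix":
        rows = rows[1:]  # header line
    if rows and rows[0][0] in ("s(t)", "st", "s"):
        rows = rows[1:]
    if dialect == "dense_matrix":
        exact = False if exact is None else exact
        return Network.from_dense([[Fraction(x) if exact else float(x) for x in r]
                                   for r in rows], node_labels, exact=exact)
    exact = True if exact is None else exact
    for i, r in enumerate(rows):
        if len(r) != 2:
            raise FormatError(f"row {i}: expected two columns, got {len(r)}")
    binary = dialect == "transition_table_binary"
    return network_from_transition_pairs([(r[0], r[1]) for r in rows],
                                         node_labels, binary=binary, exact=exact)


def write_tpm(network: Network, path, dialect: str = None):
    """Write a Network's TPM; round-trips with :func:`load_tpm`."""
    if dialect is None:
        dialect = "transition_table_binary" if network.deterministic else "dense_matrix"
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        if dialect == "dense_matrix":
            for row in network.dense_tpm():
                fh.write("\t".join(repr(float(x)) if not network.exact else str(x)
                                   for x in row) + "\n")
            return
        if network.next_states is None:
            raise FormatError("transition-table dialects require a deterministic network")
        for r, nxt in enumerate(network.next_states):
            if dialect == "transition_table_binary":
                fh.write(f"{state_string(index_to_state(r, network.n))}\t"
                         f"{state_string(index_to_state(nxt, network.n))}\n")
            else:
                fh.write(f"{r}\t{nxt}\n")
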