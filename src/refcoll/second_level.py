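"""Second-level Ziv–Lempel factoring over first-level tuple streams.

Collections of near-identical genomes factor into near-identical tuple
streams: the same run of (literal, match, literal, ...) tuples shows up in
sequence after sequence wherever two genomes carry the same variants.  The
second level exploits this by replacing a run of tuples in L^k with a
single reference to an identical run in an earlier stream L^u.

Runs are weighed, not counted: a literal tuple weighs 1 and a first-level
match tuple weighs ``match_weight`` (7 by default, reflecting its encoded
cost), and a second-level match must reach weight ``h2``.  The search
structure indexes, for every position of every eligible earlier stream,
the *shortest* run starting there whose weight reaches ``h2``; both sides
derive keys by the same rule, so identical tuple content always collides.
Matches require full-field tuple equality — the run is copied verbatim on
decompression, so any weaker equivalence would break losslessness.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

from ._util import MASK64
from .first_level import L1Sequence, L1Tuple, TAG_LITERAL, TAG_L1_MATCH

__all__ = [
    "TAG_L2_MATCH",
    "DEFAULT_MATCH_WEIGHT",
    "L2Tuple",
    "TupleIndex",
    "tuple_weight",
    "index_tuple_sequence",
    "factor_tuple_sequence",
    "reconstruct_tuple_sequence",
]

TAG_L2_MATCH = 2
DEFAULT_MATCH_WEIGHT = 7

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3


class L2Tuple(NamedTuple):
    """Passthrough first-level tuple or a second-level (run copy) match."""

    tag: int
    passthrough: Optional[L1Tuple] = None
    seq_id: int = -1
    tuple_pos: int = -1
    tuple_len: int = 0

    @staticmethod
    def wrap(t: L1Tuple) -> "L2Tuple":
        return L2Tuple(t.tag, passthrough=t)

    @staticmethod
    def match(seq_id: int, tuple_pos: int, tuple_len: int) -> "L2Tuple":
        return L2Tuple(TAG_L2_MATCH, seq_id=seq_id, tuple_pos=tuple_pos,
                       tuple_len=tuple_len)


def tuple_weight(t: L1Tuple, match_weight: int = DEFAULT_MATCH_WEIGHT) -> int:
    """Encoding-cost proxy: 1 for a literal, ``match_weight`` for a match."""
    return 1 if t.tag == TAG_LITERAL else match_weight


def _run_key(tuples: list[L1Tuple], start: int, stop: int) -> bytes:
    """Canonical byte serialization of ``tuples[start:stop]``."""
    parts = []
    for t in tuples[start:stop]:
        if t.tag == TAG_LITERAL:
            parts.append("L" + t.symbol)
        else:
            parts.append(f"M{t.pos},{t.length}")
    return ";".join(parts).encode("ascii")


def _fnv1a(data: bytes) -> int:
    h = _FNV_OFFSET
    for b in data:
        h = ((h ^ b) * _FNV_PRIME) & MASK64
    return h


class _LinearProbingTable:
    """Open-addressing hash table (linear probing, power-of-two capacity).

    Maps byte-string keys to lists of values; the per-key list is capped
    at ``cap_per_key`` most recent entries to bound candidate scans on
    pathological repeats.  Grows at load factor 0.7.
    """

    def __init__(self, cap_per_key: int = 64):
        self._capacity = 64
        self._keys: list[bytes | None] = [None] * self._capacity
        self._vals: list[list | None] = [None] * self._capacity
        self._n_keys = 0
        self.cap_per_key = cap_per_key

    def _probe(self, key: bytes) -> int:
        mask = self._capacity - 1
        idx = _fnv1a(key) & mask
        keys = self._keys
        while keys[idx] is not None and keys[idx] != key:
            idx = (idx + 1) & mask
        return idx

    def _grow(self) -> None:
        old_keys, old_vals = self._keys, self._vals
        self._capacity <<= 1
        self._keys = [None] * self._capacity
        self._vals = [None] * self._capacity
        for k, v in zip(old_keys, old_vals):
            if k is not None:
                idx = self._probe(k)
                self._keys[idx] = k
                self._vals[idx] = v

    def append(self, key: bytes, value) -> None:
        idx = self._probe(key)
        if self._keys[idx] is None:
            self._keys[idx] = key
            self._vals[idx] = [value]
            self._n_keys += 1
            if self._n_keys > 0.7 * self._capacity:
                self._grow()
        else:
            lst = self._vals[idx]
            lst.append(value)
            if len(lst) > self.cap_per_key:
                del lst[0]

    def get(self, key: bytes) -> list:
        idx = self._probe(key)
        return self._vals[idx] if self._keys[idx] is not None else []


class TupleIndex:
    """Search structure over previously processed first-level streams."""

    def __init__(self, h2: int, match_weight: int = DEFAULT_MATCH_WEIGHT,
                 candidates_per_key: int = 64):
        if h2 < 1:
            raise ValueError("h2 must be positive")
        self.h2 = h2
        self.match_weight = match_weight
        self._table = _LinearProbingTable(candidates_per_key)
        self._indexed: set[int] = set()

    def shortest_qualifying_run(
        self, tuples: list[L1Tuple], start: int
    ) -> int | None:
        """Exclusive end of the shortest run at ``start`` with weight >= h2."""
        w = 0
        mw = self.match_weight
        for j in range(start, len(tuples)):
            w += 1 if tuples[j].tag == TAG_LITERAL else mw
            if w >= self.h2:
                return j + 1
        return None

    def insert(self, l1: L1Sequence, seq_id: int) -> None:
        """Index every position of ``l1`` (call after its own factoring)."""
        if seq_id in self._indexed:
            raise ValueError(f"sequence {seq_id} already indexed")
        self._indexed.add(seq_id)
        tuples = l1.tuples
        for i in range(len(tuples)):
            stop = self.shortest_qualifying_run(tuples, i)
            if stop is None:
                break  # runs only get lighter toward the tail
            self._table.append(_run_key(tuples, i, stop), (seq_id, i))

    def candidates(self, tuples: list[L1Tuple], start: int) -> list[tuple[int, int]]:
        """(seq_id, tuple_pos) entries whose indexed run matches here."""
        stop = self.shortest_qualifying_run(tuples, start)
        if stop is None:
            return []
        return self._table.get(_run_key(tuples, start, stop))


def index_tuple_sequence(index: TupleIndex, l1: L1Sequence, seq_id: int) -> None:
    index.insert(l1, seq_id)


def factor_tuple_sequence(
    l1: L1Sequence,
    index: TupleIndex,
    prior: dict[int, L1Sequence],
) -> list[L2Tuple]:
    """Greedy maximal-weight parse of ``l1`` against indexed prior streams.

    At each tuple position every candidate run is extended tuple-by-tuple
    (full-field equality) as far as it goes; the heaviest extension is
    emitted as a second-level match, otherwise the tuple passes through.
    Ties go to the largest seq_id (most recent stream, which keeps the
    position predictor warm), then the smallest tuple position.  With an
    empty index the output is the input (D^1 = L^1).
    """
    tuples = l1.tuples
    n = len(tuples)
    out: list[L2Tuple] = []
    i = 0
    while i < n:
        best_len = 0
        best: tuple[int, int] | None = None
        for seq_id, pos in index.candidates(tuples, i):
            other = prior[seq_id].tuples
            limit = min(n - i, len(other) - pos)
            length = 0
            while length < limit and tuples[i + length] == other[pos + length]:
                length += 1
            if length > best_len:
                best_len, best = length, (seq_id, pos)
            elif length == best_len and best is not None:
                if (seq_id, -pos) > (best[0], -best[1]):
                    best = (seq_id, pos)
        if best is not None:
            out.append(L2Tuple.match(best[0], best[1], best_len))
            i += best_len
        else:
            out.append(L2Tuple.wrap(tuples[i]))
            i += 1
    return out


def reconstruct_tuple_sequence(
    d: list[L2Tuple], prior: dict[int, L1Sequence]
) -> L1Sequence:
    """Expand second-level matches by verbatim copy from prior streams."""
    out: list[L1Tuple] = []
    for t in d:
        if t.tag == TAG_L2_MATCH:
            src = prior[t.seq_id].tuples
            if t.tuple_pos < 0 or t.tuple_pos + t.tuple_len > len(src):
                raise ValueError(
                    f"corrupt second-level match into sequence {t.seq_id}: "
                    f"({t.tuple_pos}, {t.tuple_len}) outside {len(src)} tuples"
                )
            out.extend(src[t.tuple_pos : t.tuple_pos + t.tuple_len])
        else:
            out.append(t.passthrough)
    return L1Sequence(out)
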