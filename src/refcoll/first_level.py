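"""First-level Ziv–Lempel (LZSS) factoring against the reference.

Each collection sequence is parsed greedily left to right into literals and
reference matches.  A match found via the k-mer table must be at least
``h1m`` symbols long.  Immediately after any match the parser additionally
probes for the continuation pattern a sequencing variant would leave —
a substitution, or a 1–2 symbol insertion or deletion — and accepts the
resumed match down to a much shorter minimum ``h1e``.  These short
post-variant matches are cheap to encode because their position is exactly
predictable from the previous match, which is why the parser prefers them
on ties.  Short matches chain: a post-variant match re-arms the check, so
runs of nearby variants are handled without returning to the hash table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from ._util import longest_common_extension
from .reference_index import ReferenceIndex

__all__ = [
    "TAG_LITERAL",
    "TAG_L1_MATCH",
    "L1Tuple",
    "L1Sequence",
    "factor_sequence",
    "try_variant_extension",
    "reconstruct_sequence",
]

TAG_LITERAL = 0
TAG_L1_MATCH = 1


class L1Tuple(NamedTuple):
    """A literal (1 symbol) or a reference match (pos, length)."""

    tag: int
    symbol: str = ""
    pos: int = -1
    length: int = 0

    @property
    def coverage(self) -> int:
        """Number of sequence symbols this tuple represents."""
        return 1 if self.tag == TAG_LITERAL else self.length

    @staticmethod
    def literal(symbol: str) -> "L1Tuple":
        return L1Tuple(TAG_LITERAL, symbol=symbol)

    @staticmethod
    def match(pos: int, length: int) -> "L1Tuple":
        return L1Tuple(TAG_L1_MATCH, pos=pos, length=length)


@dataclass
class L1Sequence:
    """The tuple stream L^k for one collection sequence."""

    tuples: list[L1Tuple] = field(default_factory=list)

    @property
    def covered(self) -> int:
        return sum(t.coverage for t in self.tuples)

    def __len__(self) -> int:
        return len(self.tuples)

    def __iter__(self):
        return iter(self.tuples)


# Variant probes: (ref offset past match end, seq offset, #literal symbols).
# A substitution consumes one sequence symbol and one reference symbol; an
# insertion consumes sequence symbols only; a deletion reference symbols only.
_VARIANTS_3 = (
    (1, 1, 1),  # substitution (SNP)
    (0, 1, 1),  # 1-symbol insertion in the sequence
    (1, 0, 0),  # 1-symbol deletion from the sequence
)
_VARIANTS_5 = _VARIANTS_3 + (
    (0, 2, 2),  # 2-symbol insertion
    (2, 0, 0),  # 2-symbol deletion
)


def try_variant_extension(
    seq: str,
    i: int,
    last_match_end_ref: int,
    index: ReferenceIndex,
    h1e: int,
    indel2: bool = False,
) -> Optional[tuple[int, int, int]]:
    """Probe variant continuations after a match ending at ``last_match_end_ref``.

    Checks, in fixed order, a substitution, 1-symbol indels, and (with
    ``indel2``) 2-symbol indels.  Each candidate is the direct extension
    match starting at the shifted reference/sequence offsets; it is
    accepted when at least ``h1e`` symbols long.  Returns
    ``(ref_pos, length, n_literals)`` for the longest accepted candidate
    (first in probe order on ties), where ``n_literals`` sequence symbols
    at ``i`` must be emitted as literals before the match; or ``None``.
    """
    ref = index.reference
    probes = _VARIANTS_5 if indel2 else _VARIANTS_3
    best: Optional[tuple[int, int, int]] = None
    for d_ref, d_seq, n_lit in probes:
        rp = last_match_end_ref + d_ref
        sp = i + d_seq
        if rp >= len(ref) or sp > len(seq):
            continue
        length = longest_common_extension(seq, sp, ref, rp)
        if length >= h1e and (best is None or length > best[1]):
            best = (rp, length, n_lit)
    return best


def factor_sequence(
    seq: str,
    index: ReferenceIndex,
    h1e: int,
    indel2: bool = False,
) -> L1Sequence:
    """Greedy LZSS parse of ``seq`` against the indexed reference.

    At each position the longest hash-table match (>= h1m symbols) and,
    when armed by a preceding match, the best variant continuation
    (>= h1e symbols) are both considered; the longer match wins and ties
    go to the variant continuation, whose position costs nothing to
    encode.  Sequences shorter than h1m (and unmatched stretches) come
    out as literals.  ``reconstruct_sequence`` inverts the parse exactly.
    """
    out: list[L1Tuple] = []
    n = len(seq)
    i = 0
    armed = False  # previous emitted tuple is a match
    last_end_ref = -1  # exclusive reference end of that match
    while i < n:
        variant = None
        if armed:
            variant = try_variant_extension(
                seq, i, last_end_ref, index, h1e, indel2
            )
        hash_match = index.find_longest_match(seq, i)
        if variant is not None and (
            hash_match is None or variant[1] >= hash_match[1]
        ):
            rp, length, n_lit = variant
            for j in range(n_lit):
                out.append(L1Tuple.literal(seq[i + j]))
            out.append(L1Tuple.match(rp, length))
            i += n_lit + length
            armed = True
            last_end_ref = rp + length
        elif hash_match is not None:
            rp, length = hash_match
            out.append(L1Tuple.match(rp, length))
            i += length
            armed = True
            last_end_ref = rp + length
        else:
            out.append(L1Tuple.literal(seq[i]))
            i += 1
            armed = False
    return L1Sequence(out)


def reconstruct_sequence(l1: L1Sequence, reference: str) -> str:
    """Invert the factoring: emit literals, copy reference slices."""
    parts: list[str] = []
    for t in l1.tuples:
        if t.tag == TAG_LITERAL:
            parts.append(t.symbol)
        else:
            if t.pos < 0 or t.pos + t.length > len(reference):
                raise ValueError(
                    f"corrupt first-level match ({t.pos}, {t.length}) "
                    f"outside reference of length {len(reference)}"
                )
            parts.append(reference[t.pos : t.pos + t.length])
    return "".join(parts)
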