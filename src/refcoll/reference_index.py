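"""K-mer index over the reference genome.

The index is an open-addressing hash table (linear probing, power-of-two
capacity, load factor kept at or below 0.7) over every k-mer of the
reference.  All positions of a repeated k-mer are retained, grouped in a
single flat position array, so longest-match queries can consider every
occurrence of the seed.  Hashing is a 64-bit polynomial over raw ASCII
codes, which handles N and the degenerate IUPAC letters (both cases)
without a packed-alphabet special case; candidates are always verified by
direct string comparison, so hash collisions cannot produce false matches.
"""

from __future__ import annotations

import numpy as np

from ._util import HASH_BASE, MASK64, kmer_hash, longest_common_extension

__all__ = ["ReferenceIndex", "build_reference_index", "find_longest_match"]

_MAX_LOAD = 0.7


class ReferenceIndex:
    """Queryable k-mer hash table over a reference sequence.

    Parameters
    ----------
    reference:
        The reference sequence R (ASCII letters, case significant).
    k:
        Seed length (the minimum first-level match length h1m).
    """

    def __init__(self, reference: str, k: int):
        if k < 1:
            raise ValueError("k must be positive")
        if len(reference) < k:
            raise ValueError(
                f"reference length {len(reference)} is shorter than k={k}"
            )
        self.reference = reference
        self.k = k
        self._build()

    # -- construction -------------------------------------------------

    def _build(self) -> None:
        ref = self.reference
        k = self.k
        n_kmers = len(ref) - k + 1

        arr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
        hashes = np.zeros(n_kmers, dtype=np.uint64)
        base = np.uint64(HASH_BASE)
        for i in range(k):
            hashes = hashes * base + arr[i : i + n_kmers].astype(np.uint64)

        # group positions by hash; stable sort keeps positions ascending
        # within each group, which fixes smallest-position tie-breaking
        order = np.argsort(hashes, kind="stable")
        self._positions = order.astype(np.int64)
        sorted_hashes = hashes[order]
        uniq, starts, counts = np.unique(
            sorted_hashes, return_index=True, return_counts=True
        )

        cap = 1
        while cap * _MAX_LOAD < len(uniq):
            cap <<= 1
        self._capacity = cap
        mask = cap - 1

        slot_hash = [0] * cap
        slot_start = [-1] * cap
        slot_count = [0] * cap
        for h, s, c in zip(uniq.tolist(), starts.tolist(), counts.tolist()):
            idx = h & mask
            while slot_start[idx] >= 0:
                idx = (idx + 1) & mask
            slot_hash[idx] = h
            slot_start[idx] = s
            slot_count[idx] = c
        self._slot_hash = slot_hash
        self._slot_start = slot_start
        self._slot_count = slot_count
        self._n_keys = len(uniq)

    # -- introspection -------------------------------------------------

    @property
    def capacity(self) -> int:
        return self._capacity

    @property
    def load_factor(self) -> float:
        return self._n_keys / self._capacity

    # -- queries -------------------------------------------------------

    def positions_of(self, h: int) -> list[int]:
        """Reference start positions stored under hash value ``h``."""
        mask = self._capacity - 1
        idx = h & mask
        while self._slot_start[idx] >= 0:
            if self._slot_hash[idx] == h:
                s = self._slot_start[idx]
                return self._positions[s : s + self._slot_count[idx]].tolist()
            idx = (idx + 1) & mask
        return []

    def find_longest_match(
        self, query: str, start: int, min_len: int | None = None
    ) -> tuple[int, int] | None:
        """Longest reference match for the seed k-mer at ``query[start:]``.

        Returns ``(ref_pos, length)`` with ``length`` maximal over all
        verified occurrences of the seed, or ``None`` when there is no
        seed hit or the best extension is shorter than ``min_len``
        (default: the seed length).  Ties in length resolve to the
        smallest reference position.
        """
        if min_len is None:
            min_len = self.k
        k = self.k
        if start + k > len(query):
            return None
        h = kmer_hash(query, start, k)
        ref = self.reference
        seed = query[start : start + k]
        best_len = 0
        best_pos = -1
        for p in self.positions_of(h):
            if ref[p : p + k] != seed:  # collision guard
                continue
            length = k + longest_common_extension(query, start + k, ref, p + k)
            if length > best_len:
                best_len = length
                best_pos = p
        if best_len >= min_len:
            return best_pos, best_len
        return None


def build_reference_index(reference: str, k: int) -> ReferenceIndex:
    """Build the reference k-mer table (functional wrapper)."""
    return ReferenceIndex(reference, k)


def find_longest_match(
    index: ReferenceIndex, query: str, start: int, min_len: int | None = None
) -> tuple[int, int] | None:
    return index.find_longest_match(query, start, min_len)
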