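"""Independent brute-force oracles for the factoring layers.

These deliberately avoid the package's hash tables and extension tricks:
matches are found by scanning every occurrence with ``str.find`` and
extending character by character (first level), or by trying every
(sequence, position) pair (second level).  They re-state the greedy
parsing semantics from scratch so the production parsers can be checked
against them on small instances.
"""

from __future__ import annotations

from refcoll.first_level import L1Tuple, TAG_LITERAL
from refcoll.second_level import TAG_L2_MATCH, L2Tuple


def _char_lce(a: str, i: int, b: str, j: int) -> int:
    n = 0
    while i + n < len(a) and j + n < len(b) and a[i + n] == b[j + n]:
        n += 1
    return n


def _scan_longest_match(seq: str, i: int, ref: str, h1m: int):
    """Longest match via exhaustive seed scan; smallest position wins ties."""
    if i + h1m > len(seq):
        return None
    seed = seq[i : i + h1m]
    best = None
    p = ref.find(seed)
    while p != -1:
        length = h1m + _char_lce(seq, i + h1m, ref, p + h1m)
        if best is None or length > best[1]:
            best = (p, length)
        p = ref.find(seed, p + 1)
    return best


def _scan_variant(seq: str, i: int, end_ref: int, ref: str, h1e: int,
                  indel2: bool):
    probes = [(1, 1, 1), (0, 1, 1), (1, 0, 0)]
    if indel2:
        probes += [(0, 2, 2), (2, 0, 0)]
    best = None
    for d_ref, d_seq, n_lit in probes:
        rp, sp = end_ref + d_ref, i + d_seq
        if rp >= len(ref) or sp > len(seq):
            continue
        length = _char_lce(seq, sp, ref, rp)
        if length >= h1e and (best is None or length > best[1]):
            best = (rp, length, n_lit)
    return best


def oracle_factor(seq: str, ref: str, h1m: int, h1e: int,
                  indel2: bool = False) -> list[L1Tuple]:
    """Greedy first-level parse by exhaustive scanning."""
    out: list[L1Tuple] = []
    i = 0
    armed = False
    end_ref = -1
    while i < len(seq):
        variant = (
            _scan_variant(seq, i, end_ref, ref, h1e, indel2) if armed else None
        )
        hmatch = _scan_longest_match(seq, i, ref, h1m)
        if variant is not None and (hmatch is None or variant[1] >= hmatch[1]):
            rp, length, n_lit = variant
            for j in range(n_lit):
                out.append(L1Tuple.literal(seq[i + j]))
            out.append(L1Tuple.match(rp, length))
            i += n_lit + length
            armed, end_ref = True, rp + length
        elif hmatch is not None:
            rp, length = hmatch
            out.append(L1Tuple.match(rp, length))
            i += length
            armed, end_ref = True, rp + length
        else:
            out.append(L1Tuple.literal(seq[i]))
            i += 1
            armed = False
    return out


def _weight(t: L1Tuple, match_weight: int) -> int:
    return 1 if t.tag == TAG_LITERAL else match_weight


def oracle_factor_tuples(
    tuples: list[L1Tuple],
    prior: dict[int, list[L1Tuple]],
    h2: int,
    match_weight: int = 7,
) -> list[L2Tuple]:
    """Greedy maximal-weight second-level parse over *all* candidates."""
    out: list[L2Tuple] = []
    i = 0
    n = len(tuples)
    while i < n:
        best = None  # (weight, seq_id, -pos, length)
        for u, other in prior.items():
            for p in range(len(other)):
                length = 0
                limit = min(n - i, len(other) - p)
                while (length < limit
                       and tuples[i + length] == other[p + length]):
                    length += 1
                w = sum(_weight(t, match_weight)
                        for t in tuples[i : i + length])
                if w >= h2:
                    cand = (w, u, -p, length)
                    if best is None or cand > best:
                        best = cand
        if best is not None:
            w, u, negp, length = best
            out.append(L2Tuple.match(u, -negp, length))
            i += length
        else:
            out.append(L2Tuple.wrap(tuples[i]))
            i += 1
    return out
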