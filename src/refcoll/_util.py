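"""Small shared numeric helpers."""

from __future__ import annotations

MASK64 = (1 << 64) - 1
HASH_BASE = 0x100000001B3  # 64-bit FNV prime, used as polynomial base


def longest_common_extension(a: str, i: int, b: str, j: int) -> int:
    """Length of the longest common prefix of ``a[i:]`` and ``b[j:]``.

    Compares geometrically growing blocks with C-level slice equality,
    then binary-searches the mismatch inside the failing block, so long
    identical stretches cost O(log) slice comparisons instead of a
    per-character Python loop.
    """
    limit = min(len(a) - i, len(b) - j)
    if limit <= 0:
        return 0
    off = 0
    blk = 16
    while off < limit:
        step = min(blk, limit - off)
        if a[i + off : i + off + step] == b[j + off : j + off + step]:
            off += step
            blk <<= 1
            continue
        # mismatch inside [off, off+step); bisect it
        lo, hi = 0, step  # invariant: first `lo` chars match, mismatch before hi
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if a[i + off : i + off + mid] == b[j + off : j + off + mid]:
                lo = mid
            else:
                hi = mid - 1
        return off + lo
    return limit


def kmer_hash(s: str, start: int, k: int) -> int:
    """64-bit polynomial hash of ``s[start:start+k]`` over raw ASCII codes."""
    h = 0
    for idx in range(start, start + k):
        h = (h * HASH_BASE + ord(s[idx])) & MASK64
    return h


def zigzag_encode(n: int) -> int:
    return (n << 1) ^ (n >> 63) if n >= 0 else ((-n) << 1) - 1


def zigzag_decode(z: int) -> int:
    return (z >> 1) if (z & 1) == 0 else -((z + 1) >> 1)
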