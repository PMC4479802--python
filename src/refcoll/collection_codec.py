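"""Contextual range coding of the second-level tuple streams.

Every tuple is coded as a flag (its kind, in an order-2 flag context)
followed by its fields.  Fields are not coded as raw integers: match
positions at both levels are *predicted* from what has already been coded,
and only the (usually tiny) difference between prediction and reality is
stored, bucketed into a small class plus zero to four payload bytes.

First level: the next match in a genome almost always resumes where the
previous one left off, shifted by whatever was coded in between, so the
expectation is ``last_pos + last_len + symbols_since`` and the delta is
overwhelmingly zero.

Second level: for each referenced stream L^u an entry ``(p_A, s_A)``
remembers where the last copy into L^u ended and how many symbols of the
current sequence had been processed at that point; the expectation advances
``p_A`` over L^u by the symbols coded since, which again lands exactly on
the next copy whenever two genomes share a local variant layout.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from ._util import zigzag_decode, zigzag_encode
from .first_level import L1Sequence, L1Tuple, TAG_LITERAL, TAG_L1_MATCH
from .params import CodecParams
from .rangecoder import ContextModel, RangeDecoder, RangeEncoder, models_digest
from .second_level import L2Tuple, TAG_L2_MATCH

__all__ = [
    "MAGIC",
    "FORMAT_VERSION",
    "CorruptStreamError",
    "classify_l1_position_delta",
    "classify_l1_length",
    "classify_l2_position_delta",
    "classify_l2_length",
    "split_sequence_id",
    "L2Predictor",
    "expected_l2_position",
    "CollectionEncoder",
    "CollectionDecoder",
    "encode_collection",
    "decode_collection",
]

MAGIC = b"GDC2SPEC"
FORMAT_VERSION = 1
_HEADER = struct.Struct("<8sBBBBBI")

FLAG_LITERAL = 0
FLAG_L1_MATCH = 1
FLAG_L2_MATCH = 2
FLAG_TERMINATOR = 3

# position-delta classes (both levels share the names where they overlap)
PERFECT, GOOD, MODERATE, POOR = 0, 1, 2, 3
# the first level has no moderate class: its poor code is 2
L1_POOR = 2
# first-level length classes
LEN_SHORT, LEN_LONG, LEN_VERY_LONG = 0, 1, 2
# second-level length class boundaries: 2^4, 2^4+2^5, +2^7, +2^8 tuples
_L2_LEN_BOUNDS = (16, 48, 176, 432)


class CorruptStreamError(ValueError):
    """Decoder detected an inconsistent archive stream."""


# ---------------------------------------------------------------------------
# integer classifiers (class + payload bytes), all exactly invertible
# ---------------------------------------------------------------------------

def classify_l1_position_delta(relative_pos: int) -> tuple[int, list[int]]:
    """Bucket a first-level position delta: perfect / good / poor.

    Perfect deltas cost nothing beyond the class; good ones (|delta| <=
    127) cost one zig-zag byte; the rest four zig-zag bytes.
    """
    if relative_pos == 0:
        return PERFECT, []
    if abs(relative_pos) <= 127:
        return GOOD, [zigzag_encode(relative_pos)]
    z = zigzag_encode(relative_pos)
    return L1_POOR, list(z.to_bytes(4, "little"))


def reassemble_l1_position_delta(cls: int, payload: list[int]) -> int:
    if cls == PERFECT:
        return 0
    if cls == GOOD:
        return zigzag_decode(payload[0])
    return zigzag_decode(int.from_bytes(bytes(payload), "little"))


def classify_l1_length(length: int) -> tuple[int, list[int]]:
    """Bucket a first-level match length: short (<=2^8) / long (<=2^16+2^8) /
    very long, with 1 / 2 / 4 payload bytes."""
    if length <= 256:
        return LEN_SHORT, [length - 1]
    if length <= 65792:
        return LEN_LONG, list((length - 257).to_bytes(2, "little"))
    return LEN_VERY_LONG, list(length.to_bytes(4, "little"))


def reassemble_l1_length(cls: int, payload: list[int]) -> int:
    if cls == LEN_SHORT:
        return payload[0] + 1
    if cls == LEN_LONG:
        return int.from_bytes(bytes(payload), "little") + 257
    return int.from_bytes(bytes(payload), "little")


def split_sequence_id(seq_id: int) -> tuple[int, int]:
    """Radix-256 split; the prefix is the suffix's coding context."""
    if not 0 <= seq_id < 1 << 16:
        raise ValueError(f"sequence id {seq_id} exceeds the 2^16 archive limit")
    return seq_id >> 8, seq_id & 0xFF


def join_sequence_id(prefix: int, suffix: int) -> int:
    return (prefix << 8) | suffix


def classify_l2_position_delta(diff: int) -> tuple[int, list[int]]:
    """Bucket a second-level position delta.

    perfect: 0; good: |diff| in 1..16 (one byte: sign bit + magnitude-1);
    moderate: |diff| in 17..256 (sign byte + magnitude-17); poor: four
    zig-zag bytes.
    """
    if diff == 0:
        return PERFECT, []
    mag = abs(diff)
    if mag <= 16:
        return GOOD, [(mag - 1) | (0x80 if diff < 0 else 0)]
    if mag <= 256:
        return MODERATE, [1 if diff < 0 else 0, mag - 17]
    z = zigzag_encode(diff)
    return POOR, list(z.to_bytes(4, "little"))


def reassemble_l2_position_delta(cls: int, payload: list[int]) -> int:
    if cls == PERFECT:
        return 0
    if cls == GOOD:
        mag = (payload[0] & 0x7F) + 1
        return -mag if payload[0] & 0x80 else mag
    if cls == MODERATE:
        mag = payload[1] + 17
        return -mag if payload[0] else mag
    return zigzag_decode(int.from_bytes(bytes(payload), "little"))


def classify_l2_length(tuple_len: int) -> tuple[int, list[int]]:
    """Bucket a second-level match length (in tuples) into five classes
    with boundaries 16 / 48 / 176 / 432; one offset byte per bounded
    class, four raw bytes for the unbounded tail."""
    lo = 0
    for cls, hi in enumerate(_L2_LEN_BOUNDS):
        if tuple_len <= hi:
            return cls, [tuple_len - lo - 1]
        lo = hi
    return len(_L2_LEN_BOUNDS), list(tuple_len.to_bytes(4, "little"))


def reassemble_l2_length(cls: int, payload: list[int]) -> int:
    if cls < len(_L2_LEN_BOUNDS):
        lo = 0 if cls == 0 else _L2_LEN_BOUNDS[cls - 1]
        return payload[0] + lo + 1
    return int.from_bytes(bytes(payload), "little")


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------

@dataclass
class L1Predictor:
    """Expected position of the next first-level match (reset per sequence)."""

    last_pos: int = 0
    last_len: int = 0
    symbols_since: int = 0

    @property
    def expected_pos(self) -> int:
        return self.last_pos + self.last_len + self.symbols_since

    def observe_symbols(self, n: int) -> None:
        self.symbols_since += n

    def observe_match(self, pos: int, length: int) -> None:
        self.last_pos = pos
        self.last_len = length
        self.symbols_since = 0


@dataclass
class L2Predictor:
    """Per-referenced-stream state for second-level position prediction.

    ``A[u] = (p_A, s_A)``: the tuple position of the last copy into L^u
    and the number of symbols of the current sequence processed before
    that copy.  Absent entries are cold and predict offset 0.
    """

    A: dict[int, tuple[int, int]] = field(default_factory=dict)

    def reset(self) -> None:
        self.A.clear()

    def expected(self, u: int, sym_pos: int, coverage_prefix: np.ndarray) -> int:
        entry = self.A.get(u)
        if entry is None:
            return 0
        p_a, s_a = entry
        d = sym_pos - s_a
        # advance p_a while the covered symbol count stays <= d
        target = int(coverage_prefix[p_a]) + d
        q = int(np.searchsorted(coverage_prefix, target, side="right")) - 1
        return min(max(q, p_a), len(coverage_prefix) - 1)

    def update(self, u: int, tuple_pos: int, sym_pos: int) -> None:
        self.A[u] = (tuple_pos, sym_pos)


def expected_l2_position(
    pred: L2Predictor, u: int, sym_pos: int, l_u: L1Sequence
) -> int:
    """Functional wrapper over :meth:`L2Predictor.expected`."""
    cov = np.cumsum([0] + [t.coverage for t in l_u.tuples])
    return pred.expected(u, sym_pos, cov)


# ---------------------------------------------------------------------------
# codec
# ---------------------------------------------------------------------------

def _new_models() -> dict[str, ContextModel]:
    return {
        "flags": ContextModel(4),
        "literal": ContextModel(256),
        "l1_pos_class": ContextModel(3),
        "l1_pos_byte": ContextModel(256),
        "l1_len_class": ContextModel(3),
        "l1_len_byte": ContextModel(256),
        "l2_id_prefix": ContextModel(256),
        "l2_id_suffix": ContextModel(256),
        "l2_pos_class": ContextModel(4),
        "l2_pos_byte": ContextModel(256),
        "l2_len_class": ContextModel(5),
        "l2_len_byte": ContextModel(256),
    }


class _CodecBase:
    def __init__(self, params: CodecParams):
        self.params = params
        self.models = _new_models()
        self.flag_ctx = (FLAG_TERMINATOR, FLAG_TERMINATOR)
        self.literal_ctx = 0
        self.l2_pred = L2Predictor()
        # eligible prior streams: seq_id -> (L1Sequence, coverage prefix)
        self.prior: dict[int, L1Sequence] = {}
        self._cov: dict[int, np.ndarray] = {}

    def add_prior(self, seq_id: int, l1: L1Sequence) -> None:
        """Register an eligible earlier stream for second-level reference."""
        self.prior[seq_id] = l1
        cov = np.zeros(len(l1.tuples) + 1, dtype=np.int64)
        np.cumsum([t.coverage for t in l1.tuples], out=cov[1:])
        self._cov[seq_id] = cov

    def _push_flag(self, f: int) -> None:
        self.flag_ctx = (self.flag_ctx[1], f)

    def _l2_coverage(self, u: int, pos: int, length: int) -> int:
        cov = self._cov[u]
        return int(cov[pos + length] - cov[pos])

    def state_digest(self) -> str:
        """Digest of all adaptive model state (for determinism checks)."""
        return models_digest(self.models)


class CollectionEncoder(_CodecBase):
    """Streaming encoder: feed one second-level stream per sequence."""

    def __init__(self, params: CodecParams):
        super().__init__(params)
        self.enc = RangeEncoder()
        self.n_sequences = 0

    def encode_sequence(self, d: list[L2Tuple]) -> None:
        m = self.models
        enc = self.enc
        pred1 = L1Predictor()
        self.l2_pred.reset()
        sym_pos = 0
        for t in d:
            m["flags"].encode(enc, self.flag_ctx, t.tag)
            self._push_flag(t.tag)
            if t.tag == TAG_LITERAL:
                b = ord(t.passthrough.symbol)
                m["literal"].encode(enc, self.literal_ctx, b)
                self.literal_ctx = b
                pred1.observe_symbols(1)
                sym_pos += 1
            elif t.tag == TAG_L1_MATCH:
                pos, length = t.passthrough.pos, t.passthrough.length
                rel = pred1.expected_pos - pos
                cls, payload = classify_l1_position_delta(rel)
                m["l1_pos_class"].encode(enc, None, cls)
                for bi, b in enumerate(payload):
                    m["l1_pos_byte"].encode(enc, (cls, bi), b)
                cls, payload = classify_l1_length(length)
                m["l1_len_class"].encode(enc, None, cls)
                for bi, b in enumerate(payload):
                    m["l1_len_byte"].encode(enc, (cls, bi), b)
                pred1.observe_match(pos, length)
                sym_pos += length
            else:
                u, pos, length = t.seq_id, t.tuple_pos, t.tuple_len
                prefix, suffix = split_sequence_id(u)
                m["l2_id_prefix"].encode(enc, None, prefix)
                m["l2_id_suffix"].encode(enc, prefix, suffix)
                diff = self.l2_pred.expected(u, sym_pos, self._cov[u]) - pos
                cls, payload = classify_l2_position_delta(diff)
                m["l2_pos_class"].encode(enc, None, cls)
                for bi, b in enumerate(payload):
                    m["l2_pos_byte"].encode(enc, (cls, bi), b)
                cls, payload = classify_l2_length(length)
                m["l2_len_class"].encode(enc, None, cls)
                for bi, b in enumerate(payload):
                    m["l2_len_byte"].encode(enc, (cls, bi), b)
                self.l2_pred.update(u, pos, sym_pos)
                covered = self._l2_coverage(u, pos, length)
                pred1.observe_symbols(covered)
                sym_pos += covered
        m["flags"].encode(enc, self.flag_ctx, FLAG_TERMINATOR)
        self._push_flag(FLAG_TERMINATOR)
        self.n_sequences += 1

    def finish(self) -> bytes:
        p = self.params
        flags = (1 if p.indel2 else 0) | (p.stride << 1)
        header = _HEADER.pack(
            MAGIC, FORMAT_VERSION, p.h1m, p.h1e, p.h2, flags, self.n_sequences
        )
        return header + self.enc.finish()


def read_header(stream: bytes) -> tuple[CodecParams, int, int]:
    """Parse the stream header -> (params, n_sequences, payload offset)."""
    if len(stream) < _HEADER.size:
        raise CorruptStreamError("stream shorter than its header")
    magic, version, h1m, h1e, h2, flags, count = _HEADER.unpack_from(stream)
    if magic != MAGIC:
        raise CorruptStreamError("bad magic; not a collection stream")
    if version != FORMAT_VERSION:
        raise CorruptStreamError(f"unsupported format version {version}")
    stride = flags >> 1
    params = CodecParams(
        h1m=h1m,
        h1e=h1e,
        h2=h2,
        indel2=bool(flags & 1),
        ref_fraction=(0.0 if stride == 0 else 1.0 / stride),
    )
    return params, count, _HEADER.size


class CollectionDecoder(_CodecBase):
    """Streaming decoder: exact model-state mirror of the encoder."""

    def __init__(self, stream: bytes):
        params, count, offset = read_header(stream)
        super().__init__(params)
        self.n_sequences = count
        self.dec = RangeDecoder(stream, offset)

    def decode_sequence(self) -> list[L2Tuple]:
        m = self.models
        dec = self.dec
        pred1 = L1Predictor()
        self.l2_pred.reset()
        sym_pos = 0
        out: list[L2Tuple] = []
        while True:
            flag = m["flags"].decode(dec, self.flag_ctx)
            self._push_flag(flag)
            if flag == FLAG_TERMINATOR:
                return out
            if flag == FLAG_LITERAL:
                b = m["literal"].decode(dec, self.literal_ctx)
                self.literal_ctx = b
                out.append(L2Tuple.wrap(L1Tuple.literal(chr(b))))
                pred1.observe_symbols(1)
                sym_pos += 1
            elif flag == FLAG_L1_MATCH:
                cls = m["l1_pos_class"].decode(dec, None)
                n_bytes = {PERFECT: 0, GOOD: 1, L1_POOR: 4}[cls]
                payload = [
                    m["l1_pos_byte"].decode(dec, (cls, bi))
                    for bi in range(n_bytes)
                ]
                pos = pred1.expected_pos - reassemble_l1_position_delta(
                    cls, payload
                )
                cls = m["l1_len_class"].decode(dec, None)
                n_bytes = {LEN_SHORT: 1, LEN_LONG: 2, LEN_VERY_LONG: 4}[cls]
                payload = [
                    m["l1_len_byte"].decode(dec, (cls, bi))
                    for bi in range(n_bytes)
                ]
                length = reassemble_l1_length(cls, payload)
                if pos < 0:
                    raise CorruptStreamError(
                        f"negative match position at stream offset {dec.pos}"
                    )
                out.append(L2Tuple.wrap(L1Tuple.match(pos, length)))
                pred1.observe_match(pos, length)
                sym_pos += length
            elif flag == FLAG_L2_MATCH:
                prefix = m["l2_id_prefix"].decode(dec, None)
                suffix = m["l2_id_suffix"].decode(dec, prefix)
                u = join_sequence_id(prefix, suffix)
                if u not in self.prior:
                    raise CorruptStreamError(
                        f"reference to unknown sequence {u} at stream "
                        f"offset {dec.pos}"
                    )
                cls = m["l2_pos_class"].decode(dec, None)
                n_bytes = {PERFECT: 0, GOOD: 1, MODERATE: 2, POOR: 4}[cls]
                payload = [
                    m["l2_pos_byte"].decode(dec, (cls, bi))
                    for bi in range(n_bytes)
                ]
                diff = reassemble_l2_position_delta(cls, payload)
                pos = self.l2_pred.expected(u, sym_pos, self._cov[u]) - diff
                cls = m["l2_len_class"].decode(dec, None)
                n_bytes = 1 if cls < 4 else 4
                payload = [
                    m["l2_len_byte"].decode(dec, (cls, bi))
                    for bi in range(n_bytes)
                ]
                length = reassemble_l2_length(cls, payload)
                if pos < 0 or pos + length > len(self.prior[u].tuples):
                    raise CorruptStreamError(
                        f"second-level match out of bounds at stream "
                        f"offset {dec.pos}"
                    )
                out.append(L2Tuple.match(u, pos, length))
                self.l2_pred.update(u, pos, sym_pos)
                covered = self._l2_coverage(u, pos, length)
                pred1.observe_symbols(covered)
                sym_pos += covered
            else:  # pragma: no cover - flag alphabet is exhaustive
                raise CorruptStreamError(f"invalid flag {flag}")


# ---------------------------------------------------------------------------
# convenience whole-collection entry points
# ---------------------------------------------------------------------------

def encode_collection(
    d_streams: list[list[L2Tuple]],
    l1_streams: list[L1Sequence],
    params: CodecParams,
) -> bytes:
    """Encode all second-level streams into one collection byte stream."""
    enc = CollectionEncoder(params)
    for k, d in enumerate(d_streams):
        enc.encode_sequence(d)
        if params.is_eligible_reference(k):
            enc.add_prior(k, l1_streams[k])
    return enc.finish()


def decode_collection(stream: bytes) -> tuple[list[list[L2Tuple]], CodecParams]:
    """Decode a collection stream back into second-level tuple streams."""
    from .second_level import reconstruct_tuple_sequence

    dec = CollectionDecoder(stream)
    out: list[list[L2Tuple]] = []
    for k in range(dec.n_sequences):
        d = dec.decode_sequence()
        out.append(d)
        if dec.params.is_eligible_reference(k):
            dec.add_prior(k, reconstruct_tuple_sequence(d, dec.prior))
    return out, dec.params
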