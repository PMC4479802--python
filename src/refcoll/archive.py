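"""End-to-end compression, the three-file container, and random access.

An archive is three files sharing a prefix:

``<prefix>.gdc2_desc``
    zlib-compressed JSON: parameters plus, per record in compression
    order, (source file, id, length, wrap width).  Lengths are verified
    on decompression.
``<prefix>.gdc2_rc``
    The range-coded collection stream (the bytes that matter for the
    compression ratio, together with desc).
``<prefix>.gdc2_ref``
    The range-coded reference sequence.  It is stored for completeness
    — decompression is self-contained — but is conventionally excluded
    from ratio accounting because the reference is not part of the
    collection being compressed.

Sequences are processed in deterministic order (file order, then record
order), so archives are byte-reproducible.  With ``ref_fraction`` f < 1
only every round(1/f)-th sequence is indexed as a second-level reference,
which bounds the number of streams that must be fully expanded to extract
a single sequence.
"""

from __future__ import annotations

import json
import os
import struct
import zlib
from dataclasses import dataclass

from .collection_codec import (
    CollectionDecoder,
    CollectionEncoder,
    CorruptStreamError,
)
from .first_level import L1Sequence, factor_sequence, reconstruct_sequence
from .params import CodecParams
from .rangecoder import ContextModel, RangeDecoder, RangeEncoder
from .reference_index import ReferenceIndex
from .second_level import (
    L2Tuple,
    TupleIndex,
    factor_tuple_sequence,
    reconstruct_tuple_sequence,
)
from .sequence_io import (
    CollectionMeta,
    SequenceRecord,
    read_multifasta,
    write_multifasta,
)

__all__ = [
    "Archive",
    "compress",
    "decompress",
    "extract_sequence",
    "encode_reference_stream",
    "decode_reference_stream",
    "archive_info",
]

DESC_EXT = ".gdc2_desc"
RC_EXT = ".gdc2_rc"
REF_EXT = ".gdc2_ref"

_REF_MAGIC = b"GDC2REF\x00"


@dataclass
class Archive:
    """Handle to the three streams of a compressed collection."""

    desc_path: str
    rc_path: str
    ref_path: str

    @classmethod
    def at_prefix(cls, prefix: str | os.PathLike) -> "Archive":
        prefix = os.fspath(prefix)
        return cls(prefix + DESC_EXT, prefix + RC_EXT, prefix + REF_EXT)

    def read_meta(self) -> CollectionMeta:
        with open(self.desc_path, "rb") as fh:
            payload = zlib.decompress(fh.read())
        doc = json.loads(payload.decode("utf-8"))
        return CollectionMeta(
            records=[tuple(r) for r in doc["records"]], params=doc["params"]
        )

    def params(self) -> CodecParams:
        return CodecParams(**self.read_meta().params)

    def stream_sizes(self) -> dict[str, int]:
        return {
            "desc": os.path.getsize(self.desc_path),
            "rc": os.path.getsize(self.rc_path),
            "ref": os.path.getsize(self.ref_path),
        }


# ---------------------------------------------------------------------------
# reference stream
# ---------------------------------------------------------------------------

def encode_reference_stream(reference: str) -> bytes:
    """Range-code the reference, symbols gathered in triples.

    Each symbol of a triple is coded in order-1 context (the previous
    symbol) with a separate model per slot of the triple; an explicit
    length header handles references whose length is not divisible by 3.
    """
    enc = RangeEncoder()
    model = ContextModel(256)
    prev = 0
    for i, ch in enumerate(reference):
        b = ord(ch)
        model.encode(enc, (i % 3, prev), b)
        prev = b
    return _REF_MAGIC + struct.pack("<Q", len(reference)) + enc.finish()


def decode_reference_stream(stream: bytes) -> str:
    if stream[: len(_REF_MAGIC)] != _REF_MAGIC:
        raise CorruptStreamError("bad magic; not a reference stream")
    (length,) = struct.unpack_from("<Q", stream, len(_REF_MAGIC))
    dec = RangeDecoder(stream, len(_REF_MAGIC) + 8)
    model = ContextModel(256)
    prev = 0
    out = bytearray()
    for i in range(length):
        b = model.decode(dec, (i % 3, prev))
        out.append(b)
        prev = b
    return out.decode("ascii")


# ---------------------------------------------------------------------------
# compression
# ---------------------------------------------------------------------------

def _read_reference(path: str | os.PathLike) -> str:
    records = read_multifasta(path)
    if not records:
        raise ValueError(f"reference file {path!s} contains no sequences")
    return "".join(r.data for r in records)


def _compress_records(
    reference: str, records: list[SequenceRecord], params: CodecParams
) -> tuple[bytes, bytes, bytes]:
    """Core pipeline: records -> (desc, rc, ref) byte streams."""
    index = ReferenceIndex(reference, params.h1m)
    use_l2 = params.stride > 0
    tindex = TupleIndex(params.h2, params.match_weight) if use_l2 else None
    prior: dict[int, L1Sequence] = {}
    encoder = CollectionEncoder(params)

    for k, rec in enumerate(records):
        l1 = factor_sequence(rec.data, index, params.h1e, params.indel2)
        if use_l2:
            d = factor_tuple_sequence(l1, tindex, prior)
        else:
            d = [L2Tuple.wrap(t) for t in l1.tuples]
        encoder.encode_sequence(d)
        if params.is_eligible_reference(k):
            if use_l2:
                tindex.insert(l1, k)
                prior[k] = l1
            encoder.add_prior(k, l1)

    meta_doc = {
        "params": {
            "h1m": params.h1m,
            "h1e": params.h1e,
            "h2": params.h2,
            "indel2": params.indel2,
            "ref_fraction": params.ref_fraction,
            "match_weight": params.match_weight,
        },
        "records": [
            [r.source_file, r.id, len(r.data), r.line_width] for r in records
        ],
    }
    desc = zlib.compress(json.dumps(meta_doc).encode("utf-8"), 9)
    rc = encoder.finish()
    ref = encode_reference_stream(reference)
    return desc, rc, ref


def compress(
    reference_path: str | os.PathLike,
    collection_paths: list[str | os.PathLike],
    out_prefix: str | os.PathLike,
    params: CodecParams = CodecParams(),
) -> Archive:
    """Compress multi-FASTA files against a reference into an archive.

    All inputs are read and validated before any output is written.
    """
    reference = _read_reference(reference_path)
    records: list[SequenceRecord] = []
    for path in collection_paths:
        records.extend(read_multifasta(path))
    desc, rc, ref = _compress_records(reference, records, params)
    archive = Archive.at_prefix(out_prefix)
    for path, payload in (
        (archive.desc_path, desc),
        (archive.rc_path, rc),
        (archive.ref_path, ref),
    ):
        with open(path, "wb") as fh:
            fh.write(payload)
    return archive


# ---------------------------------------------------------------------------
# decompression and extraction
# ---------------------------------------------------------------------------

def _decode_records(
    archive: Archive,
    stop_after: int | None = None,
    expand_only_needed: bool = False,
) -> tuple[list[SequenceRecord | None], CollectionMeta, int]:
    """Decode the archive up to ``stop_after`` (inclusive index).

    When ``expand_only_needed`` is set, only eligible reference streams
    and the final target are expanded to first-level streams (and on to
    symbols); other entries come back as ``None``.  Returns the records,
    the metadata, and the number of streams that were fully expanded.
    """
    meta = archive.read_meta()
    params = CodecParams(**meta.params)
    with open(archive.ref_path, "rb") as fh:
        reference = decode_reference_stream(fh.read())
    with open(archive.rc_path, "rb") as fh:
        decoder = CollectionDecoder(fh.read())
    if decoder.n_sequences != len(meta.records):
        raise CorruptStreamError(
            f"desc lists {len(meta.records)} sequences but the collection "
            f"stream holds {decoder.n_sequences}"
        )
    last = decoder.n_sequences - 1 if stop_after is None else stop_after
    out: list[SequenceRecord | None] = []
    n_expanded = 0
    for k in range(last + 1):
        d = decoder.decode_sequence()
        eligible = params.is_eligible_reference(k)
        is_target = k == last
        if eligible or is_target or not expand_only_needed:
            l1 = reconstruct_tuple_sequence(d, decoder.prior)
            n_expanded += 1
            if eligible:
                decoder.add_prior(k, l1)
            if is_target or not expand_only_needed:
                source, seq_id, length, width = meta.records[k]
                data = reconstruct_sequence(l1, reference)
                if len(data) != length:
                    raise CorruptStreamError(
                        f"sequence {k} ({seq_id!r}) decoded to {len(data)} "
                        f"symbols, expected {length}"
                    )
                out.append(
                    SequenceRecord(
                        id=seq_id,
                        data=data,
                        source_file=source,
                        index_in_file=0,
                        line_width=width,
                    )
                )
            else:
                out.append(None)
        else:
            out.append(None)
    return out, meta, n_expanded


def decompress(
    archive: Archive | str | os.PathLike, out_dir: str | os.PathLike
) -> list[str]:
    """Rebuild the original multi-FASTA files; returns written paths."""
    if not isinstance(archive, Archive):
        archive = Archive.at_prefix(archive)
    records, meta, _ = _decode_records(archive)
    os.makedirs(out_dir, exist_ok=True)
    by_file: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_file.setdefault(rec.source_file, []).append(rec)
    written = []
    for name, recs in by_file.items():
        for i, r in enumerate(recs):
            r.index_in_file = i
        path = os.path.join(os.fspath(out_dir), name)
        write_multifasta(recs, path)
        written.append(path)
    return written


def extract_sequence(
    archive: Archive | str | os.PathLike,
    target: int | str,
    return_stats: bool = False,
):
    """Extract one sequence by ordinal or id without a full decompress.

    Only the eligible second-level reference streams preceding the
    target (at most ceil(ref_fraction * n)) plus the target itself are
    expanded; everything else is merely field-decoded to keep the coder
    in sync.  With ``return_stats`` also returns that expansion count.
    """
    if not isinstance(archive, Archive):
        archive = Archive.at_prefix(archive)
    meta = archive.read_meta()
    if isinstance(target, int):
        if not 0 <= target < len(meta.records):
            raise KeyError(f"no sequence with ordinal {target}")
        idx = target
    else:
        ids = [r[1] for r in meta.records]
        if target not in ids:
            raise KeyError(f"no sequence with id {target!r}")
        idx = ids.index(target)
    records, _, n_expanded = _decode_records(
        archive, stop_after=idx, expand_only_needed=True
    )
    rec = records[idx]
    if return_stats:
        return rec, n_expanded
    return rec


def archive_info(archive: Archive | str | os.PathLike) -> dict:
    """Parameters, record table and size accounting for an archive.

    The reported ratio is raw FASTA bytes over (desc + rc) bytes; the
    reference stream is excluded by convention.
    """
    if not isinstance(archive, Archive):
        archive = Archive.at_prefix(archive)
    meta = archive.read_meta()
    sizes = archive.stream_sizes()
    raw = 0
    for source, seq_id, length, width in meta.records:
        n_lines = (length + width - 1) // width if length else 0
        raw += len(seq_id) + 2 + length + n_lines  # '>' + header + newlines
    compressed = sizes["desc"] + sizes["rc"]
    return {
        "params": meta.params,
        "n_sequences": len(meta.records),
        "records": meta.records,
        "sizes": sizes,
        "raw_bytes": raw,
        "ratio": raw / compressed if compressed else float("nan"),
    }
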