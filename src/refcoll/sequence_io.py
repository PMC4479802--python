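"""Multi-FASTA reading/writing and collection metadata.

The compressor is lossless at the level of (header, sequence content, one
wrap width per record): a file re-emitted after decompression has identical
ids and residues, wrapped uniformly at the width observed for each record in
the source file.  Case is significant (soft-masked runs survive a round
trip) and the sequence alphabet is restricted to ASCII letters, which covers
A/C/G/T, N and the degenerate IUPAC codes in both cases.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

__all__ = [
    "FastaFormatError",
    "SequenceRecord",
    "CollectionMeta",
    "read_multifasta",
    "write_multifasta",
]

DEFAULT_LINE_WIDTH = 60

_LETTERS = frozenset(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
)


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA input (with a line number)."""


@dataclass
class SequenceRecord:
    """One FASTA record plus the provenance needed for reconstruction.

    Attributes
    ----------
    id:
        Header line without the leading ``>``; never empty.
    data:
        Sequence residues, ASCII letters only, case preserved.  May be
        empty (a header with no body lines).
    source_file:
        Basename of the file the record came from ("" if synthetic).
    index_in_file:
        0-based position of the record within its source file.
    line_width:
        Wrap width observed in the source (length of the first full
        sequence line), used to re-wrap on output.
    """

    id: str
    data: str
    source_file: str = ""
    index_in_file: int = 0
    line_width: int = DEFAULT_LINE_WIDTH

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.line_width < 1:
            raise ValueError("line_width must be positive")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class CollectionMeta:
    """Ordered per-record metadata stored in the archive description stream.

    ``records`` holds (source_file, id, length, line_width) in compression
    order; lengths are authoritative and checked against the decoded stream.
    ``params`` is the parameter mapping the archive was written with.
    """

    records: list[tuple[str, str, int, int]] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _validate_body(data: str, path: str, line_no: int) -> None:
    if not set(data) <= _LETTERS:
        bad = next(c for c in data if c not in _LETTERS)
        raise FastaFormatError(
            f"{path}:{line_no}: non-letter character {bad!r} in sequence body"
        )


def read_multifasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a multi-FASTA file into a list of :class:`SequenceRecord`.

    The wrap width of a record is the length of its first sequence line
    (or the full sequence length for single-line records; a default for
    empty records).  Raises :class:`FastaFormatError` on a missing header
    or non-letter body characters, naming the offending line.
    """
    path = os.fspath(path)
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    parts: list[str] = []
    first_line_len = 0

    def flush() -> None:
        nonlocal header, parts, first_line_len
        if header is None:
            return
        data = "".join(parts)
        width = first_line_len if first_line_len > 0 else DEFAULT_LINE_WIDTH
        records.append(
            SequenceRecord(
                id=header,
                data=data,
                source_file=os.path.basename(path),
                index_in_file=len(records),
                line_width=width,
            )
        )
        header, parts, first_line_len = None, [], 0

    with open(path, "r", encoding="ascii") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = line_no
                if not header:
                    raise FastaFormatError(
                        f"{path}:{line_no}: empty FASTA header"
                    )
            else:
                if header is None:
                    raise FastaFormatError(
                        f"{path}:{line_no}: sequence data before any '>' header"
                    )
                _validate_body(line, path, line_no)
                if not parts:
                    first_line_len = len(line)
                parts.append(line)
        flush()
    return records


def write_multifasta(records: list[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records in order, wrapping each at its own ``line_width``."""
    path = os.fspath(path)
    with open(path, "w", encoding="ascii") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            w = rec.line_width
            for i in range(0, len(rec.data), w):
                fh.write(rec.data[i : i + w])
                fh.write("\n")
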