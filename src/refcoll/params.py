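"""Compression parameters shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CodecParams", "DEFAULT_PARAMS", "TOY_PARAMS"]


@dataclass(frozen=True)
class CodecParams:
    """Tunables of the two-level factoring and its entropy coding.

    Attributes
    ----------
    h1m:
        Seed / minimum length (symbols) of a first-level reference match.
    h1e:
        Minimum length of a short match accepted right after a variant
        check (substitution or 1–2 bp indel) following another match.
    h2:
        Minimum weight of a second-level match (literal tuples weigh 1,
        first-level match tuples weigh ``match_weight``).
    indel2:
        Also probe 2-symbol insertions/deletions in the variant check
        (5 probes instead of 3).
    ref_fraction:
        Fraction of the collection usable as second-level references;
        1.0 indexes every processed sequence, 0 disables the second
        level entirely.  Eligible sequences are spread evenly (every
        round(1/f)-th sequence), bounding how much must be decoded to
        extract one sequence.
    match_weight:
        Weight of a first-level match tuple in the run-weight rule.
    """

    h1m: int = 15
    h1e: int = 4
    h2: int = 11
    indel2: bool = False
    ref_fraction: float = 1.0
    match_weight: int = 7

    def __post_init__(self) -> None:
        if not (1 <= self.h1e <= self.h1m <= 255):
            raise ValueError("need 1 <= h1e <= h1m <= 255")
        if not (1 <= self.h2 <= 255):
            raise ValueError("need 1 <= h2 <= 255")
        if not (0.0 <= self.ref_fraction <= 1.0):
            raise ValueError("ref_fraction must be in [0, 1]")
        if self.stride > 127:
            raise ValueError("ref_fraction below 1/127 is not representable")

    @property
    def stride(self) -> int:
        """Eligibility stride: 0 disables the second level."""
        if self.ref_fraction <= 0.0:
            return 0
        return max(1, round(1.0 / self.ref_fraction))

    def is_eligible_reference(self, seq_index: int) -> bool:
        """May sequence ``seq_index`` serve as a second-level reference?"""
        s = self.stride
        return s > 0 and seq_index % s == 0


DEFAULT_PARAMS = CodecParams()

#: Tiny hand-checkable configuration (short seeds, light match weight)
#: used by the worked factoring examples and fixtures.
TOY_PARAMS = CodecParams(h1m=3, h1e=2, h2=3, match_weight=2)
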