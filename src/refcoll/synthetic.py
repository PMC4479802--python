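"""Synthetic references and genome collections with controlled divergence.

The generator emulates the inputs the compressor targets: collections of
near-identical same-species genomes.  Divergence from the reference is
built from the variant types that drive the parser design — SNPs, short
(1–3 bp) indels, longer structural insertions/deletions, runs of N
(unknown bases) and optional lowercase soft-masking.

Two collection modes exist.  *Independent* mode mutates each record
separately, which produces sequences that share a reference but not each
other's variants.  *Diploid* mode emulates a resequencing panel with
linkage structure: a small panel of founder haplotypes carries the
population's variants, each individual's ancestor genotype is a mosaic of
founder segments (switch points playing the role of historical
recombination), and the two haplotypes of an individual are that ancestor
plus a small private divergence step.  Siblings are therefore far closer
to each other than to the reference, and unrelated individuals share long
identical stretches wherever their mosaics use the same founder — the
linkage disequilibrium that gives the second factoring level runs to
copy.  Fully independent mutants would leave it almost nothing to find.

All randomness flows from ``numpy.random.default_rng`` seeded via
``SeedSequence(profile.seed)``; fixed seeds give byte-identical output on
any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .sequence_io import DEFAULT_LINE_WIDTH, SequenceRecord

__all__ = [
    "DivergenceProfile",
    "generate_reference",
    "mutate",
    "generate_collection",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
_N = ord("N")


@dataclass(frozen=True)
class DivergenceProfile:
    """Per-sequence divergence rates (probabilities are per base).

    ``sv_count`` long insertions/deletions of ``sv_len_range`` bases are
    applied per sequence; ``n_run_rate``/``n_run_len`` control unknown-base
    runs and ``lowercase_rate``/``lowercase_run_len`` soft-masked runs.
    """

    snp_rate: float = 0.001
    indel_rate: float = 0.0001
    indel_max: int = 3
    sv_count: int = 0
    sv_len_range: tuple[int, int] = (300, 1000)
    n_run_rate: float = 0.0
    n_run_len: int = 100
    lowercase_rate: float = 0.0
    lowercase_run_len: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "n_run_rate", "lowercase_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def generate_reference(
    length: int,
    seed: int = 0,
    n_run_rate: float = 0.0,
    n_run_len: int = 100,
) -> str:
    """Uniform ACGT reference of ``length`` bases, optionally with N-runs."""
    if length < 1:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    arr = _ACGT[rng.integers(0, 4, size=length)]
    if n_run_rate > 0:
        starts = np.flatnonzero(rng.random(length) < n_run_rate)
        for s in starts:
            arr[s : s + n_run_len] = _N
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# mutation machinery
# ---------------------------------------------------------------------------

def _substitute(arr: np.ndarray, positions: np.ndarray, rng) -> None:
    """Replace bases at ``positions`` with a *different* ACGT base, in place."""
    if len(positions) == 0:
        return
    old = arr[positions]
    # map ACGT to 0..3; anything else (N, IUPAC, lowercase) to 4
    idx = np.full(len(positions), 4, dtype=np.int64)
    for code, b in enumerate(_ACGT):
        idx[old == b] = code
    shift = rng.integers(1, 4, size=len(positions))
    new = _ACGT[(idx + shift) % 4]
    non_acgt = idx == 4
    if non_acgt.any():
        new[non_acgt] = _ACGT[rng.integers(0, 4, size=int(non_acgt.sum()))]
    arr[positions] = new


def _apply_indels(
    arr: np.ndarray,
    positions: np.ndarray,
    is_insertion: np.ndarray,
    lengths: np.ndarray,
    rng,
) -> np.ndarray:
    """Apply short indels at sorted ``positions``; returns a new array."""
    if len(positions) == 0:
        return arr
    pieces: list[np.ndarray] = []
    prev = 0
    for pos, ins, ln in zip(positions.tolist(), is_insertion.tolist(),
                            lengths.tolist()):
        if pos < prev:
            continue  # overlapping event, skip
        if ins:
            pieces.append(arr[prev:pos])
            pieces.append(_ACGT[rng.integers(0, 4, size=ln)])
            prev = pos
        else:
            pieces.append(arr[prev:pos])
            prev = min(pos + ln, len(arr))
    pieces.append(arr[prev:])
    return np.concatenate(pieces)


def _mask_runs(arr: np.ndarray, rate: float, run_len: int, rng,
               lowercase: bool) -> np.ndarray:
    if rate <= 0 or len(arr) == 0:
        return arr
    starts = np.flatnonzero(rng.random(len(arr)) < rate)
    for s in starts:
        if lowercase:
            seg = arr[s : s + run_len]
            upper = (seg >= ord("A")) & (seg <= ord("Z"))
            seg[upper] += 32
        else:
            arr[s : s + run_len] = _N
    return arr


def mutate(reference: str, profile: DivergenceProfile, rng=None) -> str:
    """One mutated copy of ``reference`` under ``profile``.

    Events are applied in order: structural variants, then per-base SNPs
    and short indels, then N-runs and lowercase masking.  Deterministic
    for a fixed ``profile.seed`` (or an explicitly supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(profile.seed))
    arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8).copy()

    for _ in range(profile.sv_count):
        lo, hi = profile.sv_len_range
        ln = int(rng.integers(lo, hi + 1))
        pos = int(rng.integers(0, max(len(arr), 1)))
        if rng.random() < 0.5:
            arr = np.concatenate(
                [arr[:pos], _ACGT[rng.integers(0, 4, size=ln)], arr[pos:]]
            )
        else:
            arr = np.concatenate([arr[:pos], arr[pos + ln :]])

    if len(arr) and profile.snp_rate > 0:
        mask = rng.random(len(arr)) < profile.snp_rate
        _substitute(arr, np.flatnonzero(mask), rng)
    if len(arr) and profile.indel_rate > 0:
        pos = np.flatnonzero(rng.random(len(arr)) < profile.indel_rate)
        ins = rng.random(len(pos)) < 0.5
        lens = rng.integers(1, profile.indel_max + 1, size=len(pos))
        arr = _apply_indels(arr, pos, ins, lens, rng)

    arr = _mask_runs(arr, profile.n_run_rate, profile.n_run_len, rng, False)
    arr = _mask_runs(arr, profile.lowercase_rate, profile.lowercase_run_len,
                     rng, True)
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# founder panel (diploid mode)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _FounderPanel:
    """Variant tables of the founder haplotypes, in reference coordinates.

    Per founder: SNP positions with a cyclic-substitution shift, and indel
    positions with direction and length.  Keeping variants as tables (not
    strings) lets mosaics switch founders at reference coordinates even in
    the presence of indels.
    """

    snp_pos: list[np.ndarray]
    snp_shift: list[np.ndarray]
    indel_pos: list[np.ndarray]
    indel_ins: list[np.ndarray]
    indel_len: list[np.ndarray]


def _build_panel(length: int, profile: DivergenceProfile, rng,
                 n_founders: int) -> _FounderPanel:
    snp_pos, snp_shift = [], []
    indel_pos, indel_ins, indel_len = [], [], []
    for _ in range(n_founders):
        sp = np.flatnonzero(rng.random(length) < profile.snp_rate)
        snp_pos.append(sp)
        snp_shift.append(rng.integers(1, 4, size=len(sp)))
        ip = np.flatnonzero(rng.random(length) < profile.indel_rate)
        indel_pos.append(ip)
        indel_ins.append(rng.random(len(ip)) < 0.5)
        indel_len.append(rng.integers(1, profile.indel_max + 1, size=len(ip)))
    return _FounderPanel(snp_pos, snp_shift, indel_pos, indel_ins, indel_len)


def _mosaic_haplotype(
    ref_arr: np.ndarray,
    panel: _FounderPanel,
    switches: np.ndarray,
    founders: np.ndarray,
) -> np.ndarray:
    """Apply the variants of a founder mosaic to the reference.

    ``switches`` are segment boundaries (sorted, ending at len(ref)) and
    ``founders`` the founder index used within each segment.
    """
    arr = ref_arr.copy()
    sel_ipos, sel_iins, sel_ilen = [], [], []
    lo = 0
    for hi, f in zip(switches.tolist(), founders.tolist()):
        sp, sh = panel.snp_pos[f], panel.snp_shift[f]
        m = (sp >= lo) & (sp < hi)
        pos, shift = sp[m], sh[m]
        if len(pos):
            old = arr[pos]
            idx = np.full(len(pos), 4, dtype=np.int64)
            for code, b in enumerate(_ACGT):
                idx[old == b] = code
            new = _ACGT[(idx + shift) % 4]
            bad = idx == 4
            if bad.any():
                new[bad] = _ACGT[shift[bad] % 4]
            arr[pos] = new
        ip = panel.indel_pos[f]
        m = (ip >= lo) & (ip < hi)
        sel_ipos.append(ip[m])
        sel_iins.append(panel.indel_ins[f][m])
        sel_ilen.append(panel.indel_len[f][m])
        lo = hi
    ipos = np.concatenate(sel_ipos) if sel_ipos else np.empty(0, np.int64)
    if len(ipos):
        # inserted bases derived from a fixed stream: identical sites in
        # different haplotypes insert identical bases
        site_rng = np.random.default_rng(np.random.SeedSequence(0xD1CE))
        arr = _apply_indels(
            arr,
            ipos,
            np.concatenate(sel_iins),
            np.concatenate(sel_ilen),
            site_rng,
        )
    return arr


def generate_collection(
    reference: str,
    n: int,
    profile: DivergenceProfile,
    diploid: bool = False,
    n_founders: int = 8,
    recomb_rate: float = 3e-6,
    private_fraction: float = 0.1,
    id_prefix: str = "seq",
) -> list[SequenceRecord]:
    """Generate ``n`` mutated records from ``reference``.

    Independent mode derives one seed per record and calls :func:`mutate`.
    Diploid mode builds ``n_founders`` founder variant tables at the
    profile's rates, draws one founder mosaic per individual (switch
    points at ``recomb_rate`` per base) and emits records ``2k`` and
    ``2k+1`` as that ancestor plus a private divergence step of
    ``private_fraction`` times the nominal rates — so haplotype pairs are
    mutually far more similar than either is to the reference, and
    unrelated individuals share long founder stretches.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ss = np.random.SeedSequence(profile.seed)
    children = ss.spawn(n + 1)
    records: list[SequenceRecord] = []

    if not diploid:
        for i in range(n):
            rng = np.random.default_rng(children[i])
            data = mutate(reference, profile, rng=rng)
            records.append(
                SequenceRecord(
                    id=f"{id_prefix}_{i:04d}",
                    data=data,
                    index_in_file=i,
                    line_width=DEFAULT_LINE_WIDTH,
                )
            )
        return records

    panel_rng = np.random.default_rng(children[n])
    ref_arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
    panel = _build_panel(len(reference), profile, panel_rng, n_founders)
    private = replace(
        profile,
        snp_rate=profile.snp_rate * private_fraction,
        indel_rate=profile.indel_rate * private_fraction,
        sv_count=0,
    )
    length = len(reference)
    for i in range(n):
        rng = np.random.default_rng(children[i])
        if i % 2 == 0:
            # new individual: draw the ancestor mosaic
            n_switch = rng.poisson(recomb_rate * length)
            cuts = np.sort(rng.integers(1, max(length, 2), size=n_switch))
            switches = np.append(cuts, length)
            founders = rng.integers(0, n_founders, size=len(switches))
            _mosaic = (switches, founders)
        else:
            switches, founders = _mosaic
        hap = _mosaic_haplotype(ref_arr, panel, switches, founders)
        data = mutate(hap.tobytes().decode("ascii"), private, rng=rng)
        records.append(
            SequenceRecord(
                id=f"{id_prefix}_{i // 2:04d}_h{i % 2}",
                data=data,
                index_in_file=i,
                line_width=DEFAULT_LINE_WIDTH,
            )
        )
    return records
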