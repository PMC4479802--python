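import os

import pytest

from conftest import mutated_copy, random_dna
from refcoll.archive import (
    Archive,
    archive_info,
    compress,
    decode_reference_stream,
    decompress,
    encode_reference_stream,
    extract_sequence,
)
from refcoll.params import CodecParams
from refcoll.sequence_io import SequenceRecord, read_multifasta, write_multifasta
from refcoll.synthetic import DivergenceProfile, generate_collection, generate_reference


def _setup(tmp_path, reference, records, name="coll.fa"):
    ref_path = tmp_path / "ref.fa"
    write_multifasta([SequenceRecord(id="ref", data=reference)], ref_path)
    coll_path = tmp_path / name
    for r in records:
        r.source_file = name
    write_multifasta(records, coll_path)
    return ref_path, coll_path


def _assert_roundtrip(tmp_path, reference, records, params=CodecParams(),
                      n_files=1):
    paths = []
    per_file = max(1, len(records) // n_files)
    ref_path = tmp_path / "ref.fa"
    write_multifasta([SequenceRecord(id="ref", data=reference)], ref_path)
    for fi in range(0, len(records), per_file):
        name = f"coll{fi}.fa"
        chunk = records[fi : fi + per_file]
        for r in chunk:
            r.source_file = name
        p = tmp_path / name
        write_multifasta(chunk, p)
        paths.append(p)
    arch = compress(ref_path, paths, tmp_path / "arch", params)
    out_dir = tmp_path / "out"
    written = decompress(arch, out_dir)
    assert len(written) == len(paths)
    for p in paths:
        original = p.read_bytes()
        restored = (out_dir / p.name).read_bytes()
        assert restored == original
    return arch


class TestRoundTrip:
    def test_single_sequence(self, tmp_path, rng):
        ref = random_dna(rng, 500)
        recs = [SequenceRecord(id="s0", data=mutated_copy(rng, ref, 0.01))]
        _assert_roundtrip(tmp_path, ref, recs)

    def test_empty_collection(self, tmp_path, rng):
        ref = random_dna(rng, 100)
        ref_path = tmp_path / "ref.fa"
        write_multifasta([SequenceRecord(id="ref", data=ref)], ref_path)
        arch = compress(ref_path, [], tmp_path / "arch")
        written = decompress(arch, tmp_path / "out")
        assert written == []

    def test_mixed_case_n_rich_collection(self, tmp_path, rng):
        ref = random_dna(rng, 800)
        recs = []
        for i in range(6):
            data = mutated_copy(rng, ref, 0.01)
            if i % 2:
                data = data[:100].lower() + data[100:]
            if i % 3 == 0:
                data = data[:50] + "N" * 120 + data[170:]
            recs.append(SequenceRecord(id=f"s{i}", data=data, line_width=50))
        recs.append(SequenceRecord(id="empty", data=""))
        recs.append(SequenceRecord(id="allN", data="N" * 80))
        recs.append(SequenceRecord(id="tiny", data="ACG"))
        _assert_roundtrip(tmp_path, ref, recs, n_files=3)

    def test_level1_only_mode(self, tmp_path, rng):
        ref = random_dna(rng, 600)
        recs = [
            SequenceRecord(id=f"s{i}", data=mutated_copy(rng, ref, 0.01))
            for i in range(4)
        ]
        _assert_roundtrip(tmp_path, ref, recs,
                          params=CodecParams(ref_fraction=0.0))

    def test_compression_order_is_file_then_record_order(self, tmp_path, rng):
        ref = random_dna(rng, 300)
        recs = [
            SequenceRecord(id=f"s{i}", data=mutated_copy(rng, ref, 0.02))
            for i in range(4)
        ]
        arch = _assert_roundtrip(tmp_path, ref, recs, n_files=2)
        meta = arch.read_meta()
        assert [r[1] for r in meta.records] == ["s0", "s1", "s2", "s3"]


class TestExtraction:
    @pytest.fixture()
    def small_archive(self, tmp_path, rng):
        ref = random_dna(rng, 2000)
        prof = DivergenceProfile(snp_rate=0.005, indel_rate=0.0005, seed=11)
        recs = generate_collection(ref, 20, prof, diploid=True)
        ref_path, coll_path = _setup(tmp_path, ref, recs)
        params = CodecParams(ref_fraction=0.2)
        arch = compress(ref_path, [coll_path], tmp_path / "arch", params)
        return arch, recs

    def test_first_sequence_decodes_exactly_one(self, small_archive):
        arch, recs = small_archive
        rec, n_expanded = extract_sequence(arch, 0, return_stats=True)
        assert rec.data == recs[0].data
        assert n_expanded == 1

    def test_extraction_matches_full_decompress(self, small_archive):
        arch, recs = small_archive
        for target in (3, 7, 19):
            rec, n_expanded = extract_sequence(arch, target,
                                               return_stats=True)
            assert rec.data == recs[target].data
            # eligible references before target (stride 5) plus the target
            eligible_before = len(
                [u for u in range(target) if u % 5 == 0]
            )
            assert n_expanded <= eligible_before + 1

    def test_extract_by_id(self, small_archive):
        arch, recs = small_archive
        rec = extract_sequence(arch, recs[5].id)
        assert rec.data == recs[5].data

    def test_unknown_target_raises(self, small_archive):
        arch, _ = small_archive
        with pytest.raises(KeyError):
            extract_sequence(arch, "no-such-id")
        with pytest.raises(KeyError):
            extract_sequence(arch, 99)


class TestReferenceStream:
    def test_empty_reference_roundtrips(self):
        assert decode_reference_stream(encode_reference_stream("")) == ""

    def test_length_not_divisible_by_three(self):
        assert decode_reference_stream(
            encode_reference_stream("ACGTA")
        ) == "ACGTA"

    def test_random_reference_roundtrip_and_entropy_bound(self, rng):
        """Round trip plus a 2-bit/symbol ceiling on uniform ACGT + N."""
        ref = generate_reference(200_000, seed=5, n_run_rate=1e-4,
                                 n_run_len=200)
        stream = encode_reference_stream(ref)
        assert decode_reference_stream(stream) == ref
        assert len(stream) < 0.35 * len(ref)

    def test_corrupt_stream_detected(self):
        with pytest.raises(ValueError, match="magic"):
            decode_reference_stream(b"garbagegarbage")


class TestInfo:
    def test_info_reports_sizes_and_ratio(self, tmp_path, rng):
        ref = random_dna(rng, 1000)
        recs = [
            SequenceRecord(id=f"s{i}", data=mutated_copy(rng, ref, 0.005))
            for i in range(5)
        ]
        arch = _assert_roundtrip(tmp_path, ref, recs)
        info = archive_info(arch)
        assert info["n_sequences"] == 5
        assert info["ratio"] > 1
        assert set(info["sizes"]) == {"desc", "rc", "ref"}

    def test_archive_open_by_prefix(self, tmp_path, rng):
        ref = random_dna(rng, 400)
        recs = [SequenceRecord(id="s0", data=ref)]
        _assert_roundtrip(tmp_path, ref, recs)
        arch = Archive.at_prefix(tmp_path / "arch")
        assert arch.read_meta().records[0][1] == "s0"


def test_second_level_shrinks_archive(tmp_path, rng):
    """The second level must beat level-1-only on a redundant collection."""
    ref = generate_reference(60_000, seed=3)
    prof = DivergenceProfile(snp_rate=0.001, indel_rate=0.0001, seed=4)
    recs = generate_collection(ref, 12, prof, diploid=True)
    ref_path, coll_path = _setup(tmp_path, ref, recs)
    a2 = compress(ref_path, [coll_path], tmp_path / "with_l2",
                  CodecParams(ref_fraction=1.0))
    a1 = compress(ref_path, [coll_path], tmp_path / "no_l2",
                  CodecParams(ref_fraction=0.0))
    assert a2.stream_sizes()["rc"] < a1.stream_sizes()["rc"]
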