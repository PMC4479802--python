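import numpy as np
import pytest

from conftest import mutated_copy, random_dna
from refcoll.collection_codec import (
    GOOD,
    L1_POOR,
    MODERATE,
    PERFECT,
    POOR,
    CollectionDecoder,
    CollectionEncoder,
    L1Predictor,
    L2Predictor,
    classify_l1_length,
    classify_l1_position_delta,
    classify_l2_length,
    classify_l2_position_delta,
    expected_l2_position,
    join_sequence_id,
    reassemble_l1_length,
    reassemble_l1_position_delta,
    reassemble_l2_length,
    reassemble_l2_position_delta,
    split_sequence_id,
)
from refcoll.first_level import L1Sequence, L1Tuple, factor_sequence
from refcoll.params import CodecParams
from refcoll.rangecoder import AdaptiveModel, ContextModel, RangeDecoder, RangeEncoder
from refcoll.reference_index import ReferenceIndex
from refcoll.second_level import L2Tuple, TupleIndex, factor_tuple_sequence


class TestClassifiers:
    @pytest.mark.parametrize(
        "delta,cls,n_bytes",
        [(0, PERFECT, 0), (-3, GOOD, 1), (127, GOOD, 1), (-127, GOOD, 1),
         (128, L1_POOR, 4), (100_000, L1_POOR, 4)],
    )
    def test_l1_position_classes(self, delta, cls, n_bytes):
        got_cls, payload = classify_l1_position_delta(delta)
        assert (got_cls, len(payload)) == (cls, n_bytes)
        assert reassemble_l1_position_delta(got_cls, payload) == delta

    def test_l1_position_roundtrip_scan(self):
        for delta in range(-1500, 1500):
            cls, payload = classify_l1_position_delta(delta)
            assert reassemble_l1_position_delta(cls, payload) == delta

    @pytest.mark.parametrize(
        "length,cls,n_bytes",
        [(1, 0, 1), (256, 0, 1), (257, 1, 2), (65792, 1, 2), (65793, 2, 4)],
    )
    def test_l1_length_classes(self, length, cls, n_bytes):
        got_cls, payload = classify_l1_length(length)
        assert (got_cls, len(payload)) == (cls, n_bytes)

    def test_l1_length_roundtrip_scan(self):
        for length in list(range(1, 70_000, 7)) + [65792, 65793, 100_000]:
            cls, payload = classify_l1_length(length)
            assert reassemble_l1_length(cls, payload) == length

    @pytest.mark.parametrize(
        "diff,cls",
        [(0, PERFECT), (1, GOOD), (-16, GOOD), (17, MODERATE),
         (-256, MODERATE), (257, POOR), (-1_000_000, POOR)],
    )
    def test_l2_position_classes(self, diff, cls):
        assert classify_l2_position_delta(diff)[0] == cls

    def test_l2_position_roundtrip_scan(self):
        deltas = list(range(-300, 300)) + [1000, -1000, 10**6, -(10**6)]
        for diff in deltas:
            cls, payload = classify_l2_position_delta(diff)
            assert reassemble_l2_position_delta(cls, payload) == diff

    @pytest.mark.parametrize(
        "length,cls",
        [(1, 0), (16, 0), (17, 1), (48, 1), (49, 2), (176, 2), (177, 3),
         (432, 3), (433, 4)],
    )
    def test_l2_length_classes(self, length, cls):
        assert classify_l2_length(length)[0] == cls

    def test_l2_length_roundtrip_scan(self):
        for length in list(range(1, 2000)) + [50_000, 100_000]:
            cls, payload = classify_l2_length(length)
            assert reassemble_l2_length(cls, payload) == length

    def test_sequence_id_split_exhaustive(self):
        for i in range(0, 1 << 16, 37):
            assert join_sequence_id(*split_sequence_id(i)) == i
        assert split_sequence_id(258) == (1, 2)
        assert split_sequence_id(0) == (0, 0)
        with pytest.raises(ValueError, match="2\\^16"):
            split_sequence_id(1 << 16)


class TestRangeCoder:
    def test_known_small_stream(self):
        enc = RangeEncoder()
        m = AdaptiveModel(4)
        for s in [0, 1, 2, 3, 0, 0, 1]:
            m.encode(enc, s)
        data = enc.finish()
        dec = RangeDecoder(data)
        m2 = AdaptiveModel(4)
        assert [m2.decode(dec) for _ in range(7)] == [0, 1, 2, 3, 0, 0, 1]

    def test_random_model_configurations_roundtrip(self, rng):
        """decode(encode(x)) == x across many model/stream shapes."""
        for _ in range(300):
            n_sym = int(rng.integers(2, 260))
            n_models = int(rng.integers(1, 4))
            length = int(rng.integers(1, 200))
            stream = rng.integers(0, n_sym, size=length).tolist()
            picks = rng.integers(0, n_models, size=length).tolist()
            enc = RangeEncoder()
            models = [AdaptiveModel(n_sym) for _ in range(n_models)]
            for s, p in zip(stream, picks):
                models[p].encode(enc, s)
            data = enc.finish()
            dec = RangeDecoder(data)
            models2 = [AdaptiveModel(n_sym) for _ in range(n_models)]
            out = [models2[p].decode(dec) for p in picks]
            assert out == stream

    def test_skewed_model_compresses(self, rng):
        """A heavily skewed source should code well under 1 bit/symbol."""
        enc = RangeEncoder()
        m = AdaptiveModel(256)
        stream = [0 if rng.random() < 0.98 else 1 for _ in range(5000)]
        for s in stream:
            m.encode(enc, s)
        assert len(enc.finish()) < 5000 / 8

    def test_rescaling_keeps_totals_bounded(self):
        m = AdaptiveModel(3)
        enc = RangeEncoder()
        for i in range(10_000):
            m.encode(enc, i % 3)
            assert m.total < 1 << 16


class TestPredictors:
    def test_l1_expected_position(self):
        p = L1Predictor()
        assert p.expected_pos == 0
        p.observe_match(100, 50)
        p.observe_symbols(3)
        assert p.expected_pos == 153

    def test_l2_cold_entry_predicts_zero(self):
        l_u = L1Sequence([L1Tuple.literal("A")] * 5)
        assert expected_l2_position(L2Predictor(), 3, 100, l_u) == 0

    def test_l2_no_advance_when_no_symbols_passed(self):
        pred = L2Predictor()
        pred.update(0, 5, 1000)
        l_u = L1Sequence([L1Tuple.literal("A")] * 10)
        assert expected_l2_position(pred, 0, 1000, l_u) == 5

    def test_l2_advance_matches_step_simulation(self, rng):
        """Vectorized advance equals a per-tuple simulation loop."""
        for _ in range(50):
            tuples = [
                L1Tuple.literal("A") if rng.random() < 0.5
                else L1Tuple.match(0, int(rng.integers(1, 30)))
                for _ in range(30)
            ]
            l_u = L1Sequence(tuples)
            p_a = int(rng.integers(0, 30))
            s_a = int(rng.integers(0, 50))
            sym_pos = s_a + int(rng.integers(0, 100))
            pred = L2Predictor()
            pred.update(7, p_a, s_a)
            got = expected_l2_position(pred, 7, sym_pos, l_u)
            # independent simulation of the advance rule
            d = sym_pos - s_a
            acc, q = 0, p_a
            while q < len(tuples) and acc + tuples[q].coverage <= d:
                acc += tuples[q].coverage
                q += 1
            assert got == q


def _random_collection_streams(rng, n_seqs=5, ref_len=400, params=None):
    params = params or CodecParams(h1m=9, h1e=4, h2=11)
    ref = random_dna(rng, ref_len)
    ridx = ReferenceIndex(ref, params.h1m)
    tidx = TupleIndex(params.h2, params.match_weight)
    prior = {}
    l1s, ds = [], []
    for k in range(n_seqs):
        seq = mutated_copy(rng, ref[: int(rng.integers(50, ref_len))], 0.02)
        l1 = factor_sequence(seq, ridx, params.h1e)
        d = factor_tuple_sequence(l1, tidx, prior)
        if params.is_eligible_reference(k):
            tidx.insert(l1, k)
            prior[k] = l1
        l1s.append(l1)
        ds.append(d)
    return ds, l1s, params


class TestCollectionCodec:
    def test_empty_collection(self):
        params = CodecParams()
        enc = CollectionEncoder(params)
        stream = enc.finish()
        dec = CollectionDecoder(stream)
        assert dec.n_sequences == 0
        assert dec.params == params

    def test_single_literal_sequence(self):
        enc = CollectionEncoder(CodecParams())
        enc.encode_sequence([L2Tuple.wrap(L1Tuple.literal("G"))])
        dec = CollectionDecoder(enc.finish())
        [d] = [dec.decode_sequence() for _ in range(dec.n_sequences)]
        assert d == [L2Tuple.wrap(L1Tuple.literal("G"))]

    def test_roundtrip_field_exact_with_state_digests(self, rng):
        """decode mirrors encode tuple-for-tuple and model-state-exact."""
        for trial in range(10):
            ds, l1s, params = _random_collection_streams(rng)
            enc = CollectionEncoder(params)
            enc_digests = []
            for k, d in enumerate(ds):
                enc.encode_sequence(d)
                if params.is_eligible_reference(k):
                    enc.add_prior(k, l1s[k])
                enc_digests.append(enc.state_digest())
            stream = enc.finish()
            dec = CollectionDecoder(stream)
            from refcoll.second_level import reconstruct_tuple_sequence

            for k in range(dec.n_sequences):
                got = dec.decode_sequence()
                assert got == ds[k]
                if dec.params.is_eligible_reference(k):
                    dec.add_prior(
                        k, reconstruct_tuple_sequence(got, dec.prior)
                    )
                assert dec.state_digest() == enc_digests[k]

    def test_header_rejects_garbage(self):
        with pytest.raises(ValueError, match="magic"):
            CollectionDecoder(b"NOTANARCHIVE" + b"\x00" * 16)

    def test_params_roundtrip_through_header(self):
        params = CodecParams(h1m=13, h1e=5, h2=9, indel2=True,
                             ref_fraction=0.25)
        enc = CollectionEncoder(params)
        dec = CollectionDecoder(enc.finish())
        assert dec.params.h1m == 13
        assert dec.params.h1e == 5
        assert dec.params.h2 == 9
        assert dec.params.indel2 is True
        assert dec.params.stride == 4


def test_unchanged_layout_predicts_perfectly(rng):
    """On a repeat of the same sequence, every later L1 delta is perfect."""
    ref = random_dna(rng, 3000)
    ridx = ReferenceIndex(ref, 15)
    seq = mutated_copy(rng, ref, 0.005)
    l1 = factor_sequence(seq, ridx, 4)
    pred = L1Predictor()
    classes = []
    for t in l1.tuples:
        if t.tag == L1Tuple.literal("A").tag:
            pred.observe_symbols(1)
        else:
            classes.append(classify_l1_position_delta(
                pred.expected_pos - t.pos)[0])
            pred.observe_match(t.pos, t.length)
    assert len(classes) >= 2
    assert all(c == PERFECT for c in classes[1:])
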