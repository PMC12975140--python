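"""Encoder unit and property tests.

Worked examples are frozen from hand enumeration; dimensional audits
cover every scheme x window-length combination.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m6ahd.encoders import (
    DINUCLEOTIDES,
    SCHEMES,
    EncoderSpec,
    EncodingError,
    FeatureMatrix,
    PseDNCParams,
    SequenceWindow,
    build_feature_matrix,
    encode_anf,
    encode_cp,
    encode_eiip,
    encode_nac,
    encode_onehot,
    encode_psednc,
    scheme_dims,
)

windows_st = st.text(alphabet="ACGU", min_size=4, max_size=30)


def _random_window(rng, L=21):
    half = (L - 1) // 2
    s = "".join(rng.choice(list("ACGU"), size=L))
    return s[:half] + "A" + s[half + 1 :]


class TestOneHot:
    def test_worked_example_uacgc(self):
        expected = [0, 0, 0, 1, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 1, 0, 0]
        assert encode_onehot("UACGC").tolist() == expected

    def test_single_bases(self):
        assert encode_onehot("A").tolist() == [1, 0, 0, 0]
        assert encode_onehot("C").tolist() == [0, 1, 0, 0]
        assert encode_onehot("G").tolist() == [0, 0, 1, 0]
        assert encode_onehot("U").tolist() == [0, 0, 0, 1]

    @given(windows_st)
    @settings(max_examples=50, derandomize=True)
    def test_exactly_one_hot_bit_per_position(self, seq):
        v = encode_onehot(seq).reshape(-1, 4)
        assert (v.sum(axis=1) == 1).all()
        assert v.sum() == len(seq)

    def test_bad_character_names_position(self):
        with pytest.raises(EncodingError, match="position 2"):
            encode_onehot("ACNG")

    def test_dna_input_normalized(self):
        assert (encode_onehot("ACGT") == encode_onehot("ACGU")).all()


class TestNAC:
    def test_homopolymer(self):
        v = encode_nac("AAAA")
        assert v[DINUCLEOTIDES.index("AA")] == 1.0
        assert v.sum() == 1.0

    def test_single_dinucleotide(self):
        v = encode_nac("AU")
        assert v[DINUCLEOTIDES.index("AU")] == 1.0

    def test_auau_hand_enumeration(self):
        # overlapping dinucleotides of AUAU: AU, UA, AU
        v = encode_nac("AUAU")
        assert v[DINUCLEOTIDES.index("AU")] == pytest.approx(2 / 3)
        assert v[DINUCLEOTIDES.index("UA")] == pytest.approx(1 / 3)

    def test_too_short(self):
        with pytest.raises(EncodingError):
            encode_nac("A")

    @given(windows_st)
    @settings(max_examples=50, derandomize=True)
    def test_sums_to_one(self, seq):
        assert encode_nac(seq).sum() == pytest.approx(1.0, abs=1e-12)


class TestCP:
    def test_base_triples(self):
        assert encode_cp("A").tolist() == [1, 1, 1]
        assert encode_cp("C").tolist() == [0, 1, 0]
        assert encode_cp("G").tolist() == [1, 0, 0]
        assert encode_cp("U").tolist() == [0, 0, 1]

    def test_uacg_concatenation(self):
        assert encode_cp("UACG").tolist() == [0, 0, 1, 1, 1, 1, 0, 1, 0, 1, 0, 0]

    @given(windows_st)
    @settings(max_examples=50, derandomize=True)
    def test_x_channel_is_purine_indicator(self, seq):
        x = encode_cp(seq).reshape(-1, 3)[:, 0]
        assert x.tolist() == [1.0 if c in "AG" else 0.0 for c in seq]


class TestEIIP:
    def test_uacg_vector(self):
        assert encode_eiip("UACG").tolist() == [0.1335, 0.1260, 0.1340, 0.0806]

    def test_constant_sequence(self):
        assert encode_eiip("AAAA").tolist() == [0.1260] * 4

    def test_single_g(self):
        assert encode_eiip("G").tolist() == [0.0806]


class TestANF:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAA", [1.0, 1.0, 1.0, 1.0]),
            ("UACG", [1.0, 0.5, 1 / 3, 0.25]),
            ("AUAA", [1.0, 0.5, 2 / 3, 0.75]),
        ],
    )
    def test_hand_computed(self, seq, expected):
        assert encode_anf(seq).tolist() == pytest.approx(expected)

    @given(windows_st)
    @settings(max_examples=50, derandomize=True)
    def test_final_entry_is_overall_frequency_of_last_base(self, seq):
        v = encode_anf(seq)
        assert v[-1] == pytest.approx(seq.count(seq[-1]) / len(seq))
        assert ((v > 0) & (v <= 1)).all()


class TestPseDNC:
    def test_components_sum_to_one(self, rng):
        for _ in range(10):
            seq = _random_window(rng, 21)
            v = encode_psednc(seq, PseDNCParams(lam=3))
            assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_lambda_zero_reduces_to_nac(self, rng):
        for _ in range(10):
            seq = _random_window(rng, 21)
            v = encode_psednc(seq, PseDNCParams(lam=0))
            assert np.abs(v - encode_nac(seq)).max() < 1e-12

    def test_auau_lag1_hand_computed(self):
        # prop table with a single scalar property; lag-1 pairs of AUAU's
        # dinucleotides (AU, UA, AU) are (AU,UA) and (UA,AU)
        table = {d: np.array([0.0]) for d in DINUCLEOTIDES}
        table["AU"] = np.array([0.5])
        table["UA"] = np.array([-0.5])
        theta1 = ((0.5 - -0.5) ** 2 + (-0.5 - 0.5) ** 2) / 2  # = 1.0
        w = 0.1
        p = PseDNCParams(lam=1, w=w, prop_table=table)
        v = encode_psednc("AUAU", p)
        denom = 1.0 + w * theta1
        assert v[-1] == pytest.approx(w * theta1 / denom, abs=1e-12)
        assert v[DINUCLEOTIDES.index("AU")] == pytest.approx((2 / 3) / denom, abs=1e-12)

    def test_lambda_exceeding_length_rejected(self):
        with pytest.raises(EncodingError):
            encode_psednc("ACGU", PseDNCParams(lam=3))

    def test_incomplete_prop_table_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            PseDNCParams(prop_table={"AA": np.array([1.0])})


class TestSequenceWindow:
    def test_center_check_enforced(self):
        SequenceWindow("GGAGG")  # center A, odd -> fine
        with pytest.raises(ValueError, match="not 'A'"):
            SequenceWindow("GGCGG")
        with pytest.raises(ValueError, match="odd"):
            SequenceWindow("GGAG")

    def test_center_check_disabled(self):
        w = SequenceWindow("GGCG", center_check=False)
        assert len(w) == 4


class TestFeatureMatrix:
    @pytest.mark.parametrize("scheme", SCHEMES)
    @pytest.mark.parametrize("L", [21, 41, 81])
    def test_dimensional_audit(self, scheme, L, rng):
        lam = 3
        spec = EncoderSpec(schemes=(scheme,),
                           psednc=PseDNCParams(lam=lam) if scheme == "PseDNC" else None)
        w = SequenceWindow(_random_window(rng, L))
        fm = build_feature_matrix([w], spec, [1])
        assert fm.n_columns == scheme_dims(scheme, L, lam)
        assert len(spec.column_names(L)) == fm.n_columns

    def test_combined_dims_all_six(self, rng):
        # L=41, lam=3: 164+16+123+41+41+19 = 404
        ws = [SequenceWindow(_random_window(rng, 41)) for _ in range(3)]
        fm = build_feature_matrix(ws, EncoderSpec(), [1, 0, 1])
        assert fm.n_columns == 404

    def test_oh_plus_eiip_dims(self, rng):
        ws = [SequenceWindow(_random_window(rng, 41))]
        fm = build_feature_matrix(ws, EncoderSpec(schemes=("OH", "EIIP")), [1])
        assert fm.n_columns == 205

    def test_mixed_lengths_rejected(self, rng):
        ws = [SequenceWindow(_random_window(rng, 21)),
              SequenceWindow(_random_window(rng, 31))]
        with pytest.raises(ValueError, match="mixed"):
            build_feature_matrix(ws, EncoderSpec(schemes=("NAC",)), [0, 1])

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            EncoderSpec(schemes=())

    def test_canonical_order_independent_of_input_order(self):
        assert EncoderSpec(schemes=("EIIP", "OH")).schemes == ("OH", "EIIP")

    def test_encoding_is_pure(self, rng):
        w = SequenceWindow(_random_window(rng, 21))
        spec = EncoderSpec()
        a = build_feature_matrix([w], spec, [1]).values
        b = build_feature_matrix([w], spec, [1]).values
        assert (a == b).all()

    def test_tsv_round_trip(self, tmp_path, rng):
        ws = [SequenceWindow(_random_window(rng, 21)) for _ in range(5)]
        fm = build_feature_matrix(ws, EncoderSpec(), [1, 0, 1, 0, 1])
        path = tmp_path / "fm.tsv"
        fm.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        assert back.columns == fm.columns
        assert (back.labels == fm.labels).all()
        assert np.abs(back.values - fm.values).max() < 1e-12

    def test_value_ranges(self, rng):
        ws = [SequenceWindow(_random_window(rng, 21)) for _ in range(5)]
        fm = build_feature_matrix(ws, EncoderSpec(), [1, 0, 1, 0, 1])
        cols = np.array(fm.columns)
        for scheme, lo, hi in (("OH", 0, 1), ("CP", 0, 1)):
            block = fm.values[:, [c.startswith(scheme + ":") for c in cols]]
            assert set(np.unique(block)) <= {0.0, 1.0}
        for scheme in ("NAC", "ANF", "PseDNC"):
            block = fm.values[:, [c.startswith(scheme + ":") for c in cols]]
            assert block.min() >= 0 and block.max() <= 1
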