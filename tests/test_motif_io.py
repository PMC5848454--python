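import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbpknn.exceptions import FormatError, InputError
from rbpknn.motifs import (
    BACKGROUND_RATIO,
    PROBABILITY,
    PWM,
    PositionFrequencyMatrix,
    RBPRecord,
    filter_records,
    pfm_to_pwm,
    read_meme,
    read_pwm_text,
    write_meme,
    write_pwm_text,
)

from conftest import random_probability_pwm


class TestPwmType:
    def test_probability_columns_must_sum_to_one(self):
        bad = np.full((4, 3), 0.3)
        with pytest.raises(InputError):
            PWM(bad, PROBABILITY)

    def test_background_ratio_columns_must_average_one(self):
        ok = np.full((4, 3), 1.0)
        assert PWM(ok, BACKGROUND_RATIO).width == 3
        with pytest.raises(InputError):
            PWM(np.full((4, 3), 0.9), BACKGROUND_RATIO)

    def test_entries_must_be_positive(self):
        weights = np.full((4, 2), 0.25)
        weights[0, 0] = 0.0
        weights[1, 0] = 0.5
        with pytest.raises(InputError):
            PWM(weights, PROBABILITY)

    def test_scale_conversion_round_trip(self, rng):
        pwm = random_probability_pwm(rng)
        back = pwm.to_background_ratio().to_probability()
        np.testing.assert_allclose(back.weights, pwm.weights, rtol=1e-12)


class TestPfmToPwm:
    def test_add_one_pseudocount_column(self):
        counts = np.tile(np.array([[10.0], [0.0], [0.0], [0.0]]), (1, 7))
        pwm = pfm_to_pwm(PositionFrequencyMatrix(counts), 7, pseudocount=1.0)
        np.testing.assert_allclose(
            pwm.weights[:, 0], [11 / 14, 1 / 14, 1 / 14, 1 / 14], rtol=1e-12
        )

    def test_uniform_counts_give_flat_background_ratio(self):
        pfm = PositionFrequencyMatrix(np.ones((4, 7)))
        pwm = pfm_to_pwm(pfm, 7, pseudocount=1.0, scale=BACKGROUND_RATIO)
        np.testing.assert_allclose(pwm.weights, 1.0, rtol=1e-12)

    def test_informative_core_window_retained(self, rng):
        # 4x9 PFM: flat flanks, 7 informative core columns; brute-force the
        # best of the 3 candidate windows by total information content
        core = rng.dirichlet(np.full(4, 0.3), size=7).T * 100
        flat = np.full((4, 1), 25.0)
        counts = np.hstack([flat, core, flat])
        pfm = PositionFrequencyMatrix(counts)
        pwm = pfm_to_pwm(pfm, 7, pseudocount=0.5)

        def window_ic(start):
            w = counts[:, start : start + 7]
            p = w / w.sum(axis=0)
            p = np.clip(p, 1e-12, None)
            return np.sum(p * np.log2(p / 0.25))

        best = max(range(3), key=window_ic)
        expected = (counts[:, best : best + 7] + 0.5) / (
            counts[:, best : best + 7].sum(axis=0) + 2.0
        )
        np.testing.assert_allclose(pwm.weights, expected, rtol=1e-12)

    def test_narrow_pfm_padded_symmetrically_extra_right(self):
        counts = np.tile(np.array([[8.0], [0.0], [0.0], [0.0]]), (1, 4))
        pwm = pfm_to_pwm(PositionFrequencyMatrix(counts), 7, pseudocount=1.0)
        # 3 missing -> 1 uniform left, informative cols 1..4, 2 uniform right
        np.testing.assert_allclose(pwm.weights[:, 0], 0.25)
        np.testing.assert_allclose(pwm.weights[:, 5], 0.25)
        np.testing.assert_allclose(pwm.weights[:, 6], 0.25)
        np.testing.assert_allclose(pwm.weights[0, 1], 9 / 12)

    def test_zero_column_without_pseudocount_is_an_error(self):
        counts = np.ones((4, 7))
        counts[:, 3] = 0.0
        with pytest.raises(InputError):
            pfm_to_pwm(PositionFrequencyMatrix(counts), 7, pseudocount=0.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.integers(7, 12))
    def test_output_satisfies_scale_invariant_and_window_scale_invariance(self, seed, width):
        rng = np.random.default_rng(seed)
        counts = rng.gamma(1.0, 10.0, size=(4, width))
        pfm = PositionFrequencyMatrix(counts)
        pwm = pfm_to_pwm(pfm, 7, pseudocount=1.0)
        np.testing.assert_allclose(pwm.weights.sum(axis=0), 1.0, atol=1e-9)
        # window choice must not move under uniform count scaling
        scaled = pfm_to_pwm(PositionFrequencyMatrix(counts * 37.0), 7, pseudocount=0.0)
        unscaled = pfm_to_pwm(pfm, 7, pseudocount=0.0)
        np.testing.assert_allclose(scaled.weights, unscaled.weights, atol=1e-12)


class TestPwmTextFormat:
    def test_round_trip(self, rng, tmp_path):
        pwm = random_probability_pwm(rng, 7, "roundtrip")
        path = tmp_path / "m.txt"
        write_pwm_text(pwm, path)
        back = read_pwm_text(path)
        np.testing.assert_allclose(back.weights, pwm.weights, atol=1e-6)
        assert back.scale == pwm.scale
        assert back.motif_id == "roundtrip"

    def test_background_ratio_round_trip(self, rng, tmp_path):
        pwm = random_probability_pwm(rng).to_background_ratio()
        path = tmp_path / "m.txt"
        write_pwm_text(pwm, path)
        back = read_pwm_text(path)
        assert back.scale == BACKGROUND_RATIO
        np.testing.assert_allclose(back.weights, pwm.weights, atol=1e-6)

    def test_row_probabilities_parse_into_column(self, tmp_path):
        path = tmp_path / "m.txt"
        path.write_text("Pos\tA\tC\tG\tU\n1\t0.7\t0.1\t0.1\t0.1\n")
        pwm = read_pwm_text(path)
        np.testing.assert_allclose(pwm.weights[:, 0], [0.7, 0.1, 0.1, 0.1])

    def test_wrong_column_count_is_format_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Pos\tA\tC\tG\tU\n1\t0.5\t0.3\t0.2\n")
        with pytest.raises(FormatError):
            read_pwm_text(path)

    def test_negative_entry_is_format_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Pos\tA\tC\tG\tU\n1\t0.7\t-0.1\t0.2\t0.2\n")
        with pytest.raises(FormatError):
            read_pwm_text(path)


class TestMemeFormat:
    def test_round_trip_multiple_motifs(self, rng, tmp_path):
        pwms = [random_probability_pwm(rng, 7, f"m{i}") for i in range(3)]
        path = tmp_path / "lib.meme"
        write_meme(pwms, path)
        back = read_meme(path)
        assert [p.motif_id for p in back] == ["m0", "m1", "m2"]
        for orig, rt in zip(pwms, back):
            np.testing.assert_allclose(rt.weights, orig.weights, atol=1e-6)

    def test_missing_alphabet_is_format_error(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text("MEME version 4\n\nMOTIF x\n")
        with pytest.raises(FormatError):
            read_meme(path)

    def test_empty_motif_block_is_format_error(self, tmp_path):
        path = tmp_path / "bad.meme"
        path.write_text(
            "MEME version 4\n\nALPHABET= ACGU\n\nMOTIF empty\n"
            "letter-probability matrix: alength= 4 w= 0\n\n"
        )
        with pytest.raises(FormatError):
            read_meme(path)


class TestRecords:
    def _records(self):
        return [
            RBPRecord("a", "MKV", family="RRM", construct="FL"),
            RBPRecord("b", "MKV", family="RRM", construct="RBR"),
            RBPRecord("c", "MKV", family="KH", construct="FL"),
            RBPRecord("d", "MKV", family="RRM", construct="FL"),
        ]

    def test_filter_matches_both_tags_order_preserved(self):
        out = filter_records(self._records(), family="RRM", construct="FL")
        assert [r.rbp_id for r in out] == ["a", "d"]

    def test_filter_empty_input_and_no_match(self):
        assert filter_records([], family="RRM", construct="FL") == []
        assert filter_records(self._records(), family="KH", construct="RBR") == []

    def test_invalid_amino_acids_rejected(self):
        with pytest.raises(InputError):
            RBPRecord("bad", "MKV7")
        with pytest.raises(InputError):
            RBPRecord("empty", "")
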