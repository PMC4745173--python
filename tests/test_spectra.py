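"""Spectral slopes: closed forms, invariance, windowed series."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoslope.encoding import EncodingError, cumulate, encode_invariant
from evoslope.simulate import markov_dna, random_dna
from evoslope.spectra import (
    ParameterError,
    SequenceTooShortError,
    detail_layout,
    evolutionary_slope,
    global_slope,
    per_class_slopes,
    slope_from_energies,
    spectral_slope,
)
from evoslope.stats import two_sample_t
from evoslope.wavelet import scale_mixing_transform

dna = st.text(alphabet="ACGT", min_size=16, max_size=128)


class TestSpectralSlope:
    def test_homopolymer_closed_form_natural_log(self):
        """Linear-ramp Haar analysis: a constant letter gives s = -log 8."""
        Z = scale_mixing_transform(cumulate(encode_invariant("A" * 32)))
        sl = spectral_slope(Z)
        assert sl.s == pytest.approx(-math.log(8), abs=1e-12)
        assert sl.e1 == pytest.approx(1.0, abs=1e-12)
        assert sl.e2 == pytest.approx(0.125, abs=1e-12)

    def test_homopolymer_closed_form_base2(self):
        Z = scale_mixing_transform(cumulate(encode_invariant("A" * 32)))
        assert spectral_slope(Z, log_base="2").s == pytest.approx(-3.0, abs=1e-12)

    def test_equal_blocks_give_zero_slope(self):
        Z = np.zeros((4, 16))
        layout = detail_layout(4, 16)
        Z[1, 4:8] = 2.0  # Z1 block
        Z[2:4, 8:16] = 2.0  # Z2 block
        assert spectral_slope(Z, layout).s == 0.0

    def test_zero_finest_energy_is_negative_infinity(self):
        Z = np.zeros((4, 16))
        Z[1, 4:8] = 1.0
        sl = spectral_slope(Z, detail_layout(4, 16))
        assert sl.s == -math.inf and sl.flag == "neg_inf"

    def test_zero_coarse_energy_is_positive_infinity(self):
        Z = np.zeros((4, 16))
        Z[3, 8:] = 1.0
        sl = spectral_slope(Z, detail_layout(4, 16))
        assert sl.s == math.inf and sl.flag == "pos_inf"

    def test_both_energies_zero_is_missing(self):
        sl = slope_from_energies(0.0, 0.0)
        assert math.isnan(sl.s) and sl.flag == "missing"


class TestGlobalSlope:
    def test_truncates_to_power_of_two_prefix(self):
        seq = random_dna(877, seed=42)
        full = global_slope(seq)
        prefix = global_slope(seq.residues[:512])
        assert full.used_length == 512
        assert full.s == pytest.approx(prefix.s, abs=1e-12)

    def test_prefix_rule_on_homopolymer(self):
        a100 = global_slope("A" * 100)
        a64 = global_slope("A" * 64)
        assert a100.used_length == 64
        assert a100.s == pytest.approx(a64.s, abs=1e-15)

    def test_too_short_raises(self):
        with pytest.raises(SequenceTooShortError):
            global_slope("ACGTACG")

    def test_single_code_homopolymer_is_finite(self):
        # a constant letter drives a single ramp row: e1 = 1, e2 = 1/8,
        # so the slope is -log 8, not degenerate
        sl = global_slope("A" * 64, mode="single")
        assert sl.s == pytest.approx(-math.log(8), abs=1e-12)

    def test_invariance_under_alternative_representatives(self):
        seq = random_dna(256, seed=7)
        base = global_slope(seq)
        alt = global_slope(seq, representatives=("GTCA", "CTAG", "CGAT"))
        assert alt.s == pytest.approx(base.s, abs=1e-9)

    def test_missing_on_ambiguous_residue(self):
        seq = "ACGT" * 10 + "N" + "ACGT" * 10  # N inside the 64-long prefix
        sl = global_slope(seq)
        assert sl.used_length == 64 and sl.flag == "missing"

    def test_ambiguous_residue_outside_prefix_is_harmless(self):
        seq = "ACGT" * 16 + "NN"  # prefix 64 excludes the Ns
        assert global_slope(seq).flag == "finite"

    def test_strict_raises_on_ambiguous_residue(self):
        with pytest.raises(EncodingError):
            global_slope("ACGTN" * 13, strict=True)


class TestPerClassSlopes:
    def test_same_class_codes_agree(self):
        seq = random_dna(256, seed=3)
        a = global_slope(seq, mode="single", code="ACGT")
        b = global_slope(seq, mode="single", code="TGCA")
        assert a.s == pytest.approx(b.s, abs=1e-12)

    def test_at_most_three_distinct_over_all_codes(self, all_codes):
        seq = random_dna(128, seed=11)
        values = {
            round(global_slope(seq, mode="single", code=c).s, 9) for c in all_codes
        }
        assert len(values) == 3

    def test_homopolymer_classes_coincide(self):
        cs = per_class_slopes("A" * 64)
        s1, s2, s3 = (sl.s for sl in cs.slopes)
        assert s1 == s2 == s3 == pytest.approx(-math.log(8), abs=1e-12)
        assert cs.mean == pytest.approx(-math.log(8), abs=1e-12)


class TestEvolutionarySlope:
    def test_window_start_arithmetic(self):
        series = evolutionary_slope(random_dna(64, seed=0), window=32, step=8)
        np.testing.assert_array_equal(series.starts, [1, 9, 17, 25, 33])
        assert len(series) == 5

    @given(dna)
    @settings(max_examples=25, deadline=None)
    def test_slice_equals_restart(self, s):
        if len(s) < 16:
            return
        a = evolutionary_slope(s, window=16, step=4, engine="sliced")
        b = evolutionary_slope(s, window=16, step=4, engine="restart")
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)

    def test_homogeneous_input_constant_series(self):
        series = evolutionary_slope("A" * 96, window=32, step=8)
        single = global_slope("A" * 32)
        np.testing.assert_allclose(series.values, single.s, atol=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window": 30},
            {"window": 4},
            {"step": 6},
            {"window": 128},  # longer than the sequence
        ],
    )
    def test_parameter_validation(self, kwargs):
        with pytest.raises(ParameterError):
            evolutionary_slope(random_dna(64, seed=1), **kwargs)

    def test_ambiguous_window_is_missing_not_error(self):
        seq = "ACGT" * 8 + "N" + "ACGT" * 8 + "ACG"
        series = evolutionary_slope(seq, window=32, step=8)
        flags = [sl.flag for sl in series.slopes]
        assert "missing" in flags
        # the first window (1-32) ends before the N at position 33
        assert flags[0] == "finite"

    def test_infinite_slopes_are_retained(self):
        # alternating AC: with code ACGT rows 1,2 interleave; engineered via
        # single mode the finest energies stay positive, so instead check
        # retention on a crafted missing/inf mix through serialization
        series = evolutionary_slope("A" * 40 + "N" * 8 + "A" * 40, window=32, step=8)
        buf = io.StringIO()
        series.to_tsv(buf)
        text = buf.getvalue()
        assert "NA" in text and "missing" in text
        assert text.splitlines()[0].split("\t") == [
            "seq_id",
            "window_start",
            "window_end",
            "slope",
            "e1",
            "e2",
            "flag",
        ]

    def test_persistent_markov_more_regular_than_iid(self):
        """The headline simulation property: persistence drives slopes down."""
        probs = (0.3, 0.2, 0.2, 0.3)
        pers = markov_dna(2048, probs, persistence=0.95, seed=21)
        iid = random_dna(2048, probs, seed=22)
        s_pers = evolutionary_slope(pers).values
        s_iid = evolutionary_slope(iid).values
        s_pers = s_pers[np.isfinite(s_pers)]
        s_iid = s_iid[np.isfinite(s_iid)]
        assert len(s_pers) >= 200 and len(s_iid) >= 200
        res = two_sample_t(s_pers, s_iid)
        assert s_pers.mean() < s_iid.mean()
        assert res.t < 0 and res.p / 2 < 0.01
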