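"""CvP statistic and the CvP→OGT regression with its corrections."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from thermoasr import (
    HUA2019,
    CalibrationPoint,
    build_calibration_points,
    classify_residue,
    cvp_bias,
    expected_cvp,
    fit_calibration,
    get_calibration,
    predict_ogt,
)
from thermoasr.asr import AncestralProfile
from thermoasr.errors import (
    ClassificationError,
    DegenerateInputError,
    IdentityError,
    InsufficientDataError,
    SingularFitError,
)
from thermoasr.io import AMINO_ACIDS, OGTRecord


class TestResidueClasses:
    @pytest.mark.parametrize(
        "aa,cls",
        [("R", "charged"), ("K", "charged"), ("D", "charged"), ("E", "charged"),
         ("Q", "polar"), ("N", "polar"), ("S", "polar"), ("T", "polar"),
         ("G", "other"), ("W", "other")],
    )
    def test_partition(self, aa, cls):
        assert classify_residue(aa) == cls

    @pytest.mark.parametrize("bad", ["-", "X", "B", "Z", "U", "J", "", "RK"])
    def test_unclassifiable_rejected(self, bad):
        with pytest.raises(ClassificationError):
            classify_residue(bad)

    def test_every_canonical_residue_classified(self):
        counts = {"charged": 0, "polar": 0, "other": 0}
        for aa in AMINO_ACIDS:
            counts[classify_residue(aa)] += 1
        assert counts == {"charged": 4, "polar": 4, "other": 12}


class TestCvPBias:
    @pytest.mark.parametrize(
        "seq,value",
        [
            ("RKDE", 100.0),
            ("RKDEQNST", 0.0),
            ("RRQG", 25.0),  # (2-1)/4 · 100
            ("R-K-X", 100.0),  # gaps and X excluded entirely
            ("GGGG", 0.0),
        ],
    )
    def test_hand_counts(self, seq, value):
        assert cvp_bias(seq) == pytest.approx(value, abs=1e-12)

    def test_empty_effective_sequence(self):
        with pytest.raises(DegenerateInputError):
            cvp_bias("--XX")

    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=200), st.integers(0, 2**32))
    def test_gap_insertion_and_permutation_invariance(self, seq, seed):
        rng = random.Random(seed)
        shuffled = list(seq)
        rng.shuffle(shuffled)
        with_gaps = "".join(
            ch + ("-" if rng.random() < 0.3 else "") for ch in shuffled
        )
        assert cvp_bias(with_gaps) == pytest.approx(cvp_bias(seq), abs=1e-9)

    @given(
        st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=100),
        st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=100),
    )
    def test_concatenation_is_length_weighted_mean(self, a, b):
        combined = cvp_bias(a + b)
        expected = (len(a) * cvp_bias(a) + len(b) * cvp_bias(b)) / (len(a) + len(b))
        assert combined == pytest.approx(expected, abs=1e-9)


class TestExpectedCvP:
    def _point_mass_profile(self, seq):
        probs = np.zeros((len(seq), 20))
        for i, ch in enumerate(seq):
            probs[i, AMINO_ACIDS.index(ch)] = 1.0
        return AncestralProfile("n", probs, seq, np.ones(len(seq)))

    def test_matches_cvp_bias_on_point_mass(self):
        prof = self._point_mass_profile("RKDE")
        assert expected_cvp(prof) == pytest.approx(100.0)
        prof2 = self._point_mass_profile("RKDEQNSTGAVL")
        assert expected_cvp(prof2) == pytest.approx(cvp_bias("RKDEQNSTGAVL"))

    def test_uniform_profile_is_zero(self):
        probs = np.full((7, 20), 1 / 20)
        assert expected_cvp(AncestralProfile("n", probs, "A" * 7, np.ones(7))) == pytest.approx(0.0)

    def test_hand_mixture(self):
        # col1 point mass on R (+100), col2 half Q half G (−50) → mean +25... with
        # spec's worked variant: (100 + (0·0.5−0.5·100))/2 = 37.5 per two columns
        probs = np.zeros((2, 20))
        probs[0, AMINO_ACIDS.index("R")] = 1.0
        probs[1, AMINO_ACIDS.index("Q")] = 0.5
        probs[1, AMINO_ACIDS.index("G")] = 0.5
        prof = AncestralProfile("n", probs, "RQ", np.ones(2))
        assert expected_cvp(prof) == pytest.approx(25.0)

    def test_malformed_distribution_rejected(self):
        probs = np.full((3, 20), 0.04)
        with pytest.raises(DegenerateInputError):
            expected_cvp(AncestralProfile("n", probs, "AAA", np.ones(3)))


class TestBuildCalibrationPoints:
    def test_mesophile_group_collapses_to_mean(self):
        records = [OGTRecord("A", 37.0), OGTRecord("B", 37.0), OGTRecord("C", 80.0)]
        cvps = {("A", "1"): 4.0, ("B", "1"): 6.0, ("C", "1"): 10.0}
        points = build_calibration_points(records, cvps)
        assert [(p.cvp, p.ogt) for p in points] == [(5.0, 37.0), (10.0, 80.0)]
        assert points[0].sources == (("A", "1"), ("B", "1"))

    def test_psychrophile_exclusion_switch(self):
        records = [OGTRecord("A", 55.0), OGTRecord("B", 10.0, psychrophile=True)]
        cvps = {("A", "1"): 6.0, ("B", "1"): 2.0}
        assert len(build_calibration_points(records, cvps)) == 1
        assert len(build_calibration_points(records, cvps, exclude_psychrophiles=False)) == 2

    def test_two_copies_give_two_points(self):
        records = [OGTRecord("S", 65.0, "c1"), OGTRecord("S", 65.0, "c2")]
        cvps = {("S", "c1"): 8.0, ("S", "c2"): 9.0}
        points = build_calibration_points(records, cvps, collapse_ogt=37.0)
        assert [(p.cvp, p.ogt) for p in points] == [(8.0, 65.0), (9.0, 65.0)]

    def test_collapse_duplicates_mode(self):
        records = [OGTRecord("S", 65.0, "c1"), OGTRecord("S", 65.0, "c2"), OGTRecord("T", 50.0)]
        cvps = {("S", "c1"): 8.0, ("S", "c2"): 9.0, ("T", "1"): 5.0}
        points = build_calibration_points(records, cvps, collapse_duplicates=True)
        assert [(p.cvp, p.ogt) for p in points] == [(5.0, 50.0), (8.5, 65.0)]

    def test_missing_cvp_rejected(self):
        with pytest.raises(IdentityError):
            build_calibration_points([OGTRecord("A", 50.0)], {})

    def test_idempotent_and_order_independent(self):
        records = [OGTRecord(t, o) for t, o in [("A", 37.0), ("B", 37.0), ("C", 80.0), ("D", 55.0)]]
        cvps = {(r.taxon, "1"): i + 1.0 for i, r in enumerate(records)}
        forward = build_calibration_points(records, cvps)
        backward = build_calibration_points(records[::-1], cvps)
        assert forward == backward


class TestFitAndPredict:
    def test_exact_line_recovered(self):
        points = [CalibrationPoint(float(x), 2.0 * x + 5.0, (("s", "1"),)) for x in range(1, 6)]
        model = fit_calibration(points)
        assert model.slope == pytest.approx(2.0, abs=1e-10)
        assert model.intercept == pytest.approx(5.0, abs=1e-10)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_hand_ols_on_collinear_points(self):
        points = [
            CalibrationPoint(5.0, 37.0, (("a", "1"),)),
            CalibrationPoint(7.5, 58.5, (("b", "1"),)),
            CalibrationPoint(10.0, 80.0, (("c", "1"),)),
        ]
        model = fit_calibration(points)
        assert model.slope == pytest.approx(8.6, abs=1e-9)
        assert model.intercept == pytest.approx(-6.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_centroid_property(self):
        rng = np.random.default_rng(5)
        xs = rng.uniform(2, 12, size=20)
        ys = 6.0 * xs + 10.0 + rng.normal(0, 5, size=20)
        points = [CalibrationPoint(float(x), float(y), (("s", "1"),)) for x, y in zip(xs, ys)]
        model = fit_calibration(points)
        assert predict_ogt(model, float(xs.mean())) == pytest.approx(float(ys.mean()), abs=1e-9)

    def test_degenerate_fits_rejected(self):
        flat = [CalibrationPoint(3.0, float(o), (("s", "1"),)) for o in (40, 60, 80)]
        with pytest.raises(SingularFitError):
            fit_calibration(flat)
        with pytest.raises(InsufficientDataError):
            fit_calibration(flat[:2])

    def test_published_default_model(self):
        model = get_calibration("hua2019")
        assert predict_ogt(model, 0.0) == pytest.approx(13.858)
        assert predict_ogt(model, 10.0) == pytest.approx(81.406)
        assert predict_ogt(model, 1.0) - predict_ogt(model, 0.0) == pytest.approx(6.7548)

    def test_constant_model(self):
        from thermoasr import CalibrationModel

        const = CalibrationModel(0.0, 50.0)
        assert predict_ogt(const, -33.0) == 50.0

    def test_nonfinite_cvp_rejected(self):
        with pytest.raises(Exception):
            predict_ogt(HUA2019, math.nan)
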