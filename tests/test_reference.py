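"""Normative table integrity, percent-change arithmetic, z-scores."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mfbia.exceptions import DomainError, LookupError_
from mfbia.reference import (
    PARAMETERS,
    gender_contrast_table,
    percent_change,
    reference_entry,
    zscore_against_reference,
)
from mfbia.cole import DerivedParameters

# Independent copy of the published normative lists, keyed
# (muscle, gender) -> {parameter: (mean, sd)}, for a verbatim cross-check
# of the packaged TSV.  Parameter order in the source lists:
# Z, R, fc, PA, Ri, Re, Xc, Mc.
PRINTED = {
    ("biceps", "men"): dict(Z=(86.4, 19.2), R=(84.2, 20.2), fc=(42.3, 6.4), PA=(13.1, 5.1),
                            Ri=(140.8, 84.6), Re=(114.0, 19.2), Xc=(18.1, 3.7), Mc=(17.5, 7.6)),
    ("biceps", "women"): dict(Z=(133.0, 27.6), R=(131.9, 28.1), fc=(58.1, 8.0), PA=(7.3, 3.1),
                              Ri=(372.4, 211.7), Re=(154.9, 26.9), Xc=(15.7, 4.3), Mc=(6.4, 3.0)),
    ("triceps", "men"): dict(Z=(102.8, 19.4), R=(101.4, 20.1), fc=(30.9, 6.3), PA=(9.1, 3.9),
                             Ri=(258.9, 123.0), Re=(131.8, 18.5), Xc=(15.2, 4.1), Mc=(15.5, 6.6)),
    ("triceps", "women"): dict(Z=(154.1, 31.2), R=(153.5, 31.4), fc=(63.3, 95.4), PA=(4.8, 2.1),
                               Ri=(573.4, 288.4), Re=(195.9, 116.0), Xc=(12.5, 4.1), Mc=(11.3, 28.6)),
    ("abductor_pollicis_brevis", "men"): dict(Z=(42.8, 6.4), R=(42.2, 6.2), fc=(73.5, 14.1),
                                              PA=(8.8, 1.9), Ri=(78.6, 20.7), Re=(50.6, 9.1),
                                              Xc=(6.6, 2.0), Mc=(17.8, 4.0)),
    ("abductor_pollicis_brevis", "women"): dict(Z=(52.2, 25.8), R=(51.7, 25.8), fc=(95.9, 19.8),
                                                PA=(7.3, 1.9), Ri=(133.9, 214.7), Re=(59.2, 27.1),
                                                Xc=(6.3, 1.9), Mc=(11.6, 3.7)),
    ("trapezius", "men"): dict(Z=(71.7, 15.4), R=(70.4, 15.9), fc=(45.1, 7.2), PA=(10.6, 4.6),
                               Ri=(144.5, 90.9), Re=(90.8, 15.1), Xc=(12.3, 3.6), Mc=(18.2, 8.5)),
    ("trapezius", "women"): dict(Z=(82.7, 17.4), R=(81.7, 17.8), fc=(63.2, 18.9), PA=(8.9, 3.7),
                                 Ri=(193.0, 148.0), Re=(98.5, 17.7), Xc=(12.0, 3.7), Mc=(13.3, 12.1)),
    ("rectus_femoris", "men"): dict(Z=(83.1, 16.1), R=(81.7, 16.6), fc=(33.2, 4.2), PA=(10.5, 3.5),
                                    Ri=(173.9, 73.5), Re=(108.5, 17.0), Xc=(14.4, 2.5), Mc=(18.8, 6.0)),
    ("rectus_femoris", "women"): dict(Z=(140.9, 19.2), R=(140.4, 19.1), fc=(53.7, 69.3), PA=(5.0, 1.2),
                                      Ri=(505.1, 164.2), Re=(163.3, 23.9), Xc=(12.3, 3.4), Mc=(10.2, 19.7)),
    ("vastus_lateralis", "men"): dict(Z=(68.9, 15.9), R=(66.6, 16.4), fc=(31.8, 4.2), PA=(15.1, 4.4),
                                      Ri=(106.1, 65.7), Re=(98.2, 18.3), Xc=(17.1, 3.4), Mc=(27.4, 7.8)),
    ("vastus_lateralis", "women"): dict(Z=(124.0, 23.0), R=(123.4, 23.0), fc=(37.3, 8.4), PA=(5.5, 2.0),
                                        Ri=(436.7, 155.6), Re=(146.0, 27.2), Xc=(11.6, 3.9), Mc=(8.4, 3.6)),
    ("gastrocnemius", "men"): dict(Z=(68.2, 13.4), R=(66.6, 13.3), fc=(52.5, 7.9), PA=(12.2, 2.8),
                                   Ri=(100.3, 38.1), Re=(85.6, 16.9), Xc=(14.2, 3.8), Mc=(17.7, 4.8)),
    ("gastrocnemius", "women"): dict(Z=(102.1, 20.6), R=(101.5, 20.6), fc=(66.5, 20.3), PA=(6.4, 1.7),
                                     Ri=(298.5, 116.7), Re=(116.6, 22.4), Xc=(11.1, 2.8), Mc=(9.5, 13.9)),
    ("tibialis_anterior", "men"): dict(Z=(59.3, 8.0), R=(57.5, 7.8), fc=(48.4, 5.2), PA=(14.0, 1.8),
                                       Ri=(72.8, 18.4), Re=(78.6, 10.6), Xc=(14.3, 2.4), Mc=(22.6, 4.5)),
    ("tibialis_anterior", "women"): dict(Z=(91.1, 20.5), R=(90.2, 20.6), fc=(59.7, 16.3), PA=(7.9, 2.5),
                                         Ri=(221.7, 105.7), Re=(107.4, 22.3), Xc=(12.1, 2.8), Mc=(12.2, 12.8)),
}


class TestReferenceTable:
    def test_full_crossing_present(self, reference):
        assert len(reference) == 128
        assert (reference["n"] == 25).all()
        assert (reference["sd"] > 0).all()

    def test_every_cell_matches_published_values(self, reference):
        for (muscle, gender), params in PRINTED.items():
            for parameter, (mean, sd) in params.items():
                row = reference.loc[(muscle, gender, parameter)]
                assert float(row["mean"]) == mean, (muscle, gender, parameter)
                assert float(row["sd"]) == sd, (muscle, gender, parameter)

    @pytest.mark.parametrize(
        "muscle,gender,parameter,mean,sd",
        [
            ("biceps", "men", "Z", 86.4, 19.2),
            ("vastus_lateralis", "women", "Mc", 8.4, 3.6),
        ],
    )
    def test_lookup(self, reference, muscle, gender, parameter, mean, sd):
        e = reference_entry(muscle, gender, parameter, reference)
        assert (e.mean, e.sd, e.n) == (mean, sd, 25)

    def test_unknown_cell_raises(self, reference):
        with pytest.raises(LookupError_):
            reference_entry("deltoid", "men", "Z", reference)

    def test_extreme_sd_cells_flagged(self, reference):
        assert reference_entry("triceps", "women", "fc", reference).flagged
        assert not reference_entry("triceps", "men", "fc", reference).flagged


class TestPercentChange:
    @pytest.mark.parametrize(
        "men,women,expected",
        [
            (86.4, 133.0, 54),    # biceps Z
            (17.5, 6.4, -63),     # biceps Mc
            (140.8, 372.4, 164),  # biceps Ri
            (42.3, 58.1, 37),     # biceps fc
            (10.0, 10.0, 0),
        ],
    )
    def test_published_examples(self, men, women, expected):
        assert percent_change(men, women) == expected

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DomainError):
            percent_change(0.0, 10.0)

    @given(a=st.floats(1.0, 500.0), b=st.floats(1.0, 500.0))
    def test_baseline_swap_identity(self, a, b):
        # pc(a,b) relates to pc(b,a) through -100*u/(100+u) on the unrounded
        # scale, NOT through sign flip; guards against swapping baselines.
        u_ab = 100.0 * (b - a) / a
        u_ba = 100.0 * (a - b) / b
        assert u_ab == pytest.approx(-100.0 * u_ba / (100.0 + u_ba), rel=1e-9)

    def test_rounding_is_half_away_from_zero(self):
        assert percent_change(100.0, 156.5) == 57
        assert percent_change(100.0, 43.5) == -57  # -56.5 rounds away to -57


class TestGenderContrastTable:
    def test_shape_and_ns_cells(self, reference):
        cells = gender_contrast_table(reference)
        assert len(cells) == 64
        ns = [c for c in cells if c.direction == "NS"]
        assert all(c.printed_percent is None for c in ns)
        assert len(ns) == 7
        # triceps Mc is the one cell printed with a percent but an NS band
        ns_band = [c for c in cells if c.p_band == "NS"]
        assert len(ns_band) == 8
        (triceps_mc,) = [c for c in ns_band if c.printed_percent is not None]
        assert (triceps_mc.muscle, triceps_mc.parameter) == ("triceps", "Mc")

    @pytest.mark.parametrize(
        "muscle,parameter,expected",
        [("biceps", "Ri", 164), ("trapezius", "fc", 40), ("biceps", "Z", 54)],
    )
    def test_exact_cells(self, reference, muscle, parameter, expected):
        (cell,) = [
            c for c in gender_contrast_table(reference)
            if (c.muscle, c.parameter) == (muscle, parameter)
        ]
        assert cell.recomputed_percent == expected
        assert cell.printed_percent == expected
        assert not cell.rounding_mismatch

    def test_biceps_r_off_by_one_is_flagged(self, reference):
        (cell,) = [
            c for c in gender_contrast_table(reference)
            if (c.muscle, c.parameter) == ("biceps", "R")
        ]
        # (131.9-84.2)/84.2 = 56.65% rounds to 57; the published 56 came from
        # unrounded subject-level data.  Discrepancy recorded, not hidden.
        assert cell.recomputed_percent == 57
        assert cell.printed_percent == 56
        assert cell.rounding_mismatch


class TestZScores:
    @pytest.fixture
    def men_biceps_derived(self):
        # A recording sitting exactly at the men-biceps means for Z/R/Xc/PA.
        return DerivedParameters(
            z=86.4, r=84.2, xc=18.1, pa=13.1, fc=42.3, re=114.0, ri=140.8, mc=17.5e-9
        )

    def test_value_at_mean_scores_zero(self, men_biceps_derived, reference):
        zs = zscore_against_reference(men_biceps_derived, "biceps", "men", reference)
        for parameter in PARAMETERS:
            assert zs[parameter]["z"] == pytest.approx(0.0, abs=1e-9)
            assert not zs[parameter]["outside_range"]

    def test_one_sd_above_mean_scores_one(self, reference):
        d = DerivedParameters(
            z=86.4 + 19.2, r=84.2, xc=18.1, pa=13.1, fc=42.3, re=114.0, ri=140.8, mc=17.5e-9
        )
        zs = zscore_against_reference(d, "biceps", "men", reference)
        assert zs["Z"]["z"] == pytest.approx(1.0)

    def test_z_example_105_6(self, reference):
        d = DerivedParameters(
            z=105.6, r=84.2, xc=18.1, pa=13.1, fc=42.3, re=114.0, ri=140.8, mc=17.5e-9
        )
        zs = zscore_against_reference(d, "biceps", "men", reference)
        assert zs["Z"]["z"] == pytest.approx(1.0)

    def test_unknown_muscle_raises(self, men_biceps_derived, reference):
        with pytest.raises(LookupError_):
            zscore_against_reference(men_biceps_derived, "deltoid", "men", reference)
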