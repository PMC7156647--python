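"""Unit tests for the hematologic and organ response classifiers."""

import pytest

from chorscore import (
    HematologicResponse,
    OrganStatus,
    assess_patient,
    classify_cardiac,
    classify_hematologic,
    classify_liver,
    classify_renal,
)
from chorscore.errors import ClassificationError, CohortValidationError

from conftest import make_record


class TestHematologic:
    @pytest.mark.parametrize(
        "baseline, landmark, ifix_neg, ratio_norm, expected, low_path",
        [
            # CR: negative immunofixation + normal FLC ratio
            (19.0, 1.0, True, True, "CR", False),
            # VGPR: landmark dFLC < 4 mg/dL
            (19.0, 3.5, False, False, "VGPR", False),
            # PR: >= 50% reduction (9.5 == 0.5 x 19, inclusive)
            (19.0, 9.5, False, False, "PR", False),
            (19.0, 9.6, False, False, "NR", False),
            # boundary: landmark exactly 4 is not VGPR but can be PR
            (19.0, 4.0, False, False, "PR", False),
            # low-dFLC pathway: CR-only assessment
            (4.2, 1.0, False, True, "NR", True),
            (4.2, 1.0, True, True, "CR", True),
            # boundary: baseline exactly 5 uses the standard pathway
            (5.0, 2.0, False, False, "VGPR", False),
        ],
    )
    def test_categories(self, baseline, landmark, ifix_neg, ratio_norm, expected, low_path):
        rec = make_record(
            baseline_dflc=baseline,
            landmark_dflc=landmark,
            landmark_ifix_negative=ifix_neg,
            landmark_flc_ratio_normal=ratio_norm,
        )
        cat = classify_hematologic(rec)
        assert cat.category is HematologicResponse(expected)
        assert cat.low_dflc_pathway is low_path

    def test_missing_baseline_dflc_raises(self):
        with pytest.raises(ClassificationError, match="baseline dFLC"):
            classify_hematologic(make_record(baseline_dflc=None))

    def test_negative_value_raises(self):
        with pytest.raises(CohortValidationError):
            classify_hematologic(make_record(baseline_dflc=-1.0))

    def test_low_dflc_never_vgpr_or_pr(self):
        # sweep landmark dFLC over the VGPR/PR regions: category stays CR/NR
        for lm in (0.1, 1.0, 2.0, 3.9, 4.0):
            cat = classify_hematologic(
                make_record(baseline_dflc=3.0, landmark_dflc=lm)
            )
            assert cat.low_dflc_pathway
            assert cat.category in (HematologicResponse.CR, HematologicResponse.NR)


class TestCardiac:
    @pytest.mark.parametrize(
        "baseline, landmark, expected",
        [
            (2000.0, 1300.0, OrganStatus.RESPONSE),  # 35% and 700 pg/mL
            (2000.0, 1500.0, OrganStatus.NO_RESPONSE),  # 25% <= 30%
            # both clauses must hold: 31% relative but only 280 pg/mL absolute
            (900.0, 620.0, OrganStatus.NO_RESPONSE),
            # strict thresholds: exactly 30% / exactly 300 do not qualify
            (1000.0, 700.0, OrganStatus.NO_RESPONSE),
            (649.9, 100.0, OrganStatus.NOT_EVALUABLE),  # below evaluability floor
            (650.0, 300.0, OrganStatus.RESPONSE),
        ],
    )
    def test_rules(self, baseline, landmark, expected):
        rec = make_record(baseline_ntprobnp=baseline, landmark_ntprobnp=landmark)
        assert classify_cardiac(rec) is expected

    def test_uninvolved_and_missing(self):
        assert classify_cardiac(make_record(heart_involved=False)) is OrganStatus.NOT_EVALUABLE
        assert classify_cardiac(make_record(landmark_ntprobnp=None)) is OrganStatus.NOT_EVALUABLE

    def test_absolute_clause_breaks_scale_invariance(self):
        # doubling all values preserves the relative drop but a drop that
        # fails only the absolute clause starts passing it
        base = make_record(baseline_ntprobnp=900.0, landmark_ntprobnp=620.0)
        doubled = make_record(baseline_ntprobnp=1800.0, landmark_ntprobnp=1240.0)
        assert classify_cardiac(base) is OrganStatus.NO_RESPONSE
        assert classify_cardiac(doubled) is OrganStatus.RESPONSE


class TestRenal:
    def test_response_proteinuria_drop(self):
        rec = make_record(
            baseline_proteinuria=5000.0, landmark_proteinuria=3000.0,
            baseline_egfr=65.0, landmark_egfr=60.0,
        )
        assert classify_renal(rec) is OrganStatus.RESPONSE

    def test_egfr_decline_disqualifies(self):
        rec = make_record(
            baseline_proteinuria=5000.0, landmark_proteinuria=3000.0,
            baseline_egfr=65.0, landmark_egfr=45.0,  # -30.8% >= 25%
        )
        assert classify_renal(rec) is OrganStatus.NO_RESPONSE

    def test_low_landmark_proteinuria_clause(self):
        # 13% drop but landmark < 500 mg/24h still qualifies
        rec = make_record(
            baseline_proteinuria=520.0, landmark_proteinuria=450.0,
            baseline_egfr=65.0, landmark_egfr=65.0,
        )
        assert classify_renal(rec) is OrganStatus.RESPONSE

    def test_dialysis_excluded(self):
        assert (
            classify_renal(make_record(on_dialysis_at_baseline=True))
            is OrganStatus.NOT_EVALUABLE
        )

    def test_uninvolved(self):
        assert classify_renal(make_record(kidney_involved=False)) is OrganStatus.NOT_EVALUABLE


class TestLiver:
    @pytest.mark.parametrize(
        "baseline, landmark, expected",
        [
            (300.0, 140.0, OrganStatus.RESPONSE),
            (300.0, 160.0, OrganStatus.NO_RESPONSE),
            (300.0, 150.0, OrganStatus.RESPONSE),  # exactly 50%, inclusive
        ],
    )
    def test_rules(self, baseline, landmark, expected):
        rec = make_record(
            liver_involved=True, baseline_alp=baseline, landmark_alp=landmark
        )
        assert classify_liver(rec) is expected

    def test_missing_values(self):
        rec = make_record(liver_involved=True, baseline_alp=None)
        assert classify_liver(rec) is OrganStatus.NOT_EVALUABLE


class TestAssessPatient:
    def test_composition(self):
        rec = make_record(
            landmark_ifix_negative=True, landmark_flc_ratio_normal=True
        )
        a = assess_patient(rec)
        assert a.hematologic.category is HematologicResponse.CR
        assert a.cardiac is OrganStatus.RESPONSE
        assert a.renal is OrganStatus.RESPONSE
        assert a.liver is OrganStatus.NOT_EVALUABLE  # uninvolved

    def test_dialysis_kidney_only_patient_fully_not_evaluable(self):
        rec = make_record(
            heart_involved=False, kidney_involved=True,
            on_dialysis_at_baseline=True,
        )
        a = assess_patient(rec)
        assert a.organ_statuses == (OrganStatus.NOT_EVALUABLE,) * 3

    def test_liver_only(self):
        rec = make_record(
            heart_involved=False, kidney_involved=False, liver_involved=True,
            baseline_alp=300.0, landmark_alp=140.0, landmark_dflc=9.5,
        )
        a = assess_patient(rec)
        assert a.liver is OrganStatus.RESPONSE
        assert a.cardiac is OrganStatus.NOT_EVALUABLE
        assert a.hematologic.category is HematologicResponse.PR

    def test_idempotent(self):
        rec = make_record()
        assert assess_patient(rec) == assess_patient(rec)

    def test_error_carries_patient_id(self):
        rec = make_record(patient_id="XYZ", baseline_dflc=None)
        with pytest.raises(ClassificationError, match="XYZ"):
            assess_patient(rec)
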