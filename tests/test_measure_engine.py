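import datetime as dt

import pytest

from conftest import PERIOD_2016, SCREENING_PERIOD
from cqmbench.ehr_tables import EhrCohort
from cqmbench.measure_engine import (
    MeasureConfig,
    MeasureResult,
    bp_control,
    colorectal_screening,
    copd_mortality,
    hip_knee_complications,
    run_all,
)
from cqmbench.terminology import ConfigError

D = dt.date


class TestColorectalScreening:
    def patient_aged(self, builder, birth, procedures=(), **extra):
        return builder(patients=[dict(patient_id="P0", birth_date=birth, **extra)],
                       procedures=procedures)

    def test_colonoscopy_counts_within_ten_year_lookback(self, cohort_builder, valuesets):
        cohort = self.patient_aged(
            cohort_builder, D(1956, 6, 1),
            procedures=[dict(code="SYN-COLONOSCOPY", proc_date=D(2008, 1, 1))])
        res = colorectal_screening(cohort, SCREENING_PERIOD, valuesets)
        assert (res.denominator, res.numerator) == (1, 1)

    def test_fobt_lookback_is_one_year(self, cohort_builder, valuesets):
        cohort = self.patient_aged(
            cohort_builder, D(1956, 6, 1),
            procedures=[dict(code="SYN-FOBT", proc_date=D(2015, 6, 1))])
        res = colorectal_screening(cohort, SCREENING_PERIOD, valuesets)
        assert (res.denominator, res.numerator) == (1, 0)

        cohort = self.patient_aged(
            cohort_builder, D(1956, 6, 1),
            procedures=[dict(code="SYN-FOBT", proc_date=D(2016, 1, 1))])
        res = colorectal_screening(cohort, SCREENING_PERIOD, valuesets)
        assert (res.denominator, res.numerator) == (1, 1)

    def test_age_49_at_period_end_not_in_denominator(self, cohort_builder, valuesets):
        cohort = self.patient_aged(cohort_builder, D(1967, 6, 1))
        assert colorectal_screening(cohort, SCREENING_PERIOD, valuesets).denominator == 0

    def test_death_during_period_excludes_unless_any_point_mode(self, cohort_builder, valuesets):
        cohort = self.patient_aged(cohort_builder, D(1956, 6, 1),
                                   death_date=D(2016, 6, 1))
        assert colorectal_screening(cohort, SCREENING_PERIOD, valuesets).denominator == 0
        relaxed = colorectal_screening(cohort, SCREENING_PERIOD, valuesets, alive_any_point=True)
        assert relaxed.denominator == 1


class TestCopdMortality:
    def admission(self, builder, pdx, death=None, conditions=()):
        return builder(
            patients=[dict(patient_id="P0", death_date=death)],
            encounters=[dict(encounter_id="E0", start_date=D(2016, 3, 1),
                             principal_diagnosis=pdx)],
            conditions=conditions,
        )

    def test_death_within_30_days_counts(self, cohort_builder, valuesets):
        cohort = self.admission(cohort_builder, "185086009", death=D(2016, 3, 20))
        res = copd_mortality(cohort, PERIOD_2016, valuesets)
        assert (res.denominator, res.numerator) == (1, 1)

    def test_death_at_45_days_is_denominator_only(self, cohort_builder, valuesets):
        cohort = self.admission(cohort_builder, "185086009", death=D(2016, 4, 15))
        res = copd_mortality(cohort, PERIOD_2016, valuesets)
        assert (res.denominator, res.numerator) == (1, 0)

    def test_day_30_boundary_is_inclusive(self, cohort_builder, valuesets):
        cohort = self.admission(cohort_builder, "185086009", death=D(2016, 3, 31))
        assert copd_mortality(cohort, PERIOD_2016, valuesets).numerator == 1

    def test_active_copd_without_principal_dx_only_in_expanded(self, cohort_builder, valuesets):
        cohort = self.admission(
            cohort_builder, "233604007",
            conditions=[dict(code="84733001", onset_date=D(2010, 1, 1))])
        strict = copd_mortality(cohort, PERIOD_2016, valuesets, mode="strict")
        expanded = copd_mortality(cohort, PERIOD_2016, valuesets, mode="expanded")
        assert strict.denominator == 0
        assert expanded.denominator == 1

    def test_unknown_mode_rejected(self, cohort_builder, valuesets):
        cohort = self.admission(cohort_builder, "185086009")
        with pytest.raises(ConfigError):
            copd_mortality(cohort, PERIOD_2016, valuesets, mode="lenient")


class TestHipKneeComplications:
    def surgery(self, builder, events=(), death=None, encounters=()):
        return builder(
            patients=[dict(patient_id="P0", death_date=death)],
            procedures=[dict(code="52734007", proc_date=D(2016, 5, 1))],
            conditions=events,
            encounters=encounters,
        )

    def test_pneumonia_within_7_days_is_a_complication(self, cohort_builder, valuesets):
        cohort = self.surgery(cohort_builder,
                              events=[dict(code="233604007", onset_date=D(2016, 5, 5))])
        res = hip_knee_complications(cohort, PERIOD_2016, valuesets)
        assert (res.denominator, res.numerator) == (1, 1)

    def test_pneumonia_on_day_19_misses_the_7_day_window(self, cohort_builder, valuesets):
        cohort = self.surgery(cohort_builder,
                              events=[dict(code="233604007", onset_date=D(2016, 5, 20))])
        assert hip_knee_complications(cohort, PERIOD_2016, valuesets).numerator == 0

    def test_pulmonary_embolism_on_day_19_hits_the_30_day_window(self, cohort_builder, valuesets):
        cohort = self.surgery(
            cohort_builder,
            events=[dict(code="SYN-PULMONARY-EMBOLISM", onset_date=D(2016, 5, 20))])
        assert hip_knee_complications(cohort, PERIOD_2016, valuesets).numerator == 1

    def test_death_beyond_30_days_does_not_count(self, cohort_builder, valuesets):
        cohort = self.surgery(cohort_builder, death=D(2016, 7, 15))
        assert hip_knee_complications(cohort, PERIOD_2016, valuesets).numerator == 0

    def test_death_within_30_days_counts(self, cohort_builder, valuesets):
        cohort = self.surgery(cohort_builder, death=D(2016, 5, 20))
        assert hip_knee_complications(cohort, PERIOD_2016, valuesets).numerator == 1

    def test_complication_via_encounter_principal_diagnosis(self, cohort_builder, valuesets):
        cohort = self.surgery(
            cohort_builder,
            encounters=[dict(encounter_id="E9", start_date=D(2016, 7, 1),
                             principal_diagnosis="SYN-PJI")])
        assert hip_knee_complications(cohort, PERIOD_2016, valuesets).numerator == 1


class TestBpControl:
    def hypertensive(self, builder, birth, readings, onset=D(2016, 1, 1), diabetes=False):
        conditions = [dict(code="38341003", onset_date=onset)]
        if diabetes:
            conditions.append(dict(code="SYN-DIABETES", onset_date=D(2010, 1, 1)))
        observations = []
        for day, sbp, dbp in readings:
            observations.append(dict(obs_date=day, code="8480-6", value=sbp))
            observations.append(dict(obs_date=day, code="8462-4", value=dbp))
        return builder(patients=[dict(patient_id="P0", birth_date=birth)],
                       conditions=conditions, observations=observations)

    def test_reading_below_140_90_controls_at_age_45(self, cohort_builder, valuesets):
        cohort = self.hypertensive(cohort_builder, D(1971, 6, 1),
                                   [(D(2016, 6, 1), 135.0, 85.0)])
        res = bp_control(cohort, PERIOD_2016, valuesets)
        assert (res.denominator, res.numerator) == (1, 1)

    def test_limit_relaxes_to_150_90_at_age_70_without_diabetes(self, cohort_builder, valuesets):
        cohort = self.hypertensive(cohort_builder, D(1946, 6, 1),
                                   [(D(2016, 6, 1), 145.0, 85.0)])
        assert bp_control(cohort, PERIOD_2016, valuesets).numerator == 1

    def test_diabetes_reverts_the_limit_to_140_90(self, cohort_builder, valuesets):
        cohort = self.hypertensive(cohort_builder, D(1946, 6, 1),
                                   [(D(2016, 6, 1), 145.0, 85.0)], diabetes=True)
        assert bp_control(cohort, PERIOD_2016, valuesets).numerator == 0

    def test_exactly_140_90_fails_strict_inequality(self, cohort_builder, valuesets):
        cohort = self.hypertensive(cohort_builder, D(1971, 6, 1),
                                   [(D(2016, 6, 1), 140.0, 90.0)])
        assert bp_control(cohort, PERIOD_2016, valuesets).numerator == 0

    def test_no_qualifying_reading_is_noncompliant_but_eligible(self, cohort_builder, valuesets):
        cohort = self.hypertensive(cohort_builder, D(1971, 6, 1),
                                   [(D(2015, 12, 1), 120.0, 70.0)])  # before the period
        res = bp_control(cohort, PERIOD_2016, valuesets)
        assert (res.denominator, res.numerator) == (1, 0)

    def test_most_recent_reading_governs(self, cohort_builder, valuesets):
        improving = self.hypertensive(
            cohort_builder, D(1971, 6, 1),
            [(D(2016, 3, 1), 180.0, 100.0), (D(2016, 9, 1), 130.0, 80.0)])
        assert bp_control(improving, PERIOD_2016, valuesets).numerator == 1
        worsening = self.hypertensive(
            cohort_builder, D(1971, 6, 1),
            [(D(2016, 3, 1), 130.0, 80.0), (D(2016, 9, 1), 180.0, 100.0)])
        assert bp_control(worsening, PERIOD_2016, valuesets).numerator == 0

    def test_all_readings_mode_requires_every_reading_below(self, cohort_builder, valuesets):
        cohort = self.hypertensive(
            cohort_builder, D(1971, 6, 1),
            [(D(2016, 3, 1), 180.0, 100.0), (D(2016, 9, 1), 130.0, 80.0)])
        assert bp_control(cohort, PERIOD_2016, valuesets, all_readings=True).numerator == 0

    def test_unpaired_readings_are_logged_and_ignored(self, cohort_builder, valuesets):
        cohort = cohort_builder(
            patients=[dict(patient_id="P0", birth_date=D(1971, 6, 1))],
            conditions=[dict(code="38341003", onset_date=D(2016, 1, 1))],
            observations=[dict(obs_date=D(2016, 6, 1), code="8480-6", value=120.0)],
        )
        res = bp_control(cohort, PERIOD_2016, valuesets)
        assert res.numerator == 0
        assert res.notes["unpaired_readings"] == 1


class TestRunAll:
    def test_empty_cohort_yields_four_zero_denominator_results(self):
        results = run_all(EhrCohort.empty(), MeasureConfig())
        assert len(results) == 4
        for res in results:
            assert res.denominator == 0 and res.rate is None and res.ci_low is None

    def test_same_seed_reproduces_identical_records(self, cohort_builder, valuesets):
        from cqmbench.synthetic_cohort import CohortConfig, generate

        cohort = generate(CohortConfig(n_patients=400, seed=11))
        a = [r.to_record() for r in run_all(cohort, MeasureConfig())]
        b = [r.to_record() for r in run_all(cohort, MeasureConfig())]
        assert a == b

    def test_unknown_measure_name_is_a_config_error(self):
        cfg = MeasureConfig(measures=("colorectal_screening", "bogus"))
        with pytest.raises(ConfigError, match="bogus"):
            run_all(EhrCohort.empty(), cfg)

    def test_counts_match_unit_flag_recount(self):
        from cqmbench.synthetic_cohort import CohortConfig, generate

        cohort = generate(CohortConfig(n_patients=1000, seed=5))
        for res in run_all(cohort, MeasureConfig()):
            assert res.denominator == len(res.unit_flags)
            assert res.numerator == int(res.unit_flags.sum())
            if res.denominator:
                assert res.ci_low <= res.rate <= res.ci_high

    def test_numerator_never_exceeds_denominator(self):
        from cqmbench.synthetic_cohort import CohortConfig, generate

        cohort = generate(CohortConfig(n_patients=500, seed=2))
        for res in run_all(cohort, MeasureConfig()):
            assert 0 <= res.numerator <= res.denominator

    def test_invalid_result_counts_rejected(self):
        with pytest.raises(ValueError):
            MeasureResult("m", denominator=1, numerator=2, rate=None)
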