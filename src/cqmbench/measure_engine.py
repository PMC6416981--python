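"""The four clinical quality measures: denominators, numerators, rates.

Measures implemented over :class:`~cqmbench.ehr_tables.EhrCohort`:

* **Colorectal Cancer Screening** (process): patients aged 50-75, alive
  through the two-year window, with any of five screening modalities
  within its modality-specific lookback (colonoscopy 10 y, flexible
  sigmoidoscopy 5 y, CT colonography 5 y, FOBT 1 y, stool DNA 3 y)
  anchored at the period end.
* **COPD 30-Day Mortality** (outcome, per *encounter*): index admissions
  with a principal diagnosis of COPD (strict) or any encounter while a
  COPD condition is active (expanded); death within 30 days of the
  admission start.
* **Complications after Hip/Knee Replacement** (outcome, per patient):
  index total knee (SNOMED-CT 609588000) or total hip (52734007)
  replacement; complication events in 7/30/90-day windows after the
  index date, or death within 30 days.
* **Controlling High Blood Pressure** (outcome, per patient): patients
  aged 18-85 with hypertension (38341003) active in the period whose
  most recent paired BP reading after onset is below 140/90 mmHg
  (age 18-59, or 60-85 with diabetes) or 150/90 mmHg (60-85 without
  diabetes); thresholds are strict inequalities.

Conventions applied uniformly: ages use the completed-years anniversary
rule anchored at the period end; every "within N days" window is
inclusive of both endpoints and measured from the index start date.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Optional

import pandas as pd
import pydantic
import yaml

from .ehr_tables import EhrCohort, ages_at, years_ago
from .stats import BootstrapSettings, bootstrap_ci
from .terminology import ConfigError, ValueSetLibrary, load_valuesets

SYSTOLIC_CODE = "8480-6"   # LOINC, systolic blood pressure
DIASTOLIC_CODE = "8462-4"  # LOINC, diastolic blood pressure

MEASURES = ("colorectal_screening", "copd_mortality", "hip_knee_complications", "bp_control")


@pydantic.dataclasses.dataclass(frozen=True)
class MeasurementPeriod:
    """Calendar window over which eligibility and events are evaluated."""

    start: dt.date
    end: dt.date

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"period start {self.start} after end {self.end}")


@dataclasses.dataclass(frozen=True)
class ScreeningModality:
    name: str
    interval_years: int
    valueset: str


@dataclasses.dataclass(frozen=True)
class ComplicationRule:
    name: str
    valueset: Optional[str]
    window_days: int
    is_death_rule: bool = False


@dataclasses.dataclass(frozen=True)
class BpThresholdRule:
    """BP limits applicable to an age band and diabetes status.

    ``requires_diabetes`` is 'yes', 'no' or 'any'.
    """

    systolic_limit: float
    diastolic_limit: float
    min_age: int
    max_age: int
    requires_diabetes: str = "any"


DEFAULT_SCREENING_MODALITIES: tuple[ScreeningModality, ...] = (
    ScreeningModality("colonoscopy", 10, "colonoscopy"),
    ScreeningModality("flexible_sigmoidoscopy", 5, "flexible_sigmoidoscopy"),
    ScreeningModality("ct_colonography", 5, "ct_colonography"),
    ScreeningModality("fobt", 1, "fobt"),
    ScreeningModality("stool_dna", 3, "stool_dna"),
)

DEFAULT_COMPLICATION_RULES: tuple[ComplicationRule, ...] = (
    ComplicationRule("heart_attack", "heart_attack", 7),
    ComplicationRule("pneumonia", "pneumonia", 7),
    ComplicationRule("sepsis", "sepsis", 7),
    ComplicationRule("septicemia_shock", "septicemia_shock", 7),
    ComplicationRule("surgical_site_bleeding", "surgical_site_bleeding", 30),
    ComplicationRule("pulmonary_embolism", "pulmonary_embolism", 30),
    ComplicationRule("death", None, 30, is_death_rule=True),
    ComplicationRule("mechanical_complication", "mechanical_complication", 90),
    ComplicationRule("periprosthetic_joint_infection", "periprosthetic_joint_infection", 90),
    ComplicationRule("wound_infection", "wound_infection", 90),
)

DEFAULT_BP_THRESHOLDS: tuple[BpThresholdRule, ...] = (
    BpThresholdRule(140, 90, 18, 59, "any"),
    BpThresholdRule(140, 90, 60, 85, "yes"),
    BpThresholdRule(150, 90, 60, 85, "no"),
)


@dataclasses.dataclass
class MeasureResult:
    """Denominator/numerator counts, rate and (optional) bootstrap CI.

    ``unit_flags`` holds one boolean per denominator unit, indexed by the
    unit id (patient id, or encounter id for the COPD measure).
    """

    measure_name: str
    denominator: int
    numerator: int
    rate: Optional[float]
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    unit_flags: pd.Series = dataclasses.field(default_factory=lambda: pd.Series(dtype=bool))
    notes: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")

    def with_ci(self, settings: BootstrapSettings) -> "MeasureResult":
        ci = bootstrap_ci(self.unit_flags.to_numpy(), settings)
        if ci is not None:
            self.ci_low, self.ci_high = ci
        return self

    def to_record(self) -> dict:
        return {
            "measure": self.measure_name,
            "denominator": self.denominator,
            "numerator": self.numerator,
            "rate": self.rate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def _result(name: str, flags: pd.Series, **notes) -> MeasureResult:
    den = int(flags.size)
    num = int(flags.sum())
    return MeasureResult(
        measure_name=name,
        denominator=den,
        numerator=num,
        rate=(num / den) if den else None,
        unit_flags=flags.astype(bool),
        notes=notes,
    )


def _ts(d) -> pd.Timestamp:
    return pd.Timestamp(d)


# ---------------------------------------------------------------------------
# Colorectal Cancer Screening


def colorectal_screening(
    cohort: EhrCohort,
    period: MeasurementPeriod,
    valuesets: ValueSetLibrary,
    modalities: tuple[ScreeningModality, ...] = DEFAULT_SCREENING_MODALITIES,
    alive_any_point: bool = False,
) -> MeasureResult:
    """Screening compliance among patients aged 50-75 alive through the period.

    A patient is compliant when any modality's value set matches a
    procedure dated within ``interval_years`` before the period end
    (inclusive).  With ``alive_any_point`` the eligibility relaxes to
    being alive at any point of the period rather than through its end.
    """
    pats = cohort.patients
    age = ages_at(pats["birth_date"], period.end)
    alive_cut = _ts(period.start if alive_any_point else period.end)
    alive = pats["death_date"].isna() | (pats["death_date"] >= alive_cut)
    eligible = pats.loc[(age >= 50) & (age <= 75) & alive, "patient_id"]

    procs = cohort.procedures
    compliant: set[str] = set()
    for modality in modalities:
        codes = valuesets[modality.valueset].codes
        lo = _ts(years_ago(period.end, modality.interval_years))
        hit = procs["code"].isin(codes) & procs["proc_date"].between(lo, _ts(period.end))
        compliant.update(procs.loc[hit, "patient_id"].dropna())

    flags = pd.Series(
        eligible.isin(compliant).to_numpy(), index=eligible.to_numpy(), name="compliant"
    )
    return _result("colorectal_screening", flags)


# ---------------------------------------------------------------------------
# COPD 30-Day Mortality


def copd_mortality(
    cohort: EhrCohort,
    period: MeasurementPeriod,
    valuesets: ValueSetLibrary,
    mode: str = "strict",
) -> MeasureResult:
    """Death within 30 days of an index admission; denominator unit is the encounter.

    ``strict`` keeps only encounters whose principal diagnosis is in the
    COPD value set; ``expanded`` additionally admits any in-period
    encounter whose patient has a COPD condition active at the encounter
    start date.
    """
    if mode not in ("strict", "expanded"):
        raise ConfigError(f"copd_mortality mode must be 'strict' or 'expanded', got {mode!r}")
    codes = valuesets["copd"].codes
    enc = cohort.encounters
    in_period = enc["start_date"].between(_ts(period.start), _ts(period.end))
    mask = in_period & enc["principal_diagnosis"].isin(codes)
    if mode == "expanded":
        cond = cohort.conditions.loc[
            cohort.conditions["code"].isin(codes), ["patient_id", "onset_date", "end_date"]
        ]
        merged = enc.loc[in_period, ["encounter_id", "patient_id", "start_date"]].merge(
            cond, on="patient_id"
        )
        active = (merged["onset_date"] <= merged["start_date"]) & (
            merged["end_date"].isna() | (merged["start_date"] <= merged["end_date"])
        )
        active_ids = set(merged.loc[active, "encounter_id"])
        mask = mask | (in_period & enc["encounter_id"].isin(active_ids))

    index_enc = enc.loc[mask, ["encounter_id", "patient_id", "start_date"]].merge(
        cohort.patients[["patient_id", "death_date"]], on="patient_id", how="left"
    )
    died = (
        index_enc["death_date"].notna()
        & (index_enc["death_date"] >= index_enc["start_date"])
        & (index_enc["death_date"] <= index_enc["start_date"] + pd.Timedelta(days=30))
    )
    flags = pd.Series(died.to_numpy(), index=index_enc["encounter_id"].to_numpy(), name="died_30d")
    return _result("copd_mortality", flags, mode=mode)


# ---------------------------------------------------------------------------
# Complications after Hip/Knee Replacement


def hip_knee_complications(
    cohort: EhrCohort,
    period: MeasurementPeriod,
    valuesets: ValueSetLibrary,
    rules: tuple[ComplicationRule, ...] = DEFAULT_COMPLICATION_RULES,
) -> MeasureResult:
    """Any complication rule satisfied after the first in-period index procedure.

    A rule fires when a condition onset or an encounter principal
    diagnosis matching its value set falls within ``[index, index +
    window_days]``, or — for the death rule — when the patient dies
    within 30 days of the index date.
    """
    idx_codes = valuesets.codes("total_knee_replacement", "total_hip_replacement")
    procs = cohort.procedures
    idx = procs.loc[
        procs["code"].isin(idx_codes)
        & procs["proc_date"].between(_ts(period.start), _ts(period.end))
    ]
    index_date = idx.groupby("patient_id")["proc_date"].min()
    flags = pd.Series(False, index=index_date.index.to_numpy(), name="complication")
    if flags.empty:
        return _result("hip_knee_complications", flags)

    events = pd.concat(
        [
            cohort.conditions[["patient_id", "code", "onset_date"]].rename(
                columns={"onset_date": "event_date"}
            ),
            cohort.encounters[["patient_id", "principal_diagnosis", "start_date"]].rename(
                columns={"principal_diagnosis": "code", "start_date": "event_date"}
            ),
        ],
        ignore_index=True,
    ).dropna(subset=["code"])
    events = events[events["patient_id"].isin(index_date.index)]
    deaths = cohort.patients.set_index("patient_id")["death_date"].reindex(index_date.index)

    for rule in rules:
        window = pd.Timedelta(days=rule.window_days)
        if rule.is_death_rule:
            hit = deaths.notna() & (deaths >= index_date) & (deaths <= index_date + window)
            flags |= pd.Series(hit.to_numpy(), index=flags.index)
            continue
        codes = valuesets[rule.valueset].codes
        ev = events.loc[events["code"].isin(codes)].merge(
            index_date.rename("index_date"), left_on="patient_id", right_index=True
        )
        in_window = (ev["event_date"] >= ev["index_date"]) & (
            ev["event_date"] <= ev["index_date"] + window
        )
        hit_pats = set(ev.loc[in_window, "patient_id"])
        flags |= pd.Series(flags.index.isin(hit_pats), index=flags.index)
    return _result("hip_knee_complications", flags)


# ---------------------------------------------------------------------------
# Controlling High Blood Pressure


def _bp_limits(age: int, diabetic: bool, rules: tuple[BpThresholdRule, ...]):
    for rule in rules:
        if not rule.min_age <= age <= rule.max_age:
            continue
        if rule.requires_diabetes == "yes" and not diabetic:
            continue
        if rule.requires_diabetes == "no" and diabetic:
            continue
        return rule.systolic_limit, rule.diastolic_limit
    return None


def bp_control(
    cohort: EhrCohort,
    period: MeasurementPeriod,
    valuesets: ValueSetLibrary,
    threshold_rules: tuple[BpThresholdRule, ...] = DEFAULT_BP_THRESHOLDS,
    all_readings: bool = False,
    systolic_code: str = SYSTOLIC_CODE,
    diastolic_code: str = DIASTOLIC_CODE,
) -> MeasureResult:
    """BP control among hypertensive patients aged 18-85.

    Denominator: hypertension condition active at any point of the
    period.  Numerator: the most recent systolic/diastolic pair dated on
    or after the (earliest) hypertension onset and inside the period is
    strictly below the applicable limits; with ``all_readings`` every
    qualifying pair must be below the limits (at least one required).
    Readings without a partner on the same date are counted in
    ``notes['unpaired_readings']`` and ignored; same-date duplicate pairs
    are broken toward the highest (systolic, diastolic) reading.
    """
    pats = cohort.patients
    age = ages_at(pats["birth_date"], period.end).set_axis(pats["patient_id"])

    htn_codes = valuesets["hypertension"].codes
    cond = cohort.conditions
    htn = cond.loc[
        cond["code"].isin(htn_codes)
        & (cond["onset_date"] <= _ts(period.end))
        & (cond["end_date"].isna() | (cond["end_date"] >= _ts(period.start)))
    ]
    onset = htn.groupby("patient_id")["onset_date"].min()
    in_age = age[(age >= 18) & (age <= 85)]
    denom_ids = [pid for pid in pats["patient_id"] if pid in onset.index and pid in in_age.index]

    dia_codes = valuesets["diabetes"].codes
    dm = cond.loc[
        cond["code"].isin(dia_codes)
        & (cond["onset_date"] <= _ts(period.end))
        & (cond["end_date"].isna() | (cond["end_date"] >= _ts(period.end)))
    ]
    diabetic_ids = set(dm["patient_id"])

    obs = cohort.observations
    sys_obs = obs.loc[obs["code"] == systolic_code, ["patient_id", "obs_date", "value"]]
    dia_obs = obs.loc[obs["code"] == diastolic_code, ["patient_id", "obs_date", "value"]]
    pairs = sys_obs.merge(dia_obs, on=["patient_id", "obs_date"], suffixes=("_sys", "_dia"))
    sys_keys = set(zip(sys_obs["patient_id"], sys_obs["obs_date"]))
    dia_keys = set(zip(dia_obs["patient_id"], dia_obs["obs_date"]))
    n_unpaired = sum(k not in dia_keys for k in sys_keys) + sum(
        k not in sys_keys for k in dia_keys
    )

    pairs = pairs.merge(
        onset.rename("htn_onset"), left_on="patient_id", right_index=True
    ).reset_index(drop=True)
    qualifying = pairs.loc[
        (pairs["obs_date"] >= pairs["htn_onset"])
        & pairs["obs_date"].between(_ts(period.start), _ts(period.end))
    ]
    if not all_readings:
        qualifying = (
            qualifying.sort_values(["obs_date", "value_sys", "value_dia"], kind="mergesort")
            .groupby("patient_id", sort=False)
            .tail(1)
        )
    by_patient = dict(tuple(qualifying.groupby("patient_id", sort=False)))

    values = []
    for pid in denom_ids:
        limits = _bp_limits(int(in_age[pid]), pid in diabetic_ids, threshold_rules)
        readings = by_patient.get(pid)
        if limits is None or readings is None or readings.empty:
            values.append(False)
            continue
        s_lim, d_lim = limits
        below = (readings["value_sys"] < s_lim) & (readings["value_dia"] < d_lim)
        values.append(bool(below.all()))
    flags = pd.Series(values, index=denom_ids, dtype=bool, name="controlled")
    return _result("bp_control", flags, unpaired_readings=int(n_unpaired))


# ---------------------------------------------------------------------------
# configuration and the all-measures runner


class BootstrapConfig(pydantic.BaseModel):
    resamples: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def settings(self, offset: int = 0) -> BootstrapSettings:
        return BootstrapSettings(self.resamples, self.alpha, self.seed + offset)


class MeasureConfig(pydantic.BaseModel):
    """Declarative run configuration (YAML-loadable).

    ``period`` is the event/measurement year shared by the COPD,
    hip/knee and BP measures; the screening measure uses the wider
    ``screening_period`` (two calendar years, lookbacks anchored at its
    end).
    """

    period: MeasurementPeriod = MeasurementPeriod(dt.date(2016, 1, 1), dt.date(2016, 12, 31))
    screening_period: MeasurementPeriod = MeasurementPeriod(
        dt.date(2015, 1, 1), dt.date(2016, 12, 31)
    )
    measures: tuple[str, ...] = MEASURES
    copd_mode: str = "strict"
    alive_any_point: bool = False
    bootstrap: BootstrapConfig = BootstrapConfig()
    valuesets_path: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "MeasureConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        try:
            return cls.model_validate(doc)
        except pydantic.ValidationError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


_SEED_OFFSET = {name: i for i, name in enumerate(MEASURES)}


def run_all(
    cohort: EhrCohort,
    config: MeasureConfig | None = None,
    valuesets: ValueSetLibrary | None = None,
) -> list[MeasureResult]:
    """Run the configured measures and attach bootstrap CIs.

    Deterministic given cohort, config and seed.  Unknown measure names
    raise :class:`ConfigError`.
    """
    config = config or MeasureConfig()
    vs = valuesets if valuesets is not None else load_valuesets(config.valuesets_path)
    results = []
    for name in config.measures:
        if name == "colorectal_screening":
            res = colorectal_screening(
                cohort, config.screening_period, vs, alive_any_point=config.alive_any_point
            )
        elif name == "copd_mortality":
            res = copd_mortality(cohort, config.period, vs, mode=config.copd_mode)
        elif name == "hip_knee_complications":
            res = hip_knee_complications(cohort, config.period, vs)
        elif name == "bp_control":
            res = bp_control(cohort, config.period, vs)
        else:
            raise ConfigError(f"unknown measure name {name!r}")
        results.append(res.with_ci(config.bootstrap.settings(_SEED_OFFSET[name])))
    return results
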