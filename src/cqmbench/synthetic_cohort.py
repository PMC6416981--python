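"""Configurable synthetic EHR cohort generator.

A parameterized statistical stand-in for a Synthea-style population:
demographic marginals (age bands, sex, height/weight), chronic-condition
prevalences, service-delivery probabilities (screening modality mix and
intervals, admissions, BP readings) and — crucially — *configurable*
post-service outcome probabilities (30-day mortality after a COPD
admission, post-operative complications, BP control).  Setting every
outcome probability to zero reproduces the degenerate regime observed in
the real SyntheticMass release, where process measures score realistic
rates but outcome measures have empty numerators.

Generation is deterministic given the seed; the same seed yields
byte-identical CSV output through
:func:`~cqmbench.ehr_tables.write_cohort`.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Optional

import numpy as np
import pandas as pd
import pydantic

from .ehr_tables import EhrCohort, ages_at, make_cohort, years_ago
from .measure_engine import DEFAULT_COMPLICATION_RULES, DEFAULT_SCREENING_MODALITIES
from .terminology import ValueSetLibrary, load_valuesets

AMBULATORY_CODE = "SYN-AMBULATORY"
INPATIENT_CODE = "SYN-INPATIENT"

_AGE_BANDS = ("<18", "18-64", ">=65")
_BAND_EDGES = ((0.0, 18.0), (18.0, 65.0), (65.0, 95.0))
_RACES = ("white", "black", "asian", "hispanic", "other")
_RACE_PROBS = (0.71, 0.09, 0.07, 0.10, 0.03)

_MODALITIES = {m.name: m for m in DEFAULT_SCREENING_MODALITIES}


def _zero_complications() -> dict[str, float]:
    return {rule.name: 0.0 for rule in DEFAULT_COMPLICATION_RULES}


def _default_complications() -> dict[str, float]:
    # roughly 2.9% combined, matching the real-world reference magnitude
    probs = dict.fromkeys((r.name for r in DEFAULT_COMPLICATION_RULES), 0.003)
    probs["death"] = 0.002
    return probs


class CohortConfig(pydantic.BaseModel):
    """Generator parameters; probabilities are per the described unit.

    Defaults encode the demographic marginals of the SyntheticMass
    population (age bands 19.2/64.5/16.3%, 51% female, sex-specific
    height/weight averages) and an adult hypertension prevalence near
    30%.
    """

    n_patients: int = pydantic.Field(10_000, ge=0)
    seed: int = 0
    period_start: dt.date = dt.date(2015, 1, 1)
    period_end: dt.date = dt.date(2016, 12, 31)

    age_band_probs: tuple[float, float, float] = (0.192, 0.645, 0.163)
    female_prob: float = 0.51
    hypertension_prev_adult: float = 0.30
    diabetes_prev_adult: float = 0.10
    copd_prev_adult: float = 0.055

    #: expected index admissions per COPD patient in the event year
    copd_admission_rate: float = 0.15
    copd_mortality_30d: float = 0.07
    #: background ambulatory encounters per patient per year
    visit_rate: float = 2.0

    screening_offer_prob: float = 0.70
    modality_mix: dict[str, float] = pydantic.Field(
        default_factory=lambda: {
            "colonoscopy": 0.40,
            "flexible_sigmoidoscopy": 0.05,
            "ct_colonography": 0.05,
            "fobt": 0.40,
            "stool_dna": 0.10,
        }
    )

    #: fraction of patients aged >= 45 with a joint replacement in the event year
    hipknee_rate: float = 0.01
    complication_probs: dict[str, float] = pydantic.Field(default_factory=_default_complications)

    #: paired BP readings per hypertensive patient per year (at least one emitted)
    bp_reading_rate: float = 2.0
    bp_control_prob: float = 0.70

    #: per sex: (mean cm, sd cm) for height; (mean kg, log-sd) for lognormal weight
    height_cm_params: dict[str, tuple[float, float]] = pydantic.Field(
        default_factory=lambda: {"male": (176.77, 7.0), "female": (163.33, 6.5)}
    )
    weight_kg_params: dict[str, tuple[float, float]] = pydantic.Field(
        default_factory=lambda: {"male": (97.98, 0.22), "female": (86.04, 0.22)}
    )

    @pydantic.model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        for name in (
            "female_prob",
            "hypertension_prev_adult",
            "diabetes_prev_adult",
            "copd_prev_adult",
            "copd_mortality_30d",
            "screening_offer_prob",
            "hipknee_rate",
            "bp_control_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name, v in self.complication_probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"complication_probs[{name!r}] out of [0, 1]: {v}")
        if abs(sum(self.age_band_probs) - 1.0) > 1e-9:
            raise ValueError("age_band_probs must sum to 1")
        if abs(sum(self.modality_mix.values()) - 1.0) > 1e-9:
            raise ValueError("modality_mix must sum to 1")
        unknown = set(self.modality_mix) - set(_MODALITIES)
        if unknown:
            raise ValueError(f"unknown screening modalities: {sorted(unknown)}")
        for rate in ("copd_admission_rate", "visit_rate", "bp_reading_rate"):
            if getattr(self, rate) < 0:
                raise ValueError(f"{rate} must be non-negative")
        if self.period_start > self.period_end:
            raise ValueError("period_start after period_end")
        return self

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        import yaml

        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


def paper_mimic_config(n_patients: int = 50_000, seed: int = 0) -> CohortConfig:
    """The shipped SyntheticMass-mimicking regime.

    Service probabilities are realistic (screening offered to 68.7% of
    the eligible, only colonoscopy and FOBT in the modality mix, sparse
    principal-diagnosis COPD admissions) while every post-service
    outcome probability is zero except a 0.7% 30-day mortality after
    COPD admissions — so outcome measures return empty or near-empty
    numerators over non-empty denominators.
    """
    mix = dict.fromkeys(_MODALITIES, 0.0)
    mix.update({"colonoscopy": 0.9, "fobt": 0.1})
    return CohortConfig(
        n_patients=n_patients,
        seed=seed,
        hypertension_prev_adult=0.2991,
        copd_prev_adult=0.055,
        copd_admission_rate=0.0077,
        copd_mortality_30d=0.007,
        screening_offer_prob=0.687,
        modality_mix=mix,
        hipknee_rate=0.0004,
        complication_probs=_zero_complications(),
        bp_control_prob=0.0,
    )


def _rand_date(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    span = (hi - lo).days
    return lo + dt.timedelta(days=int(rng.integers(0, span + 1)))


def generate(config: CohortConfig, valuesets: Optional[ValueSetLibrary] = None) -> EhrCohort:
    """Sample a full cohort from the configured probabilities.

    Events that would postdate a patient's death are removed in a final
    cleanup pass, so the emitted tables always satisfy referential and
    temporal integrity.
    """
    vs = valuesets if valuesets is not None else load_valuesets()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ps, pe = config.period_start, config.period_end
    event_start = dt.date(pe.year, 1, 1)  # index admissions, surgeries, readings
    horizon_days = (pe - ps).days + 1

    # --- demographics -----------------------------------------------------
    band = rng.choice(3, size=n, p=list(config.age_band_probs))
    lo_age = np.array([e[0] for e in _BAND_EDGES])[band]
    hi_age = np.array([e[1] for e in _BAND_EDGES])[band]
    age_cont = rng.uniform(lo_age, hi_age)
    birth = pd.Timestamp(pe) - pd.to_timedelta(
        np.floor(age_cont * 365.2425).astype(np.int64), unit="D"
    )
    female = rng.random(n) < config.female_prob
    race = rng.choice(_RACES, size=n, p=_RACE_PROBS)
    pid = np.array([f"P{i:07d}" for i in range(n)])
    age_at_end = ages_at(pd.Series(birth), pe).to_numpy() if n else np.zeros(0, dtype=int)
    adult = age_at_end >= 18

    height = np.full(n, np.nan)
    weight = np.full(n, np.nan)
    for sex, is_female in (("male", False), ("female", True)):
        mask = adult & (female == is_female)
        hm, hs = config.height_cm_params[sex]
        wm, wsig = config.weight_kg_params[sex]
        height[mask] = rng.normal(hm, hs, mask.sum())
        weight[mask] = rng.lognormal(math.log(wm) - wsig**2 / 2, wsig, mask.sum())

    htn = adult & (rng.random(n) < config.hypertension_prev_adult)
    diab = adult & (rng.random(n) < config.diabetes_prev_adult)
    copd = adult & (rng.random(n) < config.copd_prev_adult)

    encounters: list[dict] = []
    conditions: list[dict] = []
    observations: list[dict] = []
    procedures: list[dict] = []
    death: dict[int, dt.date] = {}
    eid_counter = iter(range(10**8))

    def next_eid() -> str:
        return f"E{next(eid_counter):08d}"

    copd_codes = sorted(vs["copd"].codes)

    # --- COPD: condition, index admissions, 30-day mortality --------------
    # Admissions are spaced >= 31 days apart and truncated at death, so
    # every emitted admission is an independent Bernoulli mortality trial.
    for i in np.flatnonzero(copd):
        code = copd_codes[int(rng.integers(0, len(copd_codes)))]
        onset = _rand_date(rng, years_ago(pe, 10), dt.date(pe.year - 1, 12, 31))
        conditions.append(
            dict(patient_id=pid[i], encounter_id=None, code=code, onset_date=onset, end_date=None)
        )
        k = int(rng.poisson(config.copd_admission_rate))
        if k == 0:
            continue
        days = np.sort(rng.integers(0, (pe - event_start).days + 1, size=k))
        kept: list[int] = []
        for d in days:
            if not kept or d - kept[-1] >= 31:
                kept.append(int(d))
        for d in kept:
            start = event_start + dt.timedelta(days=d)
            encounters.append(
                dict(
                    encounter_id=next_eid(),
                    patient_id=pid[i],
                    start_date=start,
                    stop_date=start + dt.timedelta(days=3),
                    encounter_code=INPATIENT_CODE,
                    principal_diagnosis=code,
                )
            )
            if rng.random() < config.copd_mortality_30d:
                death[i] = start + dt.timedelta(days=int(rng.integers(0, 31)))
                break

    # --- hip/knee replacement and post-operative complications ------------
    idx_valuesets = ("total_knee_replacement", "total_hip_replacement")
    for i in np.flatnonzero(age_at_end >= 45):
        if rng.random() >= config.hipknee_rate:
            continue
        idx_date = _rand_date(rng, event_start, pe)
        idx_code = sorted(vs[idx_valuesets[int(rng.integers(0, 2))]].codes)[0]
        procedures.append(dict(patient_id=pid[i], proc_date=idx_date, code=idx_code))
        encounters.append(
            dict(
                encounter_id=next_eid(),
                patient_id=pid[i],
                start_date=idx_date,
                stop_date=idx_date + dt.timedelta(days=3),
                encounter_code=INPATIENT_CODE,
                principal_diagnosis=idx_code,
            )
        )
        for rule in DEFAULT_COMPLICATION_RULES:
            p = config.complication_probs.get(rule.name, 0.0)
            if p <= 0.0 or rng.random() >= p:
                continue
            when = idx_date + dt.timedelta(days=int(rng.integers(0, rule.window_days + 1)))
            if rule.is_death_rule:
                death[i] = min(death.get(i, when), when)
                continue
            ccode = sorted(vs[rule.valueset].codes)[0]
            feid = next_eid()
            encounters.append(
                dict(
                    encounter_id=feid,
                    patient_id=pid[i],
                    start_date=when,
                    stop_date=when,
                    encounter_code=AMBULATORY_CODE,
                    principal_diagnosis=ccode,
                )
            )
            conditions.append(
                dict(
                    patient_id=pid[i],
                    encounter_id=feid,
                    code=ccode,
                    onset_date=when,
                    end_date=None,
                )
            )

    # --- colorectal-cancer screening procedures ---------------------------
    mod_names = sorted(config.modality_mix)
    mod_probs = np.array([config.modality_mix[m] for m in mod_names])
    eligible = np.flatnonzero((age_at_end >= 50) & (age_at_end <= 75))
    offered = eligible[rng.random(eligible.size) < config.screening_offer_prob]
    if offered.size and mod_probs.sum() > 0:
        choice = rng.choice(len(mod_names), size=offered.size, p=mod_probs)
        for i, c in zip(offered, choice):
            modality = _MODALITIES[mod_names[int(c)]]
            when = _rand_date(rng, years_ago(pe, modality.interval_years), pe)
            code = sorted(vs[modality.valueset].codes)[0]
            procedures.append(dict(patient_id=pid[i], proc_date=when, code=code))

    # --- hypertension, diabetes and paired BP readings ---------------------
    # Reading days are drawn without replacement so the most recent
    # reading is unique; its control status is the configured Bernoulli.
    for i in np.flatnonzero(diab):
        onset = _rand_date(rng, years_ago(pe, 10), dt.date(pe.year - 1, 12, 31))
        conditions.append(
            dict(
                patient_id=pid[i],
                encounter_id=None,
                code=sorted(vs["diabetes"].codes)[0],
                onset_date=onset,
                end_date=None,
            )
        )
    htn_code = sorted(vs["hypertension"].codes)[0]
    for i in np.flatnonzero(htn):
        onset = _rand_date(rng, years_ago(ps, 3), pe - dt.timedelta(days=60))
        conditions.append(
            dict(patient_id=pid[i], encounter_id=None, code=htn_code, onset_date=onset, end_date=None)
        )
        win_lo = max(onset, event_start)
        win_days = (pe - win_lo).days + 1
        k = min(max(1, int(rng.poisson(config.bp_reading_rate))), win_days)
        offsets = np.sort(rng.choice(win_days, size=k, replace=False))
        controlled_last = rng.random() < config.bp_control_prob
        for j, off in enumerate(offsets):
            day = win_lo + dt.timedelta(days=int(off))
            controlled = controlled_last if j == k - 1 else bool(rng.random() < 0.5)
            if controlled:
                sbp = round(float(rng.uniform(105, 135)), 1)
                dbp = round(float(rng.uniform(62, 85)), 1)
            else:
                sbp = round(float(rng.uniform(152, 185)), 1)
                dbp = round(float(rng.uniform(92, 115)), 1)
            observations.append(
                dict(patient_id=pid[i], obs_date=day, code="8480-6", value=sbp, units="mm[Hg]")
            )
            observations.append(
                dict(patient_id=pid[i], obs_date=day, code="8462-4", value=dbp, units="mm[Hg]")
            )

    # --- background ambulatory encounters ----------------------------------
    counts = rng.poisson(config.visit_rate * horizon_days / 365.2425, size=n)
    owners = np.repeat(np.arange(n), counts)
    offs = rng.integers(0, horizon_days, size=owners.size)
    for i, off in zip(owners, offs):
        start = ps + dt.timedelta(days=int(off))
        encounters.append(
            dict(
                encounter_id=next_eid(),
                patient_id=pid[i],
                start_date=start,
                stop_date=start,
                encounter_code=AMBULATORY_CODE,
                principal_diagnosis=None,
            )
        )

    # --- assemble, drop post-death events ----------------------------------
    death_col = pd.to_datetime(
        pd.Series([death.get(i) for i in range(n)], dtype="object"), errors="coerce"
    )
    patients = pd.DataFrame(
        dict(
            patient_id=pid,
            birth_date=pd.Series(birth),
            death_date=death_col,
            gender=np.where(female, "female", "male"),
            race=race,
            height_cm=height,
            weight_kg=weight,
        )
    )
    death_by_pid = {pid[i]: pd.Timestamp(d) for i, d in death.items()}

    def _alive_mask(rows: list[dict], date_key: str) -> list[dict]:
        out = []
        for row in rows:
            d = death_by_pid.get(row["patient_id"])
            if d is None or pd.Timestamp(row[date_key]) <= d:
                out.append(row)
        return out

    encounters = _alive_mask(encounters, "start_date")
    conditions = _alive_mask(conditions, "onset_date")
    observations = _alive_mask(observations, "obs_date")
    procedures = _alive_mask(procedures, "proc_date")

    return make_cohort(
        patients=patients,
        encounters=encounters,
        conditions=conditions,
        observations=observations,
        procedures=procedures,
    )
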