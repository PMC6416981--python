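"""Independent brute-force re-implementations of the four measures.

Pure-Python row-by-row enumeration over plain dicts and ``datetime.date``
objects, written directly from the measure definitions without reusing
any engine code paths.  Intended for small cohorts only.
"""

from __future__ import annotations

import datetime as dt

import pandas as pd

DAY = dt.timedelta(days=1)


def _date(x):
    if x is None or pd.isna(x):
        return None
    if isinstance(x, pd.Timestamp):
        return x.date()
    if isinstance(x, dt.datetime):
        return x.date()
    return x


def _rows(df):
    out = []
    for rec in df.to_dict("records"):
        row = {}
        for key, val in rec.items():
            if key.endswith("_date") or key == "obs_date":
                row[key] = _date(val)
            elif val is pd.NA or (not isinstance(val, (str, int, float)) and pd.isna(val)):
                row[key] = None
            else:
                row[key] = val
        out.append(row)
    return out


def _age(birth: dt.date, asof: dt.date) -> int:
    years = asof.year - birth.year
    if (asof.month, asof.day) < (birth.month, birth.day):
        years -= 1
    return years


def _anniv_before(d: dt.date, years: int) -> dt.date:
    try:
        return d.replace(year=d.year - years)
    except ValueError:
        return d.replace(year=d.year - years, day=28)


def _active(row, day: dt.date) -> bool:
    onset, end = row["onset_date"], row["end_date"]
    return onset is not None and onset <= day and (end is None or day <= end)


def screening_oracle(cohort, start: dt.date, end: dt.date, valuesets, modalities):
    """(denominator, numerator) for colorectal screening, by enumeration."""
    procs = _rows(cohort.procedures)
    den = num = 0
    for p in _rows(cohort.patients):
        age = _age(p["birth_date"], end)
        if not 50 <= age <= 75:
            continue
        if p["death_date"] is not None and p["death_date"] < end:
            continue
        den += 1
        ok = False
        for m in modalities:
            codes = valuesets[m.valueset].codes
            cutoff = _anniv_before(end, m.interval_years)
            for pr in procs:
                if pr["patient_id"] == p["patient_id"] and pr["code"] in codes \
                        and cutoff <= pr["proc_date"] <= end:
                    ok = True
        num += ok
    return den, num


def copd_oracle(cohort, start: dt.date, end: dt.date, valuesets, mode: str):
    codes = valuesets["copd"].codes
    conds = _rows(cohort.conditions)
    deaths = {p["patient_id"]: p["death_date"] for p in _rows(cohort.patients)}
    den = num = 0
    for e in _rows(cohort.encounters):
        day = e["start_date"]
        if not start <= day <= end:
            continue
        eligible = e["principal_diagnosis"] in codes
        if mode == "expanded" and not eligible:
            eligible = any(
                c["patient_id"] == e["patient_id"] and c["code"] in codes and _active(c, day)
                for c in conds
            )
        if not eligible:
            continue
        den += 1
        death = deaths.get(e["patient_id"])
        if death is not None and day <= death <= day + 30 * DAY:
            num += 1
    return den, num


def hipknee_oracle(cohort, start: dt.date, end: dt.date, valuesets, rules):
    idx_codes = valuesets["total_knee_replacement"].codes | valuesets["total_hip_replacement"].codes
    index: dict[str, dt.date] = {}
    for pr in _rows(cohort.procedures):
        if pr["code"] in idx_codes and start <= pr["proc_date"] <= end:
            cur = index.get(pr["patient_id"])
            if cur is None or pr["proc_date"] < cur:
                index[pr["patient_id"]] = pr["proc_date"]
    conds = _rows(cohort.conditions)
    encs = _rows(cohort.encounters)
    deaths = {p["patient_id"]: p["death_date"] for p in _rows(cohort.patients)}
    den = len(index)
    num = 0
    for pid, idx in index.items():
        hit = False
        for rule in rules:
            hi = idx + rule.window_days * DAY
            if rule.is_death_rule:
                d = deaths.get(pid)
                if d is not None and idx <= d <= hi:
                    hit = True
                continue
            codes = valuesets[rule.valueset].codes
            for c in conds:
                if c["patient_id"] == pid and c["code"] in codes and idx <= c["onset_date"] <= hi:
                    hit = True
            for e in encs:
                if e["patient_id"] == pid and e["principal_diagnosis"] in codes \
                        and idx <= e["start_date"] <= hi:
                    hit = True
        num += hit
    return den, num


def bp_oracle(cohort, start: dt.date, end: dt.date, valuesets,
              systolic_code="8480-6", diastolic_code="8462-4"):
    htn_codes = valuesets["hypertension"].codes
    dia_codes = valuesets["diabetes"].codes
    conds = _rows(cohort.conditions)
    obs = _rows(cohort.observations)
    den = num = 0
    for p in _rows(cohort.patients):
        age = _age(p["birth_date"], end)
        if not 18 <= age <= 85:
            continue
        onsets = [
            c["onset_date"] for c in conds
            if c["patient_id"] == p["patient_id"] and c["code"] in htn_codes
            and c["onset_date"] <= end and (c["end_date"] is None or c["end_date"] >= start)
        ]
        if not onsets:
            continue
        den += 1
        onset = min(onsets)
        diabetic = any(
            c["patient_id"] == p["patient_id"] and c["code"] in dia_codes and _active(c, end)
            for c in conds
        )
        if age <= 59 or diabetic:
            s_lim, d_lim = 140.0, 90.0
        else:
            s_lim, d_lim = 150.0, 90.0
        # all (systolic, diastolic) pairs sharing a date, onset <= date <= end
        pairs = []
        for s in obs:
            if s["patient_id"] != p["patient_id"] or s["code"] != systolic_code:
                continue
            if not (onset <= s["obs_date"] <= end and start <= s["obs_date"]):
                continue
            for d in obs:
                if d["patient_id"] == p["patient_id"] and d["code"] == diastolic_code \
                        and d["obs_date"] == s["obs_date"]:
                    pairs.append((s["obs_date"], s["value"], d["value"]))
        if not pairs:
            continue
        latest = max(pairs)  # max date, ties broken toward the highest reading
        num += (latest[1] < s_lim) and (latest[2] < d_lim)
    return den, num
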