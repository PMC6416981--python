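"""Demographic summaries and comparison against publicly reported rates."""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .ehr_tables import EhrCohort, ages_at
from .measure_engine import MeasureResult
from .terminology import ConfigError

AGE_BANDS = ("<18", "18-64", ">=65")
BMI_BANDS = ("<18.5", "18.5-24.99", "25-29.99", ">=30")


@dataclasses.dataclass
class DemographicSummary:
    """Cohort-level demographic marginals (population-table analogue)."""

    total: int
    age_band_fractions: dict[str, float]
    mean_age: Optional[float]
    female_fraction: Optional[float]
    bmi_category_fractions: dict[str, float]
    mean_height_cm: dict[str, float]
    mean_weight_kg: dict[str, float]
    adult_hypertension_fraction: Optional[float]

    def to_frame(self) -> pd.DataFrame:
        rows = [("total_population", self.total)]
        rows += [(f"age {b}", f) for b, f in self.age_band_fractions.items()]
        rows += [("mean_age", self.mean_age), ("female_fraction", self.female_fraction)]
        rows += [(f"bmi {b}", f) for b, f in self.bmi_category_fractions.items()]
        rows += [(f"mean_height_cm {s}", v) for s, v in self.mean_height_cm.items()]
        rows += [(f"mean_weight_kg {s}", v) for s, v in self.mean_weight_kg.items()]
        rows += [("adult_hypertension_fraction", self.adult_hypertension_fraction)]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def summarize_demographics(
    cohort: EhrCohort,
    as_of_date,
    hypertension_codes: frozenset[str] = frozenset({"38341003"}),
) -> DemographicSummary:
    """Age-band/sex/BMI marginals and adult hypertension prevalence.

    BMI = weight_kg / (height_cm/100)^2; patients missing height or
    weight are excluded from the BMI rows only.  Hypertension prevalence
    is the fraction of adults (18+ at ``as_of_date``) with a
    hypertension-coded condition active on that date.
    """
    pats = cohort.patients
    total = len(pats)
    if total == 0:
        return DemographicSummary(0, {}, None, None, {}, {}, {}, None)

    age = ages_at(pats["birth_date"], as_of_date)
    band_fracs = {
        "<18": float((age < 18).mean()),
        "18-64": float(((age >= 18) & (age < 65)).mean()),
        ">=65": float((age >= 65).mean()),
    }

    bmi = pats["weight_kg"] / (pats["height_cm"] / 100.0) ** 2
    with_bmi = bmi.dropna()
    adult_bmi = with_bmi[age.reindex(with_bmi.index) >= 18]
    if len(adult_bmi):
        bmi_fracs = {
            "<18.5": float((adult_bmi < 18.5).mean()),
            "18.5-24.99": float(((adult_bmi >= 18.5) & (adult_bmi < 25)).mean()),
            "25-29.99": float(((adult_bmi >= 25) & (adult_bmi < 30)).mean()),
            ">=30": float((adult_bmi >= 30).mean()),
        }
    else:
        bmi_fracs = {}

    mean_h: dict[str, float] = {}
    mean_w: dict[str, float] = {}
    for sex in ("male", "female"):
        sel = pats["gender"] == sex
        h = pats.loc[sel, "height_cm"].dropna()
        w = pats.loc[sel, "weight_kg"].dropna()
        if len(h):
            mean_h[sex] = float(h.mean())
        if len(w):
            mean_w[sex] = float(w.mean())

    adults = set(pats.loc[age >= 18, "patient_id"])
    cond = cohort.conditions
    ts = pd.Timestamp(as_of_date)
    active = (
        cond["code"].isin(hypertension_codes)
        & (cond["onset_date"] <= ts)
        & (cond["end_date"].isna() | (cond["end_date"] >= ts))
    )
    hyp_adults = set(cond.loc[active, "patient_id"]) & adults
    htn_frac = (len(hyp_adults) / len(adults)) if adults else None

    return DemographicSummary(
        total=total,
        age_band_fractions=band_fracs,
        mean_age=float(age.mean()),
        female_fraction=float((pats["gender"] == "female").mean()),
        bmi_category_fractions=bmi_fracs,
        mean_height_cm=mean_h,
        mean_weight_kg=mean_w,
        adult_hypertension_fraction=htn_frac,
    )


class ReferenceRates:
    """Per-measure Massachusetts and national reference rates (static config)."""

    def __init__(self, entries: dict[str, dict]):
        for name, e in entries.items():
            for key in ("massachusetts", "national"):
                v = e.get(key)
                if v is None or not 0.0 <= float(v) <= 1.0:
                    raise ConfigError(f"reference rate {name}.{key} must be in [0, 1], got {v!r}")
        self._entries = entries

    def get(self, measure: str) -> Optional[dict]:
        return self._entries.get(measure)

    def __contains__(self, measure: str) -> bool:
        return measure in self._entries


def load_reference_rates(config_path=None) -> ReferenceRates:
    if config_path is None:
        text = resources.files("cqmbench").joinpath("data/reference_rates.yaml").read_text()
    else:
        path = Path(config_path)
        if not path.exists():
            raise ConfigError(f"reference-rate config not found: {path}")
        text = path.read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "measures" not in doc:
        raise ConfigError("reference-rate config must contain a 'measures' mapping")
    return ReferenceRates(doc["measures"])


def compare_rates(results, reference: ReferenceRates) -> pd.DataFrame:
    """Synthetic rate + CI vs reference rates, with absolute differences.

    ``results`` are :class:`MeasureResult` objects or equivalent record
    dicts.  Measures absent from the reference config get a flagged row
    rather than a failure; denominator-0 measures carry NA rates and no
    differences.
    """
    rows = []
    for res in results:
        rec = res.to_record() if isinstance(res, MeasureResult) else dict(res)
        name = rec["measure"]
        ref = reference.get(name)
        rate = rec.get("rate")
        row = {
            "measure": name,
            "denominator": rec.get("denominator"),
            "numerator": rec.get("numerator"),
            "rate": np.nan if rate is None else float(rate),
            "ci_low": np.nan if rec.get("ci_low") is None else float(rec["ci_low"]),
            "ci_high": np.nan if rec.get("ci_high") is None else float(rec["ci_high"]),
            "massachusetts_rate": np.nan,
            "national_rate": np.nan,
            "diff_massachusetts": np.nan,
            "diff_national": np.nan,
            "reference_found": ref is not None,
        }
        if ref is not None:
            row["massachusetts_rate"] = float(ref["massachusetts"])
            row["national_rate"] = float(ref["national"])
            if rate is not None:
                row["diff_massachusetts"] = float(rate) - row["massachusetts_rate"]
                row["diff_national"] = float(rate) - row["national_rate"]
        rows.append(row)
    return pd.DataFrame(rows)


def render_comparison(comparison: pd.DataFrame) -> str:
    """Human-readable text table for the comparison report."""
    view = comparison.copy()
    for col in ("rate", "ci_low", "ci_high", "massachusetts_rate", "national_rate",
                "diff_massachusetts", "diff_national"):
        view[col] = view[col].map(lambda v: "NA" if pd.isna(v) else f"{100 * v:.1f}%")
    return view.to_string(index=False)
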