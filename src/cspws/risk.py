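"""Five-year cumulative colorectal-cancer risk model.

Annual progression rates (advanced-adenoma incidence, AA-to-CRC progression,
metachronous CRC) are stratified by colonoscopy-history category, sex and
age (< 80 / >= 80) and converted to cumulative probabilities by the
exponential-hazard relation ``1 - exp(-rate * time)``.  The cohort risk is

    CRC_risk = (AAr * sum_i AA_to_CRC_i + Nc * CRCm) / (Na + Nc)

with ``Na`` patients without cancer history (advanced-adenoma pathway,
per-patient AA-to-CRC terms), ``Nc`` patients with cancer history
(metachronous pathway), ``AAr`` the cumulative risk of developing a future
advanced adenoma and ``CRCm`` the cumulative metachronous risk.

The rate table ships with clearly labeled placeholder values (the consensus
sources publish the real ones); it is user-editable YAML.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RateRow", "RiskTable", "RiskInputs", "age_stratum",
    "cumulative_risk", "crc_5yr_risk", "cohort_group_risks",
    "default_risk_table",
]

HISTORY_CATEGORIES = ("no_history", "low_risk", "high_risk")
SEXES = ("F", "M")
AGE_STRATA = ("<80", ">=80")


def age_stratum(age: float) -> str:
    return "<80" if age < 80 else ">=80"


@dataclass(frozen=True)
class RateRow:
    annual_aa_incidence: float   # /yr, nonsignificant/diminutive -> AA
    annual_aa_to_crc: float      # /yr, AA -> CRC
    annual_metachronous: float   # /yr, metachronous CRC after cancer

    def __post_init__(self):
        if min(self.annual_aa_incidence, self.annual_aa_to_crc,
               self.annual_metachronous) < 0:
            raise ValueError("annual rates must be nonnegative")


@dataclass
class RiskTable:
    """Annual rates keyed by (history category, sex, age stratum)."""

    rates: dict
    horizon_years: float = 5.0

    def __post_init__(self):
        for cat in HISTORY_CATEGORIES:
            for sex in SEXES:
                for stratum in AGE_STRATA:
                    if (cat, sex, stratum) not in self.rates:
                        raise ValueError(
                            f"missing rate row for {(cat, sex, stratum)}")

    def row_for(self, history: str, sex: str, age: float) -> RateRow:
        key = (history, sex, age_stratum(age))
        if key not in self.rates:
            raise KeyError(f"history category {history!r} not in risk table")
        return self.rates[key]

    def to_yaml(self, path):
        out = {"horizon_years": self.horizon_years, "rates": {}}
        for (cat, sex, stratum), row in self.rates.items():
            out["rates"][f"{cat}|{sex}|{stratum}"] = {
                "annual_aa_incidence": row.annual_aa_incidence,
                "annual_aa_to_crc": row.annual_aa_to_crc,
                "annual_metachronous": row.annual_metachronous,
            }
        with open(path, "w") as fh:
            yaml.safe_dump(out, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RiskTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        rates = {}
        for key, row in raw["rates"].items():
            cat, sex, stratum = key.split("|")
            rates[(cat, sex, stratum)] = RateRow(**row)
        return cls(rates=rates, horizon_years=float(raw["horizon_years"]))


def default_risk_table() -> RiskTable:
    """Editable PLACEHOLDER rate table.

    The values below are synthetic placeholders with the qualitative
    ordering high_risk >= low_risk >= no_history and mild male / over-80
    elevation; substitute published surveillance rates for real use.
    """
    base = {
        "no_history": (0.005, 0.020, 0.000),
        "low_risk": (0.010, 0.030, 0.002),
        "high_risk": (0.020, 0.050, 0.008),
    }
    rates = {}
    for cat, (aa, aacrc, met) in base.items():
        for sex in SEXES:
            sex_f = 1.2 if sex == "M" else 1.0
            for stratum in AGE_STRATA:
                age_f = 1.5 if stratum == ">=80" else 1.0
                rates[(cat, sex, stratum)] = RateRow(
                    annual_aa_incidence=aa * sex_f * age_f,
                    annual_aa_to_crc=aacrc * sex_f * age_f,
                    annual_metachronous=met * sex_f * age_f)
    return RiskTable(rates=rates)


def cumulative_risk(annual_rate: float, years: float) -> float:
    """Convert an annual rate to a cumulative probability,
    ``1 - exp(-annual_rate * years)``."""
    annual_rate = np.asarray(annual_rate, float)
    years = np.asarray(years, float)
    if np.any(annual_rate < 0) or np.any(years < 0):
        raise ValueError("annual_rate and years must be nonnegative")
    out = 1.0 - np.exp(-annual_rate * years)
    return float(out) if out.ndim == 0 else out


@dataclass
class RiskInputs:
    """Cohort-level inputs of the 5-year risk formula."""

    na: int
    nc: int
    aa_r: float
    aa_to_crc: np.ndarray
    crc_m: float

    def __post_init__(self):
        self.aa_to_crc = np.asarray(self.aa_to_crc, float)
        if self.na < 0 or self.nc < 0 or self.na + self.nc < 1:
            raise ValueError("need Na >= 0, Nc >= 0, Na + Nc >= 1")
        if len(self.aa_to_crc) != self.na:
            raise ValueError("aa_to_crc must have one entry per Na patient")
        probs = np.concatenate([[self.aa_r, self.crc_m], self.aa_to_crc])
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("cumulative risks must lie in [0, 1]")


def crc_5yr_risk(inputs: RiskInputs) -> float:
    """Evaluate the cohort 5-year CRC risk formula; clips to [0, 1] with a
    warning if the inputs imply a value above one."""
    total = inputs.aa_r * inputs.aa_to_crc.sum() + inputs.nc * inputs.crc_m
    value = total / (inputs.na + inputs.nc)
    if value > 1.0:
        warnings.warn("risk formula exceeded 1; clipping", RuntimeWarning)
        value = 1.0
    return float(value)


def cohort_group_risks(cohort, table: RiskTable) -> pd.DataFrame:
    """Per-group 5-year risk from each patient's stratum-specific rates.

    For each cohort group: Na patients (no cancer history) contribute
    per-patient cumulative AA-to-CRC terms and their mean cumulative AA
    incidence forms the group AAr; Nc patients (cancer history) contribute
    the mean cumulative metachronous risk CRCm.
    """
    t = table.horizon_years
    rows = []
    groups: dict[str, list] = {}
    for p in cohort.patients:
        groups.setdefault(p.group, []).append(p)
    for name, members in groups.items():
        aa_r_terms, aa_to_crc, crc_m_terms = [], [], []
        for p in members:
            rates = table.row_for(p.history, p.sex, p.age)
            if p.prior_cancer:
                crc_m_terms.append(cumulative_risk(rates.annual_metachronous, t))
            else:
                # a patient who already harbors an advanced adenoma does not
                # need to develop one first: AAr contribution is 1
                if getattr(p, "current_aa", False):
                    aa_r_terms.append(1.0)
                else:
                    aa_r_terms.append(
                        cumulative_risk(rates.annual_aa_incidence, t))
                aa_to_crc.append(cumulative_risk(rates.annual_aa_to_crc, t))
        na, nc = len(aa_to_crc), len(crc_m_terms)
        inputs = RiskInputs(
            na=na, nc=nc,
            aa_r=float(np.mean(aa_r_terms)) if aa_r_terms else 0.0,
            aa_to_crc=np.asarray(aa_to_crc),
            crc_m=float(np.mean(crc_m_terms)) if crc_m_terms else 0.0)
        rows.append({"group": name, "n": len(members),
                     "five_year_risk": crc_5yr_risk(inputs)})
    return pd.DataFrame(rows)
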