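"""Lifestyle phenotype coding and derivation.

Smoking status is coded 0 = never, 1 = former, 2 = current. Pack years is
cigarettes smoked per day times years smoked, divided by 20 cigarettes per
pack; never-smokers are recorded as 0 regardless of other fields.

NOTE on the pack-years formula: read literally, "packs per day ... divided
by 20" would divide twice; the parenthetical "(cigarettes per pack)" shows
the intended computation, which is the standard cigarettes-based one
implemented here: cigarettes/day x years / 20.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NEVER, FORMER, CURRENT = 0, 1, 2

#: Group-mean starting age used when a smoker's starting age is unrecorded.
DEFAULT_MEAN_START_AGE = 16.0


@dataclass
class PhenotypeRecord:
    """Per-individual lifestyle and clinical fields. ``None`` marks missing.

    ``age_stopped_or_current`` is the age smoking stopped for former
    smokers, or the age at assessment for current smokers.
    """

    individual_id: str
    smoking_status: int = NEVER
    cigarettes_per_day: float | None = None
    age_started_smoking: float | None = None
    age_stopped_or_current: float | None = None
    alcohol_units_week: float | None = None
    bmi: float | None = None
    hdl: float | None = None

    def __post_init__(self) -> None:
        if self.smoking_status not in (NEVER, FORMER, CURRENT):
            raise ValueError(f"smoking_status must be 0/1/2, got {self.smoking_status}")
        for name in ("cigarettes_per_day", "age_started_smoking", "age_stopped_or_current",
                     "alcohol_units_week", "bmi", "hdl"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} negative: {v}")


def derive_pack_years(rec: PhenotypeRecord, cohort_mean_start_age: float = DEFAULT_MEAN_START_AGE) -> float | None:
    """Pack years = cigarettes/day x years smoked / 20.

    Rules applied, in order:

    * never-smoker -> 0.0, regardless of the other fields;
    * missing cigarettes/day -> missing (such individuals are excluded
      from pack-years analyses);
    * missing starting age -> imputed with ``cohort_mean_start_age``;
    * missing stop/current age -> missing (no imputation).
    """
    if cohort_mean_start_age < 0:
        raise ValueError("cohort_mean_start_age negative")
    if rec.smoking_status == NEVER:
        return 0.0
    if rec.cigarettes_per_day is None:
        return None
    start = rec.age_started_smoking if rec.age_started_smoking is not None else cohort_mean_start_age
    end = rec.age_stopped_or_current
    if end is None:
        return None
    years = end - start
    if years < 0:
        raise ValueError(f"{rec.individual_id}: smoking stop age {end} precedes start age {start}")
    return rec.cigarettes_per_day * years / 20.0


def records_to_table(
    records: list[PhenotypeRecord],
    cohort_mean_start_age: float | None = None,
) -> pd.DataFrame:
    """Build a tidy phenotype table with derived pack years.

    If ``cohort_mean_start_age`` is None it is computed as the mean of the
    recorded starting ages among ever-smokers (falling back to the default
    of 16 if none are recorded). The number of ever-smokers excluded from
    pack years for lack of cigarettes/day information is logged.
    """
    if not records:
        raise ValueError("no phenotype records")
    if cohort_mean_start_age is None:
        starts = [r.age_started_smoking for r in records
                  if r.smoking_status != NEVER and r.age_started_smoking is not None]
        cohort_mean_start_age = float(np.mean(starts)) if starts else DEFAULT_MEAN_START_AGE

    rows = []
    n_excluded = 0
    for r in records:
        py = derive_pack_years(r, cohort_mean_start_age)
        if py is None and r.smoking_status != NEVER:
            n_excluded += 1
        rows.append(
            {
                "individual_id": r.individual_id,
                "smoking_status": r.smoking_status,
                "cigarettes_per_day": r.cigarettes_per_day,
                "age_started_smoking": r.age_started_smoking,
                "age_stopped_or_current": r.age_stopped_or_current,
                "pack_years": py,
                "alcohol_units_week": r.alcohol_units_week,
                "bmi": r.bmi,
                "hdl": r.hdl,
            }
        )
    if n_excluded:
        logger.info("%d ever-smoker(s) excluded from pack years (no cigarettes/day information)", n_excluded)
    return pd.DataFrame(rows)


def summarize_cohort(records: list[PhenotypeRecord]) -> pd.DataFrame:
    """Cohort summary: n(%) for categorical fields, mean (SD) and unknown
    counts for continuous ones. SD is missing when n = 1."""
    if not records:
        raise ValueError("no phenotype records")
    table = records_to_table(records)
    n = len(table)
    rows: list[dict] = []

    status_names = {NEVER: "never", FORMER: "former", CURRENT: "current"}
    counts = table["smoking_status"].value_counts()
    for code in (CURRENT, FORMER, NEVER):
        k = int(counts.get(code, 0))
        rows.append({"field": "smoking_status", "level": status_names[code],
                     "n": k, "pct": 100.0 * k / n, "mean": math.nan, "sd": math.nan, "n_unknown": 0})

    for col in ("pack_years", "alcohol_units_week", "bmi", "hdl"):
        vals = table[col].astype(float)
        known = vals.dropna()
        sd = float(known.std(ddof=1)) if len(known) > 1 else math.nan
        rows.append({"field": col, "level": "", "n": len(known),
                     "pct": math.nan,
                     "mean": float(known.mean()) if len(known) else math.nan,
                     "sd": sd, "n_unknown": int(vals.isna().sum())})
    return pd.DataFrame(rows)
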