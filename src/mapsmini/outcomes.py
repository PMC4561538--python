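"""Self-report physical-activity outcomes and the analysis table.

Each age group reports activity on an age-appropriate instrument, so the
outcome columns are assembled per group:

===========  ==========================================  =============================  ======================
age group    active transport                            leisure / neighborhood PA      accelerometer MVPA
===========  ==========================================  =============================  ======================
child        mean of 9 walk/bike destination items 0-5   mean of 5 nearby-place items   in-neighborhood MVPA
adolescent   mean of 9 walk/bike destination items 0-5   mean of 5 nearby-place items   non-school MVPA
adult        GPAQ transport days/week (0-7)              GPAQ leisure minutes/day       (not worn)
older_adult  CHAMPS walk/bike errands, times/week        CHAMPS leisure walk minutes    total MVPA
===========  ==========================================  =============================  ======================

Ordinal 0-5 frequency responses are analyzed as numeric means, a documented
limitation of the instrument rather than of this implementation.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .accelerometry import AgeGroup

__all__ = [
    "mean_destination_frequency",
    "mean_neighborhood_place_frequency",
    "validate_open_frequency",
    "score_survey",
    "assemble_analysis_table",
    "model_ready_view",
    "COVARIATE_COLUMNS",
    "DEST_FREQ_COLUMNS",
    "PLACE_FREQ_COLUMNS",
]

log = logging.getLogger(__name__)

DEST_FREQ_COLUMNS = [f"dest_freq_{i}" for i in range(1, 10)]
PLACE_FREQ_COLUMNS = [f"place_freq_{i}" for i in range(1, 6)]
COVARIATE_COLUMNS = ["age", "sex", "education_college", "nonwhite",
                     "walkability_high", "mobility_impairment"]


def _mean_ordinal(responses: Sequence[float], n_expected: int, lo: int, hi: int) -> float:
    responses = list(responses)
    if len(responses) != n_expected:
        raise ValueError(f"expected {n_expected} responses, got {len(responses)}")
    arr = np.asarray(responses, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("responses contain missing values")
    if ((arr < lo) | (arr > hi)).any():
        raise ValueError(f"responses outside [{lo}, {hi}]: {responses}")
    return float(arr.mean())


def mean_destination_frequency(responses: Sequence[float]) -> float:
    """Mean of the 9 walk/bike-to-destination frequency items
    (0 = never ... 5 = four or more times a week)."""
    return _mean_ordinal(responses, 9, 0, 5)


def mean_neighborhood_place_frequency(responses: Sequence[float]) -> float:
    """Mean of the 5 active-near-home place frequency items (0-5 scale)."""
    return _mean_ordinal(responses, 5, 0, 5)


def validate_open_frequency(value: float, cap: Optional[float] = None) -> float:
    """Clean an open-ended times-per-week report: non-negative and finite,
    optionally winsorized at ``cap`` (no cap by default)."""
    v = float(value)
    if not np.isfinite(v) or v < 0:
        raise ValueError(f"open-ended frequency must be a non-negative number, got {value!r}")
    if cap is not None and v > cap:
        return float(cap)
    return v


def score_survey(survey: pd.DataFrame) -> pd.DataFrame:
    """Derive ``transport`` and ``leisure`` outcome columns from raw survey
    responses, per age group's instrument.  Rows whose group's instrument
    fields are missing get missing outcomes."""
    required = {"participant_id", "age_group"}
    missing = required - set(survey.columns)
    if missing:
        raise ValueError(f"survey table missing column(s) {sorted(missing)}")
    df = survey.copy()
    group = df["age_group"].astype(str)
    transport = pd.Series(np.nan, index=df.index, dtype=float)
    leisure = pd.Series(np.nan, index=df.index, dtype=float)

    youth = group.isin([AgeGroup.CHILD.value, AgeGroup.ADOLESCENT.value])
    if youth.any():
        if set(DEST_FREQ_COLUMNS) <= set(df.columns):
            transport[youth] = df.loc[youth, DEST_FREQ_COLUMNS].mean(axis=1, skipna=False)
        if set(PLACE_FREQ_COLUMNS) <= set(df.columns):
            leisure[youth] = df.loc[youth, PLACE_FREQ_COLUMNS].mean(axis=1, skipna=False)

    adult = group == AgeGroup.ADULT.value
    if adult.any():
        if "gpaq_transport_days" in df.columns:
            transport[adult] = df.loc[adult, "gpaq_transport_days"]
        if "gpaq_leisure_minutes" in df.columns:
            leisure[adult] = df.loc[adult, "gpaq_leisure_minutes"]

    older = group == AgeGroup.OLDER_ADULT.value
    if older.any():
        if "champs_walk_bike_per_week" in df.columns:
            transport[older] = df.loc[older, "champs_walk_bike_per_week"]
        if "champs_leisure_walk_minutes" in df.columns:
            leisure[older] = df.loc[older, "champs_leisure_walk_minutes"]

    neg = transport < 0
    if neg.any():
        raise ValueError(
            f"negative transport frequency for participant(s) "
            f"{df.loc[neg, 'participant_id'].tolist()}")
    out = df[["participant_id", "age_group"]].copy()
    out["transport"] = transport
    out["leisure"] = leisure
    return out


#: Which accelerometer summary serves as each group's MVPA outcome.
MVPA_COLUMN_BY_GROUP = {
    AgeGroup.CHILD.value: "mvpa_neighborhood",
    AgeGroup.ADOLESCENT.value: "mvpa_nonschool",
    AgeGroup.ADULT.value: None,  # parents did not wear accelerometers
    AgeGroup.OLDER_ADULT.value: "mvpa_total",
}


def assemble_analysis_table(
    scores: pd.DataFrame,
    survey: pd.DataFrame,
    covariates: pd.DataFrame,
    accel: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Join scores, survey outcomes, covariates, and accelerometer summaries
    into one analysis row per scored participant.

    ``scores`` is the participant-score table (must carry
    ``percent_of_max``); ``survey`` is either raw (scored here) or already
    carries ``transport``/``leisure``; ``accel`` carries
    ``mvpa_total`` / ``mvpa_nonschool`` / ``mvpa_neighborhood`` columns.
    Accelerometer rows without a matching score are logged and dropped;
    score rows without accelerometer data keep a missing MVPA outcome.
    """
    for name, df in (("scores", scores), ("survey", survey), ("covariates", covariates)):
        if df["participant_id"].duplicated().any():
            dups = df.loc[df["participant_id"].duplicated(), "participant_id"].tolist()
            raise ValueError(f"duplicate participant_id(s) in {name}: {dups[:5]}")

    if "transport" not in survey.columns:
        survey = score_survey(survey)
    else:
        survey = survey[["participant_id", "age_group", "transport", "leisure"]]

    table = scores.merge(survey, on="participant_id", how="left", validate="1:1")
    table = table.merge(covariates.drop(columns=["age_group"], errors="ignore"),
                        on="participant_id", how="left", validate="1:1")

    mvpa = pd.Series(np.nan, index=table.index, dtype=float)
    if accel is not None and len(accel):
        unmatched = set(accel["participant_id"]) - set(table["participant_id"])
        if unmatched:
            log.warning("%d accelerometer participant(s) without audit scores "
                        "ignored: %s ...", len(unmatched), sorted(unmatched)[:5])
        acc = table[["participant_id", "age_group"]].merge(
            accel, on="participant_id", how="left", validate="1:1")
        for grp, col in MVPA_COLUMN_BY_GROUP.items():
            if col is None or col not in acc.columns:
                continue
            sel = (acc["age_group"] == grp).to_numpy()
            mvpa[sel] = acc.loc[sel, col].to_numpy()
    table["mvpa"] = mvpa

    covs = [c for c in COVARIATE_COLUMNS if c != "mobility_impairment"]
    present = [c for c in covs if c in table.columns]
    complete = table[present].notna().all(axis=1) if present else pd.Series(False, index=table.index)
    older = table["age_group"] == AgeGroup.OLDER_ADULT.value
    if "mobility_impairment" in table.columns:
        complete &= ~older | table["mobility_impairment"].notna()
    else:
        complete &= ~older
    table["complete_covariates"] = complete

    required = {"block_group_id", "walkability_high"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"analysis table missing required column(s) {sorted(missing)}")
    return table


def model_ready_view(table: pd.DataFrame) -> pd.DataFrame:
    """Rows with complete covariates (listwise deletion happens per model
    on the outcome and predictor; covariate-incomplete rows are excluded
    here but retained in the full table)."""
    return table[table["complete_covariates"]].copy()
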