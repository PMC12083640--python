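"""Per-patient, visit-deduplicated feature counts under the pediatric age
window.

A patient's record is reduced to encounter-level *feature events* in five
categories — asthma diagnosis code (DX), inhaled bronchodilator order (BDR),
inhaled corticosteroid order (ICS), asthma-specific note keyword (KW1) and
nonspecific respiratory note keyword (KW2).  Each encounter contributes at
most one event per category, so category counts are counts of qualifying
*visits*, not of raw mentions.

The age window is [2, 18) years, with a carryover: events at ages [1, 2)
are retained only for patients who also have at least one event (of any
category) at ages [2, 18).  Ages are exact day counts divided by 365.25.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ehr_model import Cohort
from .lexicons import KeywordMention, Lexicons, default_lexicons

CATEGORIES = ("DX", "BDR", "ICS", "KW1", "KW2")

COUNT_COLUMNS = ["n_dx", "n_bdr", "n_ics", "n_kw1", "n_kw2"]
COUNTS_SCHEMA = ["patient_id"] + COUNT_COLUMNS + ["age_first_event"]

DAYS_PER_YEAR = 365.25

AGE_MIN_CARRYOVER = 1.0   # lower edge of the carryover band [1, 2)
AGE_MIN_MAIN = 2.0        # lower edge of the main pediatric band [2, 18)
AGE_MAX = 18.0


@dataclass(frozen=True)
class FeatureEvent:
    """One encounter-level feature occurrence."""

    patient_id: str
    encounter_id: str
    category: str
    event_date: date
    age_years: float


def extract_keyword_mentions(text: str, lexicons: Lexicons | None = None) -> list[KeywordMention]:
    """All kw1/kw2 keyword hits in a note, in left-to-right span order.

    Overlapping kw1 and kw2 matches are both reported (e.g. the kw1 phrase
    "exercise-induced wheezing" also yields a kw2 "wheezing" hit).
    """
    lex = lexicons if lexicons is not None else default_lexicons()
    mentions = lex.kw1.find_mentions(text) + lex.kw2.find_mentions(text)
    mentions.sort(key=lambda m: (m.span, m.category, m.term))
    return mentions


def build_feature_events(cohort: Cohort, lexicons: Lexicons | None = None) -> list[FeatureEvent]:
    """Reduce a cohort to encounter-level feature events.

    Visit-level deduplication happens here: an encounter with three asthma
    codes yields one DX event; an encounter whose notes mention "wheezing"
    twice yields one KW2 event.
    """
    lex = lexicons if lexicons is not None else default_lexicons()
    enc = cohort.encounters.merge(
        cohort.patients[["patient_id", "birth_date"]], on="patient_id", how="left"
    )
    if len(enc):
        age = (enc["date"] - enc["birth_date"]).dt.days / DAYS_PER_YEAR
    else:
        age = pd.Series(dtype=float)
    enc_info = pd.DataFrame(
        {
            "patient_id": enc["patient_id"].astype(str),
            "encounter_id": enc["encounter_id"].astype(str),
            "date": enc["date"],
            "age_years": age,
        }
    ).set_index("encounter_id")

    per_category: dict[str, set[str]] = {c: set() for c in CATEGORIES}

    dx = cohort.diagnoses
    for _, row in dx.iterrows():
        if lex.dx.match(row["code_system"], row["code"]):
            per_category["DX"].add(str(row["encounter_id"]))

    for _, row in cohort.medications.iterrows():
        text = str(row["drug_text"])
        if lex.ics.matches(text):
            per_category["ICS"].add(str(row["encounter_id"]))
        elif lex.bdr.matches(text):
            per_category["BDR"].add(str(row["encounter_id"]))

    for _, row in cohort.notes.iterrows():
        text = str(row["text"])
        eid = str(row["encounter_id"])
        if lex.kw1.find_mentions(text):
            per_category["KW1"].add(eid)
        if lex.kw2.find_mentions(text):
            per_category["KW2"].add(eid)

    events = [
        FeatureEvent(
            patient_id=enc_info.at[eid, "patient_id"],
            encounter_id=eid,
            category=category,
            event_date=enc_info.at[eid, "date"].date(),
            age_years=float(enc_info.at[eid, "age_years"]),
        )
        for category in CATEGORIES
        for eid in per_category[category]
        if eid in enc_info.index
    ]
    events.sort(key=lambda e: (e.patient_id, e.event_date, e.encounter_id, e.category))
    return events


def apply_age_window(events: Sequence[FeatureEvent], patient=None) -> list[FeatureEvent]:
    """Apply the pediatric age window with the 1–2-year carryover.

    Events outside [1, 18) are dropped.  Events in [2, 18) are always kept.
    Events in [1, 2) are kept iff the same patient has at least one event of
    *any* category in [2, 18).  Idempotent.  The optional ``patient``
    argument is accepted for symmetry but unused: events carry their own
    patient id and age.
    """
    unlocked = {
        e.patient_id for e in events if AGE_MIN_MAIN <= e.age_years < AGE_MAX
    }
    kept = []
    for e in events:
        if AGE_MIN_MAIN <= e.age_years < AGE_MAX:
            kept.append(e)
        elif AGE_MIN_CARRYOVER <= e.age_years < AGE_MIN_MAIN and e.patient_id in unlocked:
            kept.append(e)
    return kept


def restrict_to_age_range(
    events: Sequence[FeatureEvent], lo_years: float, hi_years: float
) -> list[FeatureEvent]:
    """Keep events with lo <= age < hi.  The carryover rule is NOT re-applied;
    the window is literal (used for age-subgroup analyses)."""
    if not lo_years < hi_years:
        raise ValueError(f"invalid age range [{lo_years}, {hi_years})")
    return [e for e in events if lo_years <= e.age_years < hi_years]


def count_features(
    events: Sequence[FeatureEvent], patient_ids: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-patient category counts and age at first event.

    Events must already be age-filtered.  ``patient_ids``, when given, fixes
    the output population: patients without events get all-zero rows (and a
    null ``age_first_event``).  Output is sorted by patient_id.
    """
    ids = set(patient_ids) if patient_ids is not None else {e.patient_id for e in events}
    rows = {
        pid: {"patient_id": pid, **{c: 0 for c in COUNT_COLUMNS}, "age_first_event": np.nan}
        for pid in ids
    }
    col_for = {c: f"n_{c.lower()}" for c in CATEGORIES}
    for e in events:
        row = rows.setdefault(
            e.patient_id,
            {"patient_id": e.patient_id, **{c: 0 for c in COUNT_COLUMNS}, "age_first_event": np.nan},
        )
        row[col_for[e.category]] += 1
        if np.isnan(row["age_first_event"]) or e.age_years < row["age_first_event"]:
            row["age_first_event"] = e.age_years
    df = pd.DataFrame(list(rows.values()), columns=COUNTS_SCHEMA)
    for c in COUNT_COLUMNS:
        df[c] = df[c].astype(int)
    return df.sort_values("patient_id", kind="mergesort").reset_index(drop=True)


def extract_feature_counts(
    cohort: Cohort,
    lexicons: Lexicons | None = None,
    age_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Cohort -> feature-count table, the standard end-to-end path.

    Builds events, applies the age window (with carryover), optionally
    restricts to a literal age sub-range, and counts.  Every patient in the
    cohort appears in the output, zero-filled if featureless.
    """
    events = apply_age_window(build_feature_events(cohort, lexicons))
    if age_range is not None:
        events = restrict_to_age_range(events, *age_range)
    return count_features(events, patient_ids=cohort.patients["patient_id"].astype(str))
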