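"""Shared fixtures: hand-built micro-cohorts and a small synthetic cohort."""

from __future__ import annotations

import re

import pandas as pd
import pytest

from compac import SyntheticConfig, extract_feature_counts, generate_cohort
from compac.ehr_model import TABLE_COLUMNS, Cohort, _empty_table


def make_cohort(
    patients=(),
    encounters=(),
    diagnoses=(),
    medications=(),
    notes=(),
    labels=None,
) -> Cohort:
    """Build a Cohort from plain tuples.

    patients: (patient_id, birth_date, sex, race)
    encounters: (encounter_id, patient_id, date)
    diagnoses: (encounter_id, code_system, code)
    medications: (encounter_id, drug_text)
    notes: (note_id, encounter_id, text)
    labels: (patient_id, reviewer_id, label) or None
    """

    def frame(rows, name):
        if not rows:
            return _empty_table(name)
        df = pd.DataFrame(list(rows), columns=TABLE_COLUMNS[name])
        for col in ("birth_date", "date"):
            if col in df.columns:
                df[col] = pd.to_datetime(df[col])
        return df

    return Cohort(
        patients=frame(patients, "patients"),
        encounters=frame(encounters, "encounters"),
        diagnoses=frame(diagnoses, "diagnoses"),
        medications=frame(medications, "medications"),
        notes=frame(notes, "notes"),
        labels=frame(labels, "labels") if labels is not None else None,
    )


def eval_rule_textually(text: str, counts: dict) -> bool:
    """Independent oracle: translate rule text to a Python boolean expression
    and evaluate it, relying on Python's own operator precedence (``and``
    over ``or``) instead of the package's parser/evaluator."""
    expr = text.replace("∣", "|").replace("≥", ">=")
    expr = re.sub(
        r"([A-Za-z]\w*)\s*(>=|=)\s*(\d+)",
        lambda m: "(c[%r] %s %s)" % (
            {"ib": "bdr"}.get(m.group(1).lower(), m.group(1).lower()),
            ">=" if m.group(2) == ">=" else "==",
            m.group(3),
        ),
        expr,
    )
    expr = expr.replace("&", " and ").replace("|", " or ")
    return bool(eval(expr, {"__builtins__": {}}, {"c": counts}))


@pytest.fixture(scope="session")
def small_synth():
    """A small generated cohort with truth table and extracted counts."""
    config = SyntheticConfig(n_patients=400, seed=11)
    cohort, truth = generate_cohort(config)
    counts = extract_feature_counts(cohort)
    return config, cohort, truth, counts
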