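"""Tabular EHR data model: patients, encounters, diagnoses, medications,
notes and chart-review labels, with CSV readers/writers and referential
validation.

A :class:`Cohort` bundles the five linked tables (plus an optional labels
table) as pandas DataFrames with fixed column schemas.  Files are plain
CSV, UTF-8, header row required, ISO-8601 dates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

SEX_VALUES = frozenset({"Female", "Male", "Unknown"})
RACE_VALUES = frozenset({"NHW", "NHB", "Hispanic", "Other", "Unknown"})
CODE_SYSTEMS = frozenset({"ICD9CM", "ICD10CM"})
LABEL_VALUES = frozenset({"asthma", "not_asthma"})

#: reviewer_id whose row, when present, overrides disagreeing reviewers
ADJUDICATOR_ID = "adjudicated"

TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "birth_date", "sex", "race_ethnicity"],
    "encounters": ["encounter_id", "patient_id", "date"],
    "diagnoses": ["encounter_id", "code_system", "code"],
    "medications": ["encounter_id", "drug_text"],
    "notes": ["note_id", "encounter_id", "text"],
    "labels": ["patient_id", "reviewer_id", "label"],
}

TABLE_KEYS: dict[str, list[str]] = {
    "patients": ["patient_id"],
    "encounters": ["encounter_id"],
    "diagnoses": ["encounter_id", "code_system", "code"],
    "medications": ["encounter_id", "drug_text"],
    "notes": ["note_id"],
    "labels": ["patient_id", "reviewer_id"],
}

_DATE_COLUMNS = {"patients": "birth_date", "encounters": "date"}


class CohortError(ValueError):
    """Raised on structurally invalid cohort files or tables."""


class Violation(NamedTuple):
    """One invariant violation found by :func:`validate_cohort`."""

    table: str
    key: str
    rule: str
    message: str


def _empty_table(name: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in TABLE_COLUMNS[name]})
    date_col = _DATE_COLUMNS.get(name)
    if date_col:
        df[date_col] = pd.Series(dtype="datetime64[ns]")
    return df


@dataclass
class Cohort:
    """The five linked EHR tables plus an optional chart-review label table."""

    patients: pd.DataFrame = field(default_factory=lambda: _empty_table("patients"))
    encounters: pd.DataFrame = field(default_factory=lambda: _empty_table("encounters"))
    diagnoses: pd.DataFrame = field(default_factory=lambda: _empty_table("diagnoses"))
    medications: pd.DataFrame = field(default_factory=lambda: _empty_table("medications"))
    notes: pd.DataFrame = field(default_factory=lambda: _empty_table("notes"))
    labels: pd.DataFrame | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        out = {
            "patients": self.patients,
            "encounters": self.encounters,
            "diagnoses": self.diagnoses,
            "medications": self.medications,
            "notes": self.notes,
        }
        if self.labels is not None:
            out["labels"] = self.labels
        return out

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.patients["patient_id"].astype(str))

    def equals(self, other: "Cohort") -> bool:
        """Table-wise equality after primary-key sorting."""
        mine, theirs = self.tables(), other.tables()
        if set(mine) != set(theirs):
            return False
        for name, df in mine.items():
            a = _sorted_table(name, df).reset_index(drop=True)
            b = _sorted_table(name, theirs[name]).reset_index(drop=True)
            if not a.equals(b):
                return False
        return True


def _sorted_table(name: str, df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(TABLE_KEYS[name], kind="mergesort")[TABLE_COLUMNS[name]]


def _read_table(name: str, path: Path) -> pd.DataFrame:
    if not Path(path).exists():
        raise CohortError(f"missing file for table '{name}': {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = TABLE_COLUMNS[name]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortError(f"{name}: missing column(s) {missing} in {path}")
    date_col = _DATE_COLUMNS.get(name)
    if date_col:
        try:
            df[date_col] = pd.to_datetime(df[date_col], format="%Y-%m-%d")
        except (ValueError, TypeError) as exc:
            raise CohortError(f"{name}: unparseable date in column '{date_col}': {exc}") from exc
    return df


def read_cohort(paths: Mapping[str, str | Path]) -> Cohort:
    """Read and validate a cohort from per-table CSV paths.

    ``paths`` maps table names (``patients``, ``encounters``, ``diagnoses``,
    ``medications``, ``notes``, optionally ``labels``) to file paths.  The
    five core tables are required.  Any invariant violation is fatal.
    """
    required = [t for t in TABLE_COLUMNS if t != "labels"]
    missing = [t for t in required if t not in paths]
    if missing:
        raise CohortError(f"missing table path(s): {missing}")
    frames = {name: _read_table(name, Path(p)) for name, p in paths.items()}
    cohort = Cohort(
        patients=frames["patients"],
        encounters=frames["encounters"],
        diagnoses=frames["diagnoses"],
        medications=frames["medications"],
        notes=frames["notes"],
        labels=frames.get("labels"),
    )
    violations = validate_cohort(cohort)
    if violations:
        head = "; ".join(f"{v.table}[{v.key}]: {v.message}" for v in violations[:5])
        raise CohortError(f"{len(violations)} cohort violation(s): {head}")
    return cohort


def read_cohort_dir(data_dir: str | Path) -> Cohort:
    """Read a cohort from a directory holding the standard file names."""
    data_dir = Path(data_dir)
    paths: dict[str, Path] = {
        name: data_dir / f"{name}.csv" for name in TABLE_COLUMNS if name != "labels"
    }
    labels_path = data_dir / "labels.csv"
    if labels_path.exists():
        paths["labels"] = labels_path
    return read_cohort(paths)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort to ``<out_dir>/<table>.csv``, sorted by primary key.

    Output is byte-stable: writing the same cohort twice yields identical
    files.  Returns the mapping table name -> written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in cohort.tables().items():
        df = _sorted_table(name, df).copy()
        date_col = _DATE_COLUMNS.get(name)
        if date_col:
            df[date_col] = pd.to_datetime(df[date_col]).dt.strftime("%Y-%m-%d")
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    return written


def _dup_keys(df: pd.DataFrame, cols: list[str]) -> Iterable[str]:
    dup = df.duplicated(subset=cols, keep=False)
    if dup.any():
        seen = df.loc[dup, cols].astype(str).agg("/".join, axis=1)
        yield from sorted(set(seen))


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """Check all cohort invariants; violations are returned, never raised."""
    v: list[Violation] = []
    pat, enc = cohort.patients, cohort.encounters

    for key in _dup_keys(pat, ["patient_id"]):
        v.append(Violation("patients", key, "unique_patient_id", f"duplicate patient_id {key!r}"))
    bad_sex = ~pat["sex"].isin(SEX_VALUES)
    for _, row in pat[bad_sex].iterrows():
        v.append(Violation("patients", row["patient_id"], "sex_enum", f"invalid sex {row['sex']!r}"))
    bad_race = ~pat["race_ethnicity"].isin(RACE_VALUES)
    for _, row in pat[bad_race].iterrows():
        v.append(
            Violation(
                "patients", row["patient_id"], "race_enum",
                f"invalid race_ethnicity {row['race_ethnicity']!r}",
            )
        )

    known_patients = set(pat["patient_id"])
    for key in _dup_keys(enc, ["encounter_id"]):
        v.append(Violation("encounters", key, "unique_encounter_id", f"duplicate encounter_id {key!r}"))
    unresolved = ~enc["patient_id"].isin(known_patients)
    for _, row in enc[unresolved].iterrows():
        v.append(
            Violation(
                "encounters", row["encounter_id"], "patient_fk",
                f"unknown patient_id {row['patient_id']!r}",
            )
        )
    if len(enc) and len(pat):
        merged = enc.merge(pat[["patient_id", "birth_date"]], on="patient_id", how="inner")
        before = merged["date"] < merged["birth_date"]
        for _, row in merged[before].iterrows():
            v.append(
                Violation(
                    "encounters", row["encounter_id"], "date_after_birth",
                    f"encounter date {row['date'].date()} precedes birth {row['birth_date'].date()}",
                )
            )

    known_encounters = set(enc["encounter_id"])
    for table_name, df in (("diagnoses", cohort.diagnoses), ("medications", cohort.medications)):
        unresolved = ~df["encounter_id"].isin(known_encounters)
        for _, row in df[unresolved].iterrows():
            v.append(
                Violation(
                    table_name, row["encounter_id"], "encounter_fk",
                    f"unknown encounter_id {row['encounter_id']!r}",
                )
            )
    bad_sys = ~cohort.diagnoses["code_system"].isin(CODE_SYSTEMS)
    for _, row in cohort.diagnoses[bad_sys].iterrows():
        v.append(
            Violation(
                "diagnoses", row["encounter_id"], "code_system_enum",
                f"invalid code_system {row['code_system']!r}",
            )
        )
    empty_code = cohort.diagnoses["code"].astype(str).str.strip() == ""
    for _, row in cohort.diagnoses[empty_code].iterrows():
        v.append(Violation("diagnoses", row["encounter_id"], "code_nonempty", "empty diagnosis code"))

    for key in _dup_keys(cohort.notes, ["note_id"]):
        v.append(Violation("notes", key, "unique_note_id", f"duplicate note_id {key!r}"))
    unresolved = ~cohort.notes["encounter_id"].isin(known_encounters)
    for _, row in cohort.notes[unresolved].iterrows():
        v.append(
            Violation(
                "notes", row["note_id"], "encounter_fk",
                f"unknown encounter_id {row['encounter_id']!r}",
            )
        )

    if cohort.labels is not None:
        lab = cohort.labels
        unresolved = ~lab["patient_id"].isin(known_patients)
        for _, row in lab[unresolved].iterrows():
            v.append(
                Violation(
                    "labels", row["patient_id"], "patient_fk",
                    f"unknown patient_id {row['patient_id']!r}",
                )
            )
        bad_label = ~lab["label"].isin(LABEL_VALUES)
        for _, row in lab[bad_label].iterrows():
            v.append(
                Violation("labels", row["patient_id"], "label_enum", f"invalid label {row['label']!r}")
            )
        for key in _dup_keys(lab, ["patient_id", "reviewer_id"]):
            v.append(
                Violation(
                    "labels", key, "one_label_per_reviewer",
                    f"multiple labels for patient/reviewer {key!r}",
                )
            )
    return v


def consensus_labels(labels: pd.DataFrame) -> dict[str, str]:
    """Derive one adjudicated label per patient from per-reviewer rows.

    A row by reviewer ``"adjudicated"`` wins outright.  Otherwise the
    reviewers' labels must all agree; patients whose reviewers disagree
    without adjudication are excluded from the result (and hence from any
    downstream evaluation).
    """
    out: dict[str, str] = {}
    for patient_id, grp in labels.groupby("patient_id"):
        adj = grp[grp["reviewer_id"] == ADJUDICATOR_ID]
        if len(adj):
            out[str(patient_id)] = adj["label"].iloc[0]
            continue
        values = set(grp["label"])
        if len(values) == 1:
            out[str(patient_id)] = values.pop()
    return out


def label_disagreements(labels: pd.DataFrame) -> list[str]:
    """Patients whose reviewers disagree and that lack an adjudicated row."""
    return sorted(
        str(pid)
        for pid, grp in labels.groupby("patient_id")
        if ADJUDICATOR_ID not in set(grp["reviewer_id"]) and len(set(grp["label"])) > 1
    )


def filter_notes_by_type(cohort: Cohort, include_regex: str) -> Cohort:
    """Restrict the notes table to rows whose ``note_type`` matches a regex.

    Note files carry no type column by default; extracts that do include one
    (e.g. progress notes vs discharge summaries) can be narrowed here.  A
    cohort without a ``note_type`` column is returned unchanged with a
    warning.
    """
    if "note_type" not in cohort.notes.columns:
        warnings.warn("notes table has no 'note_type' column; filter not applied")
        return cohort
    keep = cohort.notes["note_type"].astype(str).str.contains(include_regex, regex=True)
    return Cohort(
        patients=cohort.patients,
        encounters=cohort.encounters,
        diagnoses=cohort.diagnoses,
        medications=cohort.medications,
        notes=cohort.notes[keep].reset_index(drop=True),
        labels=cohort.labels,
    )
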