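"""Phenotype performance evaluation against chart-review labels.

Point and stratified-bootstrap sensitivity / PPV / specificity / F1, base-
rule-pattern confirmation rates, demographic subgroup analysis in two
encounter-window modes, cohort characterization, and inter-annotator
agreement.

The bootstrap follows the 20+20 stratified scheme: per iteration, draw
``n_pos`` labeled patients with replacement from the phenotype-identified
stratum and ``n_neg`` from the remaining labeled patients, compute the
metrics on that sample, and summarize over (by default) 10,000 iterations
with percentile 95% intervals.  F1 is computed per iteration, not from the
mean sensitivity and PPV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ehr_model import Cohort, consensus_labels
from .feature_extraction import (
    apply_age_window,
    build_feature_events,
    count_features,
    restrict_to_age_range,
)
from .lexicons import Lexicons
from .rule_engine import (
    BasePattern,
    IDENTIFIED,
    PhenotypeRule,
    apply_phenotype,
    stratify_by_pattern,
)

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "ppv", "specificity", "f1")

AGE_BINS: tuple[tuple[float, float], ...] = ((2.0, 6.0), (6.0, 13.0), (13.0, 18.0))
AGE_BIN_LABELS = ("2-5", "6-12", "13-18")

ALL_ENCOUNTERS = "ALL_ENCOUNTERS"
WITHIN_GROUP = "WITHIN_GROUP"


def round_half_up(x: float, digits: int) -> float:
    """Decimal round-half-up (display convention for metrics/percentages)."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts; ``n_excluded`` tallies labeled-but-unresolved
    patients (reviewer disagreement without adjudication)."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
            self.n_excluded + other.n_excluded,
        )


@dataclass(frozen=True)
class MetricSummary:
    """One metric: point value plus bootstrap mean and percentile 95% CI.

    ``point`` is computed on the full labeled set; any field is None when
    its ratio is undefined (0/0).  ``n_dropped`` counts bootstrap iterations
    where this metric was undefined and therefore excluded from mean/CI.
    """

    point: float | None
    boot_mean: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_dropped: int = 0


@dataclass
class EvaluationResult:
    """Full evaluation of one phenotype against consensus labels."""

    rule_text: str
    confusion: ConfusionCounts
    metrics: dict[str, MetricSummary]
    n_boot: int = 0
    seed: int | None = None
    n_labeled: int = 0

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "metric": name,
                "point": m.point,
                "boot_mean": m.boot_mean,
                "ci_low": m.ci_low,
                "ci_high": m.ci_high,
            }
            for name, m in self.metrics.items()
        ]
        return pd.DataFrame(rows)


def _as_label_map(labels) -> dict[str, str]:
    if isinstance(labels, pd.DataFrame):
        return consensus_labels(labels)
    return {str(k): v for k, v in dict(labels).items()}


def confusion(
    identified: Iterable[str],
    labels,
    evaluated: Iterable[str] | None = None,
) -> ConfusionCounts:
    """Confusion counts of an identified set against consensus labels.

    ``labels`` is a per-reviewer label DataFrame (consensus is derived,
    disagreements excluded and tallied) or an already-adjudicated mapping
    patient -> "asthma"/"not_asthma".  ``evaluated`` optionally restricts
    the evaluated population; by default every consensus-labeled patient is
    evaluated.
    """
    if isinstance(labels, pd.DataFrame):
        if not len(labels):
            raise ValueError("empty label set")
        all_labeled = set(labels["patient_id"].astype(str))
    else:
        if not labels:
            raise ValueError("empty label set")
        all_labeled = {str(k) for k in dict(labels)}
    label_map = _as_label_map(labels)
    pop = set(map(str, evaluated)) if evaluated is not None else all_labeled
    excluded = pop & all_labeled - set(label_map)
    ident = set(map(str, identified))
    tp = fp = fn = tn = 0
    for pid in pop & set(label_map):
        is_case = label_map[pid] == "asthma"
        if pid in ident:
            tp += is_case
            fp += not is_case
        else:
            fn += is_case
            tn += not is_case
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, n_excluded=len(excluded))


def point_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """sensitivity, PPV, specificity, F1; undefined ratios (0/0) are None."""

    def ratio(num: int, den: int) -> float | None:
        return num / den if den else None

    sens = ratio(c.tp, c.tp + c.fn)
    ppv = ratio(c.tp, c.tp + c.fp)
    spec = ratio(c.tn, c.tn + c.fp)
    if sens is None or ppv is None or (sens + ppv) == 0:
        f1 = None
    else:
        f1 = 2 * sens * ppv / (sens + ppv)
    return {"sensitivity": sens, "ppv": ppv, "specificity": spec, "f1": f1}


def _resolve_identified(rule_or_ids, counts_table: pd.DataFrame | None) -> tuple[str, set[str]]:
    if isinstance(rule_or_ids, PhenotypeRule):
        if counts_table is None:
            raise ValueError("a feature-count table is required to apply a rule")
        return str(rule_or_ids), set(apply_phenotype(rule_or_ids, counts_table))
    ids = set(map(str, rule_or_ids))
    return f"<identified set, n={len(ids)}>", ids


def bootstrap_metrics(
    rule_or_ids,
    counts_table: pd.DataFrame | None,
    labels,
    n_pos: int = 20,
    n_neg: int = 20,
    iters: int = 10_000,
    seed: int = 0,
) -> EvaluationResult:
    """Stratified 20+20 bootstrap over the labeled (chart-reviewed) cohort.

    The positive stratum is the labeled patients identified by the
    phenotype; the negative stratum is the remaining labeled patients.
    Iterations where a metric is undefined are dropped from that metric's
    mean and CI (with the count recorded).  Deterministic under ``seed``.
    """
    rule_text, identified = _resolve_identified(rule_or_ids, counts_table)
    label_map = _as_label_map(labels)
    if not label_map:
        raise ValueError("empty label set")

    pos_ids = sorted(set(label_map) & identified)
    neg_ids = sorted(set(label_map) - identified)
    if not pos_ids:
        raise ValueError("empty stratum: no labeled patient is identified by the rule")
    if not neg_ids:
        raise ValueError("empty stratum: every labeled patient is identified by the rule")

    conf = confusion(identified, label_map)
    points = point_metrics(conf)

    pos_case = np.array([label_map[p] == "asthma" for p in pos_ids])
    neg_case = np.array([label_map[p] == "asthma" for p in neg_ids])

    rng = np.random.default_rng(seed)
    pos_draw = rng.integers(0, len(pos_ids), size=(iters, n_pos))
    neg_draw = rng.integers(0, len(neg_ids), size=(iters, n_neg))
    tp = pos_case[pos_draw].sum(axis=1).astype(float)
    fp = n_pos - tp
    fn = neg_case[neg_draw].sum(axis=1).astype(float)
    tn = n_neg - fn

    with np.errstate(divide="ignore", invalid="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
        denom = sens + ppv
        f1 = np.where(
            np.isnan(sens) | np.isnan(ppv) | (denom == 0), np.nan, 2 * sens * ppv / denom
        )

    metrics: dict[str, MetricSummary] = {}
    for name, values in zip(METRIC_NAMES, (sens, ppv, spec, f1)):
        valid = values[~np.isnan(values)]
        n_dropped = int(iters - valid.size)
        if n_dropped:
            logger.info("%s: dropped %d/%d undefined bootstrap iterations", name, n_dropped, iters)
        if valid.size:
            metrics[name] = MetricSummary(
                point=points[name],
                boot_mean=float(valid.mean()),
                ci_low=float(np.percentile(valid, 2.5)),
                ci_high=float(np.percentile(valid, 97.5)),
                n_dropped=n_dropped,
            )
        else:
            metrics[name] = MetricSummary(point=points[name], n_dropped=n_dropped)

    return EvaluationResult(
        rule_text=rule_text,
        confusion=conf,
        metrics=metrics,
        n_boot=iters,
        seed=seed,
        n_labeled=len(label_map),
    )


def confirmation_rate_from_counts(confirmed: int, reviewed: int) -> float:
    """Chart-review confirmation rate (an empirical within-stratum PPV) as a
    percentage rounded half-up to 1 decimal."""
    if reviewed <= 0:
        raise ValueError("no reviewed patients in stratum")
    return round_half_up(100.0 * confirmed / reviewed, 1)


def confirmation_rate(
    pattern: BasePattern,
    reviewed_labels,
    identified_set: Iterable[str],
) -> float:
    """Confirmation rate of a base-rule pattern stratum.

    ``identified_set`` is the pattern's identified patients (absence
    enforced); the rate is the percentage of reviewed patients in that set
    whose consensus label is asthma.
    """
    label_map = _as_label_map(reviewed_labels)
    in_set = set(map(str, identified_set)) & set(label_map)
    if not in_set:
        raise ValueError(f"no reviewed patients identified by pattern {pattern}")
    confirmed = sum(label_map[p] == "asthma" for p in in_set)
    return confirmation_rate_from_counts(confirmed, len(in_set))


@dataclass(frozen=True)
class SubgroupSpec:
    """One subgroup analysis: partition dimension plus encounter-window mode.

    Age bins are half-open and keyed by the age at the patient's first
    phenotype-related event; ``WITHIN_GROUP`` additionally recomputes the
    feature counts from encounters inside the bin before applying the rule.
    """

    dimension: str  # "sex" | "race_ethnicity" | "age_group"
    age_bins: tuple[tuple[float, float], ...] = AGE_BINS
    age_bin_labels: tuple[str, ...] = AGE_BIN_LABELS
    window_mode: str = ALL_ENCOUNTERS

    def __post_init__(self):
        if self.dimension not in ("sex", "race_ethnicity", "age_group"):
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.window_mode not in (ALL_ENCOUNTERS, WITHIN_GROUP):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")
        for (lo, hi), (lo2, _) in zip(self.age_bins, self.age_bins[1:]):
            if not (lo < hi <= lo2):
                raise ValueError("age bins must be disjoint and ordered")


def age_bin_label(age: float, spec: SubgroupSpec) -> str | None:
    for (lo, hi), label in zip(spec.age_bins, spec.age_bin_labels):
        if lo <= age < hi:
            return label
    return None


def subgroup_eval(
    rule: PhenotypeRule,
    cohort: Cohort,
    labels,
    spec: SubgroupSpec,
    lexicons: Lexicons | None = None,
    n_pos: int = 20,
    n_neg: int = 20,
    iters: int = 10_000,
    seed: int = 0,
) -> dict[str, EvaluationResult | None]:
    """Evaluate a phenotype within demographic subgroups.

    Sex and race/ethnicity partition patients by attribute.  Age subgroups
    partition by the age at the first phenotype-related event (full-window
    events).  In WITHIN_GROUP mode the rule is re-applied to counts built
    only from events inside each age bin.  Subgroups with no labeled
    members, or with an empty bootstrap stratum, yield None.
    """
    label_map = _as_label_map(labels)
    events = apply_age_window(build_feature_events(cohort, lexicons))
    all_ids = cohort.patients["patient_id"].astype(str)
    full_counts = count_features(events, patient_ids=all_ids)

    groups: dict[str, set[str]] = {}
    if spec.dimension in ("sex", "race_ethnicity"):
        for value, grp in cohort.patients.groupby(spec.dimension):
            groups[str(value)] = set(grp["patient_id"].astype(str))
    else:
        first_age = full_counts.set_index("patient_id")["age_first_event"]
        for label in spec.age_bin_labels:
            groups[label] = set()
        for pid, age in first_age.items():
            if np.isnan(age):
                continue
            label = age_bin_label(float(age), spec)
            if label is not None:
                groups[label].add(str(pid))

    results: dict[str, EvaluationResult | None] = {}
    for i, (name, members) in enumerate(sorted(groups.items())):
        sub_labels = {p: v for p, v in label_map.items() if p in members}
        if not sub_labels:
            results[name] = None
            continue
        if spec.dimension == "age_group" and spec.window_mode == WITHIN_GROUP:
            lo, hi = spec.age_bins[spec.age_bin_labels.index(name)]
            bin_events = restrict_to_age_range(events, lo, hi)
            counts = count_features(bin_events, patient_ids=all_ids)
        else:
            counts = full_counts
        member_counts = counts[counts["patient_id"].astype(str).isin(members)]
        try:
            results[name] = bootstrap_metrics(
                rule, member_counts, sub_labels,
                n_pos=n_pos, n_neg=n_neg, iters=iters,
                seed=int(np.random.default_rng([seed, i]).integers(2**31)),
            )
        except ValueError:
            conf = confusion(set(apply_phenotype(rule, member_counts)), sub_labels)
            results[name] = EvaluationResult(
                rule_text=str(rule),
                confusion=conf,
                metrics={k: MetricSummary(point=v) for k, v in point_metrics(conf).items()},
                n_labeled=len(sub_labels),
            )
    return results


def characterize_cohort(
    cohort: Cohort,
    identified_set: Iterable[str],
    counts_table: pd.DataFrame | None = None,
    lexicons: Lexicons | None = None,
    top_k: int = 5,
) -> pd.DataFrame:
    """Characterize an identified cohort: N (%) by age bin at first event,
    sex, and race/ethnicity, plus the top-k non-asthma diagnosis codes and
    medication order strings by patient-level prevalence.

    Returns a tidy frame with columns (dimension, category, n, pct);
    percentages are of the identified N, rounded half-up to 1 decimal, with
    Unknown rows reported but excluded from no dimension.
    """
    ids = set(map(str, identified_set))
    n_total = len(ids)
    if counts_table is None:
        from .feature_extraction import extract_feature_counts

        counts_table = extract_feature_counts(cohort, lexicons)
    lex = lexicons
    if lex is None:
        from .lexicons import default_lexicons

        lex = default_lexicons()

    def pct(n: int) -> float:
        return round_half_up(100.0 * n / n_total, 1) if n_total else 0.0

    rows: list[dict] = []
    sub_counts = counts_table[counts_table["patient_id"].astype(str).isin(ids)]
    spec = SubgroupSpec(dimension="age_group")
    bin_counts = {label: 0 for label in spec.age_bin_labels}
    for age in sub_counts["age_first_event"]:
        if not np.isnan(age):
            label = age_bin_label(float(age), spec)
            if label is not None:
                bin_counts[label] += 1
    for label, n in bin_counts.items():
        rows.append({"dimension": "age", "category": label, "n": n, "pct": pct(n)})

    patients = cohort.patients[cohort.patients["patient_id"].astype(str).isin(ids)]
    for dim, order in (("sex", ["Male", "Female", "Unknown"]),
                       ("race_ethnicity", ["NHW", "NHB", "Hispanic", "Other", "Unknown"])):
        value_counts = patients[dim].value_counts()
        for category in order:
            n = int(value_counts.get(category, 0))
            rows.append({"dimension": dim, "category": category, "n": n, "pct": pct(n)})

    enc = cohort.encounters
    pid_of = dict(zip(enc["encounter_id"].astype(str), enc["patient_id"].astype(str)))

    dx = cohort.diagnoses
    non_asthma = dx[~dx.apply(lambda r: lex.dx.match(r["code_system"], r["code"]), axis=1)] \
        if len(dx) else dx
    code_patients: dict[str, set[str]] = {}
    for _, row in non_asthma.iterrows():
        pid = pid_of.get(str(row["encounter_id"]))
        if pid in ids:
            code_patients.setdefault(str(row["code"]), set()).add(pid)
    for code, pats in sorted(code_patients.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:top_k]:
        rows.append({"dimension": "diagnosis", "category": code, "n": len(pats), "pct": pct(len(pats))})

    med_patients: dict[str, set[str]] = {}
    for _, row in cohort.medications.iterrows():
        pid = pid_of.get(str(row["encounter_id"]))
        if pid in ids:
            med_patients.setdefault(str(row["drug_text"]), set()).add(pid)
    for med, pats in sorted(med_patients.items(), key=lambda kv: (-len(kv[1]), kv[0]))[:top_k]:
        rows.append({"dimension": "prescription", "category": med, "n": len(pats), "pct": pct(len(pats))})

    return pd.DataFrame(rows, columns=["dimension", "category", "n", "pct"])


def interannotator_agreement(labels: pd.DataFrame) -> float:
    """Proportion of multiply-annotated patients whose reviewers all agree.

    Adjudicated rows are ignored; patients with a single reviewer are
    excluded from the denominator.
    """
    from .ehr_model import ADJUDICATOR_ID

    reviewer_rows = labels[labels["reviewer_id"] != ADJUDICATOR_ID]
    n_double = n_agree = 0
    for _, grp in reviewer_rows.groupby("patient_id"):
        if grp["reviewer_id"].nunique() < 2:
            continue
        n_double += 1
        n_agree += int(grp["label"].nunique() == 1)
    if n_double == 0:
        raise ValueError("no doubly-annotated patients")
    return n_agree / n_double
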