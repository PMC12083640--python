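"""Synthetic longitudinal EHR cohorts with planted asthma status.

The generator emulates the structure a phenotype pipeline consumes —
patients with demographics, dated encounters at ages 0–18, asthma ICD
codes, bronchodilator/corticosteroid order strings, clinical notes with
embedded keyword phrases, and two-reviewer chart labels — with every signal
rate configurable and known, so phenotype performance has a computable
ground truth.

Generative model, per patient: asthma status ~ Bernoulli(prevalence); an
encounter count ~ Poisson(mean_encounters) (or fixed); per encounter an
age in days uniform over [age_lo, age_hi) years; per encounter and per
feature category an independent status-conditional Bernoulli emission.
Emitted categories materialize as a diagnosis row with an asthma code, a
medication row with a bronchodilator or corticosteroid order string, or a
keyword phrase embedded in that encounter's note among neutral filler
sentences.  Non-signal noise (non-asthma codes, unrelated prescriptions,
keyword-free notes) is added independently and is invisible to the
extraction lexicons.

:func:`expected_rule_performance` is the independent oracle: it computes
P(rule | status) either by exact enumeration over the per-category binomial
count distributions (fixed encounter count, no carryover band) or by direct
Monte-Carlo simulation of count vectors — without touching the cohort
tables or the feature-extraction pipeline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from math import comb, isclose
from typing import Mapping

import numpy as np
import pandas as pd

from .ehr_model import Cohort
from .rule_engine import BasePattern, PhenotypeRule, RuleAtom, evaluate_rule

CATEGORY_KEYS = ("dx", "bdr", "ics", "kw1", "kw2")

DAYS_PER_YEAR = 365.25

# --- signal vocabularies (drawn from the packaged lexicons) ----------------

ASTHMA_CODES = (
    ("ICD10CM", "J45.901"),
    ("ICD10CM", "J45.909"),
    ("ICD10CM", "J45.40"),
    ("ICD10CM", "J45.20"),
    ("ICD9CM", "493.92"),
    ("ICD9CM", "493.90"),
)

BDR_ORDER_STRINGS = (
    "albuterol (PROAIR HFA;VENTOLIN HFA) 108 (90 BASE) MCG/ACT inhaler",
    "albuterol (PROVENTIL) (2.5 MG/3ML) 0.083% nebulizer solution 2.5 mg",
    "levalbuterol (XOPENEX HFA) 45 MCG/ACT inhaler",
    "ipratropium bromide (ATROVENT) 0.02% nebulizer solution",
)

ICS_ORDER_STRINGS = (
    "budesonide (PULMICORT FLEXHALER) 90 MCG/ACT inhaler",
    "fluticasone propionate (FLOVENT HFA) 44 MCG/ACT inhaler",
    "mometasone (ASMANEX TWISTHALER) 110 MCG/ACT inhaler",
    "beclomethasone propionate (QVAR) 40 MCG/ACT inhaler",
)

# None of the kw1 sample phrases contains a kw2 phrase (and vice versa), so
# note keyword categories stay independent as the emission model assumes.
KW1_PHRASES = (
    "asthma exacerbation",
    "asthma action plan reviewed with family",
    "reactive airway disease",
    "bronchospasm noted on exam",
)

KW2_PHRASES = (
    "diffuse wheezing on auscultation",
    "reports shortness of breath with exertion",
    "mild dyspnea",
    "nighttime cough most evenings",
)

# --- noise vocabularies (invisible to the extraction lexicons) -------------

BACKGROUND_CODES = (
    ("ICD10CM", "R05"),       # cough
    ("ICD10CM", "R50.9"),     # fever, unspecified
    ("ICD10CM", "J06.9"),     # acute upper respiratory infection
    ("ICD9CM", "465.9"),
)

BACKGROUND_ORDER_STRINGS = (
    "amoxicillin (AMOXIL) 400 MG/5ML suspension",
    "fluticasone (FLONASE) 50 MCG/ACT Nasal Suspension",
    "ibuprofen (MOTRIN) 100 MG/5ML suspension",
    "cetirizine (ZYRTEC) 5 MG/5ML solution",
)

FILLER_SENTENCES = (
    "Patient seen in clinic today for routine follow-up.",
    "Vital signs reviewed and within normal limits for age.",
    "Immunizations up to date; anticipatory guidance provided.",
    "Diet, sleep, and activity discussed with caregiver.",
    "Return precautions reviewed; follow up as needed.",
)


def _prob_mapping(value: Mapping[str, float], name: str) -> dict[str, float]:
    out = {k: float(value.get(k, 0.0)) for k in CATEGORY_KEYS}
    for k, p in out.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}[{k}] = {p} outside [0, 1]")
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Emission probabilities are per encounter and status-conditional; the
    defaults plant a clear diagnosis/prescription signal in cases with
    noisy, mostly nonspecific keyword chatter in controls, so base-rule
    strata show the qualitative confirmation-rate gradient seen in chart
    review (keyword-only strata mostly non-asthma, repeat-diagnosis strata
    mostly asthma).  They are illustrative conditions, not fitted values.
    """

    n_patients: int = 2000
    prevalence: float = 0.30
    mean_encounters: float = 6.0
    n_encounters_fixed: int | None = None
    age_lo: float = 1.0
    age_hi: float = 18.0
    p_case: Mapping[str, float] = field(
        default_factory=lambda: {"dx": 0.30, "bdr": 0.10, "ics": 0.10, "kw1": 0.35, "kw2": 0.25}
    )
    p_control: Mapping[str, float] = field(
        default_factory=lambda: {"dx": 0.01, "bdr": 0.01, "ics": 0.015, "kw1": 0.04, "kw2": 0.10}
    )
    # demographic mix of a large pediatric potential-asthma population
    sex_probs: Mapping[str, float] = field(
        default_factory=lambda: {"Male": 0.526, "Female": 0.474, "Unknown": 0.0}
    )
    race_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "NHW": 0.485, "NHB": 0.308, "Hispanic": 0.099, "Other": 0.038, "Unknown": 0.07,
        }
    )
    p_background_dx: float = 0.25
    p_background_med: float = 0.10
    p_background_note: float = 0.30
    reviewer_disagreement: float = 0.0
    label_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if not 1.0 <= self.age_lo < self.age_hi:
            raise ValueError("need 1 <= age_lo < age_hi")
        object.__setattr__(self, "p_case", _prob_mapping(self.p_case, "p_case"))
        object.__setattr__(self, "p_control", _prob_mapping(self.p_control, "p_control"))
        for name in ("p_background_dx", "p_background_med", "p_background_note",
                     "reviewer_disagreement", "label_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")
        for name in ("sex_probs", "race_probs"):
            probs = dict(getattr(self, name))
            if any(p < 0 for p in probs.values()) or not isclose(sum(probs.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must be non-negative and sum to 1")
            object.__setattr__(self, name, probs)


TruthTable = dict  # patient_id -> bool (planted asthma status)

_REFERENCE_BIRTH_START = date(2004, 1, 1)
_BIRTH_SPAN_DAYS = 3653  # ten years of birth dates


def _categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> list[str]:
    names = list(probs)
    p = np.array([probs[k] for k in names], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(names), size=n, p=p)
    return [names[i] for i in idx]


def _age_day_bounds(cfg: SyntheticConfig) -> tuple[int, int]:
    return int(np.ceil(cfg.age_lo * DAYS_PER_YEAR)), int(np.floor(cfg.age_hi * DAYS_PER_YEAR))


def generate_cohort(config: SyntheticConfig) -> tuple[Cohort, TruthTable]:
    """Generate a cohort and its planted truth table, reproducibly.

    Labels are written for a ``label_fraction`` subset of patients as two
    reviewers; the second reviewer's label is flipped with probability
    ``reviewer_disagreement`` (0 by default: perfect agreement with truth).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    patient_ids = [f"P{i:06d}" for i in range(n)]
    status = rng.random(n) < cfg.prevalence
    sexes = _categorical(rng, cfg.sex_probs, n)
    races = _categorical(rng, cfg.race_probs, n)
    birth_offsets = rng.integers(0, _BIRTH_SPAN_DAYS, size=n)
    birth_dates = [_REFERENCE_BIRTH_START + timedelta(days=int(d)) for d in birth_offsets]

    if cfg.n_encounters_fixed is not None:
        n_enc = np.full(n, cfg.n_encounters_fixed)
    else:
        n_enc = rng.poisson(cfg.mean_encounters, size=n)

    day_lo, day_hi = _age_day_bounds(cfg)

    patients_rows, encounter_rows, dx_rows, med_rows, note_rows = [], [], [], [], []
    truth: TruthTable = {}

    for i, pid in enumerate(patient_ids):
        truth[pid] = bool(status[i])
        probs = cfg.p_case if status[i] else cfg.p_control
        patients_rows.append(
            {"patient_id": pid, "birth_date": pd.Timestamp(birth_dates[i]),
             "sex": sexes[i], "race_ethnicity": races[i]}
        )
        for j in range(int(n_enc[i])):
            eid = f"E{i:06d}_{j:03d}"
            age_days = int(rng.integers(day_lo, day_hi))
            enc_date = birth_dates[i] + timedelta(days=age_days)
            encounter_rows.append(
                {"encounter_id": eid, "patient_id": pid, "date": pd.Timestamp(enc_date)}
            )
            emitted = {k: bool(rng.random() < probs[k]) for k in CATEGORY_KEYS}
            if emitted["dx"]:
                system, code = ASTHMA_CODES[rng.integers(len(ASTHMA_CODES))]
                dx_rows.append({"encounter_id": eid, "code_system": system, "code": code})
            if rng.random() < cfg.p_background_dx:
                system, code = BACKGROUND_CODES[rng.integers(len(BACKGROUND_CODES))]
                dx_rows.append({"encounter_id": eid, "code_system": system, "code": code})
            if emitted["bdr"]:
                med_rows.append(
                    {"encounter_id": eid,
                     "drug_text": BDR_ORDER_STRINGS[rng.integers(len(BDR_ORDER_STRINGS))]}
                )
            if emitted["ics"]:
                med_rows.append(
                    {"encounter_id": eid,
                     "drug_text": ICS_ORDER_STRINGS[rng.integers(len(ICS_ORDER_STRINGS))]}
                )
            if rng.random() < cfg.p_background_med:
                med_rows.append(
                    {"encounter_id": eid,
                     "drug_text": BACKGROUND_ORDER_STRINGS[rng.integers(len(BACKGROUND_ORDER_STRINGS))]}
                )
            sentences = [FILLER_SENTENCES[rng.integers(len(FILLER_SENTENCES))]]
            if emitted["kw1"]:
                sentences.append(KW1_PHRASES[rng.integers(len(KW1_PHRASES))].capitalize() + ".")
            if emitted["kw2"]:
                sentences.append(KW2_PHRASES[rng.integers(len(KW2_PHRASES))].capitalize() + ".")
            if emitted["kw1"] or emitted["kw2"] or rng.random() < cfg.p_background_note:
                note_rows.append(
                    {"note_id": f"N{eid}", "encounter_id": eid, "text": " ".join(sentences)}
                )

    labeled = np.arange(n)[rng.random(n) < cfg.label_fraction] if cfg.label_fraction < 1.0 \
        else np.arange(n)
    label_rows = []
    for i in labeled:
        pid = patient_ids[i]
        true_label = "asthma" if truth[pid] else "not_asthma"
        flipped = "not_asthma" if truth[pid] else "asthma"
        label_rows.append({"patient_id": pid, "reviewer_id": "R1", "label": true_label})
        second = flipped if rng.random() < cfg.reviewer_disagreement else true_label
        label_rows.append({"patient_id": pid, "reviewer_id": "R2", "label": second})

    from .ehr_model import TABLE_COLUMNS, _empty_table

    def frame(rows, name):
        return pd.DataFrame(rows, columns=TABLE_COLUMNS[name]) if rows else _empty_table(name)

    cohort = Cohort(
        patients=frame(patients_rows, "patients"),
        encounters=frame(encounter_rows, "encounters"),
        diagnoses=frame(dx_rows, "diagnoses"),
        medications=frame(med_rows, "medications"),
        notes=frame(note_rows, "notes"),
        labels=frame(label_rows, "labels"),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# Oracle: expected rule performance under the generative model
# ---------------------------------------------------------------------------

def _rule_caps(rule: PhenotypeRule) -> dict[str, int]:
    caps: dict[str, int] = {}
    for atom in rule.atoms:
        extra = 1 if atom.op == "=" else 0
        caps[atom.feature] = max(caps.get(atom.feature, 0), atom.threshold + extra)
    return caps


def _exact_probability(rule: PhenotypeRule, n_enc: int, probs: Mapping[str, float]) -> float:
    """P(rule true) with a fixed encounter count and no age filtering:
    category counts are independent Binomial(n_enc, p) variables.

    Counts are capped one past the largest threshold per feature; the capped
    bin absorbs the binomial upper tail.
    """
    caps = _rule_caps(rule)
    features = sorted(caps)

    def pmf(feature: str) -> list[tuple[int, float]]:
        p = probs[feature]
        cap = min(caps[feature], n_enc)
        out = [(k, comb(n_enc, k) * p**k * (1 - p) ** (n_enc - k)) for k in range(cap)]
        tail = 1.0 - sum(w for _, w in out)
        out.append((cap, tail))
        return out

    total = 0.0
    for combo in itertools.product(*(pmf(f) for f in features)):
        counts = {k: 0 for k in CATEGORY_KEYS}
        weight = 1.0
        for feature, (k, w) in zip(features, combo):
            counts[feature] = k
            weight *= w
        if weight and evaluate_rule(rule, counts):
            total += weight
    return total


def _simulate_counts(
    cfg: SyntheticConfig, probs: Mapping[str, float], n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Vectorized count-vector simulation mirroring the generative model and
    the pediatric age window (with the 1–2-year carryover unlock)."""
    if cfg.n_encounters_fixed is not None:
        n_enc = np.full(n, cfg.n_encounters_fixed)
    else:
        n_enc = rng.poisson(cfg.mean_encounters, size=n)
    pid = np.repeat(np.arange(n), n_enc)
    total = int(n_enc.sum())
    day_lo, day_hi = _age_day_bounds(cfg)
    ages = rng.integers(day_lo, day_hi, size=total) / DAYS_PER_YEAR

    emits = {k: rng.random(total) < probs[k] for k in CATEGORY_KEYS}
    any_emit = np.zeros(total, dtype=bool)
    for k in CATEGORY_KEYS:
        any_emit |= emits[k]

    in_main = (ages >= 2.0) & (ages < 18.0)
    in_carry = (ages >= 1.0) & (ages < 2.0)
    unlocked = np.zeros(n, dtype=bool)
    np.logical_or.at(unlocked, pid[in_main & any_emit], True)
    keep = in_main | (in_carry & unlocked[pid])

    data = {"patient_id": [f"S{i}" for i in range(n)]}
    for k in CATEGORY_KEYS:
        data[f"n_{k}"] = np.bincount(pid[keep & emits[k]], minlength=n)
    return pd.DataFrame(data)


def expected_rule_performance(
    config: SyntheticConfig,
    rule: PhenotypeRule,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Expected (sensitivity, specificity) of a rule under the generator.

    Uses exact binomial enumeration when the encounter count is fixed and
    every encounter age falls in the plain [2, 18) window (no carryover
    band); otherwise Monte-Carlo over ``n_mc`` simulated count vectors per
    status.  This is the brute-force oracle used to validate the full
    pipeline; it never touches cohort tables or feature extraction.
    """
    cfg = config
    exact_ok = (
        cfg.n_encounters_fixed is not None
        and cfg.age_lo >= 2.0
        and cfg.age_hi <= 18.0
    )
    if exact_ok:
        sens = _exact_probability(rule, cfg.n_encounters_fixed, cfg.p_case)
        spec = 1.0 - _exact_probability(rule, cfg.n_encounters_fixed, cfg.p_control)
        return sens, spec
    if seed is None:
        seed = (cfg.seed + 987_654_321) % (2**31)
    rng = np.random.default_rng(seed)
    from .rule_engine import evaluate_rule_frame

    case_counts = _simulate_counts(cfg, cfg.p_case, n_mc, rng)
    control_counts = _simulate_counts(cfg, cfg.p_control, n_mc, rng)
    sens = float(evaluate_rule_frame(rule, case_counts).mean())
    spec = float(1.0 - evaluate_rule_frame(rule, control_counts).mean())
    return sens, spec


# ---------------------------------------------------------------------------
# Published chart-review stratum fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StratumRow:
    """One base-rule combination stratum from the published chart review."""

    pattern: BasePattern
    identified: int
    covered: int
    reviewed: int
    confirmed: int


def table2_fixture() -> list[StratumRow]:
    """The 13 published base-rule combination strata (pattern flags,
    identified/covered population counts, reviewed and confirmed counts)."""
    from importlib import resources

    with resources.files("compac.data").joinpath("table2.csv").open("r", encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype=str)
    rows = []
    for _, r in df.iterrows():
        pattern = BasePattern.from_row(
            dx=r["dx"], bdr=r["bdr"], ics=r["ics"], kw1=r["kw1"], kw2=r["kw2"]
        )
        rows.append(
            StratumRow(
                pattern=pattern,
                identified=int(r["identified"]),
                covered=int(r["covered"]),
                reviewed=int(r["reviewed"]),
                confirmed=int(r["confirmed"]),
            )
        )
    return rows
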