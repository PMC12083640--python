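"""Iterative chart-review cohort selection.

The selection procedure mirrors phenotype-development practice: an initial
uniform random sample from the whole cohort, per-rule top-ups so each
candidate rule has a minimum number of selected patients, and qualification
of base-rule pattern groups by their identified/covered ratio, with a
reviewed-count floor for qualifying groups.  All draws are uniform without
replacement within a round and reproducible under the plan's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .rule_engine import BasePattern


@dataclass(frozen=True)
class SamplingPlan:
    """Tunable parameters of the selection procedure.

    initial_n: size of the first uniform sample (default 500).
    min_per_rule: minimum selected patients per candidate rule (default 10).
    min_group_reviewed: reviewed-count floor per qualifying pattern group
        (default 18).
    qualify_threshold: identified/covered ratio floor for a pattern group
        to qualify (default 0.10).
    max_rounds: fixed-point guard on the top-up iteration.
    """

    initial_n: int = 500
    min_per_rule: int = 10
    min_group_reviewed: int = 18
    qualify_threshold: float = 0.10
    max_rounds: int = 10
    seed: int = 0

    def __post_init__(self):
        if min(self.initial_n, self.min_per_rule, self.min_group_reviewed, self.max_rounds) < 1:
            raise ValueError("plan sizes must be positive")
        if not 0.0 < self.qualify_threshold < 1.0:
            raise ValueError("qualify_threshold must be in (0, 1)")


@dataclass
class SamplingResult:
    """Selections per round plus an event log."""

    rounds: list[list[str]] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def selected(self) -> set[str]:
        return {pid for rnd in self.rounds for pid in rnd}


def _draw(rng: np.random.Generator, pool: Sequence[str], k: int) -> list[str]:
    pool = sorted(pool)
    if k >= len(pool):
        return pool
    idx = rng.choice(len(pool), size=k, replace=False)
    return [pool[i] for i in sorted(idx)]


def select_initial(cohort_ids: Iterable[str], plan: SamplingPlan,
                   rng: np.random.Generator | None = None) -> set[str]:
    """Uniform sample without replacement of ``plan.initial_n`` patients."""
    ids = sorted(map(str, cohort_ids))
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    if len(ids) < plan.initial_n:
        import warnings

        warnings.warn(
            f"cohort ({len(ids)}) smaller than initial_n ({plan.initial_n}); selecting all"
        )
        return set(ids)
    return set(_draw(rng, ids, plan.initial_n))


def topup_per_rule(
    selected: set[str],
    rule_strata: Mapping[str, Iterable[str]],
    plan: SamplingPlan,
    cohort_size: int,
    rng: np.random.Generator | None = None,
    log: list[str] | None = None,
) -> set[str]:
    """Top up the selection so each rule has >= ``min_per_rule`` members.

    For a deficient rule the draw size is
    ``max(min_per_rule - current, ceil(stratum_size * initial_n / cohort_size))``
    — at least the deficit, scaled up for large strata to keep the sample
    proportionate to the overall sampling fraction.  Draws come from the
    rule's identified stratum, excluding already-selected patients; if the
    stratum cannot cover the deficit everything available is taken and
    logged.
    """
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    log = log if log is not None else []
    out = set(selected)
    for rule_name in sorted(rule_strata):
        stratum = {str(p) for p in rule_strata[rule_name]}
        current = len(out & stratum)
        if current >= plan.min_per_rule:
            continue
        deficit = plan.min_per_rule - current
        proportional = math.ceil(len(stratum) * plan.initial_n / cohort_size) if cohort_size else 0
        want = max(deficit, proportional)
        available = stratum - out
        if len(available) < deficit:
            log.append(
                f"rule {rule_name}: stratum exhausted, took all {len(available)} "
                f"available (deficit {deficit})"
            )
        out |= set(_draw(rng, sorted(available), want))
    return out


def qualify_groups(
    pattern_tallies: Mapping[BasePattern, tuple[int, int]],
    plan: SamplingPlan,
) -> list[BasePattern]:
    """Pattern groups whose identified/covered ratio reaches the threshold.

    ``pattern_tallies`` maps each pattern to (identified, covered) counts.
    Patterns with zero covered patients are skipped.  Qualifying groups are
    the ones that must accumulate ``min_group_reviewed`` reviewed members
    in subsequent rounds.
    """
    qualifying = []
    for pattern, (identified, covered) in pattern_tallies.items():
        if covered <= 0:
            continue
        if identified / covered >= plan.qualify_threshold:
            qualifying.append(pattern)
    return sorted(qualifying, key=str)


def run_sampling(
    cohort_ids: Iterable[str],
    rule_strata: Mapping[str, Iterable[str]],
    pattern_strata: Mapping[BasePattern, tuple[Iterable[str], Iterable[str]]],
    plan: SamplingPlan,
) -> SamplingResult:
    """Full selection: initial sample, per-rule top-up, then rounds topping
    up each qualifying pattern group to the reviewed floor.

    ``pattern_strata`` maps each pattern to its (identified, covered)
    patient id sets.  Iterates to a fixed point or ``plan.max_rounds``.
    """
    ids = sorted(map(str, cohort_ids))
    rng = np.random.default_rng(plan.seed)
    result = SamplingResult()

    selected = select_initial(ids, plan, rng=rng)
    result.rounds.append(sorted(selected))

    after_topup = topup_per_rule(
        selected, rule_strata, plan, cohort_size=len(ids), rng=rng, log=result.log
    )
    result.rounds.append(sorted(after_topup - selected))
    selected = after_topup

    tallies = {
        p: (len(set(map(str, ident))), len(set(map(str, cov))))
        for p, (ident, cov) in pattern_strata.items()
    }
    qualifying = qualify_groups(tallies, plan)
    result.log.append(f"{len(qualifying)} of {len(tallies)} pattern groups qualify")

    for _ in range(plan.max_rounds):
        added: set[str] = set()
        for pattern in qualifying:
            ident = {str(p) for p in pattern_strata[pattern][0]}
            current = len(selected & ident)
            if current >= plan.min_group_reviewed:
                continue
            deficit = plan.min_group_reviewed - current
            available = ident - selected
            if len(available) < deficit:
                result.log.append(
                    f"pattern {pattern}: stratum exhausted, took all {len(available)}"
                )
            added |= set(_draw(rng, sorted(available), deficit))
        if not added:
            break
        selected |= added
        result.rounds.append(sorted(added))
    return result
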