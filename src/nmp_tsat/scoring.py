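"""Per-rater evaluation validation, multi-rater consensus, and score summaries.

Each study is scored by one or more raters, assigning every criterion a level
in {0, 1, 2}.  The total assessment score (TAS) is the plain sum over all
criteria (equal weights); its integer percent of the maximum uses
round-half-away-from-zero, which reproduces every printed TAS/percent pair
(44/52 -> 85, 37/52 -> 71, 34/46 -> 74, 12/52 -> 23, 16/46 -> 35).

Advisory rubric helpers (`suggest_dose_response_score`,
`particle_size_context`) encode quantitative decision rules from the scoring
guidance; they annotate, and never overwrite, a rater's judgement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

from .registry import (
    Category,
    CriteriaRegistry,
    Issue,
    SCORE_LEVELS,
    StudySystem,
)

__all__ = [
    "ExposureRoute",
    "MaterialClass",
    "Shape",
    "StudyMeta",
    "StudyEvaluation",
    "ConsensusRule",
    "ConsensusEvaluation",
    "ScoreSummary",
    "SizeContext",
    "DiscordanceError",
    "EvaluationError",
    "validate_evaluation",
    "consensus",
    "summarize",
    "tas_percent",
    "suggest_dose_response_score",
    "particle_size_context",
]


class ExposureRoute(str, Enum):
    ORAL = "oral"
    INHALATION = "inhalation"
    OTHER = "other"


class MaterialClass(str, Enum):
    NMP = "nmp"
    CELLULOSE = "cellulose"
    OTHER = "other"


class Shape(str, Enum):
    SPHERE = "sphere"
    FRAGMENT = "fragment"
    FIBRE = "fibre"
    OTHER = "other"


@dataclass(frozen=True)
class StudyMeta:
    """Study-level metadata used for stratified corpus analytics.

    A study reporting both in vivo and in vitro arms is two independent
    evaluations keyed by (study_id, study_system).
    """

    citation: str
    year: int
    study_system: StudySystem
    exposure_route: ExposureRoute = ExposureRoute.OTHER
    material_class: MaterialClass = MaterialClass.NMP
    polymer: Optional[str] = None
    shape: Optional[Shape] = None
    median_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.median_size_um is not None and self.median_size_um <= 0:
            raise ValueError("median_size_um must be positive when present")


@dataclass(frozen=True)
class StudyEvaluation:
    """One rater's complete 0/1/2 score map for one study."""

    study_id: str
    rater_id: str
    registry_name: str
    scores: Mapping[str, int]
    metadata: Optional[StudyMeta] = None


class ConsensusRule(str, Enum):
    STRICT = "strict"
    MIN = "min"
    MODE = "mode"


@dataclass(frozen=True)
class ConsensusEvaluation:
    """Merged multi-rater scores with a record of every disagreement.

    ``discordant`` lists (criterion_id, {rater_id: level}) for each criterion
    where raters differ; it is empty iff all raters agreed everywhere.
    """

    study_id: str
    scores: Mapping[str, int]
    rule: ConsensusRule
    discordant: tuple[tuple[str, Mapping[str, int]], ...] = ()
    registry_name: str = ""
    rater_id: str = "consensus"
    metadata: Optional[StudyMeta] = None


@dataclass(frozen=True)
class ScoreSummary:
    """Category subtotals and TAS-derived statistics for one evaluation."""

    study_id: str
    subtotals: Mapping[Category, int]
    tas: int
    tas_max: int
    tas_percent: int
    max_score_fraction: float
    n_zero: int


class EvaluationError(ValueError):
    """An evaluation failed validation; carries the issue list."""

    def __init__(self, issues: Sequence[Issue]):
        self.issues = list(issues)
        super().__init__("invalid evaluation: " + "; ".join(str(i) for i in issues))


class DiscordanceError(ValueError):
    """Strict consensus requested but raters disagree; names the criteria."""

    def __init__(self, criteria: Sequence[str]):
        self.criteria = list(criteria)
        super().__init__(
            "raters disagree on criteria: " + ", ".join(criteria)
        )


Evaluation = Union[StudyEvaluation, ConsensusEvaluation]


def validate_evaluation(ev: Evaluation, reg: CriteriaRegistry) -> list[Issue]:
    """Check coverage (every registry criterion scored, no extras), score
    range, and that metadata study system matches the registry.

    Returns issue records; empty list iff the evaluation is valid.
    """
    issues: list[Issue] = []
    expected = set(reg.ids)
    got = set(ev.scores)
    for cid in reg.ids:
        if cid not in got:
            issues.append(Issue("missing_criterion", "no score assigned", cid))
    for cid in sorted(got - expected):
        issues.append(Issue("unknown_criterion", "not in registry", cid))
    for cid, level in ev.scores.items():
        if not isinstance(level, int) or isinstance(level, bool) or level not in SCORE_LEVELS:
            issues.append(
                Issue("out_of_range", f"score {level!r} not in {list(SCORE_LEVELS)}", cid)
            )
    meta = getattr(ev, "metadata", None)
    if meta is not None and meta.study_system != reg.study_system:
        issues.append(
            Issue(
                "system_mismatch",
                f"metadata says {meta.study_system.value}, registry is "
                f"{reg.study_system.value}",
            )
        )
    return issues


def consensus(
    evals: Sequence[StudyEvaluation],
    rule: Union[str, ConsensusRule] = ConsensusRule.MIN,
) -> ConsensusEvaluation:
    """Merge one study's per-rater evaluations into a single score map.

    Rules:

    * ``strict`` — raise :class:`DiscordanceError` on any disagreement;
    * ``min`` — per-criterion minimum across raters (conservative default);
    * ``mode`` — per-criterion majority, ties broken to the LOWER level.

    All rules are idempotent on a single evaluation; disagreements are always
    recorded in ``discordant`` regardless of rule.
    """
    rule = ConsensusRule(rule)
    if not evals:
        raise ValueError("consensus requires at least one evaluation")
    study_ids = {e.study_id for e in evals}
    if len(study_ids) != 1:
        raise ValueError(f"evaluations span multiple studies: {sorted(study_ids)}")
    registries = {e.registry_name for e in evals}
    if len(registries) != 1:
        raise ValueError(
            f"evaluations use different registries: {sorted(registries)}"
        )
    key_sets = {frozenset(e.scores) for e in evals}
    if len(key_sets) != 1:
        raise ValueError("evaluations do not cover the same criteria")

    criterion_ids = list(evals[0].scores)
    merged: dict[str, int] = {}
    discordant: list[tuple[str, dict[str, int]]] = []
    for cid in criterion_ids:
        levels = [e.scores[cid] for e in evals]
        if len(set(levels)) > 1:
            discordant.append((cid, {e.rater_id: e.scores[cid] for e in evals}))
        if rule is ConsensusRule.MIN:
            merged[cid] = min(levels)
        elif rule is ConsensusRule.MODE:
            counts = Counter(levels)
            best = max(counts.values())
            merged[cid] = min(lvl for lvl, n in counts.items() if n == best)
        else:  # strict resolved below; fill with the common value meanwhile
            merged[cid] = levels[0]
    if rule is ConsensusRule.STRICT and discordant:
        raise DiscordanceError([cid for cid, _ in discordant])
    return ConsensusEvaluation(
        study_id=evals[0].study_id,
        scores=merged,
        rule=rule,
        discordant=tuple(discordant),
        registry_name=evals[0].registry_name,
        metadata=evals[0].metadata,
    )


def tas_percent(tas: int, tas_max: int) -> int:
    """Integer percent of the maximum TAS, rounded half away from zero.

    (44, 52) -> 85; (12, 52) -> 23; (16, 46) -> 35; (26, 52) -> 50.
    """
    if tas_max <= 0:
        raise ValueError("tas_max must be positive")
    if not 0 <= tas <= tas_max:
        raise ValueError(f"tas {tas} outside [0, {tas_max}]")
    # exact integer arithmetic: floor((100*tas/tas_max) + 1/2) for tas >= 0
    return (200 * tas + tas_max) // (2 * tas_max)


def summarize(ev: Evaluation, reg: CriteriaRegistry) -> ScoreSummary:
    """Category subtotals, TAS, integer percent-of-maximum, fraction of
    criteria at the maximum score, and the count of zero-scored criteria."""
    issues = validate_evaluation(ev, reg)
    if issues:
        raise EvaluationError(issues)
    subtotals: dict[Category, int] = {cat: 0 for cat in Category}
    n_max = 0
    n_zero = 0
    for crit in reg.criteria:
        level = ev.scores[crit.id]
        subtotals[crit.category] += level
        if level == reg.max_score_per_criterion:
            n_max += 1
        if level == 0:
            n_zero += 1
    tas = sum(subtotals.values())
    tmax = reg.max_tas
    return ScoreSummary(
        study_id=ev.study_id,
        subtotals=subtotals,
        tas=tas,
        tas_max=tmax,
        tas_percent=tas_percent(tas, tmax),
        max_score_fraction=n_max / len(reg),
        n_zero=n_zero,
    )


def suggest_dose_response_score(
    n_doses: int, has_control: bool, range_ratio: Optional[float] = None
) -> int:
    """Advisory score for the dose-response criterion.

    Level 2 requires at least three concentration doses plus the control and a
    highest/lowest concentration ratio of at least 3; level 1 requires two or
    more doses plus the control; otherwise 0.  Advisory only — this never
    overwrites a rater's assigned score.

    ``range_ratio`` is highest/lowest tested concentration; it may be omitted
    for designs with fewer than two doses, where it is undefined.
    """
    if n_doses < 0:
        raise ValueError("n_doses must be non-negative")
    if n_doses >= 2:
        if range_ratio is None:
            raise ValueError("range_ratio required when n_doses >= 2")
        if range_ratio < 1:
            raise ValueError("range_ratio must be >= 1")
    if n_doses >= 3 and has_control and range_ratio >= 3:
        return 2
    if n_doses >= 2 and has_control:
        return 1
    return 0


class SizeContext(str, Enum):
    """Advisory absorption context for a particle's median size, after oral
    exposure: particles above 150 um are unlikely to be absorbed (local
    intestinal effects only), particles below 1.5 um can cross the epithelium
    and may induce systemic toxicity."""

    UNLIKELY_ABSORBED_LOCAL_EFFECTS = "unlikely_absorbed_local_effects"
    INTERMEDIATE_LIMITED_ABSORPTION = "intermediate_limited_absorption"
    EPITHELIAL_CROSSING_POSSIBLE = "epithelial_crossing_possible"


def particle_size_context(median_size_um: float) -> SizeContext:
    """Classify a median particle size (um) into an absorption context."""
    if median_size_um <= 0:
        raise ValueError("median_size_um must be positive")
    if median_size_um > 150:
        return SizeContext.UNLIKELY_ABSORBED_LOCAL_EFFECTS
    if median_size_um < 1.5:
        return SizeContext.EPITHELIAL_CROSSING_POSSIBLE
    return SizeContext.INTERMEDIATE_LIMITED_ABSORPTION
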