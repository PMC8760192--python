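"""Study screening and classification schemes.

Three schemes are implemented and can be contrasted on the same corpus:

* **Red-criteria Tier-1 gate** — a study passing scores at least 1 (by
  default) on every red (critical) criterion, regardless of its TAS, and is
  prioritized for Tier-2 expert elicitation.
* **Fernández-Cruz reliability classes** — reliable (> 85% of criteria at the
  maximum score, critical criteria met), reliable with restrictions (61-85%,
  critical met), otherwise not reliable.  The default basis is the fraction of
  criteria at the maximum; the TAS-percent basis is offered as an alternative
  because a 3-level rubric makes the two framings diverge (an all-ones study
  sits at 50% of the maximum TAS yet has no criterion at the maximum, hence
  is not reliable either way).
* **de Ruijter adequacy** — adequate only if no criterion scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence, Union

from .registry import CriteriaRegistry
from .scoring import (
    Evaluation,
    EvaluationError,
    ScoreSummary,
    summarize,
    validate_evaluation,
)

__all__ = [
    "ClassificationBasis",
    "ClassificationConfig",
    "FernandezClass",
    "ScreeningResult",
    "red_criteria_check",
    "fernandez_cruz_class",
    "de_ruijter_adequate",
    "screen_study",
    "tier1_screen",
]


class ClassificationBasis(str, Enum):
    MAX_SCORE_FRACTION = "max_score_fraction"
    TAS_PERCENT = "tas_percent"


class FernandezClass(str, Enum):
    RELIABLE = "reliable"
    RELIABLE_WITH_RESTRICTIONS = "reliable_with_restrictions"
    NOT_RELIABLE = "not_reliable"


@dataclass(frozen=True)
class ClassificationConfig:
    """Cut-offs and gate levels for the classification schemes.

    ``reliable_cutoff`` is strict (> 0.85 for reliable); ``restricted_lower``
    is inclusive (fraction exactly 0.61 is reliable with restrictions, as is
    exactly 0.85).  ``red_min_level`` is the minimum level every red criterion
    must reach to pass the Tier-1 gate.
    """

    basis: ClassificationBasis = ClassificationBasis.MAX_SCORE_FRACTION
    reliable_cutoff: float = 0.85
    restricted_lower: float = 0.61
    red_min_level: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.restricted_lower <= self.reliable_cutoff < 1:
            raise ValueError(
                "need 0 < restricted_lower <= reliable_cutoff < 1, got "
                f"{self.restricted_lower} / {self.reliable_cutoff}"
            )
        if self.red_min_level not in (1, 2):
            raise ValueError("red_min_level must be 1 or 2")


@dataclass(frozen=True)
class ScreeningResult:
    """All three scheme outcomes plus the score statistics they derive from."""

    study_id: str
    red_pass: bool
    failing_red: tuple[str, ...]
    fernandez_class: FernandezClass
    de_ruijter_adequate: bool
    tier1_prioritized: bool
    tas: int
    tas_max: int
    tas_percent: int
    max_score_fraction: float


def _require_valid(ev: Evaluation, reg: CriteriaRegistry) -> None:
    issues = validate_evaluation(ev, reg)
    if issues:
        raise EvaluationError(issues)


def red_criteria_check(
    ev: Evaluation,
    reg: CriteriaRegistry,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> tuple[bool, list[str]]:
    """Pass iff every red criterion scores >= cfg.red_min_level.

    Returns (passed, failing ids in registry order).  The result does not
    depend on the TAS: a study scoring 1 on every red criterion and 0 on
    everything else still passes.
    """
    _require_valid(ev, reg)
    red = reg.red_ids
    if not red:
        raise ValueError(
            "registry defines no red criteria; the Tier-1 gate is undefined"
        )
    failing = [cid for cid in red if ev.scores[cid] < cfg.red_min_level]
    return (not failing, failing)


def fernandez_cruz_class(
    ev: Evaluation,
    reg: CriteriaRegistry,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> FernandezClass:
    """Reliability class from the configured basis and the red-criteria gate."""
    _require_valid(ev, reg)
    summary = summarize(ev, reg)
    if cfg.basis is ClassificationBasis.MAX_SCORE_FRACTION:
        value = summary.max_score_fraction
    else:
        value = summary.tas / summary.tas_max
    red_pass, _ = red_criteria_check(ev, reg, cfg)
    if not red_pass:
        return FernandezClass.NOT_RELIABLE
    if value > cfg.reliable_cutoff:
        return FernandezClass.RELIABLE
    if value >= cfg.restricted_lower:
        return FernandezClass.RELIABLE_WITH_RESTRICTIONS
    return FernandezClass.NOT_RELIABLE


def de_ruijter_adequate(ev: Evaluation, reg: CriteriaRegistry) -> bool:
    """Adequate iff every criterion scores at least 1 (no zeros anywhere)."""
    _require_valid(ev, reg)
    return all(ev.scores[cid] >= 1 for cid in reg.ids)


def screen_study(
    ev: Evaluation,
    reg: CriteriaRegistry,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> ScreeningResult:
    """Apply all three schemes to one evaluation."""
    summary = summarize(ev, reg)
    red_pass, failing = red_criteria_check(ev, reg, cfg)
    return ScreeningResult(
        study_id=ev.study_id,
        red_pass=red_pass,
        failing_red=tuple(failing),
        fernandez_class=fernandez_cruz_class(ev, reg, cfg),
        de_ruijter_adequate=de_ruijter_adequate(ev, reg),
        tier1_prioritized=red_pass,
        tas=summary.tas,
        tas_max=summary.tas_max,
        tas_percent=summary.tas_percent,
        max_score_fraction=summary.max_score_fraction,
    )


def tier1_screen(
    corpus: Sequence[Evaluation],
    reg: CriteriaRegistry,
    cfg: ClassificationConfig = ClassificationConfig(),
) -> list[ScreeningResult]:
    """Screen a corpus; prioritized studies are exactly the red-pass studies.

    Output order is deterministic: prioritized first, then TAS descending,
    then study_id ascending — a stable report order independent of input
    order.  All evaluations must share the registry's study system.
    """
    for ev in corpus:
        meta = getattr(ev, "metadata", None)
        if meta is not None and meta.study_system != reg.study_system:
            raise ValueError(
                f"evaluation {ev.study_id!r} is {meta.study_system.value} but "
                f"registry is {reg.study_system.value}; screen systems separately"
            )
    results = [screen_study(ev, reg, cfg) for ev in corpus]
    results.sort(key=lambda r: (not r.tier1_prioritized, -r.tas, r.study_id))
    return results
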