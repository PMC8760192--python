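"""QA/QC criteria registries for nano- and microplastic toxicity study assessment.

A registry is the rubric: an ordered list of criteria, each scored 0/1/2
(inadequate / adequate with restrictions / adequate), grouped into three
assessment areas — particle characterization, study design and applicability
for risk assessment.  A subset of criteria is flagged "red" (critical): a
study must score at least 1 on every red criterion to pass Tier-1 screening.
Red sets are configurable; the shipped defaults follow the SCCWRP Health
Effects Workshop recommendation (particle size, shape, polymer type, source,
plus the risk-assessment criteria on endpoints, dose-response and — in vivo —
effect thresholds).

Two defaults ship with the package: an in vivo registry with 26 criteria
(maximum total assessment score, TAS, of 52) and an in vitro registry with 23
criteria (maximum TAS 46).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Mapping, Optional, Union

import yaml

__all__ = [
    "Category",
    "StudySystem",
    "Criterion",
    "CriteriaRegistry",
    "Issue",
    "RegistryFormatError",
    "RegistryValidationError",
    "load_registry",
    "write_registry",
    "validate_registry",
    "default_registry",
    "max_tas",
]

MAX_SCORE = 2
SCORE_LEVELS = (0, 1, 2)


class Category(str, Enum):
    """The three assessment areas every criterion belongs to."""

    PARTICLE_CHARACTERIZATION = "particle_characterization"
    STUDY_DESIGN = "study_design"
    RISK_ASSESSMENT = "risk_assessment"


class StudySystem(str, Enum):
    IN_VIVO = "in_vivo"
    IN_VITRO = "in_vitro"


class RegistryFormatError(ValueError):
    """The registry source could not be parsed as YAML/JSON."""


class RegistryValidationError(ValueError):
    """The parsed registry violates the schema; carries the issue list."""

    def __init__(self, issues: list["Issue"]):
        self.issues = issues
        super().__init__(
            "invalid registry: " + "; ".join(str(i) for i in issues)
        )


@dataclass(frozen=True)
class Issue:
    """One validation finding.  Issues are data, not exceptions."""

    rule: str
    message: str
    criterion_id: Optional[str] = None

    def __str__(self) -> str:
        where = f" [{self.criterion_id}]" if self.criterion_id else ""
        return f"{self.rule}{where}: {self.message}"


@dataclass(frozen=True)
class Criterion:
    """A single QA/QC criterion scored 0 (inadequate), 1 (adequate with
    restrictions) or 2 (adequate)."""

    id: str
    label: str
    category: Category
    red: bool = False
    score_guidance: Mapping[int, str] = field(default_factory=dict)
    applicability_note: Optional[str] = None


@dataclass(frozen=True)
class CriteriaRegistry:
    """An ordered rubric of criteria for one study system."""

    name: str
    version: str
    study_system: StudySystem
    criteria: tuple[Criterion, ...]
    max_score_per_criterion: int = MAX_SCORE

    def __len__(self) -> int:
        return len(self.criteria)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    @property
    def red_ids(self) -> tuple[str, ...]:
        """Red (critical) criterion ids, in registry order."""
        return tuple(c.id for c in self.criteria if c.red)

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(criterion_id)

    def by_category(self, category: Category) -> tuple[Criterion, ...]:
        return tuple(c for c in self.criteria if c.category == category)

    @property
    def max_tas(self) -> int:
        return self.max_score_per_criterion * len(self.criteria)


def max_tas(reg: CriteriaRegistry) -> int:
    """Maximum achievable total assessment score: 2 x number of criteria
    (52 for the default in vivo registry, 46 in vitro)."""
    return reg.max_tas


def _criterion_from_mapping(raw: Mapping, issues: list[Issue]) -> Optional[Criterion]:
    cid = raw.get("id")
    if not cid or not isinstance(cid, str):
        issues.append(Issue("missing_id", "criterion without a string id"))
        return None
    label = raw.get("label", "")
    try:
        category = Category(raw.get("category"))
    except ValueError:
        issues.append(
            Issue(
                "bad_category",
                f"category {raw.get('category')!r} is not one of "
                f"{[c.value for c in Category]}",
                criterion_id=cid,
            )
        )
        return None
    guidance_raw = raw.get("score_guidance", {}) or {}
    guidance: dict[int, str] = {}
    for key, text in guidance_raw.items():
        try:
            level = int(key)
        except (TypeError, ValueError):
            issues.append(
                Issue("bad_guidance_level", f"non-integer guidance level {key!r}", cid)
            )
            continue
        guidance[level] = str(text)
    return Criterion(
        id=cid,
        label=str(label),
        category=category,
        red=bool(raw.get("red", False)),
        score_guidance=guidance,
        applicability_note=raw.get("applicability_note"),
    )


def _registry_from_mapping(data: Mapping) -> CriteriaRegistry:
    if not isinstance(data, Mapping):
        raise RegistryValidationError(
            [Issue("bad_document", "registry document must be a mapping")]
        )
    issues: list[Issue] = []
    try:
        system = StudySystem(data.get("study_system"))
    except ValueError:
        raise RegistryValidationError(
            [
                Issue(
                    "bad_study_system",
                    f"study_system {data.get('study_system')!r} is not one of "
                    f"{[s.value for s in StudySystem]}",
                )
            ]
        ) from None
    raw_criteria = data.get("criteria")
    if not isinstance(raw_criteria, list) or not raw_criteria:
        raise RegistryValidationError(
            [Issue("no_criteria", "registry has no criteria list")]
        )
    criteria = []
    for raw in raw_criteria:
        crit = _criterion_from_mapping(raw, issues)
        if crit is not None:
            criteria.append(crit)
    if issues:
        raise RegistryValidationError(issues)
    reg = CriteriaRegistry(
        name=str(data.get("name", "")),
        version=str(data.get("version", "")),
        study_system=system,
        criteria=tuple(criteria),
    )
    issues = validate_registry(reg, require_defaults=False)
    if issues:
        raise RegistryValidationError(issues)
    return reg


def load_registry(
    source: Union[str, Path, IO[str]], format: Optional[str] = None
) -> CriteriaRegistry:
    """Load a criteria registry from a YAML or JSON file or stream.

    The two dialects are semantically identical; ``format`` is inferred from
    the filename extension when not given (streams default to YAML, which is
    a superset of JSON).

    Raises
    ------
    RegistryFormatError
        If the source does not parse; the message names the offending line
        where the parser reports one.
    RegistryValidationError
        If the document parses but violates the registry schema; carries the
        list of :class:`Issue` records.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        if format is None:
            format = "json" if path.suffix.lower() == ".json" else "yaml"
        text = path.read_text(encoding="utf-8")
        name = str(path)
    else:
        text = source.read()
        name = getattr(source, "name", "<stream>")
        if format is None:
            format = "yaml"
    if format not in ("yaml", "json"):
        raise ValueError(f"unknown registry format {format!r}")
    try:
        if format == "json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except json.JSONDecodeError as exc:
        raise RegistryFormatError(
            f"{name}: JSON parse error at line {exc.lineno}: {exc.msg}"
        ) from exc
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise RegistryFormatError(f"{name}: YAML parse error{line}: {exc}") from exc
    return _registry_from_mapping(data)


def _registry_to_mapping(reg: CriteriaRegistry) -> dict:
    out: dict = {
        "name": reg.name,
        "version": reg.version,
        "study_system": reg.study_system.value,
        "criteria": [],
    }
    for c in reg.criteria:
        entry: dict = {
            "id": c.id,
            "label": c.label,
            "category": c.category.value,
            "red": c.red,
            "score_guidance": {str(k): v for k, v in sorted(c.score_guidance.items())},
        }
        if c.applicability_note is not None:
            entry["applicability_note"] = c.applicability_note
        out["criteria"].append(entry)
    return out


def write_registry(
    reg: CriteriaRegistry, path: Union[str, Path], format: Optional[str] = None
) -> None:
    """Write a registry to YAML or JSON; round-trips through load_registry."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "yaml"
    data = _registry_to_mapping(reg)
    if format == "json":
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
    elif format == "yaml":
        path.write_text(
            yaml.safe_dump(data, sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )
    else:
        raise ValueError(f"unknown registry format {format!r}")


def validate_registry(
    reg: CriteriaRegistry, require_defaults: bool = True
) -> list[Issue]:
    """Check registry invariants; returns an empty list iff the registry is valid.

    With ``require_defaults`` (the default), a registry with an empty red set
    is reported, since Tier-1 screening is undefined without red criteria.
    """
    issues: list[Issue] = []
    seen: set[str] = set()
    for c in reg.criteria:
        if c.id in seen:
            issues.append(Issue("duplicate_id", "criterion id appears twice", c.id))
        seen.add(c.id)
        if not c.label:
            issues.append(Issue("empty_label", "criterion has no label", c.id))
        missing = [lvl for lvl in SCORE_LEVELS if lvl not in c.score_guidance]
        extra = [lvl for lvl in c.score_guidance if lvl not in SCORE_LEVELS]
        if missing:
            issues.append(
                Issue(
                    "incomplete_guidance",
                    f"missing guidance for level(s) {missing}",
                    c.id,
                )
            )
        if extra:
            issues.append(
                Issue("extra_guidance", f"guidance for unknown level(s) {extra}", c.id)
            )
    if reg.max_score_per_criterion != MAX_SCORE:
        issues.append(
            Issue(
                "bad_max_score",
                f"max_score_per_criterion must be {MAX_SCORE}, "
                f"got {reg.max_score_per_criterion}",
            )
        )
    if require_defaults and not reg.red_ids:
        issues.append(Issue("no_red_criteria", "registry defines no red criteria"))
    return issues


_DEFAULT_FILES = {
    StudySystem.IN_VIVO: "nmp_tsat_invivo_v1.yaml",
    StudySystem.IN_VITRO: "nmp_tsat_invitro_v1.yaml",
}
_DEFAULT_CACHE: dict[StudySystem, CriteriaRegistry] = {}


def default_registry(study_system: Union[str, StudySystem]) -> CriteriaRegistry:
    """The shipped default registry for a study system.

    ``in_vivo`` has 26 criteria (8 particle characterization, 13 study design,
    5 risk assessment; max TAS 52); ``in_vitro`` has 23 (8 + 11 + 4; max TAS 46).
    """
    try:
        system = StudySystem(study_system)
    except ValueError:
        raise ValueError(
            f"unknown study system {study_system!r}; expected one of "
            f"{[s.value for s in StudySystem]}"
        ) from None
    if system not in _DEFAULT_CACHE:
        ref = resources.files("nmp_tsat.registries") / _DEFAULT_FILES[system]
        with ref.open("r", encoding="utf-8") as fh:
            _DEFAULT_CACHE[system] = load_registry(fh, format="yaml")
    return _DEFAULT_CACHE[system]
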