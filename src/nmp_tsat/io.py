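"""Evaluation and metadata sheet readers/writers.

Evaluation sheets are long-format delimited text, one row per
(study, rater, criterion) score, columns exactly::

    study_id, rater_id, study_system, criterion_id, score

Metadata sheets carry one row per (study_id, study_system)::

    study_id, citation, year, study_system, exposure_route, material_class,
    polymer, shape, median_size_um

Both are UTF-8 with a header row; the delimiter is inferred from the
extension (.tsv/.tab -> tab, otherwise comma).  Malformed rows are reported
with their line numbers; unknown criterion ids (when a registry is supplied)
and duplicate (study, rater, criterion) rows are errors.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Optional, Sequence, Union

from .registry import CriteriaRegistry, StudySystem
from .scoring import (
    ExposureRoute,
    MaterialClass,
    Shape,
    StudyEvaluation,
    StudyMeta,
)

__all__ = [
    "SheetError",
    "read_evaluations",
    "write_evaluations",
    "read_metadata",
    "write_metadata",
    "attach_metadata",
]

EVAL_COLUMNS = ("study_id", "rater_id", "study_system", "criterion_id", "score")
META_COLUMNS = (
    "study_id",
    "citation",
    "year",
    "study_system",
    "exposure_route",
    "material_class",
    "polymer",
    "shape",
    "median_size_um",
)


class SheetError(ValueError):
    """A sheet failed to parse; collects per-line problem messages."""

    def __init__(self, path, problems: Sequence[str]):
        self.path = str(path)
        self.problems = list(problems)
        lines = "\n  ".join(self.problems)
        super().__init__(f"{self.path}:\n  {lines}")


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_evaluations(
    path: Union[str, Path], registry: Optional[CriteriaRegistry] = None
) -> list[StudyEvaluation]:
    """Read a long-format evaluation sheet into per-rater evaluations.

    Rows are grouped by (study_id, study_system, rater_id); the order of
    first appearance is preserved.  When ``registry`` is given, criterion ids
    not in the registry are an error (listed with their line numbers).
    Completeness against the registry is not enforced here — that is
    :func:`nmp_tsat.scoring.validate_evaluation`'s job.
    """
    path = Path(path)
    problems: list[str] = []
    groups: dict[tuple[str, str, str], dict[str, int]] = {}
    known = set(registry.ids) if registry is not None else None
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=_delimiter(path))
        try:
            header = next(reader)
        except StopIteration:
            raise SheetError(path, ["empty file (header row required)"]) from None
        if tuple(h.strip() for h in header) != EVAL_COLUMNS:
            raise SheetError(
                path,
                [
                    f"line 1: expected header {','.join(EVAL_COLUMNS)}, "
                    f"got {','.join(header)}"
                ],
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(EVAL_COLUMNS):
                problems.append(
                    f"line {lineno}: expected {len(EVAL_COLUMNS)} fields, got {len(row)}"
                )
                continue
            study_id, rater_id, system, criterion_id, score_text = (
                cell.strip() for cell in row
            )
            try:
                StudySystem(system)
            except ValueError:
                problems.append(
                    f"line {lineno}: unknown study_system {system!r}"
                )
                continue
            try:
                score = int(score_text)
                if score not in (0, 1, 2):
                    raise ValueError
            except ValueError:
                problems.append(
                    f"line {lineno}: score {score_text!r} is not 0, 1 or 2"
                )
                continue
            if known is not None and criterion_id not in known:
                problems.append(
                    f"line {lineno}: unknown criterion id {criterion_id!r}"
                )
                continue
            key = (study_id, system, rater_id)
            scores = groups.setdefault(key, {})
            if criterion_id in scores:
                problems.append(
                    f"line {lineno}: duplicate row for "
                    f"({study_id}, {rater_id}, {criterion_id})"
                )
                continue
            scores[criterion_id] = score
    if problems:
        raise SheetError(path, problems)
    registry_name = registry.name if registry is not None else ""
    return [
        StudyEvaluation(
            study_id=study_id,
            rater_id=rater_id,
            registry_name=registry_name,
            scores=scores,
        )
        for (study_id, system, rater_id), scores in groups.items()
    ]


def write_evaluations(
    evals: Sequence[StudyEvaluation],
    path: Union[str, Path],
    study_system: Optional[StudySystem] = None,
) -> None:
    """Write evaluations back to a long-format sheet (lossless round-trip).

    The sheet's study_system column is taken from each evaluation's metadata
    when present, else from ``study_system``.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path), lineterminator="\n")
        writer.writerow(EVAL_COLUMNS)
        for ev in evals:
            if ev.metadata is not None:
                system = ev.metadata.study_system.value
            elif study_system is not None:
                system = StudySystem(study_system).value
            else:
                raise ValueError(
                    f"evaluation {ev.study_id!r} has no metadata; pass study_system"
                )
            for cid, level in ev.scores.items():
                writer.writerow([ev.study_id, ev.rater_id, system, cid, level])


def read_metadata(path: Union[str, Path]) -> dict[tuple[str, str], StudyMeta]:
    """Read a metadata sheet keyed by (study_id, study_system)."""
    path = Path(path)
    problems: list[str] = []
    out: dict[tuple[str, str], StudyMeta] = {}
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=_delimiter(path))
        try:
            header = next(reader)
        except StopIteration:
            raise SheetError(path, ["empty file (header row required)"]) from None
        if tuple(h.strip() for h in header) != META_COLUMNS:
            raise SheetError(
                path,
                [
                    f"line 1: expected header {','.join(META_COLUMNS)}, "
                    f"got {','.join(header)}"
                ],
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) != len(META_COLUMNS):
                problems.append(
                    f"line {lineno}: expected {len(META_COLUMNS)} fields, got {len(row)}"
                )
                continue
            (
                study_id,
                citation,
                year,
                system,
                route,
                material,
                polymer,
                shape,
                size,
            ) = (cell.strip() for cell in row)
            try:
                meta = StudyMeta(
                    citation=citation,
                    year=int(year),
                    study_system=StudySystem(system),
                    exposure_route=ExposureRoute(route) if route else ExposureRoute.OTHER,
                    material_class=MaterialClass(material)
                    if material
                    else MaterialClass.OTHER,
                    polymer=polymer or None,
                    shape=Shape(shape) if shape else None,
                    median_size_um=float(size) if size else None,
                )
            except ValueError as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
            key = (study_id, system)
            if key in out:
                problems.append(
                    f"line {lineno}: duplicate metadata for {key}"
                )
                continue
            out[key] = meta
    if problems:
        raise SheetError(path, problems)
    return out


def write_metadata(
    meta: dict[tuple[str, str], StudyMeta], path: Union[str, Path]
) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path), lineterminator="\n")
        writer.writerow(META_COLUMNS)
        for (study_id, system), m in meta.items():
            writer.writerow(
                [
                    study_id,
                    m.citation,
                    m.year,
                    system,
                    m.exposure_route.value,
                    m.material_class.value,
                    m.polymer or "",
                    m.shape.value if m.shape else "",
                    m.median_size_um if m.median_size_um is not None else "",
                ]
            )


def attach_metadata(
    evals: Sequence[StudyEvaluation],
    meta: dict[tuple[str, str], StudyMeta],
    study_system: StudySystem,
) -> list[StudyEvaluation]:
    """Return evaluations with metadata attached where available."""
    out = []
    for ev in evals:
        key = (ev.study_id, StudySystem(study_system).value)
        if key in meta:
            ev = StudyEvaluation(
                study_id=ev.study_id,
                rater_id=ev.rater_id,
                registry_name=ev.registry_name,
                scores=ev.scores,
                metadata=meta[key],
            )
        out.append(ev)
    return out
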