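"""Corpus-level analytics: per-criterion score distributions, TAS league
statistics, stratified metadata summaries, and the prioritization table.

Evaluations entering a corpus should already be consensus-merged (one score
map per study per study system) and carry metadata for stratification.
Distributions are stratified by (study_system, exposure_route,
material_class); TAS statistics are reported per study system and overall.
The TAS mean is kept unrounded internally — its percent-of-maximum is
computed from the unrounded mean and only display-rounded in reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .registry import Category, CriteriaRegistry
from .scoring import Evaluation, ScoreSummary, summarize
from .screening import ScreeningResult

__all__ = [
    "Stratum",
    "CriterionDistribution",
    "StratumStats",
    "CorpusSummary",
    "criterion_distributions",
    "distributions_frame",
    "corpus_summary",
    "prioritization_table",
]


@dataclass(frozen=True)
class Stratum:
    study_system: str
    exposure_route: str
    material_class: str


@dataclass(frozen=True)
class CriterionDistribution:
    """How many studies in one stratum scored 0 / 1 / 2 on one criterion."""

    criterion_id: str
    category: Category
    stratum: Stratum
    counts: Mapping[int, int]

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class StratumStats:
    n_studies: int
    tas_min: int
    tas_max: int
    tas_mean: float
    tas_mean_percent: float  # from the unrounded mean


@dataclass(frozen=True)
class CorpusSummary:
    """TAS league statistics per stratum plus particle metadata summaries."""

    strata: Mapping[str, StratumStats]
    size_median_um: Optional[float]
    size_mean_um: Optional[float]
    size_sd_um: Optional[float]
    polymer_counts: Mapping[str, int]
    shape_counts: Mapping[str, int]


def _stratum_of(ev: Evaluation) -> Stratum:
    meta = getattr(ev, "metadata", None)
    if meta is None:
        raise ValueError(
            f"evaluation {ev.study_id!r} has no metadata; corpus analytics "
            "require study metadata for stratification"
        )
    return Stratum(
        study_system=meta.study_system.value,
        exposure_route=meta.exposure_route.value,
        material_class=meta.material_class.value,
    )


def criterion_distributions(
    corpus: Sequence[Evaluation], reg: CriteriaRegistry
) -> list[CriterionDistribution]:
    """One record per (criterion, stratum); counts partition the stratum."""
    if not corpus:
        return []
    by_stratum: dict[Stratum, list[Evaluation]] = {}
    for ev in corpus:
        by_stratum.setdefault(_stratum_of(ev), []).append(ev)
    out: list[CriterionDistribution] = []
    for stratum in sorted(
        by_stratum, key=lambda s: (s.study_system, s.exposure_route, s.material_class)
    ):
        evals = by_stratum[stratum]
        for crit in reg.criteria:
            counts = {0: 0, 1: 0, 2: 0}
            for ev in evals:
                counts[ev.scores[crit.id]] += 1
            out.append(
                CriterionDistribution(
                    criterion_id=crit.id,
                    category=crit.category,
                    stratum=stratum,
                    counts=counts,
                )
            )
    return out


def distributions_frame(
    distributions: Sequence[CriterionDistribution],
) -> pd.DataFrame:
    """Distribution records as a flat table (the distribution CSV layout)."""
    rows = [
        {
            "criterion_id": d.criterion_id,
            "category": d.category.value,
            "study_system": d.stratum.study_system,
            "exposure_route": d.stratum.exposure_route,
            "material_class": d.stratum.material_class,
            "n0": d.counts[0],
            "n1": d.counts[1],
            "n2": d.counts[2],
        }
        for d in distributions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "criterion_id",
            "category",
            "study_system",
            "exposure_route",
            "material_class",
            "n0",
            "n1",
            "n2",
        ],
    )


def corpus_summary(
    corpus: Sequence[Evaluation], reg: CriteriaRegistry
) -> CorpusSummary:
    """TAS min/mean/max per study system and overall, particle-size summary
    (per-study reported median sizes), and polymer/shape frequency tables."""
    if not corpus:
        raise ValueError("no evaluations")
    summaries = [summarize(ev, reg) for ev in corpus]
    systems = pd.Series(
        [_stratum_of(ev).study_system for ev in corpus], dtype="object"
    )
    tas = pd.Series([s.tas for s in summaries])
    tmax = reg.max_tas

    def stats(mask: pd.Series) -> StratumStats:
        sub = tas[mask]
        mean = float(sub.mean())
        return StratumStats(
            n_studies=int(mask.sum()),
            tas_min=int(sub.min()),
            tas_max=int(sub.max()),
            tas_mean=mean,
            tas_mean_percent=100.0 * mean / tmax,
        )

    strata = {"all": stats(pd.Series(True, index=tas.index))}
    for system in sorted(systems.unique()):
        strata[system] = stats(systems == system)

    sizes = [
        ev.metadata.median_size_um
        for ev in corpus
        if ev.metadata is not None and ev.metadata.median_size_um is not None
    ]
    if sizes:
        arr = np.asarray(sizes, dtype=float)
        size_median = float(np.median(arr))
        size_mean = float(arr.mean())
        size_sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    else:
        size_median = size_mean = size_sd = None

    polymers = pd.Series(
        [
            ev.metadata.polymer
            for ev in corpus
            if ev.metadata is not None and ev.metadata.polymer
        ],
        dtype="object",
    )
    shapes = pd.Series(
        [
            ev.metadata.shape.value
            for ev in corpus
            if ev.metadata is not None and ev.metadata.shape is not None
        ],
        dtype="object",
    )
    return CorpusSummary(
        strata=strata,
        size_median_um=size_median,
        size_mean_um=size_mean,
        size_sd_um=size_sd,
        polymer_counts={k: int(v) for k, v in polymers.value_counts().sort_index().items()}
        if not polymers.empty
        else {},
        shape_counts={k: int(v) for k, v in shapes.value_counts().sort_index().items()}
        if not shapes.empty
        else {},
    )


def prioritization_table(
    corpus: Sequence[Evaluation],
    results: Sequence[ScreeningResult],
    annotations: Optional[Mapping[str, tuple[str, str]]] = None,
    warn: Optional[list] = None,
) -> pd.DataFrame:
    """Tier-1 prioritization report: one row per red-pass study, ordered by
    TAS descending then study_id, with optional strengths/weaknesses text.

    ``annotations`` maps study_id -> (strengths, weaknesses).  Annotations for
    unknown study ids are collected into ``warn`` (if given) rather than
    raising.
    """
    annotations = dict(annotations or {})
    meta_by_id = {
        ev.study_id: getattr(ev, "metadata", None) for ev in corpus
    }
    known = {r.study_id for r in results}
    for sid in sorted(set(annotations) - known):
        msg = f"annotation for unknown study_id {sid!r} ignored"
        if warn is not None:
            warn.append(msg)
    rows = []
    for r in sorted(
        (r for r in results if r.tier1_prioritized),
        key=lambda r: (-r.tas, r.study_id),
    ):
        meta = meta_by_id.get(r.study_id)
        strengths, weaknesses = annotations.get(r.study_id, ("", ""))
        rows.append(
            {
                "study_id": r.study_id,
                "author_year": meta.citation if meta is not None else r.study_id,
                "strengths": strengths,
                "weaknesses": weaknesses,
                "tas": r.tas,
                "tas_max": r.tas_max,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["study_id", "author_year", "strengths", "weaknesses", "tas", "tas_max"],
    )
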