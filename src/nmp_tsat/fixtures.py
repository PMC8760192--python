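"""Synthetic-corpus fixture generator.

Generates multi-rater evaluation corpora whose min-consensus TAS hits
prescribed targets exactly, with optional red-criteria constraints and
seeded rater disagreement.  Used both for testing and for reproducing
corpora with a known TAS column, such as the 15 prioritized in vivo studies
(TAS 44, 37, 37, 34, 34, 34, 34, 31, 30, 30, 27, 27, 27, 27, 23 of 52).

Score composition: the target TAS is distributed over criteria by seeded
random increments.  When the study must pass the red gate, every red
criterion is first floored at the gate level; remaining points are then
assigned one at a time to uniformly chosen criteria below the per-criterion
maximum of 2.  An anchor rater carries this base composition; additional
raters deviate by one level with probability ``rater_noise``, clamped to
[base, 2], so the pointwise minimum across raters — and hence the
min-consensus TAS — equals the target while discordance still occurs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .registry import CriteriaRegistry, StudySystem, default_registry
from .scoring import (
    ExposureRoute,
    MaterialClass,
    Shape,
    StudyEvaluation,
    StudyMeta,
)

__all__ = [
    "StudyTarget",
    "FixtureSpec",
    "generate_fixture",
    "table1_fixture_spec",
    "load_fixture_spec",
    "TABLE1_TAS",
]

#: TAS (/52) column of the 15 prioritized in vivo studies, report order.
TABLE1_TAS = (44, 37, 37, 34, 34, 34, 34, 31, 30, 30, 27, 27, 27, 27, 23)

DEFAULT_RED_MIN = 1


@dataclass(frozen=True)
class StudyTarget:
    """One study's fixture prescription."""

    study_id: str
    target_tas: int
    must_pass_red: bool = True
    metadata: Optional[StudyMeta] = None


@dataclass(frozen=True)
class FixtureSpec:
    """A full fixture prescription: registry, per-study targets, rater count
    and disagreement rate, and the seed making generation deterministic."""

    registry: Union[str, CriteriaRegistry]
    studies: tuple[StudyTarget, ...]
    n_raters: int = 2
    rater_noise: float = 0.1
    seed: int = 0
    red_min_level: int = DEFAULT_RED_MIN

    def resolve_registry(self) -> CriteriaRegistry:
        if isinstance(self.registry, CriteriaRegistry):
            return self.registry
        return default_registry(self.registry)


def _compose_scores(
    rng: np.random.Generator,
    reg: CriteriaRegistry,
    target: StudyTarget,
    red_min: int,
) -> dict[str, int]:
    ids = list(reg.ids)
    cap = reg.max_score_per_criterion
    scores = {cid: 0 for cid in ids}
    floor_total = 0
    if target.must_pass_red:
        for cid in reg.red_ids:
            scores[cid] = red_min
        floor_total = red_min * len(reg.red_ids)
    lo, hi = floor_total, cap * len(ids)
    if not lo <= target.target_tas <= hi:
        raise ValueError(
            f"study {target.study_id!r}: target TAS {target.target_tas} "
            f"infeasible; feasible range is [{lo}, {hi}]"
        )
    remaining = target.target_tas - floor_total
    while remaining > 0:
        open_ids = [cid for cid in ids if scores[cid] < cap]
        cid = open_ids[rng.integers(len(open_ids))]
        scores[cid] += 1
        remaining -= 1
    return scores


def generate_fixture(spec: FixtureSpec) -> list[StudyEvaluation]:
    """Generate the per-rater evaluation corpus prescribed by ``spec``.

    Deterministic given the seed.  For every study,
    ``summarize(consensus(evals, "min"))`` yields exactly the target TAS, and
    red criteria stay at or above the gate level when required.
    """
    reg = spec.resolve_registry()
    if spec.n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    if not 0 <= spec.rater_noise <= 1:
        raise ValueError("rater_noise must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    out: list[StudyEvaluation] = []
    for target in spec.studies:
        base = _compose_scores(rng, reg, target, spec.red_min_level)
        for k in range(spec.n_raters):
            if k == 0:
                scores = dict(base)
            else:
                scores = {}
                for cid, level in base.items():
                    if rng.random() < spec.rater_noise:
                        proposal = level + rng.choice((-1, 1))
                        # clamp to [base, 2]: disagreement never drags the
                        # pointwise minimum below the composed target
                        scores[cid] = int(
                            min(reg.max_score_per_criterion, max(level, proposal))
                        )
                    else:
                        scores[cid] = level
            out.append(
                StudyEvaluation(
                    study_id=target.study_id,
                    rater_id=f"rater_{k + 1}",
                    registry_name=reg.name,
                    scores=scores,
                    metadata=target.metadata,
                )
            )
    return out


# (study_id, citation, year, route, material, polymer, shape, TAS/52)
_TABLE1_ROWS = (
    ("ong_2020", "Ong et al. (2020)", 2020, "oral", "cellulose", "cellulose", "fibre", 44),
    ("lim_2021", "Lim et al. (2021)", 2021, "inhalation", "nmp", "polystyrene", "sphere", 37),
    ("mahock_2012", "Ma-Hock et al. (2012)", 2012, "inhalation", "nmp", "acrylic-ester", "other", 37),
    ("amereh_2019", "Amereh et al. (2019)", 2019, "oral", "nmp", "polystyrene", "sphere", 34),
    ("amereh_2020", "Amereh et al. (2020)", 2020, "oral", "nmp", "polystyrene", "sphere", 34),
    ("deng_2017", "Deng et al. (2017)", 2017, "oral", "nmp", "polystyrene", "sphere", 34),
    ("dolan_2016", "Dolan et al. (2016)", 2016, "oral", "cellulose", "cellulose", "fibre", 34),
    ("an_2021", "An et al. (2021)", 2021, "oral", "nmp", "polystyrene", "sphere", 31),
    ("kotkoskie_1996", "Kotkoskie et al. (1996)", 1996, "oral", "cellulose", "cellulose", "fibre", 30),
    ("park_2020", "Park et al. (2020)", 2020, "oral", "nmp", "polyethylene", "sphere", 30),
    ("hou_2020", "Hou et al. (2020)", 2020, "oral", "nmp", "polystyrene", "sphere", 27),
    ("li_2020a", "Li et al. (2020a)", 2020, "oral", "nmp", "polystyrene", "sphere", 27),
    ("wei_2021", "Wei et al. (2021)", 2021, "oral", "nmp", "polystyrene", "sphere", 27),
    ("xie_2020", "Xie et al. (2020)", 2020, "oral", "nmp", "polystyrene", "sphere", 27),
    ("li_2020b", "Li et al. (2020b)", 2020, "oral", "nmp", "polyethylene", "sphere", 23),
)


def table1_fixture_spec(
    seed: int = 0, n_raters: int = 2, rater_noise: float = 0.1
) -> FixtureSpec:
    """Fixture prescription for the 15 Tier-1 prioritized in vivo studies.

    Targets are the published TAS (/52) values; every study must pass the red
    gate (the studies were prioritized precisely because they score at least
    1 on every red criterion).
    """
    studies = tuple(
        StudyTarget(
            study_id=sid,
            target_tas=tas,
            must_pass_red=True,
            metadata=StudyMeta(
                citation=citation,
                year=year,
                study_system=StudySystem.IN_VIVO,
                exposure_route=ExposureRoute(route),
                material_class=MaterialClass(material),
                polymer=polymer,
                shape=Shape(shape),
            ),
        )
        for sid, citation, year, route, material, polymer, shape, tas in _TABLE1_ROWS
    )
    return FixtureSpec(
        registry="in_vivo",
        studies=studies,
        n_raters=n_raters,
        rater_noise=rater_noise,
        seed=seed,
    )


def load_fixture_spec(path: Union[str, Path]) -> FixtureSpec:
    """Load a fixture prescription from YAML.

    Layout::

        registry: in_vivo            # or a registry file path
        seed: 7
        n_raters: 2
        rater_noise: 0.1
        studies:
          - study_id: s1
            target_tas: 30
            must_pass_red: true
    """
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    registry = data.get("registry", "in_vivo")
    if isinstance(registry, str) and registry not in ("in_vivo", "in_vitro"):
        from .registry import load_registry

        registry = load_registry(registry)
    studies = tuple(
        StudyTarget(
            study_id=str(s["study_id"]),
            target_tas=int(s["target_tas"]),
            must_pass_red=bool(s.get("must_pass_red", True)),
        )
        for s in data.get("studies", [])
    )
    if not studies:
        raise ValueError(f"{path}: fixture spec lists no studies")
    return FixtureSpec(
        registry=registry,
        studies=studies,
        n_raters=int(data.get("n_raters", 2)),
        rater_noise=float(data.get("rater_noise", 0.1)),
        seed=int(data.get("seed", 0)),
    )
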