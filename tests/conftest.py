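import numpy as np
import pytest

from nmp_tsat.registry import (
    Category,
    CriteriaRegistry,
    Criterion,
    StudySystem,
    default_registry,
)
from nmp_tsat.scoring import (
    ExposureRoute,
    MaterialClass,
    StudyEvaluation,
    StudyMeta,
)

GUIDANCE = {0: "inadequate", 1: "adequate with restrictions", 2: "adequate"}


@pytest.fixture(scope="session")
def invivo_reg():
    return default_registry("in_vivo")


@pytest.fixture(scope="session")
def invitro_reg():
    return default_registry("in_vitro")


def make_registry(n, red=("c01",), system=StudySystem.IN_VIVO, name="synthetic"):
    """A synthetic registry of n criteria c01..cNN with a configurable red set."""
    cats = list(Category)
    criteria = tuple(
        Criterion(
            id=f"c{i:02d}",
            label=f"criterion {i}",
            category=cats[i % 3],
            red=f"c{i:02d}" in red,
            score_guidance=GUIDANCE,
        )
        for i in range(1, n + 1)
    )
    return CriteriaRegistry(
        name=name, version="1", study_system=system, criteria=criteria
    )


def make_eval(reg, scores, study_id="s1", rater_id="r1", meta=True):
    """An evaluation over reg; `scores` is an int (uniform), dict, or sequence."""
    if isinstance(scores, int):
        score_map = {cid: scores for cid in reg.ids}
    elif isinstance(scores, dict):
        score_map = {cid: scores.get(cid, 0) for cid in reg.ids}
    else:
        score_map = dict(zip(reg.ids, scores))
    metadata = None
    if meta:
        metadata = StudyMeta(
            citation=f"{study_id} et al.",
            year=2020,
            study_system=reg.study_system,
            exposure_route=ExposureRoute.ORAL,
            material_class=MaterialClass.NMP,
        )
    return StudyEvaluation(
        study_id=study_id,
        rater_id=rater_id,
        registry_name=reg.name,
        scores=score_map,
        metadata=metadata,
    )


def random_eval(reg, rng, study_id="s1", rater_id="r1"):
    levels = rng.integers(0, 3, size=len(reg))
    return make_eval(reg, [int(v) for v in levels], study_id=study_id, rater_id=rater_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
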