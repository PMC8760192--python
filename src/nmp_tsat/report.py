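"""Report rendering: screening CSV, score-summary CSV, markdown reports and
an optional criteria-by-studies heatmap."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .corpus import CorpusSummary
from .registry import CriteriaRegistry
from .scoring import (
    Evaluation,
    ScoreSummary,
    SizeContext,
    particle_size_context,
)
from .screening import ScreeningResult

__all__ = [
    "summaries_frame",
    "screening_frame",
    "summary_json",
    "render_markdown_report",
    "render_heatmap",
]


def summaries_frame(summaries: Sequence[ScoreSummary]) -> pd.DataFrame:
    """ScoreSummary records as the score CSV layout."""
    rows = []
    for s in summaries:
        row = {"study_id": s.study_id}
        for cat, subtotal in s.subtotals.items():
            row[f"subtotal_{cat.value}"] = subtotal
        row.update(
            tas=s.tas,
            tas_max=s.tas_max,
            tas_percent=s.tas_percent,
            max_score_fraction=s.max_score_fraction,
            n_zero=s.n_zero,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def screening_frame(
    results: Sequence[ScreeningResult], study_system: str
) -> pd.DataFrame:
    """ScreeningResult records as the screening CSV layout."""
    rows = [
        {
            "study_id": r.study_id,
            "study_system": study_system,
            "tas": r.tas,
            "tas_max": r.tas_max,
            "tas_percent": r.tas_percent,
            "max_score_fraction": r.max_score_fraction,
            "red_pass": r.red_pass,
            "failing_red": ";".join(r.failing_red),
            "fernandez_class": r.fernandez_class.value,
            "de_ruijter_adequate": r.de_ruijter_adequate,
            "tier1_prioritized": r.tier1_prioritized,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "study_id",
            "study_system",
            "tas",
            "tas_max",
            "tas_percent",
            "max_score_fraction",
            "red_pass",
            "failing_red",
            "fernandez_class",
            "de_ruijter_adequate",
            "tier1_prioritized",
        ],
    )


def summary_json(summary: CorpusSummary) -> str:
    """CorpusSummary as indented JSON."""
    payload = {
        "strata": {
            name: {
                "n_studies": st.n_studies,
                "tas_min": st.tas_min,
                "tas_max": st.tas_max,
                "tas_mean": st.tas_mean,
                "tas_mean_percent": st.tas_mean_percent,
            }
            for name, st in summary.strata.items()
        },
        "particle_size_um": {
            "median": summary.size_median_um,
            "mean": summary.size_mean_um,
            "sd": summary.size_sd_um,
        },
        "polymer_counts": dict(summary.polymer_counts),
        "shape_counts": dict(summary.shape_counts),
    }
    return json.dumps(payload, indent=2)


_SIZE_NOTES = {
    SizeContext.UNLIKELY_ABSORBED_LOCAL_EFFECTS: (
        "> 150 um: unlikely to be absorbed; local intestinal effects possible"
    ),
    SizeContext.INTERMEDIATE_LIMITED_ABSORPTION: (
        "1.5-150 um: limited absorption expected"
    ),
    SizeContext.EPITHELIAL_CROSSING_POSSIBLE: (
        "< 1.5 um: can cross the epithelium; systemic toxicity possible"
    ),
}


def render_markdown_report(
    corpus: Sequence[Evaluation],
    summaries: Sequence[ScoreSummary],
    results: Sequence[ScreeningResult],
    reg: CriteriaRegistry,
    annotations: Optional[Mapping[str, tuple[str, str]]] = None,
    title: str = "Study screening report",
) -> str:
    """Per-study markdown report: TAS, percent, reliability class, red
    failures and advisory particle-size annotations, prioritized studies
    first in the screening order."""
    annotations = dict(annotations or {})
    meta_by_id = {ev.study_id: getattr(ev, "metadata", None) for ev in corpus}
    summary_by_id = {s.study_id: s for s in summaries}
    lines = [
        f"# {title}",
        "",
        f"Registry: {reg.name} v{reg.version} "
        f"({len(reg)} criteria, max TAS {reg.max_tas}, "
        f"{len(reg.red_ids)} red)",
        "",
        f"Studies screened: {len(results)}; "
        f"Tier-1 prioritized: {sum(r.tier1_prioritized for r in results)}",
        "",
    ]
    for r in results:
        s = summary_by_id[r.study_id]
        meta = meta_by_id.get(r.study_id)
        heading = meta.citation if meta is not None and meta.citation else r.study_id
        lines.append(f"## {heading}")
        lines.append("")
        lines.append(
            f"- TAS: {r.tas} / {r.tas_max} ({r.tas_percent}%); "
            f"criteria at maximum: {r.max_score_fraction:.0%}; "
            f"criteria at zero: {s.n_zero}"
        )
        lines.append(
            f"- Tier-1: {'PRIORITIZED' if r.tier1_prioritized else 'not prioritized'}"
            + (
                f" (red criteria failing: {', '.join(r.failing_red)})"
                if r.failing_red
                else ""
            )
        )
        lines.append(f"- Reliability class: {r.fernandez_class.value}")
        lines.append(
            f"- Adequacy (no zero scores): "
            f"{'adequate' if r.de_ruijter_adequate else 'not adequate'}"
        )
        if meta is not None and meta.median_size_um is not None:
            ctx = particle_size_context(meta.median_size_um)
            lines.append(
                f"- Particle size context ({meta.median_size_um:g} um): "
                f"{_SIZE_NOTES[ctx]}"
            )
        if r.study_id in annotations:
            strengths, weaknesses = annotations[r.study_id]
            if strengths:
                lines.append(f"- Strengths: {strengths}")
            if weaknesses:
                lines.append(f"- Weaknesses: {weaknesses}")
        lines.append("")
    return "\n".join(lines)


def render_heatmap(
    corpus: Sequence[Evaluation],
    reg: CriteriaRegistry,
    path: Union[str, Path],
) -> None:
    """Criteria x studies heatmap, coloured by score level, to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    import numpy as np

    study_ids = [ev.study_id for ev in corpus]
    data = np.array(
        [[ev.scores[cid] for ev in corpus] for cid in reg.ids], dtype=int
    )
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.45 * len(study_ids) + 2), 0.28 * len(reg) + 1.5)
    )
    cmap = ListedColormap(["#c0392b", "#f1c40f", "#27ae60"])
    im = ax.imshow(data, cmap=cmap, vmin=0, vmax=2, aspect="auto")
    ax.set_xticks(range(len(study_ids)), study_ids, rotation=90, fontsize=7)
    ax.set_yticks(range(len(reg)), reg.ids, fontsize=7)
    cbar = fig.colorbar(im, ticks=[0, 1, 2], shrink=0.5)
    cbar.ax.set_yticklabels(["0 inadequate", "1 restricted", "2 adequate"])
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
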