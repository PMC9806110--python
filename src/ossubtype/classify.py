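"""Single-sample subtype assignment from marker-panel scores.

Two scoring modes mirror the two validation routes of the classification
system: ``panel_mean`` averages a group's normalized marker expression
(cohort-level expression data), ``single_marker`` takes the strongest
normalized marker within each group (the IHC rule, where each sample is
assigned to the group of its most strongly expressed marker).  Because raw
marker intensities are not cross-comparable, markers are standardized across
the cohort before the argmax (z-score by default; rank and none available).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import MissingMarkersError
from .markers import MarkerPanel

__all__ = [
    "SubtypeAssignment",
    "DEFAULT_IHC_MARKER_MAP",
    "normalize_expression",
    "score_panels",
    "assign_group",
    "assign_all",
    "classify_ihc_table",
    "assignment_accuracy",
]

logger = logging.getLogger(__name__)

#: published six-marker IHC panel and its group mapping
DEFAULT_IHC_MARKER_MAP: dict[str, str] = {
    "ALKBH5": "A",
    "TOM1L2": "A",
    "CDK4": "B",
    "LMO7": "B",
    "COL6A3": "C",
    "THBS2": "C",
}


@dataclass
class SubtypeAssignment:
    sample_id: str
    group: str
    scores: dict[str, float]
    margin: float
    tie_flag: bool


def normalize_expression(expr: pd.DataFrame, normalization: str = "zscore_cohort") -> pd.DataFrame:
    """Per-gene cohort normalization: ``zscore_cohort``, ``rank`` or ``none``."""
    if normalization == "none":
        return expr.astype(float)
    if normalization == "zscore_cohort":
        mu, sd = expr.mean(axis=0), expr.std(axis=0, ddof=0)
        sd = sd.replace(0, 1.0)
        return (expr - mu) / sd
    if normalization == "rank":
        return expr.rank(axis=0, method="average") / len(expr)
    raise ValueError(f"unknown normalization {normalization!r}")


def score_panels(
    expr: pd.DataFrame,
    panel: MarkerPanel | Mapping[str, Sequence[str]],
    mode: str = "panel_mean",
    normalization: str = "zscore_cohort",
) -> pd.DataFrame:
    """Per-sample, per-group panel scores (samples×groups).

    ``panel_mean``: mean normalized expression over the group's panel genes.
    ``single_marker``: maximum normalized marker value within the group.
    Panel genes missing from ``expr`` are logged and skipped; a group with no
    measured marker raises :class:`MissingMarkersError`.
    """
    if mode not in {"panel_mean", "single_marker"}:
        raise ValueError(f"unknown mode {mode!r}")
    panels = panel.panels if isinstance(panel, MarkerPanel) else {g: list(v) for g, v in panel.items()}
    norm = normalize_expression(expr, normalization)
    scores = {}
    for grp in sorted(panels):
        present = [g for g in panels[grp] if g in norm.columns]
        missing = [g for g in panels[grp] if g not in norm.columns]
        if missing:
            logger.warning("group %s: %d panel genes missing from input: %s",
                           grp, len(missing), missing[:10])
        if not present:
            raise MissingMarkersError(f"group {grp!r} has no measured marker gene")
        block = norm[present]
        scores[grp] = block.mean(axis=1) if mode == "panel_mean" else block.max(axis=1)
    return pd.DataFrame(scores)


def assign_group(
    scores: Mapping[str, float] | pd.Series,
    sample_id: str = "",
    tie_tol: float = 0.0,
) -> SubtypeAssignment:
    """Argmax group with deterministic alphabetical tie-break.

    ``tie_flag`` is set when the top-two margin is ``<= tie_tol`` (default 0:
    exact ties only).  Any non-finite score is an error.
    """
    s = pd.Series(dict(scores), dtype=float).sort_index()
    if not np.isfinite(s.to_numpy()).all():
        bad = s[~np.isfinite(s)].index.tolist()
        raise ValueError(f"non-finite scores for groups {bad} (sample {sample_id!r})")
    ordered = s.sort_values(ascending=False, kind="stable")  # stable: ties stay alphabetical
    group = str(ordered.index[0])
    margin = float(ordered.iloc[0] - ordered.iloc[1]) if len(ordered) > 1 else 0.0
    return SubtypeAssignment(
        sample_id=str(sample_id),
        group=group,
        scores={str(g): float(v) for g, v in s.items()},
        margin=margin,
        tie_flag=margin <= tie_tol,
    )


def assign_all(scores: pd.DataFrame, tie_tol: float = 0.0) -> pd.DataFrame:
    """Row-wise :func:`assign_group`; returns group/margin/tie_flag plus scores."""
    rows = [assign_group(scores.loc[i], sample_id=str(i), tie_tol=tie_tol) for i in scores.index]
    out = pd.DataFrame(
        {
            "group": [a.group for a in rows],
            "margin": [a.margin for a in rows],
            "tie_flag": [a.tie_flag for a in rows],
        },
        index=scores.index,
    )
    return out.join(scores.add_prefix("score_"))


def classify_ihc_table(
    table: pd.DataFrame,
    marker_to_group: Mapping[str, str] = DEFAULT_IHC_MARKER_MAP,
    normalization: str = "zscore_cohort",
    tie_tol: float = 0.0,
) -> pd.DataFrame:
    """Strongest-marker assignment of an IHC score table (samples×markers)."""
    missing = [m for m in marker_to_group if m not in table.columns]
    if missing:
        raise MissingMarkersError(f"IHC table lacks marker columns: {missing}")
    panels: dict[str, list[str]] = {}
    for marker, grp in marker_to_group.items():
        panels.setdefault(grp, []).append(marker)
    scores = score_panels(table, panels, mode="single_marker", normalization=normalization)
    return assign_all(scores, tie_tol=tie_tol)


def assignment_accuracy(assignments: pd.DataFrame, truth: Mapping[str, str]) -> float:
    """Fraction of samples whose assigned group equals the ground truth."""
    truth_s = pd.Series(dict(truth))
    common = assignments.index.intersection(truth_s.index)
    if len(common) == 0:
        raise ValueError("no overlap between assignments and truth")
    return float((assignments.loc[common, "group"] == truth_s.loc[common]).mean())
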