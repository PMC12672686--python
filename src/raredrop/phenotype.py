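"""Marker-combination phenotyping of curated rare-cell events.

Each nucleated event is characterized by per-channel positivity for CD138
and CD45 and by a three-state BCMA axis (negative / membrane-localized /
perinuclear), yielding 12 mutually exclusive phenotype classes named by
their positive markers (``"D"`` for a DAPI-only event up to
``"D | 138 | BCMA-Memb | 45"``).  Aggregate categories (total cells, total
CD138+, total BCMA+, total per BCMA localization) are unions of those
classes.

Positivity is called from per-event median channel intensities against
per-channel cutoffs; BCMA localization is called from the membrane-band
versus perinuclear-annulus intensity scores.  All thresholds are inclusive
(``>=``) so calls are reproducible at exact-tie inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MarkerCalls",
    "PHENOTYPE_CLASSES",
    "AGGREGATE_CATEGORIES",
    "PositivityThresholds",
    "assign_class",
    "call_positivity",
    "call_bcma_localization",
    "estimate_thresholds",
    "phenotype_events",
    "aggregate_counts",
]

BCMA_STATES = ("negative", "Memb", "Peri")


def _class_name(cd138_pos: bool, bcma_state: str, cd45_pos: bool) -> str:
    parts = ["D"]
    if cd138_pos:
        parts.append("138")
    if bcma_state == "Memb":
        parts.append("BCMA-Memb")
    elif bcma_state == "Peri":
        parts.append("BCMA-Peri")
    elif bcma_state != "negative":
        raise ValueError(f"unknown BCMA state: {bcma_state!r}")
    if cd45_pos:
        parts.append("45")
    return " | ".join(parts)


#: The 12 phenotype classes: {CD138 +/-} x {BCMA negative/Memb/Peri} x {CD45 +/-}.
PHENOTYPE_CLASSES: tuple[str, ...] = tuple(
    _class_name(cd138, bcma, cd45)
    for cd138 in (False, True)
    for bcma in BCMA_STATES
    for cd45 in (False, True)
)

#: Aggregate categories as unions of member classes.
AGGREGATE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "Total Cells": PHENOTYPE_CLASSES,
    "Total 138+ Cells": tuple(c for c in PHENOTYPE_CLASSES if "138" in c),
    "Total BCMA+ Cells": tuple(c for c in PHENOTYPE_CLASSES if "BCMA" in c),
    "Total BCMA-Memb Cells": tuple(c for c in PHENOTYPE_CLASSES if "BCMA-Memb" in c),
    "Total BCMA-Peri Cells": tuple(c for c in PHENOTYPE_CLASSES if "BCMA-Peri" in c),
}


@dataclass(frozen=True)
class MarkerCalls:
    """Per-event marker calls; ``bcma_state`` is one of ``BCMA_STATES``."""

    dapi_pos: bool
    cd138_pos: bool
    bcma_state: str
    cd45_pos: bool

    def __post_init__(self) -> None:
        if self.bcma_state not in BCMA_STATES:
            raise ValueError(f"bcma_state must be one of {BCMA_STATES}")


@dataclass(frozen=True)
class PositivityThresholds:
    """Per-channel intensity cutoffs (inclusive) plus the BCMA contrast ratio.

    ``bcma_contrast_ratio`` controls the membrane-vs-perinuclear call: the
    membrane state is assigned when the membrane-band score is at least
    ``ratio`` times the perinuclear score, the perinuclear state when the
    reverse holds, and otherwise the larger score wins (exact tie goes to
    membrane).
    """

    dapi: float
    cd138: float
    bcma: float
    cd45: float
    bcma_contrast_ratio: float = 1.2

    def __post_init__(self) -> None:
        for name in ("dapi", "cd138", "bcma", "cd45"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"threshold {name} must be finite")
        if self.bcma_contrast_ratio < 1:
            raise ValueError("bcma_contrast_ratio must be >= 1")


def assign_class(calls: MarkerCalls) -> str:
    """Map marker calls to the canonical phenotype-class name.

    The mapping is a pure lookup on (CD138, BCMA state, CD45) and is a
    bijection onto the 12 class names.  DAPI-negative events are not cells
    and must be filtered out before classification.
    """
    if not calls.dapi_pos:
        raise ValueError("DAPI-negative event: not a nucleated cell, filter upstream")
    return _class_name(calls.cd138_pos, calls.bcma_state, calls.cd45_pos)


def call_bcma_localization(
    median_bcma: float,
    membrane_score: float,
    perinuclear_score: float,
    thresholds: PositivityThresholds,
) -> str:
    """Call the BCMA axis state for one event.

    An event is BCMA+ when the median BCMA intensity or either localization
    score reaches the BCMA cutoff; otherwise the state is ``"negative"``.
    For BCMA+ events the localization is membrane if the membrane-band score
    dominates the perinuclear score by ``bcma_contrast_ratio``, perinuclear
    for the reverse, else whichever score is larger (tie -> membrane).
    """
    positive = (
        median_bcma >= thresholds.bcma
        or membrane_score >= thresholds.bcma
        or perinuclear_score >= thresholds.bcma
    )
    if not positive:
        return "negative"
    r = thresholds.bcma_contrast_ratio
    if membrane_score >= r * perinuclear_score:
        return "Memb"
    if perinuclear_score >= r * membrane_score:
        return "Peri"
    return "Memb" if membrane_score >= perinuclear_score else "Peri"


def call_positivity(event: Mapping[str, float], thresholds: PositivityThresholds) -> MarkerCalls:
    """Call marker positivity for one event (mapping or DataFrame row).

    Requires the feature columns ``median_dapi``, ``median_cd138``,
    ``median_bcma``, ``median_cd45``, ``bcma_membrane_score`` and
    ``bcma_perinuclear_score``.  Positivity is median intensity >= cutoff.
    """
    for key in (
        "median_dapi",
        "median_cd138",
        "median_bcma",
        "median_cd45",
        "bcma_membrane_score",
        "bcma_perinuclear_score",
    ):
        if key not in event:
            raise KeyError(f"event is missing channel feature {key!r}")
    return MarkerCalls(
        dapi_pos=bool(event["median_dapi"] >= thresholds.dapi),
        cd138_pos=bool(event["median_cd138"] >= thresholds.cd138),
        bcma_state=call_bcma_localization(
            event["median_bcma"],
            event["bcma_membrane_score"],
            event["bcma_perinuclear_score"],
            thresholds,
        ),
        cd45_pos=bool(event["median_cd45"] >= thresholds.cd45),
    )


def estimate_thresholds(
    events: pd.DataFrame,
    n_mads: float = 5.0,
    bcma_contrast_ratio: float = 1.2,
    common_mask: np.ndarray | None = None,
) -> PositivityThresholds:
    """Estimate per-channel cutoffs from the common (non-rare) population.

    The cutoff for each channel is ``median + n_mads * MAD`` of that
    channel's median intensity over the common events (all events when no
    mask is given; the dominant white-blood-cell background makes the global
    median robust to the rare fraction).  CD45 is a special case: the
    background population is CD45-positive leukocytes, so a high-quantile
    rule would misclassify them.  Its cutoff is instead placed at half the
    background median, separating CD45-bright leukocytes from CD45-dim
    plasma cells.  DAPI similarly gates on half the background median since
    every true cell is nucleated.
    """
    sub = events if common_mask is None else events.loc[np.asarray(common_mask)]
    if len(sub) == 0:
        raise ValueError("no events available for threshold estimation")

    def _cut(col: str) -> float:
        x = sub[col].to_numpy(dtype=float)
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        return med + n_mads * 1.4826 * mad

    return PositivityThresholds(
        dapi=0.5 * float(np.median(sub["median_dapi"])),
        cd138=_cut("median_cd138"),
        bcma=_cut("median_bcma"),
        cd45=0.5 * float(np.median(sub["median_cd45"])),
        bcma_contrast_ratio=bcma_contrast_ratio,
    )


def phenotype_events(
    events: pd.DataFrame,
    thresholds: PositivityThresholds | None = None,
    drop_dapi_negative: bool = True,
) -> pd.DataFrame:
    """Phenotype an event table; returns a copy with call columns appended.

    Adds ``cd138_pos``, ``bcma_state``, ``cd45_pos`` and ``class``.
    DAPI-negative events (anuclear artifacts) are dropped by default, since
    the class system only covers nucleated cells.
    """
    if thresholds is None:
        thresholds = estimate_thresholds(events)
    out = events.copy()
    dapi_pos = out["median_dapi"].to_numpy(dtype=float) >= thresholds.dapi
    cd138 = out["median_cd138"].to_numpy(dtype=float) >= thresholds.cd138
    cd45 = out["median_cd45"].to_numpy(dtype=float) >= thresholds.cd45

    bcma_med = out["median_bcma"].to_numpy(dtype=float)
    memb = out["bcma_membrane_score"].to_numpy(dtype=float)
    peri = out["bcma_perinuclear_score"].to_numpy(dtype=float)
    bcma_pos = (
        (bcma_med >= thresholds.bcma) | (memb >= thresholds.bcma) | (peri >= thresholds.bcma)
    )
    r = thresholds.bcma_contrast_ratio
    is_memb = np.where(
        memb >= r * peri, True, np.where(peri >= r * memb, False, memb >= peri)
    )
    bcma_state = np.where(bcma_pos, np.where(is_memb, "Memb", "Peri"), "negative")

    out["cd138_pos"] = cd138
    out["bcma_state"] = bcma_state
    out["cd45_pos"] = cd45
    names = np.array(
        [
            [
                [_class_name(bool(c1), s, bool(c4)) for c4 in (0, 1)]
                for s in BCMA_STATES
            ]
            for c1 in (0, 1)
        ]
    )
    state_idx = np.select(
        [bcma_state == "negative", bcma_state == "Memb"], [0, 1], default=2
    )
    out["class"] = names[cd138.astype(int), state_idx, cd45.astype(int)]
    out.loc[~dapi_pos, "class"] = ""
    if drop_dapi_negative:
        out = out.loc[dapi_pos].copy()
    return out


def aggregate_counts(classes: Iterable[str]) -> pd.Series:
    """Count events per phenotype class and aggregate category.

    Returns a Series indexed by the 12 class names followed by the 5
    aggregates.  Each event contributes to exactly one class; aggregates
    are sums of member classes, so ``Total BCMA+ = Total BCMA-Memb +
    Total BCMA-Peri`` holds by construction.
    """
    vc = pd.Series(list(classes)).value_counts()
    counts = pd.Series({c: int(vc.get(c, 0)) for c in PHENOTYPE_CLASSES})
    for agg, members in AGGREGATE_CATEGORIES.items():
        counts[agg] = int(sum(counts[m] for m in members))
    return counts
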