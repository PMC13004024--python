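"""Folding classes, accessibility scores, class fractions and time profiles.

A molecule's *folding class* is its per-reporter sign vector: "+" if at
least one specific binding event of that reporter falls in the molecule's
usable window (from reagent delivery / elongation start until donor
bleach, excluding the laser dead time), "-" otherwise; with k reporters
there are exactly 2^k classes.  The *accessibility score* of an ensemble or
class is the arithmetic mean over molecules of the fraction of usable time
spent probe-bound.  Time profiles bin the aligned traces into 5-s intervals
and report, per reporter, the percentage of molecules with an event
overlapping each bin, with the class median transcription-machinery
residence time as an overlay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EventTable, ExperimentMeta
from .selection import MoleculeAnnotation

#: canonical reporter ordering in class labels: the r-protein readout first,
#: then probes by 5'->3' position of their target site on the RNA
REPORTER_ORDER = ("S7", "H2829", "H30", "H32")


def canonical_reporter_order(reporters: list[str]) -> list[str]:
    known = [r for r in REPORTER_ORDER if r in reporters]
    rest = sorted(r for r in reporters if r not in REPORTER_ORDER)
    return known + rest


@dataclass(frozen=True)
class ClassAssignment:
    """Per-molecule folding-class label over the declared reporters."""

    molecule_id: str
    signs: dict[str, bool]
    class_label: str


def usable_window(
    annotation: MoleculeAnnotation,
    meta: ExperimentMeta,
    t0: float | None = None,
) -> tuple[float, float]:
    """Usable window ``[start, end)`` of one selected molecule.

    Starts at reagent delivery (or the detected elongation start if later)
    and ends at the donor bleach (or trace end if no bleach was annotated).
    """
    start = meta.delivery_time if t0 is None else t0
    if not math.isnan(annotation.elongation_start):
        start = max(start, annotation.elongation_start)
    end = annotation.donor_bleach_time
    if math.isnan(end):
        end = annotation.duration
    return (start, end)


def _usable_duration(window: tuple[float, float], meta: ExperimentMeta) -> float:
    start, end = window
    lo, hi = meta.dead_window
    overlap = max(min(end, hi) - max(start, lo), 0.0)
    return max(end - start - overlap, 0.0)


def classify_molecules(
    events: EventTable,
    annotations: list[MoleculeAnnotation],
    reporters: list[str],
    meta: ExperimentMeta,
    t0: float | None = None,
) -> list[ClassAssignment]:
    """Assign every selected molecule to one of the 2^k folding classes.

    The sign of a reporter is "+" iff at least one event of that reporter
    overlaps the molecule's usable window; censored (boundary-touching)
    events count — a partial event is still evidence of accessibility.
    """
    known = set(meta.channel_reporter_map.values())
    for r in reporters:
        if r not in known:
            raise ValueError(f"reporter {r!r} not declared in experiment metadata")
    order = canonical_reporter_order(list(reporters))
    out = []
    for ann in annotations:
        if not ann.selected:
            continue
        window = usable_window(ann, meta, t0)
        signs = {}
        for reporter in order:
            ev = events.select(molecule_id=ann.molecule_id, reporter=reporter)
            signs[reporter] = bool(ev.total_time_in(*window) > 0)
        label = "/".join(f"{r}{'+' if signs[r] else '-'}" for r in order)
        out.append(ClassAssignment(molecule_id=ann.molecule_id, signs=signs, class_label=label))
    return out


@dataclass
class AccessibilityResult:
    """Fraction of usable time bound, per molecule, and the ensemble mean."""

    per_molecule: dict[str, float]
    score: float


def accessibility_scores(
    events: EventTable,
    annotations: list[MoleculeAnnotation],
    meta: ExperimentMeta,
    reporter: str,
    molecule_ids: set[str] | None = None,
    t0: float | None = None,
) -> AccessibilityResult:
    """Per-molecule bound-time fraction and its mean over the selection.

    ``molecule_ids`` restricts the ensemble, e.g. to one folding class.
    """
    fractions: dict[str, float] = {}
    for ann in annotations:
        if not ann.selected:
            continue
        if molecule_ids is not None and ann.molecule_id not in molecule_ids:
            continue
        window = usable_window(ann, meta, t0)
        usable = _usable_duration(window, meta)
        if usable <= 0:
            raise ValueError(f"molecule {ann.molecule_id} has an empty usable window")
        ev = events.select(molecule_id=ann.molecule_id, reporter=reporter)
        fractions[ann.molecule_id] = min(ev.total_time_in(*window) / usable, 1.0)
    score = float(np.mean(list(fractions.values()))) if fractions else math.nan
    return AccessibilityResult(per_molecule=fractions, score=score)


def class_fractions(
    assignments_by_condition: dict[str, list[ClassAssignment]],
) -> pd.DataFrame:
    """Fraction of molecules per folding class and condition.

    Replicates of a condition are pooled by concatenating their assignment
    lists before calling this.  Per-condition fractions sum to 1.
    """
    rows = []
    for condition, assignments in assignments_by_condition.items():
        if not assignments:
            raise ValueError(f"condition {condition!r} has no molecules")
        n = len(assignments)
        counts: dict[str, int] = {}
        for a in assignments:
            counts[a.class_label] = counts.get(a.class_label, 0) + 1
        for label in sorted(counts):
            rows.append(
                {
                    "condition": condition,
                    "class_label": label,
                    "fraction": counts[label] / n,
                    "n": n,
                }
            )
    return pd.DataFrame(rows, columns=["condition", "class_label", "fraction", "n"])


@dataclass(frozen=True)
class FoldChange:
    """Ratio between two class fractions, annotated with its direction."""

    ratio: float  # >= 1, full precision
    direction: str  # "increase", "decrease" or "none"

    @property
    def rounded(self) -> float:
        """One-decimal value for reporting, e.g. 2.1."""
        return round(self.ratio, 1)

    @property
    def signed_ratio(self) -> float:
        """b/a: > 1 for an increase, < 1 for a decrease."""
        return self.ratio if self.direction == "increase" else 1.0 / self.ratio


def fold_change(fraction_a: float, fraction_b: float) -> FoldChange:
    """Fold change from condition a to condition b (both fractions > 0)."""
    if fraction_a <= 0 or fraction_b <= 0:
        raise ValueError("fold change requires both fractions > 0")
    if fraction_b > fraction_a:
        return FoldChange(ratio=fraction_b / fraction_a, direction="increase")
    if fraction_b < fraction_a:
        return FoldChange(ratio=fraction_a / fraction_b, direction="decrease")
    return FoldChange(ratio=1.0, direction="none")


@dataclass
class TimeProfile:
    """Per-bin percentage of molecules with an event, per reporter."""

    bin_edges: np.ndarray  # seconds from t0, length n_bins + 1
    percent: pd.DataFrame  # index = bin start (s), one column per reporter
    median_tec_time: float  # median dissociation - t0 of the class (s)
    n_molecules: int


def time_profile(
    events: EventTable,
    annotations: list[MoleculeAnnotation],
    meta: ExperimentMeta,
    reporters: list[str],
    molecule_ids: set[str] | None = None,
    bin_width: float = 5.0,
    t0: float | None = None,
) -> TimeProfile:
    """Time-resolved accessibility: % of molecules with an event per 5-s bin.

    Molecules are aligned to ``t0`` (reagent delivery by default).  The
    percentage in a bin is over all molecules of the (sub)ensemble; the
    median time from delivery to transcription-machinery dissociation is
    attached for overlay.
    """
    start = meta.delivery_time if t0 is None else t0
    selected = [
        a
        for a in annotations
        if a.selected and (molecule_ids is None or a.molecule_id in molecule_ids)
    ]
    if not selected:
        raise ValueError("no molecules in the requested ensemble")
    max_end = max(usable_window(a, meta, t0)[1] for a in selected)
    n_bins = max(int(math.ceil((max_end - start) / bin_width)), 1)
    edges = start + np.arange(n_bins + 1) * bin_width
    data = {}
    for reporter in reporters:
        hits = np.zeros(n_bins)
        for ann in selected:
            ev = events.select(molecule_id=ann.molecule_id, reporter=reporter)
            if not len(ev):
                continue
            s = ev.df["t_start"].to_numpy()
            e = ev.df["t_end"].to_numpy()
            overlap = (s[None, :] < edges[1:, None]) & (e[None, :] > edges[:-1, None])
            hits += overlap.any(axis=1)
        data[reporter] = 100.0 * hits / len(selected)
    diss = [
        a.dna_dissociation_time - start
        for a in selected
        if not math.isnan(a.dna_dissociation_time)
    ]
    median_tec = float(np.median(diss)) if diss else math.nan
    percent = pd.DataFrame(data, index=pd.Index(edges[:-1] - start, name="bin_start_s"))
    return TimeProfile(
        bin_edges=edges - start,
        percent=percent,
        median_tec_time=median_tec,
        n_molecules=len(selected),
    )


__all__ = [
    "AccessibilityResult",
    "ClassAssignment",
    "FoldChange",
    "REPORTER_ORDER",
    "TimeProfile",
    "accessibility_scores",
    "canonical_reporter_order",
    "class_fractions",
    "classify_molecules",
    "fold_change",
    "time_profile",
    "usable_window",
]
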