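"""Trace selection: transcription detection and single-step donor bleach.

A molecule enters the analysis only if its trace certifies (i) active
transcription — a gradual rise of the transcription-reporter channel
followed by a single large drop to background within 200 s of the rise
onset (cotranscriptional mode only) — and (ii) a single donor photobleaching
step falling in the terminal window of the movie (default last 20%), which
certifies a single molecule under the diffraction-limited spot.

Step detection uses an exact penalized least-squares change-point fit:
the best two-segment piecewise-constant split of the channel (computed in
closed form from cumulative sums).  "Single step" means the split improves
substantially on the one-segment fit while neither resulting segment hides a
comparable second downward step (one level of binary segmentation).  Donor
bleaching is detected on the FRET-conserving total intensity
(donor + all acceptor channels), which is piecewise constant regardless of
binding activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io import DONOR, TRANSCRIPTION, ExperimentMeta, Trace, TraceSet

COTRANSCRIPTIONAL = "cotranscriptional"
IMMOBILIZED = "immobilized_rna"


@dataclass(frozen=True)
class SelectionParams:
    """Tunables of the selection rules.

    ``bleach_window`` is the fraction pair of total time in which the donor
    bleach step must fall; the default (0.80, 1.00) covers the deliberately
    induced terminal bleaching period.  ``max_dissociation`` is the maximum
    allowed time (s) between rise onset and the template-dissociation step.
    Signal-to-noise thresholds are multiples of the robust per-frame noise SD.
    """

    bleach_window: tuple[float, float] = (0.80, 1.00)
    max_dissociation: float = 200.0
    smooth_frames: int = 5
    min_step_snr: float = 6.0
    rise_snr: float = 5.0
    onset_snr: float = 3.0
    onset_sustain_frames: int = 5
    step_improvement: float = 0.8  # 2-segment cost must be < this * 1-segment cost
    substep_fraction: float = 0.5  # second step "comparable" above this fraction
    min_rise_spearman: float = 0.5
    # the dissociation drop must start from near the peak: a trace that has
    # already stepped partway down (stepwise photobleaching of the template
    # dyes) fails this fraction
    drop_fraction: float = 0.75
    min_segment_frames: int = 3


@dataclass
class MoleculeAnnotation:
    """Selection outcome and key times (seconds) for one molecule."""

    molecule_id: str
    selected: bool
    rejection_reasons: tuple[str, ...] = ()
    transcription_detected: bool = False
    elongation_start: float = math.nan
    dna_dissociation_time: float = math.nan
    donor_bleach_time: float = math.nan
    duration: float = math.nan


# ---------------------------------------------------------------------------
# change-point primitives
# ---------------------------------------------------------------------------


def _segment_costs(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative sums used for O(1) SSE of any contiguous segment."""
    c = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))
    return c, c2


def _sse(c: np.ndarray, c2: np.ndarray, a: int, b: int) -> float:
    n = b - a
    if n <= 0:
        return 0.0
    s = c[b] - c[a]
    return float(c2[b] - c2[a] - s * s / n)


def best_split(y: np.ndarray, min_seg: int = 1) -> tuple[int, float, float]:
    """Best two-segment piecewise-constant split of ``y``.

    Returns ``(k, cost2, cost1)`` where the segments are ``y[:k]`` and
    ``y[k:]``, ``cost2`` their summed SSE and ``cost1`` the SSE of the
    one-segment fit.
    """
    n = len(y)
    if n < 2 * min_seg:
        return 0, math.inf, _sse(*_segment_costs(y), 0, n)
    c, c2 = _segment_costs(y)
    ks = np.arange(min_seg, n - min_seg + 1)
    s_left = c[ks]
    s_right = c[n] - s_left
    sq_left = c2[ks]
    sq_right = c2[n] - sq_left
    cost = (sq_left - s_left**2 / ks) + (sq_right - s_right**2 / (n - ks))
    j = int(np.argmin(cost))
    return int(ks[j]), float(cost[j]), _sse(c, c2, 0, n)


def robust_noise_sd(y: np.ndarray) -> float:
    """Noise SD from the median absolute first difference (step-robust)."""
    d = np.diff(y)
    if len(d) == 0:
        return 0.0
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / math.sqrt(2.0))


def _smooth(y: np.ndarray, w: int) -> np.ndarray:
    if w <= 1 or len(y) < w:
        return y
    kernel = np.ones(w) / w
    return np.convolve(y, kernel, mode="same")


def _has_downward_substep(
    y: np.ndarray, main_step: float, sigma: float, params: SelectionParams
) -> bool:
    """One level of binary segmentation: comparable second downward step?"""
    if len(y) < 2 * params.min_segment_frames:
        return False
    k, _, _ = best_split(y, min_seg=params.min_segment_frames)
    if k == 0:
        return False
    step = float(np.mean(y[:k]) - np.mean(y[k:]))
    threshold = max(params.substep_fraction * main_step, params.min_step_snr * sigma)
    return step >= threshold and step > 0


def _valid_mask(trace: Trace, meta: ExperimentMeta) -> np.ndarray:
    """Frames outside the laser dead-time window."""
    n = trace.n_frames
    t = np.arange(n) * meta.frame_period
    lo, hi = meta.dead_window
    return ~((t >= lo) & (t < hi))


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------


@dataclass
class StepDetection:
    ok: bool
    time: float = math.nan
    reasons: tuple[str, ...] = ()


def detect_donor_bleach(
    trace: Trace,
    meta: ExperimentMeta,
    window_fraction: tuple[float, float] | None = None,
    params: SelectionParams = SelectionParams(),
) -> StepDetection:
    """Find the terminal single-step donor bleach on the FRET total intensity.

    ``ok`` is true iff exactly one bleaching step is present and falls inside
    the configured terminal window of the total experimental time.
    """
    window = window_fraction if window_fraction is not None else params.bleach_window
    total = trace.channels[DONOR].copy()
    for ch in trace.acceptor_channels():
        total = total + trace.channels[ch]
    mask = _valid_mask(trace, meta)
    y = total[mask]
    idx = np.nonzero(mask)[0]
    if len(y) < 2 * params.min_segment_frames:
        return StepDetection(False, reasons=("trace_too_short",))
    sigma = robust_noise_sd(y)
    eps = max(sigma, 1e-9 * max(1.0, float(np.max(np.abs(y)))))
    k, cost2, cost1 = best_split(y, min_seg=params.min_segment_frames)
    step = float(np.mean(y[:k]) - np.mean(y[k:]))
    reasons = []
    if step < params.min_step_snr * eps or not (cost2 < params.step_improvement * cost1):
        reasons.append("no_bleach_step")
    elif _has_downward_substep(y[:k], step, sigma, params) or _has_downward_substep(
        y[k:], step, sigma, params
    ):
        reasons.append("multiple_bleach_steps")
    if reasons:
        return StepDetection(False, reasons=tuple(reasons))
    bleach_time = idx[k] * meta.frame_period
    duration = trace.n_frames * meta.frame_period
    if not (window[0] * duration <= bleach_time <= window[1] * duration):
        return StepDetection(False, time=bleach_time, reasons=("bleach_outside_window",))
    return StepDetection(True, time=bleach_time)


@dataclass
class TranscriptionDetection:
    detected: bool
    elongation_start: float = math.nan
    dissociation_time: float = math.nan
    reasons: tuple[str, ...] = ()


def detect_transcription(
    trace: Trace,
    meta: ExperimentMeta,
    params: SelectionParams = SelectionParams(),
) -> TranscriptionDetection:
    """Detect the transcription rise and single-step template dissociation.

    ``detected`` is false when there is no rise, no terminal drop, more than
    one comparable downward step (stepwise photobleaching of the template
    dyes), or the drop comes later than ``params.max_dissociation`` seconds
    after the rise onset.
    """
    if TRANSCRIPTION not in trace.channels:
        raise ValueError("trace has no transcription channel")
    raw = trace.channels[TRANSCRIPTION]
    if np.all(np.isnan(raw)):
        raise ValueError("transcription channel is all-NaN")
    mask = _valid_mask(trace, meta)
    y = raw[mask]
    idx = np.nonzero(mask)[0]
    if len(y) < 2 * params.min_segment_frames:
        return TranscriptionDetection(False, reasons=("trace_too_short",))
    sigma = robust_noise_sd(y)
    eps = max(sigma, 1e-9 * max(1.0, float(np.max(np.abs(y)))))
    smooth = _smooth(y, params.smooth_frames)

    k, cost2, cost1 = best_split(y, min_seg=params.min_segment_frames)
    post_mean = float(np.mean(y[k:]))
    pre_tail = float(np.mean(y[max(0, k - 10) : k]))
    step = pre_tail - post_mean
    peak = float(np.max(smooth[:k])) if k > 0 else post_mean

    reasons = []
    if step < params.min_step_snr * eps or not (cost2 < params.step_improvement * cost1):
        reasons.append("no_dissociation_step")
    elif step < params.drop_fraction * (peak - post_mean):
        # drop does not start from the peak: stepwise photobleach pattern
        reasons.append("partial_drop")
    elif _has_downward_substep(y[:k], step, sigma, params) or _has_downward_substep(
        y[k:], step, sigma, params
    ):
        reasons.append("multiple_steps")
    if reasons:
        return TranscriptionDetection(False, reasons=tuple(reasons))

    # rise: the pre-drop segment must climb well above background
    if peak < post_mean + params.rise_snr * eps:
        return TranscriptionDetection(False, reasons=("no_rise",))
    if k >= 8:
        rho = spearmanr(np.arange(k), smooth[:k]).statistic
        if not (rho >= params.min_rise_spearman):
            return TranscriptionDetection(False, reasons=("no_monotone_rise",))

    onset_level = post_mean + params.onset_snr * eps
    above = smooth[:k] > onset_level
    onset_idx = None
    run = 0
    need = min(params.onset_sustain_frames, max(1, k))
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= need:
            onset_idx = i - need + 1
            break
    if onset_idx is None:
        return TranscriptionDetection(False, reasons=("no_rise",))

    t_onset = idx[onset_idx] * meta.frame_period
    t_diss = idx[k] * meta.frame_period
    if t_diss - t_onset > params.max_dissociation:
        return TranscriptionDetection(
            False,
            elongation_start=t_onset,
            dissociation_time=t_diss,
            reasons=("late_dissociation",),
        )
    return TranscriptionDetection(True, elongation_start=t_onset, dissociation_time=t_diss)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def select_molecules(
    traces: TraceSet,
    mode: str = COTRANSCRIPTIONAL,
    params: SelectionParams = SelectionParams(),
) -> list[MoleculeAnnotation]:
    """Annotate every molecule with the selection verdict and key times.

    Pure function of the traces and parameters; molecules are treated
    independently, so the result is order-independent and idempotent.
    """
    if mode not in (COTRANSCRIPTIONAL, IMMOBILIZED):
        raise ValueError(f"unknown selection mode {mode!r}")
    annotations = []
    for trace in traces:
        reasons: list[str] = []
        ann = MoleculeAnnotation(
            molecule_id=trace.molecule_id,
            selected=False,
            duration=trace.n_frames * traces.meta.frame_period,
        )
        if mode == COTRANSCRIPTIONAL:
            tx = detect_transcription(trace, traces.meta, params)
            ann.transcription_detected = tx.detected
            ann.elongation_start = tx.elongation_start
            ann.dna_dissociation_time = tx.dissociation_time
            if not tx.detected:
                reasons.extend(tx.reasons)
        bleach = detect_donor_bleach(trace, traces.meta, params=params)
        ann.donor_bleach_time = bleach.time
        if not bleach.ok:
            reasons.extend(bleach.reasons)
        ann.selected = not reasons
        ann.rejection_reasons = tuple(reasons)
        annotations.append(ann)
    return annotations


# ---------------------------------------------------------------------------
# annotation TSV round trip
# ---------------------------------------------------------------------------

_ANNOTATION_COLUMNS = [
    "molecule_id",
    "selected",
    "rejection_reasons",
    "transcription_detected",
    "elongation_start",
    "dna_dissociation_time",
    "donor_bleach_time",
    "duration",
]


def annotations_frame(annotations: list[MoleculeAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        rows.append(
            {
                "molecule_id": a.molecule_id,
                "selected": int(a.selected),
                "rejection_reasons": ";".join(a.rejection_reasons),
                "transcription_detected": int(a.transcription_detected),
                "elongation_start": a.elongation_start,
                "dna_dissociation_time": a.dna_dissociation_time,
                "donor_bleach_time": a.donor_bleach_time,
                "duration": a.duration,
            }
        )
    return pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS)


def write_annotations(annotations: list[MoleculeAnnotation], path) -> None:
    annotations_frame(annotations).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[MoleculeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype={"molecule_id": str})
    out = []
    for _, row in df.iterrows():
        reasons = row["rejection_reasons"]
        reasons = tuple(str(reasons).split(";")) if isinstance(reasons, str) and reasons else ()
        out.append(
            MoleculeAnnotation(
                molecule_id=row["molecule_id"],
                selected=bool(row["selected"]),
                rejection_reasons=reasons,
                transcription_detected=bool(row["transcription_detected"]),
                elongation_start=float(row["elongation_start"]),
                dna_dissociation_time=float(row["dna_dissociation_time"]),
                donor_bleach_time=float(row["donor_bleach_time"]),
                duration=float(row["duration"]),
            )
        )
    return out


__all__ = [
    "COTRANSCRIPTIONAL",
    "IMMOBILIZED",
    "MoleculeAnnotation",
    "SelectionParams",
    "StepDetection",
    "TranscriptionDetection",
    "annotations_frame",
    "best_split",
    "detect_donor_bleach",
    "detect_transcription",
    "read_annotations",
    "robust_noise_sd",
    "select_molecules",
    "write_annotations",
]
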