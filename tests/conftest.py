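"""Shared fixtures: small simulated ensembles reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from smprobe.pipeline import PipelineConfig, run_pipeline
from smprobe.selection import IMMOBILIZED
from smprobe.simulate import (
    DeadTime,
    Photophysics,
    ReporterKinetics,
    SimulationConfig,
    simulate_ensemble,
)

#: pseudo-first-order binding and unbinding of the reference ssRNA probe
#: condition (200 nM probe): arrival median ln2/0.2166 = 3.2 s, bound-dwell
#: median ln2/0.433 = 1.6 s
KON = 1.083e6  # 1/M/s
CONC = 200e-9  # M
KOFF = 0.433  # 1/s


def h30_kinetics() -> dict[str, ReporterKinetics]:
    return {"H30": ReporterKinetics(KON, CONC, unbinding_rate=KOFF)}


@pytest.fixture(scope="session")
def noiseless_ensemble():
    """Noise-free, crosstalk-free immobilized ssRNA ensemble + pipeline run."""
    config = SimulationConfig(
        n_molecules=40,
        class_probabilities={"H30+": 1.0},
        kinetics=h30_kinetics(),
        cotranscriptional=False,
        photophysics=Photophysics(noise_sd=0.0, crosstalk_leak=0.0),
        dead_time=DeadTime(15.0, 0.0),
        seed=7,
    )
    traces, truth = simulate_ensemble(config)
    result = run_pipeline(traces, PipelineConfig(mode=IMMOBILIZED))
    return config, traces, truth, result


@pytest.fixture(scope="session")
def noisy_ssrna_ensemble():
    """Default-noise immobilized ssRNA ensemble + pipeline run."""
    config = SimulationConfig(
        n_molecules=60,
        class_probabilities={"H30+": 1.0},
        kinetics=h30_kinetics(),
        cotranscriptional=False,
        seed=11,
    )
    traces, truth = simulate_ensemble(config)
    result = run_pipeline(traces, PipelineConfig(mode=IMMOBILIZED))
    return config, traces, truth, result


@pytest.fixture(scope="session")
def cotx_ensemble():
    """Cotranscriptional ensemble with a 62% accessible class."""
    config = SimulationConfig(
        n_molecules=80,
        class_probabilities={"H30+": 0.62, "H30-": 0.38},
        kinetics=h30_kinetics(),
        cotranscriptional=True,
        seed=13,
    )
    traces, truth = simulate_ensemble(config)
    result = run_pipeline(traces)
    return config, traces, truth, result


# ---------------------------------------------------------------------------
# oracle helpers: event matching tolerant to sub-resolution gap ambiguity
# ---------------------------------------------------------------------------


def merge_intervals(intervals, gap):
    """Union intervals separated by less than ``gap`` (camera-unresolvable)."""
    out = []
    for s, e in intervals:
        if out and s - out[-1][1] < gap:
            out[-1] = (out[-1][0], max(e, out[-1][1]))
        else:
            out.append((s, e))
    return out


def _ends_match(a, b, tol):
    return abs(a - b) <= tol


def detected_matches_truth(det, truth, dt):
    """Precision rule: both ends within +-1 frame of truth boundaries.

    A detected event may span several truth events if every absorbed gap is
    below two frames — at 100-ms integration such gaps produce boundary-frame
    occupancies that can round either way, so merging them is not an error.
    """
    ds, de = det
    tol = dt + 1e-9
    starts = [s for s, _ in truth]
    ends = [e for _, e in truth]
    i = next((k for k, s in enumerate(starts) if _ends_match(ds, s, tol)), None)
    j = next((k for k, e in enumerate(ends) if _ends_match(de, e, tol)), None)
    if i is None or j is None or j < i:
        return False
    for k in range(i, j):
        if truth[k + 1][0] - truth[k][1] > 2 * dt + 1e-9:
            return False
    return True


def truth_event_detected(idx, truth, detected, dt):
    """Recall rule: covered by a detected event with matching free ends.

    An end may be displaced beyond one frame only if the neighbouring truth
    event sits within two frames (the detector legitimately merged across a
    sub-resolution gap).
    """
    s, e = truth[idx]
    tol = dt + 1e-9
    for ds, de in detected:
        if not (ds <= s + tol and de >= e - tol):
            continue
        left_ok = _ends_match(ds, s, tol) or (
            idx > 0 and s - truth[idx - 1][1] <= 2 * dt + 1e-9 and ds <= s
        )
        right_ok = _ends_match(de, e, tol) or (
            idx < len(truth) - 1 and truth[idx + 1][0] - e <= 2 * dt + 1e-9 and de >= e
        )
        if left_ok and right_ok:
            return True
    return False


def event_precision_recall(result, traces, truth, reporter, min_frames=3):
    """Ambiguity-tolerant precision/recall of detected vs. true events."""
    from smprobe.classify import usable_window
    from smprobe.simulate import truth_event_table

    dt = traces.meta.frame_period
    tt = truth_event_table(truth)
    tp = fn = fp = 0
    for ann in result.selected:
        window = usable_window(ann, traces.meta)
        truth_iv = [
            (r.t_start, r.t_end)
            for r in tt.select(ann.molecule_id, reporter).df.itertuples()
        ]
        det_iv = [
            (r.t_start, r.t_end)
            for r in result.events.select(ann.molecule_id, reporter).df.itertuples()
        ]
        scored = [
            k
            for k, (s, e) in enumerate(truth_iv)
            if e - s >= min_frames * dt and s >= window[0] and e <= window[1]
        ]
        for k in scored:
            if truth_event_detected(k, truth_iv, det_iv, dt):
                tp += 1
            else:
                fn += 1
        for d in det_iv:
            if d[1] - d[0] < min_frames * dt:
                continue
            if not detected_matches_truth(d, truth_iv, dt):
                fp += 1
    recall = tp / (tp + fn) if tp + fn else 1.0
    precision = tp / (tp + fp) if tp + fp else 1.0
    return precision, recall


def binomial_band(p, n, k=3.0):
    """Half-width (in percent) of a k-SD binomial band around 100*p."""
    return 100.0 * k * np.sqrt(p * (1.0 - p) / n)
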