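"""End-to-end orchestration: select -> threshold -> detect -> classify.

Thin glue over the stage modules, used by the command-line interface, the
examples and the acceptance checks.  FRET state thresholds are estimated
per reporter per experiment by pooling efficiencies over all selected
molecules (frames inside each molecule's usable window), then every
selected molecule is state-assigned and its events extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassAssignment, classify_molecules, usable_window
from .events import (
    EventParams,
    StateModel,
    assign_states,
    estimate_fret_states,
    extract_events,
    fret_series,
    unmix_trace,
)
from .io import EventTable, TraceSet
from .selection import (
    COTRANSCRIPTIONAL,
    MoleculeAnnotation,
    SelectionParams,
    select_molecules,
)


@dataclass
class PipelineConfig:
    mode: str = COTRANSCRIPTIONAL
    selection: SelectionParams = field(default_factory=SelectionParams)
    events: EventParams = field(default_factory=EventParams)
    threshold_overrides: dict[str, float] = field(default_factory=dict)
    t0: float | None = None  # default: reagent delivery time from metadata


@dataclass
class PipelineResult:
    annotations: list[MoleculeAnnotation]
    thresholds: dict[str, StateModel]
    events: EventTable
    assignments: list[ClassAssignment]

    @property
    def selected(self) -> list[MoleculeAnnotation]:
        return [a for a in self.annotations if a.selected]


def estimate_thresholds(
    traces: TraceSet,
    annotations: list[MoleculeAnnotation],
    params: EventParams = EventParams(),
    t0: float | None = None,
) -> dict[str, StateModel]:
    """Per-reporter two-state FRET models from pooled selected molecules."""
    meta = traces.meta
    pools: dict[str, list[np.ndarray]] = {r: [] for r in meta.channel_reporter_map.values()}
    ann_by_id = {a.molecule_id: a for a in annotations}
    dt = meta.frame_period
    for trace in traces:
        ann = ann_by_id.get(trace.molecule_id)
        if ann is None or not ann.selected:
            continue
        trace = unmix_trace(trace, meta)
        window = usable_window(ann, meta, t0)
        i0 = max(int(window[0] / dt), 0)
        i1 = min(int(window[1] / dt), trace.n_frames)
        for reporter, series in fret_series(trace, meta, params).items():
            pool = series.efficiency[i0:i1]
            pools[reporter].append(pool[np.isfinite(pool)])
    models = {}
    for reporter, chunks in pools.items():
        values = np.concatenate(chunks) if chunks else np.empty(0)
        models[reporter] = estimate_fret_states(values, params)
    return models


def detect_events(
    traces: TraceSet,
    annotations: list[MoleculeAnnotation],
    thresholds: dict[str, StateModel],
    params: EventParams = EventParams(),
    threshold_overrides: dict[str, float] | None = None,
) -> EventTable:
    """State assignment and event extraction for every selected molecule."""
    meta = traces.meta
    overrides = threshold_overrides or {}
    frames: list[pd.DataFrame] = []
    ann_by_id = {a.molecule_id: a for a in annotations}
    for trace in traces:
        ann = ann_by_id.get(trace.molecule_id)
        if ann is None or not ann.selected:
            continue
        trace = unmix_trace(trace, meta)
        for reporter, series in fret_series(trace, meta, params).items():
            model = thresholds[reporter]
            threshold = overrides.get(reporter, model.threshold)
            states = assign_states(series, threshold, trace, meta, model, params)
            table = extract_events(states, ann, meta, params, fret=series)
            if len(table):
                frames.append(table.df)
    if not frames:
        return EventTable.empty()
    return EventTable(pd.concat(frames, ignore_index=True)).canonical()


def run_pipeline(traces: TraceSet, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run selection, threshold estimation, detection and classification."""
    annotations = select_molecules(traces, mode=config.mode, params=config.selection)
    thresholds = estimate_thresholds(traces, annotations, config.events, config.t0)
    events = detect_events(
        traces, annotations, thresholds, config.events, config.threshold_overrides
    )
    reporters = list(traces.meta.channel_reporter_map.values())
    assignments = classify_molecules(events, annotations, reporters, traces.meta, config.t0)
    return PipelineResult(
        annotations=annotations,
        thresholds=thresholds,
        events=events,
        assignments=assignments,
    )


__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "detect_events",
    "estimate_thresholds",
    "run_pipeline",
]
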