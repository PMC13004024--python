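"""FRET efficiency, state thresholds, anticorrelation and event extraction."""

import numpy as np
import pytest

from conftest import h30_kinetics
from smprobe.events import (
    BOUND,
    MISSING,
    EventParams,
    anticorrelation_check,
    assign_states,
    compute_fret,
    estimate_fret_states,
    extract_events,
    fret_series,
    unmix_trace,
)
from smprobe.io import DONOR, ExperimentMeta, Trace
from smprobe.pipeline import PipelineConfig, run_pipeline
from smprobe.selection import IMMOBILIZED, MoleculeAnnotation
from smprobe.simulate import SimulationConfig, StickingModel, simulate_ensemble

META = ExperimentMeta(channel_reporter_map={"acceptor_1": "H30"}, dead_time=(0.0, 0.0))


class TestComputeFret:
    def test_acceptor_only_gives_one(self):
        assert compute_fret(np.array([100.0]), np.array([0.0]))[0] == 1.0

    def test_equal_intensities_give_half(self):
        assert compute_fret(np.array([50.0]), np.array([50.0]))[0] == 0.5

    def test_zero_denominator_is_missing(self):
        assert np.isnan(compute_fret(np.array([0.0]), np.array([0.0]))[0])

    def test_floor_marks_missing(self):
        e = compute_fret(np.array([10.0, 100.0]), np.array([10.0, 100.0]), floor=50.0)
        assert np.isnan(e[0]) and e[1] == 0.5


class TestEstimateFretStates:
    def test_two_state_mixture_threshold_at_midpoint(self):
        rng = np.random.default_rng(1)
        pooled = np.concatenate(
            [rng.normal(0.1, 0.03, 6000), rng.normal(0.8, 0.05, 1500)]
        )
        model = estimate_fret_states(pooled)
        assert model.low_mean == pytest.approx(0.1, abs=0.02)
        assert model.high_mean == pytest.approx(0.8, abs=0.03)
        assert model.threshold == pytest.approx(0.45, abs=0.03)
        assert not model.fallback_used

    def test_symmetric_mixture_midpoint_arithmetic(self):
        rng = np.random.default_rng(2)
        pooled = np.concatenate(
            [rng.normal(0.2, 0.02, 4000), rng.normal(0.6, 0.02, 4000)]
        )
        model = estimate_fret_states(pooled)
        assert model.threshold == pytest.approx(0.4, abs=0.02)

    def test_unimodal_pool_falls_back_with_warning(self):
        rng = np.random.default_rng(3)
        pooled = rng.normal(0.12, 0.03, 5000)
        with pytest.warns(UserWarning, match="unimodal"):
            model = estimate_fret_states(pooled)
        assert model.fallback_used
        assert model.threshold == EventParams().fallback_threshold

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="100"):
            estimate_fret_states(np.full(50, 0.5))


def two_state_trace(states, high_e=0.75, baseline=1000.0, bg=50.0, mol="m0"):
    occ = np.asarray(states, dtype=float)
    donor = baseline * (1 - high_e * occ) + bg
    acceptor = baseline * high_e * occ + bg
    return Trace(mol, {DONOR: donor, "acceptor_1": acceptor})


class TestAssignStates:
    def test_alternating_pattern_recovered_exactly(self):
        occ = np.tile([0, 1], 50)
        trace = two_state_trace(occ)
        series = fret_series(trace, META)["H30"]
        states = assign_states(series, 0.45, trace, META, params=EventParams(anticorrelation_enabled=False))
        np.testing.assert_array_equal(states.states, occ)

    def test_all_missing_stays_missing(self):
        trace = Trace("m0", {DONOR: np.zeros(50), "acceptor_1": np.zeros(50)})
        series = fret_series(trace, META)["H30"]
        states = assign_states(series, 0.45, trace, META)
        assert (states.states == MISSING).all()

    def test_short_missing_gap_bridged(self):
        occ = np.concatenate([np.ones(10), np.ones(2), np.ones(10)])
        trace = two_state_trace(occ)
        series = fret_series(trace, META)["H30"]
        series.efficiency[10:12] = np.nan  # e.g. a blink below the floor
        states = assign_states(
            series, 0.45, trace, META, params=EventParams(anticorrelation_enabled=False)
        )
        assert (states.states == BOUND).all()

    def test_invalid_threshold_rejected(self):
        trace = two_state_trace(np.ones(10))
        series = fret_series(trace, META)["H30"]
        with pytest.raises(ValueError, match="threshold"):
            assign_states(series, 1.5, trace, META)


class TestAnticorrelation:
    def test_true_event_passes(self):
        occ = np.concatenate([np.zeros(20), np.ones(10), np.zeros(20)])
        trace = two_state_trace(occ)
        assert anticorrelation_check(trace, "acceptor_1", 20, 30)

    def test_acceptor_only_pulse_fails(self):
        donor = np.full(50, 1050.0)
        acceptor = np.full(50, 50.0)
        acceptor[20:30] += 700.0  # sticking: no donor response
        trace = Trace("m0", {DONOR: donor, "acceptor_1": acceptor})
        assert not anticorrelation_check(trace, "acceptor_1", 20, 30)

    def test_single_frame_true_event_passes(self):
        occ = np.zeros(50)
        occ[25] = 1.0
        trace = two_state_trace(occ)
        assert anticorrelation_check(trace, "acceptor_1", 25, 26)

    def test_sticking_pulses_rejected_end_to_end(self):
        config = SimulationConfig(
            n_molecules=25,
            class_probabilities={"H30+": 1.0},
            kinetics=h30_kinetics(),
            cotranscriptional=False,
            sticking=StickingModel(rate=0.05, mean_duration=0.5, amplitude=1000.0),
            seed=31,
        )
        traces, truth = simulate_ensemble(config)
        strict = run_pipeline(traces, PipelineConfig(mode=IMMOBILIZED))
        loose_params = EventParams(anticorrelation_enabled=False)
        loose = run_pipeline(
            traces,
            PipelineConfig(mode=IMMOBILIZED, events=loose_params),
        )
        # without the filter the sticking pulses inflate the event count
        assert len(loose.events) > 1.10 * len(strict.events)
        # filtered counts stay close to the detectable true events: those of
        # selected molecules, before donor bleach, longer than one frame
        selected_ids = {a.molecule_id: a for a in strict.selected}
        n_truth = 0
        for mol in truth.molecules:
            ann = selected_ids.get(mol.molecule_id)
            if ann is None:
                continue
            for s, e in mol.intervals["H30"]:
                if e - s >= 0.1 and e <= ann.donor_bleach_time:
                    n_truth += 1
        assert abs(len(strict.events) - n_truth) / n_truth < 0.10


class TestExtractEvents:
    def ann(self, n_frames=100):
        return MoleculeAnnotation(
            molecule_id="m0", selected=True, duration=n_frames * 0.1
        )

    def test_seven_frame_run_becomes_single_event(self):
        states = np.zeros(100, dtype=np.int8)
        states[40:47] = BOUND
        from smprobe.events import StateSeries

        series = StateSeries("H30", states, 0.45, 0.1, 0.8)
        table = extract_events(series, self.ann(), META)
        assert len(table) == 1
        row = table.df.iloc[0]
        assert row["t_start"] == pytest.approx(4.0)
        assert row["t_end"] == pytest.approx(4.7)
        assert not row["left_censored"] and not row["right_censored"]

    def test_run_at_trace_end_right_censored(self):
        states = np.zeros(100, dtype=np.int8)
        states[90:] = BOUND
        from smprobe.events import StateSeries

        series = StateSeries("H30", states, 0.45, 0.1, 0.8)
        table = extract_events(series, self.ann(), META)
        assert table.df.iloc[0]["right_censored"]

    def test_run_next_to_missing_censored(self):
        states = np.zeros(100, dtype=np.int8)
        states[10:20] = BOUND
        states[20:30] = MISSING
        from smprobe.events import StateSeries

        series = StateSeries("H30", states, 0.45, 0.1, 0.8)
        table = extract_events(series, self.ann(), META)
        row = table.df.iloc[0]
        assert row["right_censored"] and not row["left_censored"]

    def test_min_event_frames_filter(self):
        states = np.zeros(100, dtype=np.int8)
        states[10:11] = BOUND
        states[50:54] = BOUND
        from smprobe.events import StateSeries

        series = StateSeries("H30", states, 0.45, 0.1, 0.8)
        table = extract_events(series, self.ann(), META, EventParams(min_event_frames=2))
        assert len(table) == 1
        assert table.df.iloc[0]["t_start"] == pytest.approx(5.0)


class TestScaleInvariance:
    def test_events_invariant_under_intensity_rescaling(self, noisy_ssrna_ensemble):
        _, traces, _, result = noisy_ssrna_ensemble
        from smprobe.io import TraceSet

        scaled = TraceSet(
            traces=[
                Trace(t.molecule_id, {c: 3.7 * v for c, v in t.channels.items()})
                for t in traces.traces
            ],
            meta=traces.meta,
        )
        rescaled = run_pipeline(scaled, PipelineConfig(mode=IMMOBILIZED))
        a = result.events.canonical().df
        b = rescaled.events.canonical().df
        assert a[["molecule_id", "reporter", "t_start", "t_end"]].equals(
            b[["molecule_id", "reporter", "t_start", "t_end"]]
        )
        np.testing.assert_allclose(a["duration"], b["duration"], rtol=1e-9)
        np.testing.assert_allclose(a["t_start_sub"], b["t_start_sub"], rtol=1e-9)

    def test_unmixing_restores_ideal_channels(self, noisy_ssrna_ensemble):
        config, traces, _, _ = noisy_ssrna_ensemble
        trace = traces.traces[0]
        restored = unmix_trace(trace, traces.meta)
        # donor leak into the next channel removed: unbound acceptor level
        # returns to ~background instead of background + leak
        live = trace.channels[DONOR] > 0
        assert np.median(restored.channels["acceptor_1"][live]) < np.median(
            trace.channels["acceptor_1"][live]
        )
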