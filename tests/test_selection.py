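"""Selection rules: change-point step detection and the published selection criteria."""

import math

import numpy as np
import pytest

from conftest import h30_kinetics
from smprobe.io import DONOR, TRANSCRIPTION, ExperimentMeta, Trace, TraceSet
from smprobe.selection import (
    COTRANSCRIPTIONAL,
    IMMOBILIZED,
    best_split,
    detect_donor_bleach,
    detect_transcription,
    read_annotations,
    select_molecules,
    write_annotations,
)
from smprobe.simulate import (
    Photophysics,
    SimulationConfig,
    simulate_ensemble,
)

META = ExperimentMeta(channel_reporter_map={"acceptor_1": "H30"})
RNG = np.random.default_rng(42)


def synthetic_trace(donor, transcription=None, acceptor=None, mol="m0"):
    channels = {DONOR: np.asarray(donor, dtype=float)}
    if transcription is not None:
        channels[TRANSCRIPTION] = np.asarray(transcription, dtype=float)
    channels["acceptor_1"] = (
        np.asarray(acceptor, dtype=float) if acceptor is not None else np.full(len(donor), 50.0)
    )
    return Trace(mol, channels)


def step_signal(n, step_at, high, low, noise=8.0, rng=RNG):
    y = np.where(np.arange(n) < step_at, high, low).astype(float)
    return y + rng.normal(0, noise, n)


class TestBestSplit:
    def test_exact_split_on_clean_step(self):
        y = np.concatenate([np.full(70, 10.0), np.full(30, 1.0)])
        k, cost2, cost1 = best_split(y)
        assert k == 70
        assert cost2 == pytest.approx(0.0, abs=1e-9)
        assert cost1 > 0

    def test_flat_signal_has_no_improvement(self):
        y = np.full(50, 3.0)
        _, cost2, cost1 = best_split(y)
        assert cost1 == pytest.approx(0.0, abs=1e-9)
        assert cost2 == pytest.approx(0.0, abs=1e-9)


class TestDonorBleach:
    def test_single_terminal_step_accepted(self):
        # bleach at 92% of a 600 s trace
        trace = synthetic_trace(step_signal(6000, 5520, 1050.0, 50.0))
        result = detect_donor_bleach(trace, META)
        assert result.ok
        assert result.time == pytest.approx(552.0, abs=0.2)

    def test_step_at_half_time_rejected(self):
        trace = synthetic_trace(step_signal(6000, 3000, 1050.0, 50.0))
        result = detect_donor_bleach(trace, META)
        assert not result.ok
        assert "bleach_outside_window" in result.reasons

    def test_two_comparable_steps_rejected(self):
        # two molecules under one spot: 2100 -> 1075 -> 50
        y = np.concatenate(
            [np.full(5000, 2100.0), np.full(500, 1075.0), np.full(500, 50.0)]
        ) + RNG.normal(0, 8, 6000)
        result = detect_donor_bleach(synthetic_trace(y), META)
        assert not result.ok
        assert "multiple_bleach_steps" in result.reasons

    def test_flat_trace_has_no_step(self):
        trace = synthetic_trace(np.full(6000, 1050.0) + RNG.normal(0, 8, 6000))
        result = detect_donor_bleach(trace, META)
        assert not result.ok
        assert "no_bleach_step" in result.reasons

    def test_fret_dips_do_not_confuse_total_intensity(self):
        # donor dips are mirrored by the acceptor, total stays flat
        donor = np.full(6000, 1050.0)
        acceptor = np.full(6000, 50.0)
        bound = slice(1000, 3000)
        donor[bound] -= 750
        acceptor[bound] += 750
        donor[5500:] = 50.0
        acceptor[5500:] = 50.0  # bleach kills FRET too
        trace = synthetic_trace(donor + RNG.normal(0, 8, 6000), acceptor=acceptor)
        result = detect_donor_bleach(trace, META)
        assert result.ok
        assert result.time == pytest.approx(550.0, abs=0.2)


def rising_tx(n=6000, onset=250, diss=650, tau=250, peak=1000.0, bg=50.0):
    t = np.arange(n, dtype=float)
    y = np.full(n, bg)
    rise = (t >= onset) & (t < diss)
    y[rise] = bg + peak * np.exp((t[rise] - diss) / tau)
    return y


class TestTranscription:
    def test_clean_rise_and_drop_detected(self):
        y = rising_tx() + RNG.normal(0, 8, 6000)
        result = detect_transcription(synthetic_trace(np.full(6000, 1050.0), y), META)
        assert result.detected
        assert result.dissociation_time == pytest.approx(65.0, abs=0.3)
        assert result.elongation_start <= 30.0

    def test_flat_background_not_detected(self):
        y = np.full(6000, 50.0) + RNG.normal(0, 8, 6000)
        result = detect_transcription(synthetic_trace(np.full(6000, 1050.0), y), META)
        assert not result.detected

    def test_late_dissociation_rejected(self):
        # drop 250 s after the rise onset violates the 200-s rule
        y = rising_tx(onset=250, diss=2750, tau=600) + RNG.normal(0, 8, 6000)
        result = detect_transcription(synthetic_trace(np.full(6000, 1050.0), y), META)
        assert not result.detected
        assert "late_dissociation" in result.reasons

    def test_stepwise_photobleach_pattern_rejected(self):
        # two half-steps down instead of one dissociation drop
        y = rising_tx(onset=250, diss=900)
        y[900:1400] = 550.0
        y[1400:] = 50.0
        result = detect_transcription(
            synthetic_trace(np.full(6000, 1050.0), y + RNG.normal(0, 8, 6000)), META
        )
        assert not result.detected

    def test_all_nan_channel_is_input_error(self):
        with pytest.raises(ValueError, match="NaN"):
            detect_transcription(
                synthetic_trace(np.full(100, 1050.0), np.full(100, np.nan)), META
            )


class TestSelectMolecules:
    def test_immobilized_mode_ignores_transcription(self):
        # no transcription channel at all; bleach criterion alone decides
        traces = TraceSet(
            traces=[synthetic_trace(step_signal(6000, 5520, 1050.0, 50.0))], meta=META
        )
        anns = select_molecules(traces, mode=IMMOBILIZED)
        assert anns[0].selected
        assert not anns[0].transcription_detected
        assert math.isnan(anns[0].dna_dissociation_time)

    def test_empty_trace_set(self):
        assert select_molecules(TraceSet(traces=[], meta=META), mode=IMMOBILIZED) == []

    def test_selection_matches_truth_rules_on_simulated_ensemble(self):
        config = SimulationConfig(
            n_molecules=150,
            class_probabilities={"H30+": 0.6, "H30-": 0.4},
            kinetics=h30_kinetics(),
            cotranscriptional=True,
            seed=17,
        )
        traces, truth = simulate_ensemble(config)
        anns = select_molecules(traces, mode=COTRANSCRIPTIONAL)
        agree = 0
        for ann, mol in zip(anns, truth.molecules):
            bleach = mol.bleach_times[DONOR]
            truth_selected = (
                mol.dissociation_time - config.delivery <= 200.0
                and 0.8 * config.duration <= bleach <= config.duration
            )
            agree += truth_selected == ann.selected
        assert agree / len(anns) >= 0.95

    def test_noiseless_times_within_one_frame(self):
        config = SimulationConfig(
            n_molecules=40,
            class_probabilities={"H30+": 1.0},
            kinetics=h30_kinetics(),
            cotranscriptional=True,
            photophysics=Photophysics(noise_sd=0.0, crosstalk_leak=0.0),
            seed=19,
        )
        traces, truth = simulate_ensemble(config)
        anns = select_molecules(traces, mode=COTRANSCRIPTIONAL)
        checked = 0
        for ann, mol in zip(anns, truth.molecules):
            if not ann.selected:
                continue
            checked += 1
            assert ann.dna_dissociation_time == pytest.approx(
                mol.dissociation_time, abs=0.1 + 1e-9
            )
            assert ann.donor_bleach_time == pytest.approx(
                mol.bleach_times[DONOR], abs=0.1 + 1e-9
            )
        assert checked >= 20

    def test_selection_idempotent_and_order_independent(self):
        config = SimulationConfig(
            n_molecules=20,
            class_probabilities={"H30+": 1.0},
            kinetics=h30_kinetics(),
            cotranscriptional=False,
            seed=23,
        )
        traces, _ = simulate_ensemble(config)
        first = select_molecules(traces, mode=IMMOBILIZED)
        reversed_set = TraceSet(traces=list(reversed(traces.traces)), meta=traces.meta)
        second = {a.molecule_id: a for a in select_molecules(reversed_set, mode=IMMOBILIZED)}
        for a in first:
            assert second[a.molecule_id].selected == a.selected
            assert second[a.molecule_id].rejection_reasons == a.rejection_reasons

    def test_annotation_tsv_round_trip(self, tmp_path):
        config = SimulationConfig(
            n_molecules=8,
            class_probabilities={"H30+": 1.0},
            kinetics=h30_kinetics(),
            cotranscriptional=True,
            seed=29,
        )
        traces, _ = simulate_ensemble(config)
        anns = select_molecules(traces)
        path = tmp_path / "annotations.tsv"
        write_annotations(anns, path)
        back = read_annotations(path)
        for a, b in zip(anns, back):
            assert a.molecule_id == b.molecule_id
            assert a.selected == b.selected
            assert a.rejection_reasons == b.rejection_reasons
            for field in ("elongation_start", "dna_dissociation_time", "donor_bleach_time"):
                x, y = getattr(a, field), getattr(b, field)
                assert (math.isnan(x) and math.isnan(y)) or x == pytest.approx(y)
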