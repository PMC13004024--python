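"""Dwell statistics, censored exponential fits, on-rates and Kd arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smprobe.io import EventTable
from smprobe.kinetics import (
    DwellSample,
    arrival_times,
    bound_lifetimes,
    fit_exponential,
    kd_bulk,
    kd_fold_change,
    kd_single_molecule,
    on_rate_vs_concentration,
)
from smprobe.selection import MoleculeAnnotation


def make_events(rows):
    return EventTable.from_records(
        [
            {
                "molecule_id": m,
                "reporter": "S7",
                "t_start": s,
                "t_end": e,
                "left_censored": False,
                "right_censored": rc,
            }
            for m, s, e, rc in rows
        ]
    )


def make_ann(mol, bleach=600.0, duration=600.0):
    return MoleculeAnnotation(
        molecule_id=mol, selected=True, donor_bleach_time=bleach, duration=duration
    )


class TestArrivalTimes:
    def test_simple_subtraction(self):
        events = make_events([("a", 18.2, 20.0, False)])
        sample = arrival_times(events, [make_ann("a")], "S7", t0=15.0)
        assert sample.values[0] == pytest.approx(3.2)
        assert not sample.censored[0]

    def test_no_event_right_censored_at_usable_end(self):
        sample = arrival_times(EventTable.empty(), [make_ann("a")], "S7", t0=15.0)
        assert sample.values[0] == pytest.approx(585.0)
        assert sample.censored[0]

    def test_t0_after_trace_end_is_error(self):
        with pytest.raises(ValueError, match="past the usable end"):
            arrival_times(EventTable.empty(), [make_ann("a", bleach=100.0)], "S7", t0=200.0)

    def test_invariant_under_molecule_relabeling(self):
        rows = [("a", 30.0, 31.0, False), ("b", 40.0, 41.0, False)]
        anns = [make_ann("a"), make_ann("b")]
        sample = arrival_times(make_events(rows), anns, "S7", t0=25.0)
        swapped = make_events([("b", 30.0, 31.0, False), ("a", 40.0, 41.0, False)])
        sample2 = arrival_times(swapped, anns, "S7", t0=25.0)
        assert sorted(sample.values) == sorted(sample2.values)

    def test_exponential_arrival_median(self):
        # pseudo-first-order rate 0.2166/s -> median ln2/rate = 3.2 s
        rng = np.random.default_rng(0)
        n = 2000
        arrivals = rng.exponential(1 / 0.2166, n)
        rows = [(f"m{i}", 25.0 + a, 25.0 + a + 1.0, False) for i, a in enumerate(arrivals)]
        anns = [make_ann(f"m{i}") for i in range(n)]
        sample = arrival_times(make_events(rows), anns, "S7", t0=25.0)
        assert sample.median() == pytest.approx(math.log(2) / 0.2166, rel=0.05)


class TestBoundLifetimes:
    def test_median_of_plain_durations(self):
        events = make_events(
            [("a", 0.0, 1.0, False), ("a", 2.0, 4.0, False), ("a", 5.0, 9.0, False)]
        )
        sample = bound_lifetimes(events)
        assert sample.median() == pytest.approx(2.0)

    def test_censored_events_excluded_from_naive_median_kept_for_mle(self):
        events = make_events(
            [("a", 0.0, 1.0, False), ("a", 2.0, 3.0, False), ("a", 5.0, 100.0, True)]
        )
        sample = bound_lifetimes(events)
        assert sample.median(method="naive") == pytest.approx(1.0)
        assert sample.n == 3 and sample.n_uncensored == 2

    def test_km_median_used_under_heavy_censoring(self):
        rng = np.random.default_rng(1)
        true = rng.exponential(2.0, 4000)
        limit = rng.uniform(0.0, 6.0, 4000)
        observed = np.minimum(true, limit)
        censored = true > limit
        sample = DwellSample(np.maximum(observed, 1e-6), censored)
        assert sample.censoring_fraction > 0.3
        # KM corrects for censoring; naive median of observed values is low
        assert sample.median() == pytest.approx(2.0 * math.log(2), rel=0.07)
        naive = float(np.median(observed[~censored]))
        assert naive < 0.9 * 2.0 * math.log(2)


class TestFitExponential:
    def test_uncensored_rate_matches_inverse_mean(self):
        rng = np.random.default_rng(2)
        values = rng.exponential(1 / 0.433, 5000)
        sample = DwellSample(values, np.zeros(5000, dtype=bool))
        fit = fit_exponential(sample, 1)
        oracle = 1.0 / values.mean()
        assert fit.rates[0] == pytest.approx(oracle, rel=1e-9)
        assert fit.rates[0] == pytest.approx(0.433, rel=0.03)

    def test_censored_mle_beats_naive_estimator(self):
        rng = np.random.default_rng(3)
        true = rng.exponential(1 / 0.433, 5000)
        limit = rng.exponential(1 / 0.2, 5000)  # ~30% right-censoring
        observed = np.minimum(true, limit)
        censored = true > limit
        assert 0.25 < censored.mean() < 0.42
        sample = DwellSample(observed, censored)
        fit = fit_exponential(sample, 1)
        assert fit.rates[0] == pytest.approx(0.433, rel=0.05)
        naive = 1.0 / observed[~censored].mean()
        assert naive > 1.15 * 0.433  # dropping censored dwells overestimates

    def test_two_component_mixture_recovered(self):
        rng = np.random.default_rng(4)
        fast = rng.exponential(1 / 0.9, 2500)
        slow = rng.exponential(1 / 0.06, 2500)
        values = np.concatenate([fast, slow])
        sample = DwellSample(values, np.zeros(5000, dtype=bool))
        fit = fit_exponential(sample, 2)
        assert fit.rates[0] == pytest.approx(0.9, rel=0.15)
        assert fit.rates[1] == pytest.approx(0.06, rel=0.15)
        assert fit.weights[0] == pytest.approx(0.5, abs=0.08)
        assert fit.model_preference > 10  # two components clearly preferred

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="uncensored"):
            fit_exponential(DwellSample(np.ones(5), np.zeros(5, dtype=bool)), 1)


class TestOnRate:
    def test_two_points_exact_line(self):
        fit = on_rate_vs_concentration([100e-9, 400e-9], [0.108, 0.432])
        assert fit.kon == pytest.approx(1.08e6, rel=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_slope_recovered_with_scatter(self):
        rng = np.random.default_rng(5)
        conc = np.array([100e-9, 200e-9, 400e-9])
        rates = 1.08e6 * conc * (1 + rng.normal(0, 0.02, 3))
        fit = on_rate_vs_concentration(conc, rates)
        assert fit.kon == pytest.approx(1.08e6, rel=0.05)
        assert fit.r_squared > 0.98

    def test_single_concentration_is_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            on_rate_vs_concentration([200e-9], [0.2])


class TestKd:
    def test_symmetry_point(self):
        # Y = 0.5 -> Kd equals the protein concentration
        events = make_events([("a", 200.0, 300.0, False)])
        est = kd_single_molecule(events, (200.0, 400.0), p0=20e-9)
        assert est.y == pytest.approx(0.5)
        assert est.kd == pytest.approx(20e-9)

    def test_hand_arithmetic(self):
        # t_PR = 100 s, t_R = 300 s -> Y = 0.25, Kd = 3 * P0 = 60 nM
        events = make_events([("a", 200.0, 300.0, False)])
        est = kd_single_molecule(events, (200.0, 600.0), p0=20e-9)
        assert est.y == pytest.approx(0.25)
        assert est.kd == pytest.approx(60e-9)

    def test_always_bound_limit(self):
        events = make_events([("a", 200.0, 400.0, False)])
        est = kd_single_molecule(events, (200.0, 400.0), p0=20e-9)
        assert est.y == pytest.approx(1.0)
        assert est.kd == pytest.approx(0.0, abs=1e-18)

    def test_never_bound_is_flagged_undefined(self):
        est = kd_single_molecule(EventTable.empty(), (200.0, 400.0), p0=20e-9)
        assert est.y == 0.0
        assert est.kd is None and not est.defined

    def test_bulk_hand_arithmetic(self):
        # (10, 90) and (30, 70) -> Y = 40/200 = 0.2, Kd = 4 P0
        a = make_events([("a", 200.0, 210.0, False)])
        b = make_events([("b", 200.0, 230.0, False)])
        est = kd_bulk([(a, (200.0, 300.0)), (b, (200.0, 300.0))], p0=20e-9)
        assert est.y == pytest.approx(0.2)
        assert est.kd == pytest.approx(80e-9)

    def test_bulk_of_single_molecule_equals_single(self):
        events = make_events([("a", 210.0, 260.0, False)])
        single = kd_single_molecule(events, (200.0, 500.0), p0=20e-9)
        bulk = kd_bulk([(events, (200.0, 500.0))], p0=20e-9)
        assert bulk.kd == pytest.approx(single.kd)

    def test_pooling_invariance_for_identical_molecules(self):
        events = make_events([("a", 210.0, 260.0, False)])
        single = kd_single_molecule(events, (200.0, 500.0), p0=20e-9)
        bulk = kd_bulk([(events, (200.0, 500.0))] * 7, p0=20e-9)
        assert bulk.kd == pytest.approx(single.kd)

    def test_identical_conditions_fold_change_one(self):
        events = make_events([("a", 210.0, 260.0, False)])
        est = kd_bulk([(events, (200.0, 500.0))], p0=20e-9)
        assert kd_fold_change(est, est) == pytest.approx(1.0)

    def test_dead_time_excluded_from_both_terms(self):
        events = make_events([("a", 10.0, 30.0, False)])
        est = kd_single_molecule(events, (0.0, 100.0), p0=20e-9, dead_window=(15.0, 25.0))
        assert est.t_bound == pytest.approx(10.0)  # 10 s of the event fell in dead time
        assert est.t_bound + est.t_free == pytest.approx(90.0)

    def test_empty_window_is_error(self):
        with pytest.raises(ValueError, match="window"):
            kd_single_molecule(EventTable.empty(), (300.0, 200.0), p0=20e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0.01, max_value=0.99),
        st.floats(min_value=1e-10, max_value=1e-6),
    )
    def test_kd_monotone_decreasing_in_y(self, y, p0):
        window = (0.0, 100.0)
        e1 = make_events([("a", 0.0, 100.0 * y, False)])
        e2 = make_events([("a", 0.0, min(100.0 * y + 1.0, 100.0), False)])
        k1 = kd_single_molecule(e1, window, p0)
        k2 = kd_single_molecule(e2, window, p0)
        assert k2.y >= k1.y
        assert k2.kd <= k1.kd + 1e-30
        assert 0.0 <= k1.y <= 1.0
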