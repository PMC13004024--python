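"""Continuous-time simulator for multicolor single-molecule probing traces.

The simulator emulates a surface-immobilized transcription/probing assay:
each molecule is drawn from a set of *folding classes* (e.g. ``S7+/H30-``)
that fix which reporters (short DNA probes, a labeled protein) can bind at
all.  For every "+" reporter, binding follows an alternating renewal
process: arrivals at the pseudo-first-order rate ``kon * c`` and departures
from a single- or two-component exponential dwell model, optionally gated by
a slow two-state accessibility switch and blocked while a mutually exclusive
partner is bound.  Binding reports through FRET: the donor dims while the
matching acceptor channel lights up.  A transcription-reporter channel rises
exponentially as the DNA template 3' end approaches the surface and drops to
background in a single step when the template dissociates.  The donor
photobleaches in a single step, with a strongly increased bleaching hazard
late in the movie emulating the deliberately induced terminal bleach.

Rendering integrates the continuous state path over 100-ms camera frames
(boundary frames get fractional intensities), applies a linear spectral
crosstalk matrix, adds Gaussian read noise, and zeroes a laser dead-time
window used for reagent injection.  Given one master seed, molecule ``i``
uses the substream seeded by ``(seed, i)``, so ensembles are bit-reproducible
and stable under molecule reordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import (
    ACCEPTOR_PREFIX,
    DONOR,
    TRANSCRIPTION,
    EventTable,
    ExperimentMeta,
    Trace,
    TraceSet,
)


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


# ---------------------------------------------------------------------------
# class labels
# ---------------------------------------------------------------------------


def parse_class_label(label: str) -> dict[str, bool]:
    """Parse ``"S7+/H30-"`` into ``{"S7": True, "H30": False}``."""
    signs: dict[str, bool] = {}
    for token in label.split("/"):
        token = token.strip()
        if not token or token[-1] not in "+-":
            raise ConfigurationError(f"malformed class label token {token!r}")
        signs[token[:-1]] = token[-1] == "+"
    return signs


def make_class_label(signs: dict[str, bool], order: list[str]) -> str:
    return "/".join(f"{r}{'+' if signs[r] else '-'}" for r in order)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DwellMixture:
    """Mixture of exponential bound-dwell components (rates in 1/s)."""

    rates: tuple[float, ...]
    weights: tuple[float, ...]

    def validate(self) -> None:
        if len(self.rates) != len(self.weights):
            raise ConfigurationError("dwell mixture rates/weights length mismatch")
        if any(r <= 0 for r in self.rates):
            raise ConfigurationError("dwell mixture rates must be > 0")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ConfigurationError("dwell mixture weights must sum to 1")

    def draw(self, rng: np.random.Generator) -> float:
        k = rng.choice(len(self.rates), p=np.asarray(self.weights))
        return rng.exponential(1.0 / self.rates[k])


@dataclass(frozen=True)
class ReporterKinetics:
    """Binding kinetics of one reporter (DNA probe or protein).

    ``binding_rate_constant`` (1/M/s) times ``probe_concentration`` (M) gives
    the pseudo-first-order arrival rate.  Departures use either a single
    ``unbinding_rate`` (1/s) or a ``dwell_mixture``.  ``gating`` optionally
    adds a slow two-state accessibility switch ``(rate_open, rate_close)``
    (1/s); binding can initiate only while the gate is open.
    """

    binding_rate_constant: float
    probe_concentration: float
    unbinding_rate: float | None = None
    dwell_mixture: DwellMixture | None = None
    gating: tuple[float, float] | None = None

    @property
    def pseudo_first_order_rate(self) -> float:
        return self.binding_rate_constant * self.probe_concentration

    def validate(self, name: str) -> None:
        if self.binding_rate_constant < 0 or self.probe_concentration < 0:
            raise ConfigurationError(f"{name}: rates and concentrations must be >= 0")
        if (self.unbinding_rate is None) == (self.dwell_mixture is None):
            raise ConfigurationError(
                f"{name}: exactly one of unbinding_rate / dwell_mixture required"
            )
        if self.unbinding_rate is not None and self.unbinding_rate < 0:
            raise ConfigurationError(f"{name}: unbinding_rate must be >= 0")
        if self.dwell_mixture is not None:
            self.dwell_mixture.validate()
        if self.gating is not None and any(g < 0 for g in self.gating):
            raise ConfigurationError(f"{name}: gating rates must be >= 0")

    def draw_dwell(self, rng: np.random.Generator) -> float:
        if self.dwell_mixture is not None:
            return self.dwell_mixture.draw(rng)
        if self.unbinding_rate == 0:
            return math.inf
        return rng.exponential(1.0 / self.unbinding_rate)


@dataclass(frozen=True)
class TranscriptionModel:
    """Transcription-reporter signal model.

    The channel rises as ``bg + (peak - bg) * exp(-(t_d - t) / tau)`` from
    reagent delivery until the template dissociation time ``t_d``, then drops
    to background within one frame.  ``t_d - delivery`` is log-normal with
    the configured median (the time the nascent RNA stays associated with the
    transcription machinery); it is not truncated, so the downstream 200-s
    selection rule sees molecules on both sides of its cutoff.
    """

    rise_time_constant: float = 25.0
    peak: float = 1000.0
    dissociation_median: float = 50.0
    dissociation_sigma: float = 0.7
    max_allowed_dissociation: float = 200.0

    def draw_dissociation(self, rng: np.random.Generator) -> float:
        return float(
            rng.lognormal(mean=math.log(self.dissociation_median), sigma=self.dissociation_sigma)
        )


@dataclass(frozen=True)
class Photophysics:
    """Intensity model: baselines, per-reporter FRET efficiency, crosstalk.

    ``crosstalk_leak`` builds the default row-stochastic leakage matrix:
    every channel leaks that fraction of its signal into the nearest
    redder channel (dye order donor < transcription < acceptor_1..3).  A full
    ``crosstalk_matrix`` (rows = source channel, in channel order) overrides
    it.  ``noise_sd`` is additive Gaussian read noise per frame (AU).
    """

    donor_baseline: float = 1000.0
    background: float = 50.0
    noise_sd: float = 25.0
    fret_efficiency: dict[str, float] = field(default_factory=dict)
    crosstalk_leak: float = 0.1
    crosstalk_matrix: np.ndarray | None = None

    def efficiency(self, reporter: str) -> float:
        return self.fret_efficiency.get(reporter, 0.75)


@dataclass(frozen=True)
class BleachModel:
    """Two-phase single-step donor photobleaching.

    During the main acquisition the donor survives an exponential time with
    mean ``donor_mean_time`` (long; the oxygen scavenger is active).  From
    ``induction_fraction`` of the trace onward the hazard switches to the
    short ``induced_mean_time``, emulating the weakened scavenger injected
    near the end to certify single molecules by a terminal bleaching step.
    """

    donor_mean_time: float = 6000.0
    induction_fraction: float = 0.92
    induced_mean_time: float = 10.0


@dataclass(frozen=True)
class StickingModel:
    """Nonspecific surface-sticking artifacts: acceptor-only pulses.

    Poisson pulses (rate in 1/s per molecule) of exponential duration are
    added to the acceptor channel only, with no donor anticorrelation, to
    exercise the anticorrelation filter.
    """

    rate: float = 0.0
    mean_duration: float = 0.5
    amplitude: float = 600.0


@dataclass(frozen=True)
class DeadTime:
    start: float = 15.0
    length: float = 10.0


@dataclass
class SimulationConfig:
    """Full specification of a simulated ensemble (defaults = study conditions)."""

    n_molecules: int
    class_probabilities: dict[str, float]
    kinetics: dict[str, ReporterKinetics]
    frame_period: float = 0.1
    duration: float = 600.0
    exclusivity_pairs: tuple[tuple[str, str], ...] = ()
    cotranscriptional: bool = True
    transcription: TranscriptionModel = field(default_factory=TranscriptionModel)
    photophysics: Photophysics = field(default_factory=Photophysics)
    bleach: BleachModel = field(default_factory=BleachModel)
    dead_time: DeadTime = field(default_factory=DeadTime)
    delivery_time: float | None = None
    sticking: StickingModel | None = None
    seed: int = 0

    # -- derived -------------------------------------------------------------

    @property
    def reporters(self) -> list[str]:
        return list(self.kinetics)

    @property
    def delivery(self) -> float:
        if self.delivery_time is not None:
            return self.delivery_time
        return self.dead_time.start + self.dead_time.length

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_period))

    def channel_order(self) -> list[str]:
        channels = [DONOR]
        if self.cotranscriptional:
            channels.append(TRANSCRIPTION)
        channels += [f"{ACCEPTOR_PREFIX}{i + 1}" for i in range(len(self.reporters))]
        return channels

    def reporter_channel_map(self) -> dict[str, str]:
        return {
            f"{ACCEPTOR_PREFIX}{i + 1}": rep for i, rep in enumerate(self.reporters)
        }

    def crosstalk(self) -> np.ndarray:
        channels = self.channel_order()
        if self.photophysics.crosstalk_matrix is not None:
            m = np.asarray(self.photophysics.crosstalk_matrix, dtype=float)
            if m.shape != (len(channels), len(channels)):
                raise ConfigurationError("crosstalk_matrix shape mismatch")
            return m
        leak = self.photophysics.crosstalk_leak
        m = np.eye(len(channels))
        for i in range(len(channels) - 1):
            m[i, i] = 1.0 - leak
            m[i, i + 1] = leak
        return m

    def validate(self) -> None:
        if self.n_molecules < 0:
            raise ConfigurationError("n_molecules must be >= 0")
        if self.frame_period <= 0:
            raise ConfigurationError("frame_period must be > 0")
        if self.duration < self.dead_time.start + self.dead_time.length:
            raise ConfigurationError("duration must cover the dead-time window")
        total = sum(self.class_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class probabilities sum to {total}, expected 1")
        reporters = set(self.reporters)
        for name, kin in self.kinetics.items():
            kin.validate(name)
        for label in self.class_probabilities:
            signs = parse_class_label(label)
            unknown = set(signs) - reporters
            if unknown:
                raise ConfigurationError(
                    f"class label {label!r} references unknown reporters {sorted(unknown)}"
                )
            missing = reporters - set(signs)
            if missing:
                raise ConfigurationError(
                    f"class label {label!r} must sign every reporter; missing {sorted(missing)}"
                )
        for a, b in self.exclusivity_pairs:
            if a not in reporters or b not in reporters:
                raise ConfigurationError(
                    f"exclusivity pair ({a!r}, {b!r}) references unknown reporter"
                )
        for rep in reporters:
            e = self.photophysics.efficiency(rep)
            if not (0.0 < e <= 1.0):
                raise ConfigurationError(f"FRET efficiency of {rep!r} must be in (0, 1]")
        self.crosstalk()


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class MoleculeTruth:
    molecule_id: str
    class_label: str
    signs: dict[str, bool]
    intervals: dict[str, list[tuple[float, float]]]
    dissociation_time: float | None  # absolute (s); None in immobilized mode
    bleach_times: dict[str, float]  # fluorophore -> absolute time (inf = never)


@dataclass
class SimulationTruth:
    """Ground-truth state paths of a simulated ensemble."""

    molecules: list[MoleculeTruth]
    duration: float
    frame_period: float

    def molecule(self, molecule_id: str) -> MoleculeTruth:
        for m in self.molecules:
            if m.molecule_id == molecule_id:
                return m
        raise KeyError(molecule_id)


# ---------------------------------------------------------------------------
# per-molecule kinetic path
# ---------------------------------------------------------------------------


def _simulate_binding(
    rng: np.random.Generator,
    config: SimulationConfig,
    signs: dict[str, bool],
    t_start: float,
    t_end: float,
) -> dict[str, list[tuple[float, float]]]:
    """Event-driven alternating renewal processes for all active reporters.

    Exponential clocks (binding, gate flips) are resampled after every event,
    which is statistically exact by memorylessness; scheduled unbinding times
    are stored because mixture dwells are not memoryless.
    """
    active = [r for r in config.reporters if signs.get(r, False)]
    blocked_by: dict[str, list[str]] = {r: [] for r in active}
    for a, b in config.exclusivity_pairs:
        if a in blocked_by and b in blocked_by:
            blocked_by[a].append(b)
            blocked_by[b].append(a)

    bound: dict[str, bool] = {r: False for r in active}
    unbind_at: dict[str, float] = {}
    started: dict[str, float] = {}
    gate_open: dict[str, bool] = {}
    for r in active:
        gating = config.kinetics[r].gating
        if gating is None:
            gate_open[r] = True
        else:
            k_open, k_close = gating
            p_open = k_open / (k_open + k_close) if (k_open + k_close) > 0 else 1.0
            gate_open[r] = bool(rng.random() < p_open)

    intervals: dict[str, list[tuple[float, float]]] = {r: [] for r in config.reporters}
    t = t_start
    while t < t_end:
        candidates: list[tuple[float, int, str, str]] = []
        for r in active:
            kin = config.kinetics[r]
            if bound[r]:
                candidates.append((unbind_at[r], 0, "unbind", r))
            else:
                rate = kin.pseudo_first_order_rate
                free = gate_open[r] and not any(bound[p] for p in blocked_by[r])
                if free and rate > 0:
                    candidates.append((t + rng.exponential(1.0 / rate), 1, "bind", r))
            if kin.gating is not None:
                k_open, k_close = kin.gating
                flip_rate = k_close if gate_open[r] else k_open
                if flip_rate > 0:
                    candidates.append((t + rng.exponential(1.0 / flip_rate), 2, "flip", r))
        if not candidates:
            break
        t_next, _, kind, r = min(candidates)
        if t_next >= t_end:
            break
        t = t_next
        if kind == "bind":
            bound[r] = True
            started[r] = t
            unbind_at[r] = t + config.kinetics[r].draw_dwell(rng)
        elif kind == "unbind":
            bound[r] = False
            intervals[r].append((started[r], t))
        else:  # gate flip
            gate_open[r] = not gate_open[r]
    for r in active:
        if bound[r]:
            intervals[r].append((started[r], t_end))
    return intervals


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _integrate_segments(
    n_frames: int, dt: float, segments: list[tuple[float, float, float]]
) -> np.ndarray:
    """Frame-average a piecewise-constant signal given as (start, end, value)."""
    out = np.zeros(n_frames)
    t_max = n_frames * dt
    for t0, t1, v in segments:
        t0 = max(t0, 0.0)
        t1 = min(t1, t_max)
        if t1 <= t0 or v == 0.0:
            continue
        f0 = t0 / dt
        f1 = t1 / dt
        i0 = int(math.floor(f0))
        i1 = int(math.ceil(f1))
        out[i0:i1] += v
        out[i0] -= v * (f0 - i0)
        if i1 - 1 < n_frames:
            out[i1 - 1] -= v * (i1 - f1)
    return out


def _fret_rate_share(bound: list[str], photo: Photophysics) -> tuple[float, dict[str, float]]:
    """Total transfer efficiency and per-acceptor share for a bound set.

    Competing acceptors split the donor excitation according to their
    transfer-rate ratios ``E / (1 - E)``; with a single bound acceptor this
    reduces exactly to its configured efficiency.
    """
    if not bound:
        return 0.0, {}
    rates = {r: photo.efficiency(r) / (1.0 - photo.efficiency(r) + 1e-12) for r in bound}
    total = sum(rates.values())
    e_tot = total / (1.0 + total)
    return e_tot, {r: e_tot * rates[r] / total for r in bound}


def _piecewise_fret(
    intervals: dict[str, list[tuple[float, float]]],
    photo: Photophysics,
    t_stop: float,
) -> tuple[list[tuple[float, float, float]], dict[str, list[tuple[float, float, float]]]]:
    """Donor / per-reporter acceptor signal segments up to donor bleach."""
    points: list[tuple[float, int, str]] = []
    for r, ivs in intervals.items():
        for a, b in ivs:
            a, b = min(a, t_stop), min(b, t_stop)
            if b > a:
                points.append((a, 1, r))
                points.append((b, -1, r))
    donor_segments: list[tuple[float, float, float]] = []
    acceptor_segments: dict[str, list[tuple[float, float, float]]] = {r: [] for r in intervals}
    if not points:
        donor_segments.append((0.0, t_stop, photo.donor_baseline))
        return donor_segments, acceptor_segments
    points.sort()
    bound: set[str] = set()
    prev = 0.0
    idx = 0
    boundaries = points + [(t_stop, 0, "")]
    for t, delta, r in boundaries:
        if t > prev:
            e_tot, shares = _fret_rate_share(sorted(bound), photo)
            donor_segments.append((prev, t, photo.donor_baseline * (1.0 - e_tot)))
            for rep, share in shares.items():
                acceptor_segments[rep].append((prev, t, photo.donor_baseline * share))
            prev = t
        if delta == 1:
            bound.add(r)
        elif delta == -1:
            bound.discard(r)
        idx += 1
    return donor_segments, acceptor_segments


def _transcription_frames(
    n_frames: int, dt: float, model: TranscriptionModel, delivery: float, t_diss: float
) -> np.ndarray:
    """Frame-integrated transcription-reporter signal (background excluded)."""
    edges = np.arange(n_frames + 1) * dt
    lo = np.clip(edges[:-1], delivery, t_diss)
    hi = np.clip(edges[1:], delivery, t_diss)
    tau = model.rise_time_constant
    amp = model.peak  # signal above background at dissociation
    integral = amp * tau * (np.exp((hi - t_diss) / tau) - np.exp((lo - t_diss) / tau))
    return integral / dt


def simulate_ensemble(config: SimulationConfig) -> tuple[TraceSet, SimulationTruth]:
    """Simulate a full ensemble; deterministic for a fixed ``config.seed``."""
    config.validate()
    photo = config.photophysics
    dt = config.frame_period
    n_frames = config.n_frames
    channels = config.channel_order()
    crosstalk = config.crosstalk()
    labels = list(config.class_probabilities)
    probs = np.array([config.class_probabilities[k] for k in labels])
    reporter_channels = config.reporter_channel_map()
    channel_of = {rep: ch for ch, rep in reporter_channels.items()}
    dead_lo, dead_hi = config.dead_time.start, config.dead_time.start + config.dead_time.length
    frame_times = np.arange(n_frames) * dt
    dead_mask = (frame_times >= dead_lo) & (frame_times < dead_hi)

    traces: list[Trace] = []
    truth_molecules: list[MoleculeTruth] = []
    for i in range(config.n_molecules):
        rng = np.random.default_rng([config.seed, i])
        label = labels[rng.choice(len(labels), p=probs)]
        signs = parse_class_label(label)

        t_diss: float | None = None
        if config.cotranscriptional:
            t_diss = config.delivery + config.transcription.draw_dissociation(rng)

        t_bleach = rng.exponential(config.bleach.donor_mean_time)
        induction = config.bleach.induction_fraction * config.duration
        if t_bleach >= induction:
            t_bleach = induction + rng.exponential(config.bleach.induced_mean_time)

        intervals = _simulate_binding(rng, config, signs, config.delivery, config.duration)

        # -- render ---------------------------------------------------------
        t_stop = min(t_bleach, config.duration)
        donor_segments, acceptor_segments = _piecewise_fret(intervals, photo, t_stop)
        raw = np.zeros((len(channels), n_frames))
        raw[channels.index(DONOR)] = _integrate_segments(n_frames, dt, donor_segments)
        for rep in config.reporters:
            raw[channels.index(channel_of[rep])] = _integrate_segments(
                n_frames, dt, acceptor_segments[rep]
            )
        if config.cotranscriptional:
            assert t_diss is not None
            raw[channels.index(TRANSCRIPTION)] = _transcription_frames(
                n_frames, dt, config.transcription, config.delivery, min(t_diss, config.duration)
            )
        if config.sticking is not None and config.sticking.rate > 0:
            for rep in config.reporters:
                n_pulses = rng.poisson(config.sticking.rate * config.duration)
                pulses = [
                    (
                        (s := rng.uniform(0.0, config.duration)),
                        s + rng.exponential(config.sticking.mean_duration),
                        config.sticking.amplitude,
                    )
                    for _ in range(n_pulses)
                ]
                raw[channels.index(channel_of[rep])] += _integrate_segments(n_frames, dt, pulses)

        observed = crosstalk.T @ raw + photo.background
        if photo.noise_sd > 0:
            observed = observed + rng.normal(0.0, photo.noise_sd, observed.shape)
        observed[:, dead_mask] = 0.0

        mol_id = f"mol{i:05d}"
        traces.append(
            Trace(molecule_id=mol_id, channels={ch: observed[j] for j, ch in enumerate(channels)})
        )
        truth_molecules.append(
            MoleculeTruth(
                molecule_id=mol_id,
                class_label=label,
                signs=signs,
                intervals=intervals,
                dissociation_time=t_diss,
                bleach_times={DONOR: float(t_bleach)},
            )
        )

    meta = ExperimentMeta(
        frame_period=dt,
        channel_reporter_map=reporter_channels,
        probe_concentrations={
            rep: config.kinetics[rep].probe_concentration for rep in config.reporters
        },
        delivery_time=config.delivery,
        dead_time=(config.dead_time.start, config.dead_time.length),
        channels=tuple(channels),
        crosstalk=tuple(tuple(float(v) for v in row) for row in crosstalk),
    )
    trace_set = TraceSet(traces=traces, meta=meta)
    trace_set.validate()
    return trace_set, SimulationTruth(
        molecules=truth_molecules, duration=config.duration, frame_period=dt
    )


def truth_event_table(truth: SimulationTruth, clip_to_bleach: bool = True) -> EventTable:
    """Convert ground-truth bound intervals to the :class:`EventTable` schema.

    Intervals running into the trace end are right-censored; with
    ``clip_to_bleach`` (default) intervals are truncated at the donor bleach
    time — after which binding is no longer observable — and flagged
    right-censored there as well.
    """
    rows = []
    for mol in truth.molecules:
        t_bleach = mol.bleach_times.get(DONOR, math.inf)
        limit = min(truth.duration, t_bleach) if clip_to_bleach else truth.duration
        for reporter, ivs in mol.intervals.items():
            for a, b in ivs:
                end = min(b, limit)
                if end <= a:
                    continue
                rows.append(
                    {
                        "molecule_id": mol.molecule_id,
                        "reporter": reporter,
                        "t_start": a,
                        "t_end": end,
                        "left_censored": False,
                        "right_censored": bool(b > limit or b >= truth.duration),
                    }
                )
    return EventTable.from_records(rows)


__all__ = [
    "BleachModel",
    "ConfigurationError",
    "DeadTime",
    "DwellMixture",
    "MoleculeTruth",
    "Photophysics",
    "ReporterKinetics",
    "SimulationConfig",
    "SimulationTruth",
    "StickingModel",
    "TranscriptionModel",
    "make_class_label",
    "parse_class_label",
    "simulate_ensemble",
    "truth_event_table",
]
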