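# Methods

`smprobe` analyzes multicolor single-molecule fluorescence traces from
surface-immobilized RNA probing experiments: short dye-labeled DNA probes
(and a dye-labeled ribosomal protein) bind transiently to individual
(nascent) RNA molecules, and each binding event reports through FRET with a
donor dye on the RNA. The package covers the full chain from raw per-frame
intensities to folding-class statistics, and ships a trace simulator with
exact ground truth so that every stage can be validated end to end.

## The measurement model

Each molecule contributes a set of channels sampled every 100 ms (the frame
period `dt`, configurable): a donor channel, optionally a
transcription-reporter channel (a dye on the DNA template 3' end whose
evanescent-field intensity rises exponentially as transcription proceeds),
and up to three acceptor channels, one per reporter. Binding of reporter
`k` with FRET efficiency `E_k` turns donor intensity
`D = B·(1 − E_k) + bg` and acceptor intensity `A_k = B·E_k + bg`, with `B`
the donor baseline and `bg` the camera background. When several acceptors
are bound at once their transfer rates compete
(`r_k = E_k/(1−E_k)`, `E_tot = Σr/(1+Σr)`), which reduces exactly to `E_k`
whenever a single reporter is bound — the default study condition.

The camera integrates: a frame covered by an event for a fraction `q` of
its duration sits at the fraction `q` between the unbound and bound
plateaus. This is both how the simulator renders traces (exact piecewise
integration of the continuous state path) and how the detector reads
sub-frame information back out (below).

## The simulator

Per molecule, a folding class is drawn from the configured class
probabilities; the class fixes which reporters can bind at all ("+"/"−"
signs, e.g. `S7+/H30−`). Each "+" reporter then follows an alternating
renewal process from reagent delivery to the end of the trace:

* arrivals at the pseudo-first-order rate `kon·c` (default probe condition:
  `kon = 1.083×10⁶ M⁻¹s⁻¹` at 200 nM, i.e. 0.2166 s⁻¹, arrival median
  ln2/rate = 3.2 s);
* departures from a single exponential (default `koff = 0.433 s⁻¹`, dwell
  median 1.6 s) or a two-component mixture (protein default: means 1 s and
  15 s, equal weights, emulating a short-lived scanning phase and a
  longer-lived engaged phase);
* optional slow two-state accessibility gating per reporter, and optional
  mutual-exclusivity pairs (binding blocked while the partner is bound),
  used for sites that overlap a protein footprint.

The event-driven scheme resamples the memoryless clocks (binding, gate
flips) after every transition — exact by memorylessness — and stores the
scheduled unbinding time, which is not memoryless for mixtures.

Cotranscriptional ensembles additionally draw a template dissociation time
as delivery + log-normal (median 50 s — the median time the nascent RNA
stays associated with the transcription machinery — shape 0.7, not
truncated so the 200-s selection rule is exercised on both sides); the
transcription channel rises as `bg + peak·exp(−(t_d − t)/τ)` with
`τ = 25 s` and drops to background within one frame at `t_d`.

Donor photobleaching is a single step with a two-phase hazard: mean 6000 s
during the movie (oxygen scavenger active) and mean 10 s from 92% of the
trace onward, emulating the deliberately induced terminal bleach that
certifies single molecules. A single-phase exponential cannot reproduce
the experiment's design, in which nearly every usable molecule bleaches in
the final window.

Rendering: exact frame integration of the piecewise-constant intensity
path, then a row-stochastic spectral crosstalk matrix (default: each
channel leaks 10% into its nearest redder neighbor, in dye order donor <
transcription reporter < acceptor₁₋₃), then additive Gaussian read noise
(default SD 25 AU on a 1000 AU donor baseline), then zeroing of the laser
dead-time window (default 15–25 s, used for reagent injection). Optional
acceptor-only Poisson "sticking" pulses with no donor response exercise the
anticorrelation filter. What the simulator deliberately does *not*
attempt: photon shot noise / EMCCD gain statistics (Gaussian read noise
only) and distance-dependent FRET (fixed per-reporter efficiency). Noise
level, crosstalk magnitude and baselines are free parameters of the
configuration; the defaults above are chosen to give the comfortable
signal-to-noise of a well-tuned TIRF setup (bound and unbound FRET
populations ~12 noise SDs apart). Passing tests on these defaults
demonstrate correctness of the analysis chain, not robustness to arbitrarily
poor data.

Determinism: molecule `i` uses the random substream seeded by
`(master_seed, i)`, so a fixed seed reproduces traces bit-exactly and a
prefix of a larger ensemble equals the smaller ensemble.

## Trace selection

A molecule is analyzable if (cotranscriptional mode) the transcription
channel shows a gradual rise followed by a single large drop to background
within 200 s of the rise onset, and (both modes) the FRET-conserving total
intensity (donor + all acceptors) shows exactly one downward step falling
in the terminal window of the movie (default last 20%, configurable — the
protocol's wording leaves the exact window ambiguous, so it is a parameter
rather than a guess).

Steps are found by the exact two-segment piecewise-constant least-squares
split (closed form on cumulative sums). "Single step" requires the
two-segment fit to improve on one segment by a configured factor (default
cost ratio < 0.8) while one level of binary segmentation finds no
comparable second *downward* step (≥ 50% of the main step); for the
transcription channel the drop must additionally start from near the rise
peak (≥ 75%), which rejects the stepwise-photobleach pattern of the two
template dyes. Noise scales are estimated robustly (median absolute first
difference), so all thresholds degrade gracefully to exact behavior on
noiseless data. Working on the FRET-conserving total makes bleach
detection blind to binding activity — the total is piecewise constant no
matter how busy the trace is.

On noiseless simulations, annotated dissociation and bleach times are
exact to one frame; selection agrees with the rules applied to ground
truth for ≥ 98% of molecules under default noise (disagreements are
molecules within a frame or two of a rule boundary).

## Event detection

If the experiment metadata carries the instrument's calibrated crosstalk
matrix, channels are first linearly unmixed. This mirrors the routine
single-dye bleed-through calibration of multicolor TIRF microscopes and is
essential in multi-reporter experiments: the leak copy of one acceptor's
signal in the neighboring channel is itself anticorrelated with the donor,
so no per-event test can distinguish it from genuine binding of the
neighbor reporter.

FRET efficiency is `E = I_A/(I_A + I_D)` per acceptor against the shared
donor, undefined (missing) where the denominator falls below 20% of its
per-trace median — dead-time and post-bleach frames. The floor being
relative keeps every downstream result invariant under a common rescaling
of the intensities.

The two FRET states of each reporter are fitted on E values pooled over
all selected molecules of the experiment (a two-component Gaussian mixture
with deterministic quantile initialization; pools above 200k values are
thinned with a fixed substream). The bound threshold is the midpoint of
the two state means; if the pool looks unimodal (means closer than 0.15)
a configured fallback threshold (0.45) is used with a warning. Threshold
estimation per reporter per experiment (not per molecule) is the default;
per-molecule thresholds can be had by running the pipeline per molecule.

Frames at or above threshold are bound; missing runs up to 3 frames that
are flanked by the same state do not interrupt it. Every candidate bound
run is then vetted for donor/acceptor anticorrelation: over the run
extended by 3 flanking frames, the Pearson correlation must be below −0.2
*and* the donor inside the run must sit significantly below its flanking
level (≥ 3 noise SDs of the difference of means). A genuine FRET event
dims the donor exactly when the acceptor lights up; an acceptor-only
excursion (surface sticking, baseline noise) leaves the donor flat and
fails the dip test. Because the flanking frames carry the entry/exit
transitions, the test is informative down to single-frame candidates, so
the minimum event length defaults to 1 frame: with the default noise floor
a single supra-threshold frame is already ~13 SDs from the unbound state,
and a 2-frame minimum would left-truncate the dwell distribution at
~0.15 s — by memorylessness that shifts a 1.6-s median dwell up by ~9%,
a visible bias at the experiment's time scale.

Maximal bound runs become events with half-open times on the frame grid,
flagged left/right-censored where they touch the trace start/end, a
missing stretch (dead time), or the donor bleach. Detection additionally
stores two derived quantities per event, computed from the boundary-frame
fractional occupancies (`q̂ = (I_A − A_unbound)/(A_bound − A_unbound)`,
plateaus estimated per molecule): a sub-frame `duration` (occupancy mass
over the run plus directly adjacent unbound frames) and a sub-frame event
start. Dwell and arrival medians use these; without them the sample median
of frame-quantized values snaps to the 0.1-s grid, adding up to half a
frame of quantization error. Events shorter than about half a frame
(~0.05 s) are undetectable in principle at 100-ms integration; this
residual left-truncation raises a 1.6-s median dwell by ~3–4% and a 3.2-s
median arrival by ~2%, which is the accuracy limit of the
threshold-on-integrating-camera design, not of the implementation.

## Kinetics

Bound lifetimes and arrival times (reagent delivery to first event; the
delivery reference `t0` defaults to the end of the injection dead time and
is configurable, since the protocol does not pin it down) are survival
data: molecules without an event contribute right-censored arrivals at
their usable end, and censored events enter exponential fits through
survival terms. The one-component censored MLE is closed form
(`rate = #uncensored / Σ durations`); the two-component mixture is fitted
by direct likelihood maximization from moment-based starts, with an AIC
delta reported as the model preference. Medians switch from the plain
uncensored median to Kaplan–Meier when censoring exceeds 5%. The
second-order on-rate is a weighted least-squares slope of
pseudo-first-order arrival rate versus probe concentration (intercept free
by default, constrainable to the origin).

Apparent dissociation constants use the equilibrium bound-time fraction
per molecule, `Y = t_PR/(t_PR + t_R)` and `Kd = (1−Y)/Y·[P]₀`, evaluated
inside a window from 200 s until donor bleach (both ends configurable),
with dead-time overlap excluded from both numerator and denominator and
`[P]₀` the total labeled protein concentration standing in for the free
concentration (immobilized RNA is vastly outnumbered by protein in
solution). Molecules with `Y = 0` get an explicitly undefined Kd rather
than an infinity and are excluded from per-molecule Kd distributions. The
class-level ("bulk") Kd pools all molecules of a folding class into one
virtual molecule before applying the formula, which makes it exactly equal
to the single-molecule value for n identical molecules.

## Classes, accessibility, profiles

A molecule's folding class is its per-reporter sign vector over the
declared reporters (protein first, then probes by 5'→3' target position),
with "+" meaning at least one event — censored or not; a partial event is
still evidence of accessibility — overlaps the usable window
(max(delivery, elongation start) to donor bleach, minus dead time). The
usable window for the ≥1-event rule is this package's choice; the source
protocol states the trace-usability bounds but not the classification
window explicitly. Class fractions are computed per condition over all
selected molecules (replicates pooled by concatenation); fold changes are
reported as max/min with a direction and rounded to one decimal only at
the reporting layer. The accessibility score of an ensemble or class is
the arithmetic mean over molecules of the fraction of usable time bound.
Time profiles align molecules to delivery, bin into 5-s intervals and
report the percentage of molecules with ≥ 1 event overlapping each bin,
per reporter, with the class median machinery-residence time attached.

## Clustering and reports

Molecules are compared by binary frame-wise occupancy vectors for one
reporter over the shortest common usable span (truncation to a common span
is this package's convention; the source method does not state how unequal
lengths were handled). The distance is `1 − Spearman rank correlation`;
constant vectors (no events, or saturated) have undefined correlation and
get the maximal distance 2 to any non-identical vector and 0 to an
identical one — a documented convention. Agglomeration is WPGMA with
per-molecule weights equal to binding-event counts entering the averaged
distance update, `d(i∪j, k) = (w_i d(i,k) + w_j d(j,k))/(w_i + w_j)`
(event-free molecules get unit weight so the update stays defined); the
exact weighting formula is unstated in the source and the unweighted WPGMA
is available behind a flag. Occupancy vectors rather than event-summary
features are the interpretation used, also behind the same documented
convention. Rasterplots are rendered from the leaf order; the row-order
table is the reproducible artifact and the PNG is presentation. The report
builder assembles whatever stage outputs exist into a deterministic
markdown document (absent stages are marked, never fatal).

## Problem sizes and numerical choices

The test suite and the acceptance script size their ensembles at 300–1000
molecules of 600-s traces per condition — the scale at which binomial
3-SD bands on class fractions are a few percent and median-recovery
sampling error is at or below the stated tolerances; the kinetic-median
checks pool three replicate ensembles, as the experimental analysis pools
replicates. A median over ~1000 first arrivals still carries ~4–5%
sampling error, so the 3.2-s arrival check is the statistically tightest
one in the suite. Ties and degenerate inputs are handled explicitly
throughout: empty ensembles and event tables round-trip as valid empty
containers, noiseless signals drive all SNR thresholds through a tiny
relative floor instead of zero, and mixture fits report a convergence flag
rather than raising on a flat likelihood.

## Known limitations

* Threshold-based detection on an integrating camera cannot see dwells
  below ~half a frame; dwell medians inherit a small (+3–4% at 1.6 s)
  left-truncation bias. A hidden-Markov state model could push below the
  frame time but is deliberately out of scope — the method being
  implemented is threshold-plus-inspection.
* The anticorrelation filter assumes the donor responds to binding; a
  reporter with FRET efficiency near 0 would be invisible to both the
  threshold and the filter.
* Spectral unmixing assumes the calibrated leakage matrix in the metadata
  is accurate; without it, multi-reporter experiments with strong
  crosstalk will show inflated cross-reporter coincidence.
* The simulator's noise is Gaussian and white; real sCMOS/EMCCD noise is
  neither, so absolute SNR thresholds tuned here should be revisited on
  real instrument data.
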