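# smprobe

Single-molecule fluorescence trace analysis for dynamic RNA structure
probing. `smprobe` quantifies how accessible individual (nascent) RNA
molecules are to short complementary DNA probes, and whether the same
molecules can bind a ribosomal protein — the readout used to correlate
cotranscriptional RNA folding with function, one molecule at a time.

It is written for single-molecule biophysicists who have (or want to
simulate) multichannel TIRF intensity traces: a donor dye on the RNA, a
transcription-reporter dye on the DNA template, and up to three acceptor
channels reporting probe/protein binding through FRET.

## What it computes

Given per-frame intensity traces (100-ms frames, 10–30-min movies):

1. **Trace selection** — molecules must show a gradual transcription-signal
   rise followed by a single-step drop to background within 200 s (template
   dissociation), and a single donor photobleaching step in the terminal
   window of the movie (one molecule per spot). Steps are located by an
   exact two-segment least-squares change-point fit.
2. **Event detection** — apparent FRET efficiency
   `E = I_A / (I_A + I_D)` per reporter; bound frames are those above a
   threshold at the midpoint of the two FRET states (fitted on E pooled
   over all selected molecules); candidate events must show donor/acceptor
   anticorrelation, which rejects fluorophores sticking to the surface.
3. **Kinetics** — bound lifetimes and arrival times as right-censored
   survival data, censored exponential (mixture) MLE, Kaplan–Meier medians,
   on-rate versus concentration, and apparent dissociation constants from
   the bound-time fraction: `Y = t_PR/(t_PR+t_R)`,
   `K_d = (1−Y)/Y · [P]₀`, per molecule and pooled per folding class.
4. **Folding classes** — per-molecule ±-signs over the reporters (2^k
   classes, e.g. `S7+/H30−`), class fractions, fold changes between
   conditions, accessibility scores (mean fraction of time bound), and 5-s
   binned accessibility-versus-time profiles.
5. **Clustering / rasterplots** — weighted-WPGMA hierarchical clustering of
   molecules on `1 − Spearman` distances between occupancy vectors,
   molecule weights = event counts; sorted raster rendering and a
   deterministic summary report.
6. **Simulation** — a continuous-time simulator with exact ground truth
   (classes, binding intervals, dissociation/bleach times) emulating the
   full experiment: Markovian binding with exclusivity and gating,
   exponential transcription-signal rise, two-phase induced photobleaching,
   spectral crosstalk, Gaussian read noise, laser dead time, and exact
   100-ms frame integration.

## A worked example

```python
import numpy as np
from smprobe import (ReporterKinetics, SimulationConfig, simulate_ensemble,
                     run_pipeline, PipelineConfig, bound_lifetimes, arrival_times)

config = SimulationConfig(
    n_molecules=60,
    class_probabilities={"H30+": 0.62, "H30-": 0.38},
    # 200 nM probe: kon*c = 0.217/s, koff = 0.433/s
    kinetics={"H30": ReporterKinetics(1.083e6, 200e-9, unbinding_rate=0.433)},
    cotranscriptional=True,
    seed=7,
)
traces, truth = simulate_ensemble(config)
result = run_pipeline(traces, PipelineConfig())

model = result.thresholds["H30"]
print(f"selected {len(result.selected)}/{config.n_molecules} molecules")
print(f"FRET states: low {model.low_mean:.2f}, high {model.high_mean:.2f}, "
      f"threshold {model.threshold:.2f} (midpoint)")
print(f"detected events: {len(result.events)}")
frac = np.mean([a.signs['H30'] for a in result.assignments])
print(f"probe-accessible molecules: {100*frac:.0f}%")
```

prints (exact numbers from this seed):

```
selected 51/60 molecules
FRET states: low 0.04, high 0.71, threshold 0.37 (midpoint)
detected events: 2248
probe-accessible molecules: 63%
```

51 of 60 traces pass the transcription and single-bleach criteria; the
pooled FRET histogram separates into an unbound state near 0.04 and a
bound state near 0.71, so frames above the 0.37 midpoint are probe-bound;
2248 binding events are detected, and 63% of the selected molecules show
at least one event — recovering the 62% accessible-class probability the
ensemble was generated with. The scripts in `examples/` walk through each
capability the same way (simulation and ground truth, detection versus
truth, dwell/arrival kinetics and on-rates, classes/Kd/profiles,
clustering and rasterplots):

```bash
python examples/01_simulate_traces.py
python examples/03_dwell_kinetics.py   # etc.
```

A thin command-line interface mirrors the pipeline stages for shell use
(`smprobe simulate | select | detect | classify | kinetics | cluster`);
all formats are plain TSV/JSON documented in `smprobe/io.py`.

## Layout

```
src/smprobe/
  simulate.py    # ground-truth trace simulator
  io.py          # trace/event containers and TSV/JSON formats
  selection.py   # change-point trace selection
  events.py      # FRET, thresholds, anticorrelation, event extraction
  kinetics.py    # censored dwell fits, on-rates, Kd
  classify.py    # folding classes, accessibility, fold changes, profiles
  cluster.py     # weighted WPGMA, rasterplots, report
  pipeline.py    # end-to-end orchestration
  cli.py         # thin command-line veneer
docs/methods.md  # model, assumptions, defaults, limitations
examples/        # one narrative script per capability
```
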