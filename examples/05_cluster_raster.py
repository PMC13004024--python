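"""Cluster molecules by occupancy similarity and emit a sorted rasterplot.

Weighted-WPGMA clustering on 1 - Spearman distances between per-molecule
binary occupancy vectors, with event counts as weights; the leaf order
sorts the raster so that similarly behaving molecules form blocks.
"""

import numpy as np

from smprobe import (
    PipelineConfig,
    ReporterKinetics,
    SimulationConfig,
    cluster_molecules,
    occupancy_matrix,
    render_rasterplot,
    run_pipeline,
    simulate_ensemble,
)
from smprobe.selection import IMMOBILIZED

config = SimulationConfig(
    n_molecules=50,
    class_probabilities={"H30+": 0.6, "H30-": 0.4},
    kinetics={"H30": ReporterKinetics(1.083e6, 200e-9, unbinding_rate=0.433)},
    cotranscriptional=False,
    seed=5,
)
traces, truth = simulate_ensemble(config)
result = run_pipeline(traces, PipelineConfig(mode=IMMOBILIZED))

occ = occupancy_matrix(result.events, result.annotations, traces.meta, "H30")
clustered = cluster_molecules(occ, weighted=True)
rows = render_rasterplot(
    result.events, clustered.leaf_order, result.annotations, traces.meta,
    out_png="scratch/raster.png",
)
rows.to_csv("scratch/raster_order.tsv", sep="\t", index=False)

labels = [truth.molecule(m).class_label for m in clustered.leaf_order]
half = len(labels) // 2
top = 100 * np.mean([l == "H30+" for l in labels[:half]])
bottom = 100 * np.mean([l == "H30+" for l in labels[half:]])
print(f"clustered {occ.n_molecules} molecules; weights = event counts "
      f"(median {np.median(occ.weights):.0f})")
print(f"truly accessible molecules per raster half: top {top:.0f}%, bottom {bottom:.0f}%")
print("wrote scratch/raster.png and scratch/raster_order.tsv")
# The sorted raster groups binding-active molecules into contiguous blocks;
# the TSV row order is the reproducible artifact, the PNG is presentation.
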