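"""Occupancy clustering, rasterplot rendering and the summary report.

Molecules are compared by their frame-wise binary occupancy vectors for one
reporter over the common usable span.  The pairwise distance is
``1 - Spearman rank correlation`` and agglomeration follows the weighted
pair-group method with arithmetic mean (WPGMA), where each molecule
carries its number of binding events as a weight entering the averaged
distances: busy molecules dominate the profile a cluster presents to the
rest of the tree.  The resulting leaf order sorts rasterplots so that
similarly behaving molecules sit in contiguous blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .classify import usable_window
from .io import EventTable, ExperimentMeta
from .selection import MoleculeAnnotation

#: distance assigned between non-identical vectors when Spearman correlation
#: is undefined (constant occupancy); identical vectors get distance 0
MAX_DISTANCE = 2.0


@dataclass
class OccupancyMatrix:
    """Molecules x frames binary occupancy for one reporter, with weights."""

    matrix: np.ndarray  # (n_molecules, n_frames), values in {0, 1}
    molecule_ids: list[str]
    weights: np.ndarray  # per-molecule binding-event counts
    frame_period: float

    @property
    def n_molecules(self) -> int:
        return self.matrix.shape[0]


def occupancy_matrix(
    events: EventTable,
    annotations: list[MoleculeAnnotation],
    meta: ExperimentMeta,
    reporter: str,
    t0: float | None = None,
) -> OccupancyMatrix:
    """Binary occupancy over the shortest common usable span.

    Molecules are aligned to ``t0`` (delivery by default) and truncated to
    the shortest usable window in the selection so every row covers the same
    span; the per-molecule weight is its event count within that span.
    """
    start = meta.delivery_time if t0 is None else t0
    selected = [a for a in annotations if a.selected]
    if not selected:
        raise ValueError("no selected molecules")
    common_end = min(usable_window(a, meta, t0)[1] for a in selected)
    if common_end <= start:
        raise ValueError("common usable span is empty")
    dt = meta.frame_period
    n_frames = int((common_end - start) / dt)
    rows = []
    weights = []
    ids = []
    for ann in selected:
        occ = np.zeros(n_frames, dtype=np.int8)
        ev = events.select(molecule_id=ann.molecule_id, reporter=reporter)
        count = 0
        for _, row in ev.df.iterrows():
            i0 = max(int(math.floor((row["t_start"] - start) / dt)), 0)
            i1 = min(int(math.ceil((row["t_end"] - start) / dt)), n_frames)
            if i1 > i0:
                occ[i0:i1] = 1
                count += 1
        rows.append(occ)
        weights.append(count)
        ids.append(ann.molecule_id)
    return OccupancyMatrix(
        matrix=np.array(rows), molecule_ids=ids, weights=np.array(weights, dtype=float),
        frame_period=dt,
    )


def spearman_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Pairwise ``1 - Spearman`` distances between occupancy rows.

    Constant rows have no rank variance, so Spearman correlation is
    undefined there; the documented convention assigns ``MAX_DISTANCE`` to
    any pair involving a constant row unless the two rows are identical
    (distance 0).  Distances are symmetric with a zero diagonal.
    """
    x = np.asarray(matrix, dtype=float)
    n = x.shape[0]
    ranks = np.vstack([rankdata(row) for row in x])
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    constant = norms == 0
    safe = np.where(constant, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    dist = 1.0 - corr
    identical = np.ones((n, n), dtype=bool)
    for i in range(n):
        identical[i] = (x == x[i]).all(axis=1)
    undefined = constant[:, None] | constant[None, :]
    dist = np.where(undefined & ~identical, MAX_DISTANCE, dist)
    dist = np.where(undefined & identical, 0.0, dist)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)  # guard float round-off at perfect correlation
    return (dist + dist.T) / 2.0


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy-style (n-1, 4) linkage matrix
    leaf_order: list[str]
    distances: np.ndarray


def cluster_molecules(occupancy: OccupancyMatrix, weighted: bool = True) -> ClusterResult:
    """Agglomerate molecules by WPGMA on Spearman distances.

    With ``weighted=True`` (default) the merge update averages distances
    with the per-molecule event-count weights:
    ``d(i+j, k) = (w_i d(i,k) + w_j d(j,k)) / (w_i + w_j)``; molecules with
    no events get unit weight so the update stays defined.  With
    ``weighted=False`` the classic WPGMA rule (equal branch weights) is
    used.  Returns a scipy-compatible linkage matrix and the leaf order.
    """
    from scipy.cluster.hierarchy import leaves_list

    n = occupancy.n_molecules
    if n < 2:
        raise ValueError("need at least 2 molecules to cluster")
    dist = spearman_distance_matrix(occupancy.matrix)
    weights = np.maximum(occupancy.weights.astype(float), 1.0)

    d = dist.copy()
    active = list(range(n))
    cluster_weight = {i: weights[i] for i in range(n)}
    cluster_size = {i: 1 for i in range(n)}
    index_of = {i: i for i in range(n)}  # cluster id -> row in d
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = (math.inf, -1, -1)
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                dij = d[index_of[i], index_of[j]]
                if dij < best[0]:
                    best = (dij, i, j)
        dij, i, j = best
        wi = cluster_weight[i] if weighted else 1.0
        wj = cluster_weight[j] if weighted else 1.0
        row_i, row_j = index_of[i], index_of[j]
        merged_row = (wi * d[row_i] + wj * d[row_j]) / (wi + wj)
        d[row_i] = merged_row
        d[:, row_i] = merged_row
        d[row_i, row_i] = 0.0
        lo, hi = min(i, j), max(i, j)
        linkage[step] = [lo, hi, dij, cluster_size[i] + cluster_size[j]]
        index_of[next_id] = row_i
        cluster_weight[next_id] = cluster_weight[i] + cluster_weight[j]
        cluster_size[next_id] = cluster_size[i] + cluster_size[j]
        active.remove(i)
        active.remove(j)
        active.append(next_id)
        next_id += 1
    order = leaves_list(linkage)
    return ClusterResult(
        linkage=linkage,
        leaf_order=[occupancy.molecule_ids[k] for k in order],
        distances=dist,
    )


# ---------------------------------------------------------------------------
# rasterplots
# ---------------------------------------------------------------------------

DEFAULT_COLORS = {
    "transcription": "#e6b800",  # yellow
    "S7": "#7a2e8f",  # purple
    "default": "#cc2222",  # probe red
}


def render_rasterplot(
    events: EventTable,
    leaf_order: list[str],
    annotations: list[MoleculeAnnotation],
    meta: ExperimentMeta,
    reporters: list[str] | None = None,
    out_png: str | None = None,
    t0: float | None = None,
) -> pd.DataFrame:
    """Render sorted event rasters and return the row-order table.

    One row per molecule in ``leaf_order`` (top to bottom), colored bars per
    reporter plus the transcription residence interval.  The returned
    DataFrame (``row``, ``molecule_id``) is the testable artifact; the PNG
    (written when ``out_png`` is given) is presentation only.  Output is a
    pure function of the inputs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    start = meta.delivery_time if t0 is None else t0
    ann_by_id = {a.molecule_id: a for a in annotations}
    if reporters is None:
        reporters = sorted(set(events.df["reporter"])) if len(events) else []
    rows = pd.DataFrame({"row": np.arange(len(leaf_order)), "molecule_id": leaf_order})
    if out_png is not None:
        fig, ax = plt.subplots(figsize=(8, max(2, 0.08 * len(leaf_order))))
        for row_idx, mid in enumerate(leaf_order):
            y = len(leaf_order) - 1 - row_idx
            ann = ann_by_id.get(mid)
            if ann is not None and not math.isnan(ann.dna_dissociation_time):
                ax.broken_barh(
                    [(0.0, ann.dna_dissociation_time - start)],
                    (y + 0.55, 0.4),
                    color=DEFAULT_COLORS["transcription"],
                )
            for reporter in reporters:
                color = DEFAULT_COLORS.get(reporter, DEFAULT_COLORS["default"])
                ev = events.select(molecule_id=mid, reporter=reporter)
                bars = [
                    (s - start, e - s)
                    for s, e in zip(ev.df["t_start"], ev.df["t_end"])
                ]
                if bars:
                    ax.broken_barh(bars, (y + 0.1, 0.45), color=color)
        ax.set_xlabel("time after delivery (s)")
        ax.set_ylabel("molecule")
        ax.set_ylim(-0.5, len(leaf_order) + 0.5)
        fig.tight_layout()
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return rows


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def build_report(
    sections: dict[str, object],
    config_echo: dict | None = None,
    seed: int | None = None,
) -> str:
    """Assemble a deterministic markdown summary of the pipeline stages.

    ``sections`` may hold any subset of the stage outputs (class fractions
    table, fold changes, kinetics summaries, accessibility scores, profile
    tables, raster row orders); missing stages are marked absent rather than
    failing.  The report body contains no timestamps, so identical inputs
    give a byte-identical document.
    """
    from . import __version__

    lines = ["# smprobe analysis report", ""]
    lines.append(f"software version: {__version__}")
    if seed is not None:
        lines.append(f"seed: {seed}")
    lines.append("")
    order = [
        "selection",
        "class_fractions",
        "fold_changes",
        "accessibility",
        "kinetics",
        "kd",
        "time_profile",
        "raster",
    ]
    titles = {
        "selection": "Trace selection",
        "class_fractions": "Folding-class fractions",
        "fold_changes": "Fold changes",
        "accessibility": "Accessibility scores",
        "kinetics": "Dwell and arrival kinetics",
        "kd": "Kd estimates",
        "time_profile": "Time-binned accessibility",
        "raster": "Rasterplot row order",
    }
    for key in order:
        lines.append(f"## {titles[key]}")
        lines.append("")
        value = sections.get(key)
        if value is None:
            lines.append("_section absent_")
        elif isinstance(value, pd.DataFrame):
            lines.append(value.to_csv(sep="\t", index=False).rstrip())
        else:
            lines.append(str(value))
        lines.append("")
    if config_echo:
        lines.append("## Configuration")
        lines.append("")
        for k in sorted(config_echo):
            lines.append(f"- {k}: {config_echo[k]}")
        lines.append("")
    return "\n".join(lines)


__all__ = [
    "ClusterResult",
    "MAX_DISTANCE",
    "OccupancyMatrix",
    "build_report",
    "cluster_molecules",
    "occupancy_matrix",
    "render_rasterplot",
    "spearman_distance_matrix",
]
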