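"""Population-vector correlation and place-field-distance analyses.

A population vector (PV) is, for one grid point, the vector of
heading-merged activations across a pool of neurons.  Neurons enter the pool
if they were classified place-cell-like in at least one of the analyzed
conditions; pools are concatenated across independent runs.  Correlating the
PVs of two recording points grid point by grid point quantifies how similar
the two spatial maps are: values near 1 indicate a preserved map, values
near 0 global remapping.

Remapping is additionally quantified by the Euclidean distance between
merged place-field centers of neurons that are place cells in both compared
conditions, normalized by the maze's longest extent (2.8 m).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .maze import MAZE_LENGTH_M, MazeGraph
from .placefields import ActivityMap, CellClassification

__all__ = [
    "merge_headings",
    "pv_correlations",
    "placefield_distances",
    "compare_conditions",
    "RemapSummary",
    "pooled_pv_correlations",
    "salience_curves",
]


def merge_headings(m: ActivityMap | np.ndarray) -> np.ndarray:
    """Merge the four per-heading maps into one per-node map (arithmetic
    mean); returns shape (n_neurons, n_nodes)."""
    values = m.values if isinstance(m, ActivityMap) else np.asarray(m)
    return values.mean(axis=2)


def pv_correlations(pv1: np.ndarray, pv2: np.ndarray) -> np.ndarray:
    """Per-grid-point Pearson correlation between two population matrices.

    ``pv1``/``pv2`` have shape (n_pooled_neurons, n_nodes) with identical
    neuron ordering.  Nodes where either population vector has zero variance
    across neurons yield NaN (excluded from histograms; count them with
    ``np.isnan``).
    """
    a = np.asarray(pv1, dtype=np.float64)
    b = np.asarray(pv2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("population matrices must have matching shapes")
    if a.shape[0] == 0:  # empty pool: every node's correlation is undefined
        return np.full(a.shape[1], np.nan)
    scale_a = np.abs(a).max(axis=0)
    scale_b = np.abs(b).max(axis=0)
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = np.sqrt((a * a).sum(axis=0))
    sb = np.sqrt((b * b).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / (sa * sb)
    # numerically constant columns (exact zeros included) are undefined
    degenerate = (sa <= 1e-9 * np.maximum(scale_a, 1e-300)) | (
        sb <= 1e-9 * np.maximum(scale_b, 1e-300)
    )
    r[degenerate] = np.nan
    return r


def per_neuron_map_correlations(pv1: np.ndarray, pv2: np.ndarray) -> np.ndarray:
    """Alternative convention: correlate each neuron's rate map across nodes."""
    return pv_correlations(np.asarray(pv1).T, np.asarray(pv2).T)


def placefield_distances(cls_1: CellClassification, cls_2: CellClassification,
                         maze: MazeGraph) -> np.ndarray:
    """Normalized distances between merged place-field centers.

    Only neurons labeled place_cell in both conditions contribute; distances
    are divided by the maze's longest extent so values lie in [0, ~1].
    Returns an empty array (with a warning) if no neuron is a place cell in
    both conditions.
    """
    shared = sorted(set(cls_1.centers) & set(cls_2.centers))
    if not shared:
        import warnings

        warnings.warn("no neuron is a place cell in both conditions")
        return np.empty(0)
    c1 = np.asarray([cls_1.centers[i] for i in shared])
    c2 = np.asarray([cls_2.centers[i] for i in shared])
    return np.linalg.norm(c1 - c2, axis=1) / MAZE_LENGTH_M


def compare_conditions(sample_1: np.ndarray, sample_2: np.ndarray) -> dict:
    """Two-sided t-test plus means +- SEM for two correlation/distance samples."""
    x = np.asarray(sample_1, dtype=float)
    y = np.asarray(sample_2, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("compare_conditions requires at least 2 values per sample")
    t, p = stats.ttest_ind(x, y)
    return {
        "t": float(t),
        "p": float(p),
        "mean_1": float(x.mean()),
        "sem_1": float(stats.sem(x)),
        "mean_2": float(y.mean()),
        "sem_2": float(stats.sem(y)),
        "n_1": int(len(x)),
        "n_2": int(len(y)),
    }


# ---------------------------------------------------------------------------
# Pooled summaries over runs
# ---------------------------------------------------------------------------

#: Recording-point pairs reported by the remapping analysis.
DEFAULT_PAIRS = (
    ("A", "B"),
    ("A", "Aprime"),
    ("A", "A2"),
    ("Aprime", "B"),
    ("Aprime", "A2"),
)


@dataclass
class RemapSummary:
    """Pooled PV correlations and place-field distances for one layer."""

    layer_index: int
    node_correlations: dict = field(default_factory=dict)  # pair -> (n_nodes,)
    mean_correlation: dict = field(default_factory=dict)  # pair -> float
    n_dropped_nodes: dict = field(default_factory=dict)  # pair -> int
    distances: dict = field(default_factory=dict)  # pair -> (n_shared,)
    n_pooled_neurons: int = 0

    def pair_mean(self, a: str, b: str) -> float:
        return self.mean_correlation[(a, b)]


def pooled_pv_correlations(
    maps_by_run: Sequence[dict],
    classifications_by_run: Sequence[dict],
    layer: int,
    maze: MazeGraph,
    pairs: Sequence[tuple] = DEFAULT_PAIRS,
    eligibility_conditions: Optional[Sequence[str]] = None,
) -> RemapSummary:
    """Pool one layer's maps across runs and correlate recording points.

    ``maps_by_run[r]`` maps a recording-point label (e.g. "A", "B",
    "Aprime", "A2") to that run's :class:`ActivityMap` for ``layer``;
    ``classifications_by_run[r]`` maps labels to
    :class:`CellClassification`.  A neuron is eligible if it is a place cell
    in at least one of ``eligibility_conditions`` (default: all labels
    present).  Distances are pooled per pair over runs (centers only compare
    within a run).
    """
    labels = set()
    for pr in pairs:
        labels.update(pr)
    if eligibility_conditions is None:
        eligibility_conditions = sorted(labels)

    summary = RemapSummary(layer_index=layer)
    pooled: dict = {lab: [] for lab in labels}
    for maps, clss in zip(maps_by_run, classifications_by_run):
        eligible = np.zeros(maps[next(iter(labels))].values.shape[0], dtype=bool)
        for cond in eligibility_conditions:
            eligible |= clss[cond].labels == "place_cell"
        for lab in labels:
            pooled[lab].append(merge_headings(maps[lab])[eligible])
        summary.n_pooled_neurons += int(eligible.sum())
    stacked = {lab: np.concatenate(v, axis=0) for lab, v in pooled.items()}

    for pr in pairs:
        r = pv_correlations(stacked[pr[0]], stacked[pr[1]])
        summary.node_correlations[pr] = r
        summary.n_dropped_nodes[pr] = int(np.isnan(r).sum())
        summary.mean_correlation[pr] = float(np.nanmean(r)) if np.isfinite(r).any() else np.nan
        d = [
            placefield_distances(clss[pr[0]], clss[pr[1]], maze)
            for clss in classifications_by_run
            if set(clss[pr[0]].centers) & set(clss[pr[1]].centers)
        ]
        summary.distances[pr] = np.concatenate(d) if d else np.empty(0)
    return summary


def salience_curves(per_s_summaries: dict, per_s_cr_fraction: dict) -> dict:
    """Assemble per-salience mean PV correlations and early-test CR rates.

    ``per_s_summaries[s]`` is a sequence of :class:`RemapSummary` (one per
    layer); ``per_s_cr_fraction[s]`` the fraction of CR trials early in the
    test phase.  Returns arrays ordered by salience, suitable for plotting
    the U-shaped A-A' profile.
    """
    s_values = sorted(per_s_summaries)
    out = {"s": np.asarray(s_values, dtype=float),
           "cr_fraction": np.asarray([per_s_cr_fraction[s] for s in s_values])}
    for pair in (("A", "Aprime"), ("A", "B"), ("Aprime", "B")):
        out[pair] = np.asarray([
            np.nanmean([
                summ.mean_correlation[pair] for summ in per_s_summaries[s]
            ])
            for s in s_values
        ])
    return out
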