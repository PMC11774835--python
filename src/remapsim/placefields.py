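"""Classification of hidden-layer units into spatial cell types.

Hidden units are probed over all 238 grid points x 4 heading directions and
sorted, per context, into five disjoint classes:

* silent           -- zero output everywhere (exact zeros are meaningful for
                      rectified-linear units),
* context          -- spatially and directionally constant output in each
                      context, but at a different level in A than in B,
* partially_active -- activity for a non-empty strict subset of the four
                      headings,
* place_cell       -- a coherent activity cluster: per-heading tuning centers
                      exist (at most two clusters above threshold, active at
                      no more than half the grid points) and all pairwise
                      center distances stay within four grid spacings,
* heading_modulated -- everything that passes the earlier gates but fails
                      the place-field pipeline for at least one heading.

Gate precedence (silent -> context -> partially_active -> clustering) makes
the classes a partition.  Per-heading rate maps are smoothed with a
mask-normalized Gaussian before clustering, so activity mass is conserved
away from maze boundaries and constant maps stay constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .maze import (
    ContextSpec,
    AgentState,
    MazeGraph,
    ObservationSpec,
    N_BAR_COLS,
    N_BAR_ROWS,
    N_STEM_ROWS,
    explicit_context_units,
    render_observation,
)
from .network import QNetwork

__all__ = [
    "ActivityMap",
    "CellClassification",
    "ClassifierParams",
    "CELL_LABELS",
    "probe_activity",
    "classify_silent",
    "classify_context",
    "classify_partially_active",
    "smooth_map",
    "find_place_field",
    "classify_place_cell",
    "classify_all",
    "label_fractions",
]

CELL_LABELS = ("silent", "context", "partially_active", "heading_modulated", "place_cell")


@dataclass(frozen=True)
class ActivityMap:
    """Per-neuron activation over all grid points and headings.

    ``values`` has shape (n_neurons, n_nodes, 4) with non-negative entries;
    node order follows the maze's node indexing.
    """

    values: np.ndarray
    layer_index: int
    phase_label: str = ""

    def __post_init__(self):
        if self.values.ndim != 3 or self.values.shape[2] != 4:
            raise ValueError("ActivityMap values must have shape (neurons, nodes, 4)")


@dataclass
class CellClassification:
    """Per-neuron labels and tuning centers for one layer in one condition."""

    labels: np.ndarray  # (n_neurons,) strings from CELL_LABELS
    centers: dict = field(default_factory=dict)  # neuron -> merged (x, y), meters
    heading_centers: dict = field(default_factory=dict)  # neuron -> {heading: (x, y)}
    context_levels: dict = field(default_factory=dict)  # neuron -> (a_A, a_B)

    def fraction(self, label: str) -> float:
        return float(np.mean(self.labels == label))


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the cell-type classifier.

    ``context_tolerance`` is a fraction of the neuron's maximum activation
    (0.0005 = 0.05%); ``smoothing_sd`` and ``center_coherence_limit`` are in
    grid spacings; ``cluster_activity_threshold`` is a fraction of the
    smoothed map's peak (0.5 = the conventional half-peak field boundary).
    """

    context_tolerance: float = 0.0005
    smoothing_sd: float = 2.0
    cluster_activity_threshold: float = 0.5
    max_cluster_count: int = 2
    max_active_fraction: float = 0.5
    center_coherence_limit: float = 4.0

    def __post_init__(self):
        for name in ("context_tolerance", "smoothing_sd",
                     "cluster_activity_threshold", "max_active_fraction",
                     "center_coherence_limit"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# Probing
# ---------------------------------------------------------------------------


def probe_activity(
    net: QNetwork,
    maze: MazeGraph,
    ctx: ContextSpec,
    obs_spec: ObservationSpec = ObservationSpec(),
    phase_label: str = "",
) -> list[ActivityMap]:
    """Record hidden activations at every (grid point, heading) pose.

    Observations are rendered without camera jitter and evaluated in
    inference mode, so the result is deterministic for a given network.
    Returns one :class:`ActivityMap` per hidden layer, each with values of
    shape (layer size, n_nodes, 4).
    """
    n = maze.n_nodes
    obs = np.empty((n * 4, net.input_dim), dtype=np.float32)
    extra = (
        explicit_context_units(ctx.phase_label) if ctx.mode == "explicit" else None
    )
    for node in range(n):
        for h in range(4):
            img = render_observation(
                AgentState(node, h, 0), ctx, obs_spec, maze=maze, jitter=False
            ).ravel()
            if extra is not None:
                img = np.concatenate([img, extra])
            obs[node * 4 + h] = img
    acts = net.record_activations_batch(obs)
    maps = []
    for li, a in enumerate(acts):
        vals = a.reshape(n, 4, a.shape[1]).transpose(2, 0, 1).copy()
        maps.append(ActivityMap(values=vals, layer_index=li + 1,
                                phase_label=phase_label))
    return maps


# ---------------------------------------------------------------------------
# Elementary gates
# ---------------------------------------------------------------------------


def classify_silent(map_A: ActivityMap, map_B: ActivityMap,
                    scope: str = "both") -> np.ndarray:
    """Per-neuron silence: exactly zero output under all probed conditions.

    With ``scope="both"`` (default) silence spans both context maps; with
    ``scope="A"``/``"B"`` only the corresponding map is examined.
    """
    zero_A = ~np.any(map_A.values, axis=(1, 2))
    zero_B = ~np.any(map_B.values, axis=(1, 2))
    if scope == "both":
        return zero_A & zero_B
    if scope == "A":
        return zero_A
    if scope == "B":
        return zero_B
    raise ValueError("scope must be 'both', 'A', or 'B'")


def classify_context(map_A: ActivityMap, map_B: ActivityMap,
                     tol: float = ClassifierParams.context_tolerance):
    """Context cells: constant within each context, different across them.

    A neuron qualifies if its activation range within each context (over all
    nodes and headings) stays within ``tol`` of its global maximum
    activation, and the within-context mean levels a_A and a_B differ by
    more than that tolerance.  A context cell may be silent (constant zero)
    in exactly one context.  Returns ``(mask, a_A, a_B)``.
    """
    vA, vB = map_A.values, map_B.values
    gmax = np.maximum(vA.max(axis=(1, 2)), vB.max(axis=(1, 2)))
    band = tol * gmax
    const_A = vA.max(axis=(1, 2)) - vA.min(axis=(1, 2)) <= band
    const_B = vB.max(axis=(1, 2)) - vB.min(axis=(1, 2)) <= band
    a_A = vA.mean(axis=(1, 2))
    a_B = vB.mean(axis=(1, 2))
    mask = const_A & const_B & (np.abs(a_A - a_B) > band) & (gmax > 0)
    return mask, a_A, a_B


def classify_partially_active(m: ActivityMap) -> np.ndarray:
    """Neurons active for a non-empty strict subset of the four headings."""
    active_heading = np.any(m.values > 0, axis=1)  # (neurons, 4)
    n_active = active_heading.sum(axis=1)
    return (n_active >= 1) & (n_active < 4)


# ---------------------------------------------------------------------------
# Spatial pipeline
# ---------------------------------------------------------------------------


def _grid_embedding(maze: MazeGraph):
    rows = int(maze.grid_pos[:, 1].max()) + 1
    cols = int(maze.grid_pos[:, 0].max()) + 1
    mask = np.zeros((rows, cols), dtype=bool)
    mask[maze.grid_pos[:, 1], maze.grid_pos[:, 0]] = True
    return rows, cols, mask


def smooth_map(node_values: np.ndarray, maze: MazeGraph,
               smoothing_sd: float = ClassifierParams.smoothing_sd) -> np.ndarray:
    """Mask-normalized Gaussian smoothing of per-node activations.

    ``node_values`` may be (..., n_nodes); the smoothing kernel is
    renormalized over the maze footprint, so positions outside the maze do
    not dilute the result: constant maps are invariant and total activity is
    conserved on interior regions.  ``smoothing_sd`` is in grid spacings.
    """
    node_values = np.asarray(node_values, dtype=np.float64)
    rows, cols, mask = _grid_embedding(maze)
    lead = node_values.shape[:-1]
    flat = node_values.reshape(-1, node_values.shape[-1])
    out = np.empty_like(flat)
    norm = ndimage.gaussian_filter(mask.astype(np.float64), smoothing_sd,
                                   mode="constant")
    r, c = maze.grid_pos[:, 1], maze.grid_pos[:, 0]
    for i, v in enumerate(flat):
        grid = np.zeros((rows, cols))
        grid[r, c] = v
        sm = ndimage.gaussian_filter(grid, smoothing_sd, mode="constant")
        with np.errstate(invalid="ignore"):
            sm = np.where(mask, sm / norm, 0.0)
        out[i] = sm[r, c]
    return out.reshape(*lead, node_values.shape[-1])


_N4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def find_place_field(map_h: np.ndarray, maze: MazeGraph,
                     params: ClassifierParams = ClassifierParams()) -> Optional[np.ndarray]:
    """Tuning center of one heading's (smoothed) rate map, or ``None``.

    Grid points above ``cluster_activity_threshold`` of the map's peak form
    clusters under 4-neighborhood connectivity.  The map is excluded (returns
    ``None``) if there are more than ``max_cluster_count`` clusters or more
    than ``max_active_fraction`` of all grid points are active.  Otherwise
    the center is the activity-weighted mean location of the dominating
    cluster (largest summed activity; ties broken by node count, then by the
    lowest-indexed member node).
    """
    v = np.asarray(map_h, dtype=np.float64)
    peak = v.max()
    if peak <= 0:
        return None
    active = v > params.cluster_activity_threshold * peak
    if active.sum() > params.max_active_fraction * maze.n_nodes:
        return None
    rows, cols, _ = _grid_embedding(maze)
    r, c = maze.grid_pos[:, 1], maze.grid_pos[:, 0]
    grid = np.zeros((rows, cols), dtype=bool)
    grid[r[active], c[active]] = True
    lab, n_clusters = ndimage.label(grid, structure=_N4)
    if n_clusters == 0 or n_clusters > params.max_cluster_count:
        return None
    node_lab = lab[r, c]  # cluster id per node, 0 = inactive
    best, best_key = 0, None
    for k in range(1, n_clusters + 1):
        members = node_lab == k
        key = (v[members].sum(), members.sum(), -int(np.argmax(members)))
        if best_key is None or key > best_key:
            best, best_key = k, key
    members = node_lab == best
    w = v[members]
    return (w[:, None] * maze.coords[members]).sum(axis=0) / w.sum()


def classify_place_cell(heading_centers: list[Optional[np.ndarray]],
                        maze: MazeGraph,
                        params: ClassifierParams = ClassifierParams()):
    """Coherence gate over per-heading tuning centers.

    Returns ``("place_cell", merged_center)`` if a center exists for every
    heading and all pairwise center distances stay within
    ``center_coherence_limit`` grid spacings, else
    ``("heading_modulated", None)``.
    """
    if any(c is None for c in heading_centers):
        return "heading_modulated", None
    centers = np.asarray(heading_centers, dtype=np.float64)
    limit = params.center_coherence_limit * maze.grid_spacing
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    if d.max() > limit:
        return "heading_modulated", None
    return "place_cell", centers.mean(axis=0)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def classify_all(map_A: ActivityMap, map_B: ActivityMap,
                 maze: MazeGraph,
                 params: ClassifierParams = ClassifierParams()) -> dict:
    """Classify every neuron of one layer, separately for each context.

    Returns ``{"A": CellClassification, "B": CellClassification}``.  Gates
    apply in order silent -> context -> partially_active -> place-field
    pipeline; the context gate uses both maps (a context cell is constant in
    each context with distinct levels), all other gates use the map of the
    context being labeled, so a neuron may be e.g. place_cell in A and
    silent in B.
    """
    n = map_A.values.shape[0]
    ctx_mask, a_A, a_B = classify_context(map_A, map_B, params.context_tolerance)
    out = {}
    for phase, m in (("A", map_A), ("B", map_B)):
        labels = np.empty(n, dtype=object)
        cls = CellClassification(labels=labels)
        silent = ~np.any(m.values, axis=(1, 2))
        partial = classify_partially_active(m)
        smoothed = None
        for i in range(n):
            if silent[i]:
                labels[i] = "silent"
            elif ctx_mask[i]:
                labels[i] = "context"
                cls.context_levels[i] = (float(a_A[i]), float(a_B[i]))
            elif partial[i]:
                labels[i] = "partially_active"
            else:
                if smoothed is None:
                    # headings-last layout: (neurons, 4, nodes) for smoothing
                    smoothed = smooth_map(
                        m.values.transpose(0, 2, 1), maze, params.smoothing_sd
                    )
                centers = [
                    find_place_field(smoothed[i, h], maze, params) for h in range(4)
                ]
                label, merged = classify_place_cell(centers, maze, params)
                labels[i] = label
                if merged is not None:
                    cls.centers[i] = merged
                    cls.heading_centers[i] = {h: c for h, c in enumerate(centers)}
        out[phase] = cls
    return out


def label_fractions(cls: CellClassification) -> dict:
    """Fraction of neurons per cell type; values sum to 1."""
    return {lab: cls.fraction(lab) for lab in CELL_LABELS}
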