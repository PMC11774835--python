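"""Cell-type classifier tests: planted populations with known composition."""

import numpy as np
import pytest

from remapsim.maze import GRID_SPACING_M, MazeGraph, build_tmaze
from remapsim.placefields import (
    ActivityMap,
    CELL_LABELS,
    ClassifierParams,
    classify_all,
    classify_context,
    classify_partially_active,
    classify_place_cell,
    classify_silent,
    find_place_field,
    label_fractions,
    smooth_map,
)

PARAMS = ClassifierParams()


def rectangle_maze(n=20):
    """Synthetic all-interior square arena for smoothing-conservation checks."""
    grid = np.array([(c, r) for r in range(n) for c in range(n)])
    index = {(c, r): i for i, (c, r) in enumerate(grid)}
    nbr = np.full((n * n, 4), -1, dtype=np.int64)
    for i, (c, r) in enumerate(grid):
        for a, (dc, dr) in enumerate(((0, 1), (1, 0), (0, -1), (-1, 0))):
            nbr[i, a] = index.get((c + dc, r + dr), -1)
    return MazeGraph(
        grid_pos=grid,
        coords=grid * GRID_SPACING_M,
        neighbors=nbr,
        arm_labels=np.array(["stem"] * (n * n), dtype=object),
        start_node=0,
        goal_node=None,
    )


def bump(maze, center_node, sigma_spacings, amplitude=1.0):
    c = maze.coords[center_node]
    d2 = ((maze.coords - c) ** 2).sum(axis=1)
    s2 = (sigma_spacings * maze.grid_spacing) ** 2
    return amplitude * np.exp(-d2 / (2 * s2))


def _amap(values):
    return ActivityMap(values=np.asarray(values, dtype=np.float64), layer_index=1)


@pytest.fixture(scope="module")
def tmaze():
    return build_tmaze()


class TestGates:
    def test_silent_requires_zero_in_both_contexts(self, tmaze):
        n = tmaze.n_nodes
        vA = np.zeros((3, n, 4))
        vB = np.zeros((3, n, 4))
        vA[1, 5, 2] = 0.7  # active in A only
        vB[2, 9, 0] = 0.4  # active in B only
        silent = classify_silent(_amap(vA), _amap(vB))
        assert silent.tolist() == [True, False, False]
        assert classify_silent(_amap(vA), _amap(vB), scope="A").tolist() == [True, False, True]

    def test_context_cell_definitions(self, tmaze):
        n = tmaze.n_nodes
        vA = np.stack([
            np.full((n, 4), 0.3),      # constant 0.3 / 0.7 -> context
            np.full((n, 4), 0.5),      # constant 0.5 both -> not context
            np.full((n, 4), 0.2),      # constant in A, spatial in B -> not
            np.zeros((n, 4)),          # silent in A, constant in B -> context
        ])
        vB = np.stack([
            np.full((n, 4), 0.7),
            np.full((n, 4), 0.5),
            np.tile(bump(tmaze, 30, 2.0)[:, None], (1, 4)),
            np.full((n, 4), 0.6),
        ])
        mask, a_A, a_B = classify_context(_amap(vA), _amap(vB))
        assert mask.tolist() == [True, False, False, True]
        assert a_A[0] == pytest.approx(0.3) and a_B[0] == pytest.approx(0.7)

    def test_partially_active_strict_subset(self, tmaze):
        n = tmaze.n_nodes
        v = np.zeros((3, n, 4))
        v[0, :, 0] = 1.0            # one heading -> partial
        v[1, :, :] = 1.0            # all headings -> not partial
        v[2, :, :3] = 1.0           # three headings -> partial
        got = classify_partially_active(_amap(v))
        assert got.tolist() == [True, False, True]


class TestSmoothing:
    def test_constant_map_invariant(self, tmaze):
        v = np.full(tmaze.n_nodes, 3.17)
        sm = smooth_map(v, tmaze, 1.0)
        assert np.allclose(sm, 3.17, atol=1e-9)

    def test_impulse_peaks_at_source(self, tmaze):
        v = np.zeros(tmaze.n_nodes)
        v[120] = 1.0
        sm = smooth_map(v, tmaze, 1.0)
        assert sm.argmax() == 120
        assert np.all(sm >= 0)

    def test_mass_conservation_on_interior_rectangle(self):
        arena = rectangle_maze(20)
        v = np.zeros(arena.n_nodes)
        v[arena.node_at(10, 10)] = 1.0
        sm = smooth_map(v, arena, 1.0)
        assert abs(sm.sum() - v.sum()) < 1e-6


class TestPlaceField:
    def test_single_bump_center_recovered(self, tmaze):
        center = tmaze.node_at(6, 18)
        v = bump(tmaze, center, 2.0)
        got = find_place_field(smooth_map(v, tmaze, 1.0), tmaze, PARAMS)
        err = np.linalg.norm(got - tmaze.coords[center])
        assert err < 0.5 * tmaze.grid_spacing

    def test_three_bumps_excluded(self, tmaze):
        v = (
            bump(tmaze, tmaze.node_at(1, 18), 1.2)
            + bump(tmaze, tmaze.node_at(32, 18), 1.2)
            + bump(tmaze, tmaze.node_at(16, 1), 1.2)
        )
        assert find_place_field(smooth_map(v, tmaze, 1.0), tmaze, PARAMS) is None

    def test_overly_broad_activity_excluded(self, tmaze):
        v = np.zeros(tmaze.n_nodes)
        v[:144] = 1.0  # >50% of 238 nodes active
        assert find_place_field(v, tmaze, PARAMS) is None

    def test_coherence_gate(self, tmaze):
        c = tmaze.coords[tmaze.node_at(16, 10)]
        coincident = [c.copy() for _ in range(4)]
        label, merged = classify_place_cell(coincident, tmaze, PARAMS)
        assert label == "place_cell" and np.allclose(merged, c)

        split = [c.copy() for _ in range(3)] + [c + [6 * tmaze.grid_spacing, 0]]
        assert classify_place_cell(split, tmaze, PARAMS)[0] == "heading_modulated"

        near = [c + [i * 0.5 * tmaze.grid_spacing, 0] for i in range(4)]
        assert classify_place_cell(near, tmaze, PARAMS)[0] == "place_cell"

        missing = [c.copy(), None, c.copy(), c.copy()]
        assert classify_place_cell(missing, tmaze, PARAMS)[0] == "heading_modulated"


class TestClassifyAll:
    def _planted_population(self, tmaze, rng):
        n = tmaze.n_nodes
        vA, vB, expected = [], [], []
        for i in range(10):  # silent
            vA.append(np.zeros((n, 4)))
            vB.append(np.zeros((n, 4)))
            expected.append("silent")
        for i in range(10):  # context
            a = 0.2 + 0.05 * i
            vA.append(np.full((n, 4), a))
            vB.append(np.full((n, 4), a + 0.4))
            expected.append("context")
        for i in range(10):  # partially active: two headings only
            b = bump(tmaze, int(rng.integers(n)), 2.0)
            v = np.zeros((n, 4))
            v[:, :2] = b[:, None]
            vA.append(v)
            vB.append(v.copy())
            expected.append("partially_active")
        for i in range(10):  # coherent single bump on all headings
            b = bump(tmaze, int(rng.integers(n)), 2.0)
            v = np.tile(b[:, None], (1, 4))
            vA.append(v)
            vB.append(v.copy())
            expected.append("place_cell")
        corners = [
            tmaze.node_at(1, 18),
            tmaze.node_at(32, 18),
            tmaze.node_at(16, 1),
        ]
        for i in range(10):  # three disjoint bumps -> heading modulated
            b = sum(bump(tmaze, c, 1.2) for c in corners)
            v = np.tile(b[:, None], (1, 4))
            vA.append(v)
            vB.append(v.copy())
            expected.append("heading_modulated")
        return _amap(np.stack(vA)), _amap(np.stack(vB)), expected

    def test_planted_population_recovered_exactly(self, tmaze, rng):
        map_A, map_B, expected = self._planted_population(tmaze, rng)
        result = classify_all(map_A, map_B, tmaze, PARAMS)
        assert result["A"].labels.tolist() == expected
        assert result["B"].labels.tolist() == expected

    def test_all_zero_layer_is_all_silent(self, tmaze):
        z = _amap(np.zeros((7, tmaze.n_nodes, 4)))
        result = classify_all(z, z, tmaze, PARAMS)
        assert np.all(result["A"].labels == "silent")

    def test_fractions_partition(self, tmaze, rng):
        map_A, map_B, _ = self._planted_population(tmaze, rng)
        fr = label_fractions(classify_all(map_A, map_B, tmaze, PARAMS)["A"])
        assert set(fr) == set(CELL_LABELS)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_planted_bump_recovery_with_noise(self, tmaze):
        # 200 noisy gaussian place fields: >=95% classified place_cell,
        # median center error below one grid spacing
        rng = np.random.default_rng(42)
        n = tmaze.n_nodes
        centers = rng.integers(0, n, size=200)
        maps = []
        for c in centers:
            b = bump(tmaze, int(c), 1.5)
            v = np.tile(b[:, None], (1, 4)) * (1 + 0.1 * rng.standard_normal((n, 4)))
            maps.append(np.clip(v, 0, None))
        m = _amap(np.stack(maps))
        result = classify_all(m, m, tmaze, PARAMS)
        labels = result["A"].labels
        assert np.mean(labels == "place_cell") >= 0.95
        errs = [
            np.linalg.norm(result["A"].centers[i] - tmaze.coords[centers[i]])
            for i in range(200)
            if i in result["A"].centers
        ]
        assert np.median(errs) < tmaze.grid_spacing
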