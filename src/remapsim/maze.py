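"""T-maze grid world with procedural first-person rendering.

The environment emulates a T-maze of 2.8 m length discretized into 238 grid
points (a 34x4 top bar carrying the two arms plus a 6x17 stem).  An agent
occupies one grid point with one of four cardinal headings and observes the
maze through a procedurally rendered 80x20 RGB first-person view spanning a
240 degree field of view: textured walls rendered by per-column raycasting,
a distal cylindrical skybox stripe, and a floor gradient.  Context is encoded
by a global multiplicative light tint (white in context A, blue in context B,
with a salience parameter blending between them) or, alternatively, by 160
explicit binary context input units.

All textures are fixed constants of the package and are mirror-symmetric
about the stem axis, so reflecting the agent pose through that axis yields an
exactly mirrored image.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "HEADINGS",
    "MazeGraph",
    "AgentState",
    "ContextSpec",
    "ObservationSpec",
    "StepResult",
    "ProtocolError",
    "build_tmaze",
    "step",
    "light_color",
    "render_observation",
    "explicit_context_units",
    "TMazeEnv",
]

# ---------------------------------------------------------------------------
# Constants of the canonical maze
# ---------------------------------------------------------------------------

#: Cardinal headings / actions, index order used throughout the package.
HEADINGS = ("N", "E", "S", "W")

#: Unit displacement (dcol, drow) for each action index.
_ACTION_DELTAS = ((0, 1), (1, 0), (0, -1), (-1, 0))

#: Yaw angle (radians) of each heading; East = 0, counter-clockwise positive.
_HEADING_YAW = (math.pi / 2.0, 0.0, -math.pi / 2.0, math.pi)

MAZE_LENGTH_M = 2.8
N_BAR_COLS = 34
N_BAR_ROWS = 4
N_STEM_COLS = 6
N_STEM_ROWS = 17
STEM_COL_LO = (N_BAR_COLS - N_STEM_COLS) // 2  # 14
STEM_COL_HI = STEM_COL_LO + N_STEM_COLS - 1    # 19
GRID_SPACING_M = MAZE_LENGTH_M / (N_BAR_COLS - 1)

#: Default trial length cap (steps); unsuccessful trials terminate here.
MAX_TRIAL_STEPS = 400

REWARD_GOAL = 20.0
REWARD_STEP = -1.0

#: Light colors: white for context A, pure blue for context B at salience 1.
LIGHT_WHITE = (1.0, 1.0, 1.0)
LIGHT_BLUE = (0.25, 0.35, 1.0)

#: Wall slab height (m) and vertical focal length (px) of the renderer.
_WALL_HEIGHT_M = 0.40
_FOCAL_V_PX = 22.0
_CAMERA_HEIGHT_M = _WALL_HEIGHT_M / 2.0
_FLOOR_RGB = np.array([0.42, 0.36, 0.30], dtype=np.float64)


class ProtocolError(RuntimeError):
    """Raised when the environment or agent API is used out of contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MazeGraph:
    """The discretized T-maze.

    Attributes
    ----------
    grid_pos : (n, 2) int array of (col, row) grid indices, row-major from the
        bottom-left of the bounding box.
    coords : (n, 2) float array of node-center coordinates in meters.
    neighbors : (n, 4) int array; ``neighbors[i, a]`` is the node reached from
        node ``i`` by action ``a`` (N, E, S, W), or ``-1`` if the move leaves
        the maze.
    arm_labels : (n,) array of ``{"stem", "left_arm", "right_arm"}``; the
        junction columns above the stem belong to the stem.
    start_node : node id at the bottom center of the stem.
    goal_node : rewarded node id, or ``None`` (no reward in the maze).
    grid_spacing : distance in meters between adjacent nodes.
    """

    grid_pos: np.ndarray
    coords: np.ndarray
    neighbors: np.ndarray
    arm_labels: np.ndarray
    start_node: int
    goal_node: Optional[int]
    goal_zone: tuple = ()
    grid_spacing: float = GRID_SPACING_M

    @property
    def n_nodes(self) -> int:
        return len(self.grid_pos)

    def with_goal(self, arm: Optional[str]) -> "MazeGraph":
        """Return a copy with the reward zone in ``{"left", "right", None}``.

        The reward zone spans the extreme bar column of the chosen arm;
        ``goal_node`` points at its middle node for path-length queries.
        """
        if arm is None or arm == "none":
            return replace(self, goal_node=None, goal_zone=())
        if arm not in ("left", "right"):
            raise ValueError(f"unknown goal arm {arm!r}")
        col = 0 if arm == "left" else N_BAR_COLS - 1
        zone = np.nonzero(self.grid_pos[:, 0] == col)[0]
        row = N_STEM_ROWS + 1  # second bar row, mid-height of the arm
        gid = self.node_at(col, row)
        return replace(self, goal_node=gid, goal_zone=tuple(int(i) for i in zone))

    def node_at(self, col: int, row: int) -> int:
        hits = np.nonzero((self.grid_pos[:, 0] == col) & (self.grid_pos[:, 1] == row))[0]
        if len(hits) != 1:
            raise KeyError(f"no node at col={col}, row={row}")
        return int(hits[0])

    def to_tables(self):
        """Plain tabular serialization: (node table, edge table) as records."""
        nodes = [
            (i, float(self.coords[i, 0]), float(self.coords[i, 1]), str(self.arm_labels[i]))
            for i in range(self.n_nodes)
        ]
        edges = []
        for i in range(self.n_nodes):
            for a in range(4):
                j = int(self.neighbors[i, a])
                if j >= 0 and i < j:
                    edges.append((i, j))
        return nodes, edges


@dataclass(frozen=True)
class AgentState:
    """Agent pose within a trial: node id, heading index, and step count."""

    node: int
    heading: int  # index into HEADINGS; equals the last attempted action
    t: int = 0


@dataclass(frozen=True)
class ContextSpec:
    """Context definition: salience in [0, 1], phase label, and encoding mode.

    With ``mode="lighting"`` context B is rendered under a blend of white and
    blue light controlled by ``salience``; with ``mode="explicit"`` lighting
    stays white in both phases and context enters through 160 binary input
    units appended to the image.
    """

    salience: float = 1.0
    phase_label: str = "A"
    mode: str = "lighting"
    light_color_A: tuple = LIGHT_WHITE
    light_color_B_pure: tuple = LIGHT_BLUE

    def __post_init__(self):
        if not 0.0 <= self.salience <= 1.0:
            raise ValueError("salience must lie in [0, 1]")
        if self.phase_label not in ("A", "B"):
            raise ValueError("phase_label must be 'A' or 'B'")
        if self.mode not in ("lighting", "explicit"):
            raise ValueError("mode must be 'lighting' or 'explicit'")


@dataclass(frozen=True)
class ObservationSpec:
    """Rendered-observation geometry and camera jitter magnitudes."""

    width: int = 80
    height: int = 20
    channels: int = 3
    fov_deg: float = 240.0
    pos_jitter_sd: float = 0.01  # meters
    ang_jitter_sd: float = 10.0  # degrees


@dataclass(frozen=True)
class StepResult:
    """Outcome of one environment step."""

    observation: Optional[np.ndarray]
    reward: float
    terminal: bool


# ---------------------------------------------------------------------------
# Maze construction
# ---------------------------------------------------------------------------


def _in_maze(col: int, row: int) -> bool:
    if 0 <= row < N_STEM_ROWS and STEM_COL_LO <= col <= STEM_COL_HI:
        return True
    if N_STEM_ROWS <= row < N_STEM_ROWS + N_BAR_ROWS and 0 <= col < N_BAR_COLS:
        return True
    return False


def build_tmaze(goal_arm: Optional[str] = None) -> MazeGraph:
    """Construct the canonical 238-node T-maze.

    The top bar is 34x4 nodes (136) and the stem 6x17 nodes (102); nodes are
    indexed row-major from the bottom-left of the bounding box.  The start
    node sits at the bottom-center of the stem; goals (if any) sit at the
    extreme left/right bar columns.  Deterministic: no RNG is involved.
    """
    grid = [
        (col, row)
        for row in range(N_STEM_ROWS + N_BAR_ROWS)
        for col in range(N_BAR_COLS)
        if _in_maze(col, row)
    ]
    grid_pos = np.array(grid, dtype=np.int64)
    index = {(c, r): i for i, (c, r) in enumerate(grid)}
    coords = grid_pos.astype(np.float64) * GRID_SPACING_M

    neighbors = np.full((len(grid), 4), -1, dtype=np.int64)
    for i, (c, r) in enumerate(grid):
        for a, (dc, dr) in enumerate(_ACTION_DELTAS):
            j = index.get((c + dc, r + dr))
            if j is not None:
                neighbors[i, a] = j

    labels = np.empty(len(grid), dtype=object)
    for i, (c, r) in enumerate(grid):
        if c < STEM_COL_LO:
            labels[i] = "left_arm"
        elif c > STEM_COL_HI:
            labels[i] = "right_arm"
        else:
            labels[i] = "stem"

    start = index[(STEM_COL_LO + N_STEM_COLS // 2 - 1, 0)]  # col 16, row 0
    maze = MazeGraph(
        grid_pos=grid_pos,
        coords=coords,
        neighbors=neighbors,
        arm_labels=labels,
        start_node=start,
        goal_node=None,
    )
    return maze.with_goal(goal_arm) if goal_arm else maze


# ---------------------------------------------------------------------------
# Step dynamics
# ---------------------------------------------------------------------------


def step(
    state: AgentState,
    action: int,
    maze: MazeGraph,
    max_steps: int = MAX_TRIAL_STEPS,
) -> tuple[AgentState, StepResult]:
    """Advance the agent by one action.

    Moving along an existing edge changes the node; moving into a wall wastes
    the time step.  The heading always follows the attempted action.  Reaching
    the goal yields +20 and terminates; every other step yields -1, and the
    trial also terminates when the step count reaches ``max_steps``.
    The returned :class:`StepResult` carries no observation; rendering is
    composed on top by :class:`TMazeEnv`.
    """
    if state.t >= max_steps:
        raise ProtocolError("step() called on a terminal (time-capped) state")
    if not 0 <= action < 4:
        raise ValueError(f"action must be in 0..3, got {action}")
    nxt = int(maze.neighbors[state.node, action])
    node = nxt if nxt >= 0 else state.node
    t = state.t + 1
    new_state = AgentState(node=node, heading=action, t=t)
    if maze.goal_zone and node in maze.goal_zone:
        return new_state, StepResult(None, REWARD_GOAL, True)
    return new_state, StepResult(None, REWARD_STEP, t >= max_steps)


# ---------------------------------------------------------------------------
# Lighting and explicit context
# ---------------------------------------------------------------------------


def light_color(ctx: ContextSpec) -> np.ndarray:
    """Global light tint for a context: white in A, white->blue blend in B.

    In explicit-context mode lighting is pinned to context A's color for all
    phases (context enters through the input units instead)."""
    white = np.asarray(ctx.light_color_A, dtype=np.float64)
    if ctx.mode == "explicit" or ctx.phase_label == "A":
        return white
    blue = np.asarray(ctx.light_color_B_pure, dtype=np.float64)
    return (1.0 - ctx.salience) * white + ctx.salience * blue


def explicit_context_units(phase: str) -> np.ndarray:
    """160 binary context units: first half active in A, second half in B."""
    if phase not in ("A", "B"):
        raise ValueError("phase must be 'A' or 'B'")
    v = np.zeros(160, dtype=np.float32)
    if phase == "A":
        v[:80] = 1.0
    else:
        v[80:] = 1.0
    return v


# ---------------------------------------------------------------------------
# Procedural renderer
# ---------------------------------------------------------------------------

# Wall outline of the T shape, in grid units, offset half a spacing beyond the
# node centers.  Counter-clockwise; mirror-symmetric about x = 16.5.
_OUTLINE_GRID = [
    ((STEM_COL_LO - 0.5, -0.5), (STEM_COL_HI + 0.5, -0.5)),
    ((STEM_COL_HI + 0.5, -0.5), (STEM_COL_HI + 0.5, N_STEM_ROWS - 0.5)),
    ((STEM_COL_HI + 0.5, N_STEM_ROWS - 0.5), (N_BAR_COLS - 0.5, N_STEM_ROWS - 0.5)),
    ((N_BAR_COLS - 0.5, N_STEM_ROWS - 0.5), (N_BAR_COLS - 0.5, N_STEM_ROWS + N_BAR_ROWS - 0.5)),
    ((N_BAR_COLS - 0.5, N_STEM_ROWS + N_BAR_ROWS - 0.5), (-0.5, N_STEM_ROWS + N_BAR_ROWS - 0.5)),
    ((-0.5, N_STEM_ROWS + N_BAR_ROWS - 0.5), (-0.5, N_STEM_ROWS - 0.5)),
    ((-0.5, N_STEM_ROWS - 0.5), (STEM_COL_LO - 0.5, N_STEM_ROWS - 0.5)),
    ((STEM_COL_LO - 0.5, N_STEM_ROWS - 0.5), (STEM_COL_LO - 0.5, -0.5)),
]

_SEG_P0 = np.array([p0 for p0, _ in _OUTLINE_GRID], dtype=np.float64) * GRID_SPACING_M
_SEG_P1 = np.array([p1 for _, p1 in _OUTLINE_GRID], dtype=np.float64) * GRID_SPACING_M
_SEG_D = _SEG_P1 - _SEG_P0

#: x-coordinate of the stem axis (mirror plane), meters.
_AXIS_X = (N_BAR_COLS - 1) / 2.0 * GRID_SPACING_M

# Fixed texture constants (package-level seeds).  Wall albedo is a function of
# the world-space hit point only, even in (x - axis); the skybox stripe is a
# cosine series in (azimuth - pi/2), hence even about due north.
_WALL_FREQ = np.array(
    [[9.1, 4.7], [6.3, 8.9], [11.7, 3.1]], dtype=np.float64
)  # per-channel (xi, y) spatial frequencies, rad/m
_WALL_PHASE = np.array([[0.9, 2.1], [1.7, 0.3], [2.6, 1.2]], dtype=np.float64)
_SKY_HARMONICS = np.array([1, 2, 3, 5, 7], dtype=np.float64)
_SKY_AMP = np.array(
    [
        [0.22, 0.12, 0.08, 0.05, 0.04],
        [0.10, 0.20, 0.06, 0.08, 0.03],
        [0.15, 0.07, 0.18, 0.04, 0.06],
    ],
    dtype=np.float64,
)
_SKY_PHASE = np.array(
    [
        [0.4, 2.8, 1.1, 5.2, 0.7],
        [1.9, 0.2, 4.4, 2.5, 3.6],
        [3.1, 1.5, 0.8, 4.0, 2.2],
    ],
    dtype=np.float64,
)


def _wall_albedo(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Wall texture RGB at world coordinates; shape (..., 3)."""
    xi = np.abs(x - _AXIS_X)
    arg = (
        _WALL_FREQ[:, 0] * xi[..., None]
        + _WALL_FREQ[:, 1] * y[..., None]
        + _WALL_PHASE[:, 0]
    )
    mod = np.sin(arg) * np.sin(0.5 * _WALL_FREQ[:, 1] * y[..., None] + _WALL_PHASE[:, 1])
    return 0.55 + 0.40 * mod


_FLOOR_FREQ = np.array(
    [[13.9, 7.3], [8.1, 12.7], [10.3, 9.7]], dtype=np.float64
)  # per-channel (xi, y) spatial frequencies of the floor pattern, rad/m
_FLOOR_PHASE = np.array([[0.4, 1.3], [2.2, 0.7], [1.1, 2.9]], dtype=np.float64)


def _floor_albedo(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Floor texture RGB at world coordinates; shape (..., 3).

    Position-dependent (a checker-like sinusoidal pattern), so corridor
    views encode the camera's position along the corridor; even in the
    distance from the stem axis to preserve mirror symmetry.
    """
    xi = np.abs(x - _AXIS_X)
    arg1 = _FLOOR_FREQ[:, 0] * xi[..., None] + _FLOOR_PHASE[:, 0]
    arg2 = _FLOOR_FREQ[:, 1] * y[..., None] + _FLOOR_PHASE[:, 1]
    return _FLOOR_RGB * (0.70 + 0.30 * np.sin(arg1) * np.sin(arg2))


def _sky_color(phi: np.ndarray) -> np.ndarray:
    """Skybox stripe RGB as a function of absolute azimuth; shape (..., 3)."""
    delta = phi[..., None, None] - math.pi / 2.0  # (..., 1, 1)
    series = _SKY_AMP * np.cos(_SKY_HARMONICS * delta) * np.cos(_SKY_PHASE)
    base = 0.45 + series.sum(axis=-1)  # (..., 3)
    return np.clip(base, 0.0, 1.0)


def _ray_wall_hits(cam: np.ndarray, phi: np.ndarray):
    """Distance and world hit point for each ray azimuth.

    The camera is strictly inside the closed wall polygon, so every ray hits
    exactly one nearest segment.
    """
    d = np.stack([np.cos(phi), np.sin(phi)], axis=-1)  # (W, 2)
    rel = _SEG_P0 - cam  # (S, 2)
    # Solve cam + t*d = p0 + u*seg_d  for each (segment, ray).
    cross = d[:, None, 0] * _SEG_D[None, :, 1] - d[:, None, 1] * _SEG_D[None, :, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (rel[None, :, 0] * _SEG_D[None, :, 1] - rel[None, :, 1] * _SEG_D[None, :, 0]) / cross
        u = (rel[None, :, 0] * d[:, None, 1] - rel[None, :, 1] * d[:, None, 0]) / cross
    valid = (t > 1e-9) & (u >= -1e-9) & (u <= 1.0 + 1e-9)
    t = np.where(valid, t, np.inf)
    seg = np.argmin(t, axis=1)  # (W,)
    dist = t[np.arange(len(phi)), seg]
    hit = cam + d * dist[:, None]
    return dist, hit


def render_observation(
    state: AgentState,
    ctx: ContextSpec,
    obs_spec: ObservationSpec = ObservationSpec(),
    rng: Optional[np.random.Generator] = None,
    maze: Optional[MazeGraph] = None,
    jitter: bool = True,
) -> np.ndarray:
    """Render the first-person view for an agent pose.

    Per-column raycasting against the maze outline gives wall distance and
    texture; rows above the wall slab sample the skybox stripe at the column's
    azimuth, rows below fall to a floor gradient.  The whole image is then
    multiplied by the context light color.  With ``jitter`` enabled (and an
    ``rng`` given), Gaussian camera-position jitter (sd 1 cm, clipped to 3 cm)
    and yaw jitter (sd 10 deg) are resampled on every call; with jitter
    disabled the image is a deterministic function of (node, heading, ctx).
    """
    maze = maze if maze is not None else _default_maze()
    cam = maze.coords[state.node].astype(np.float64).copy()
    yaw = _HEADING_YAW[state.heading]
    if jitter and rng is not None:
        cam = cam + np.clip(
            rng.normal(0.0, obs_spec.pos_jitter_sd, size=2), -0.03, 0.03
        )
        yaw = yaw + math.radians(rng.normal(0.0, obs_spec.ang_jitter_sd))

    W, H = obs_spec.width, obs_spec.height
    fov = math.radians(obs_spec.fov_deg)
    offsets = fov / 2.0 - (np.arange(W) + 0.5) * fov / W
    phi = yaw + offsets

    dist, hit = _ray_wall_hits(cam, phi)
    half_h = _FOCAL_V_PX * (_WALL_HEIGHT_M / 2.0) / np.maximum(dist, 1e-6)  # (W,)

    rows = np.arange(H, dtype=np.float64)[:, None]  # (H, 1); row 0 = top
    rc = (H - 1) / 2.0
    wall_mask = np.abs(rows - rc) <= half_h[None, :]
    sky_mask = rows < rc - half_h[None, :]

    shade = 1.0 / (1.0 + 0.6 * dist)
    wall_rgb = _wall_albedo(hit[:, 0], hit[:, 1]) * shade[:, None]  # (W, 3)
    sky_rgb = _sky_color(phi)  # (W, 3)
    sky_grad = (1.0 - 0.25 * (rc - rows) / rc)  # (H, 1)

    # ground-plane projection: visible floor rows always project nearer
    # than the wall hit, so the composition below is depth-consistent
    lo = int(np.ceil(rc + 0.5))  # first row strictly below the horizon
    drop = rows[lo:] - rc  # (H_lo, 1)
    ground = _FOCAL_V_PX * _CAMERA_HEIGHT_M / drop  # (H_lo, 1) distance, m
    fx = cam[0] + np.cos(phi)[None, :] * ground  # (H_lo, W)
    fy = cam[1] + np.sin(phi)[None, :] * ground
    floor_rgb = np.zeros((H, W, 3))
    floor_rgb[lo:] = _floor_albedo(fx, fy) / (1.0 + 0.35 * ground[:, :, None])

    img = np.where(
        wall_mask[:, :, None],
        wall_rgb[None, :, :],
        np.where(
            sky_mask[:, :, None],
            sky_rgb[None, :, :] * sky_grad[:, :, None],
            floor_rgb,
        ),
    )
    img = img * light_color(ctx)[None, None, :]
    return np.clip(img, 0.0, 1.0).astype(np.float32)


_DEFAULT_MAZE: Optional[MazeGraph] = None


def _default_maze() -> MazeGraph:
    global _DEFAULT_MAZE
    if _DEFAULT_MAZE is None:
        _DEFAULT_MAZE = build_tmaze()
    return _DEFAULT_MAZE


# ---------------------------------------------------------------------------
# Environment wrapper
# ---------------------------------------------------------------------------


class TMazeEnv:
    """Closed-loop environment: maze dynamics + rendered observations.

    Parameters
    ----------
    maze : maze with the goal (or absence of it) already set.
    ctx : context governing lighting / explicit units.
    rng : generator driving camera jitter.
    max_steps : trial length cap.
    jitter : whether camera jitter is applied to training observations.
    """

    def __init__(
        self,
        maze: MazeGraph,
        ctx: ContextSpec,
        rng: Optional[np.random.Generator] = None,
        obs_spec: ObservationSpec = ObservationSpec(),
        max_steps: int = MAX_TRIAL_STEPS,
        jitter: bool = True,
    ):
        self.maze = maze
        self.ctx = ctx
        self.rng = rng if rng is not None else np.random.default_rng()
        self.obs_spec = obs_spec
        self.max_steps = max_steps
        self.jitter = jitter
        self.state: Optional[AgentState] = None

    def observation(self, state: AgentState, jitter: Optional[bool] = None) -> np.ndarray:
        """Flattened network input for a pose (image, plus context units in
        explicit mode)."""
        use_jitter = self.jitter if jitter is None else jitter
        img = render_observation(
            state, self.ctx, self.obs_spec, rng=self.rng, maze=self.maze,
            jitter=use_jitter,
        ).ravel()
        if self.ctx.mode == "explicit":
            return np.concatenate([img, explicit_context_units(self.ctx.phase_label)])
        return img

    def reset(self) -> np.ndarray:
        self.state = AgentState(node=self.maze.start_node, heading=0, t=0)
        return self.observation(self.state)

    def step_action(self, action: int) -> StepResult:
        if self.state is None:
            raise ProtocolError("reset() must be called before step_action()")
        self.state, res = step(self.state, action, self.maze, self.max_steps)
        obs = self.observation(self.state)
        return StepResult(obs, res.reward, res.terminal)
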