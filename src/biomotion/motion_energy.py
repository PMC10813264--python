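"""Level 1 — local motion energy detectors.

The first stage of the dorsal-stream hierarchy is a retinotopic sheet of
direction-selective units (V1/V2 -> MT analogue): 1116 small receptive
fields in a 36 x 31 grid, each tuned to one of the four cardinal directions
(right, left, up, down).  Their activity is approximated by dense optical
flow between consecutive stimulus frames: the mean flow over each receptive
field is projected onto the cardinal axes and half-wave rectified, so
opposite direction channels are mutually exclusive at every cell.

Two flow modes are provided.  ``exact`` splats the known joint velocities of
the generating skeleton at the rendered blob locations (ground truth,
bypassing estimation error); ``ilk``/``tvl1`` run classic dense estimators
on the rendered frames.  Model validation uses the exact mode so that
conclusions about the detector hierarchy are not confounded by flow
estimation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import FrameStack, PointLightSequence, RenderConfig

#: fixed direction-channel order of DirectionMaps
DIRECTIONS = ("right", "left", "up", "down")


@dataclass
class FlowField:
    """Dense 2-D velocity field for one consecutive-frame pair.

    ``u`` is the horizontal component (+ = image/world right), ``v`` the
    vertical *image-row* component (+ = downward), both in pixels/frame.
    ``frame_index`` is 1-based: flow from frame ``frame_index - 1`` to
    ``frame_index``.
    """

    u: np.ndarray
    v: np.ndarray
    frame_index: int

    def __post_init__(self):
        if self.u.shape != self.v.shape:
            raise ValueError("u and v must have the same shape")
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("flow must be finite")


@dataclass(frozen=True)
class GridConfig:
    rows: int = 36
    cols: int = 31
    overlap: float = 0.5  # linear overlap fraction between adjacent fields

    def __post_init__(self):
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")


@dataclass
class GridSpec:
    """Receptive-field tiling of the image by the 36 x 31 detector sheet.

    ``row_centers``/``col_centers`` are pixel-center coordinates; membership
    of pixel (r, c) in field (i, j) is |r + 0.5 - row_centers[i]| <= rf_h/2
    and likewise for columns.  ``pool`` is the (rows*cols, n_pixels)
    averaging matrix used to compute mean flow per field.
    """

    rows: int
    cols: int
    shape: tuple[int, int]  # image (height, width)
    deg_per_px: float
    rf_h_px: float
    rf_w_px: float
    row_centers: np.ndarray
    col_centers: np.ndarray
    pool: np.ndarray

    @property
    def n_fields(self) -> int:
        return self.rows * self.cols

    @property
    def field_size_deg(self) -> tuple[float, float]:
        return (self.rf_h_px * self.deg_per_px, self.rf_w_px * self.deg_per_px)


@dataclass
class DirectionMaps:
    """Rectified 4-direction activations of the detector grid.

    ``maps`` has shape (rows, cols, 4) ordered (right, left, up, down);
    "up" is world-up (decreasing image row).
    """

    maps: np.ndarray
    frame_index: int

    def mirror_x(self) -> "DirectionMaps":
        """Activations of the x-reflected stimulus: columns reverse and the
        right/left channels swap (up/down unchanged)."""
        m = self.maps[:, ::-1, :][:, :, [1, 0, 2, 3]].copy()
        return DirectionMaps(m, self.frame_index)


def _symmetric_centers(n: int, extent: int, rf: float) -> np.ndarray:
    """Field centers tiling [0, extent] such that the set is exactly
    symmetric under reflection (required for exact mirror equivariance)."""
    c = np.linspace(rf / 2.0, extent - rf / 2.0, n)
    return (c + (extent - c[::-1])) / 2.0


def build_grid(config: GridConfig | None = None,
               render: RenderConfig | None = None) -> GridSpec:
    """Construct the 36 x 31 receptive-field tiling of the rendered frame.

    Field size is derived from the requirement that the grid cover the full
    frame at the configured overlap: rf = extent / ((1-o)(n-1) + 1).
    """
    config = config or GridConfig()
    render = render or RenderConfig()
    h, w = render.height, render.width
    o = config.overlap
    rf_h = h / ((1.0 - o) * (config.rows - 1) + 1.0)
    rf_w = w / ((1.0 - o) * (config.cols - 1) + 1.0)
    rcen = _symmetric_centers(config.rows, h, rf_h)
    ccen = _symmetric_centers(config.cols, w, rf_w)

    pr = np.arange(h) + 0.5
    pc = np.arange(w) + 0.5
    in_row = np.abs(pr[None, :] - rcen[:, None]) <= rf_h / 2.0  # (rows, h)
    in_col = np.abs(pc[None, :] - ccen[:, None]) <= rf_w / 2.0  # (cols, w)
    # (rows*cols, h*w) membership -> row-normalized averaging matrix
    member = (in_row[:, None, :, None] & in_col[None, :, None, :])
    member = member.reshape(config.rows * config.cols, h * w).astype(float)
    counts = member.sum(axis=1, keepdims=True)
    if np.any(counts == 0):
        raise ValueError("grid field with no pixels; increase resolution")
    pool = member / counts
    return GridSpec(config.rows, config.cols, (h, w), render.deg_per_px,
                    rf_h, rf_w, rcen, ccen, pool)


# ---------------------------------------------------------------------------
# optical flow
# ---------------------------------------------------------------------------

def compute_flow(frame_a: np.ndarray, frame_b: np.ndarray,
                 method: str = "ilk", frame_index: int = 1) -> FlowField:
    """Dense optical flow from ``frame_a`` to ``frame_b``.

    ``method`` selects the classic estimator: ``ilk`` (iterative
    Lucas-Kanade) or ``tvl1``.  For ground-truth flow from known joint
    kinematics use :func:`exact_flow_sequence`.
    """
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have identical shapes")
    from skimage.registration import optical_flow_ilk, optical_flow_tvl1

    est = {"ilk": optical_flow_ilk, "tvl1": optical_flow_tvl1}
    if method not in est:
        raise ValueError(f"unknown flow method {method!r}")
    vr, vc = est[method](frame_a.astype(float), frame_b.astype(float))
    return FlowField(u=np.asarray(vc, dtype=float),
                     v=np.asarray(vr, dtype=float), frame_index=frame_index)


def exact_flow_sequence(seq: PointLightSequence,
                        render: RenderConfig | None = None) -> list[FlowField]:
    """Ground-truth flow fields for all consecutive frame pairs.

    Pixels within the blob support (3 sigma) of a joint's position in the
    earlier frame carry that joint's displacement (nearest joint wins);
    all other pixels carry zero flow.
    """
    render = render or RenderConfig()
    h, w, s = render.height, render.width, render.px_per_unit
    cx, cz = render.center_world
    radius = 3.0 * render.blob_sigma_px

    # joint positions in pixel coordinates per frame
    px = (seq.frames[:, :, 0] - cx) * s + w / 2.0 - 0.5
    pz = (cz - seq.frames[:, :, 2]) * s + h / 2.0 - 0.5
    cols = np.arange(w)
    rows = np.arange(h)
    flows = []
    for i in range(1, seq.n_frames):
        d2 = ((cols[None, None, :] - px[i - 1][:, None, None]) ** 2
              + (rows[None, :, None] - pz[i - 1][:, None, None]) ** 2)
        nearest = np.argmin(d2, axis=0)
        covered = np.min(d2, axis=0) <= radius * radius
        du = px[i] - px[i - 1]  # px/frame
        dv = pz[i] - pz[i - 1]
        u = np.where(covered, du[nearest], 0.0)
        v = np.where(covered, dv[nearest], 0.0)
        flows.append(FlowField(u=u, v=v, frame_index=i + 1))
    return flows


def local_response(flow: FlowField, grid: GridSpec) -> DirectionMaps:
    """Mean flow per receptive field, projected on the cardinal axes and
    half-wave rectified.

    World-up is decreasing image row, so the "up" channel rectifies ``-v``.
    Activations are linear in flow magnitude.
    """
    if flow.u.shape != grid.shape:
        raise ValueError("flow shape does not match the grid's image shape")
    mean_u = (grid.pool @ flow.u.ravel()).reshape(grid.rows, grid.cols)
    mean_v = (grid.pool @ flow.v.ravel()).reshape(grid.rows, grid.cols)
    maps = np.stack([
        np.maximum(mean_u, 0.0),   # right
        np.maximum(-mean_u, 0.0),  # left
        np.maximum(-mean_v, 0.0),  # up (world)
        np.maximum(mean_v, 0.0),   # down
    ], axis=-1)
    return DirectionMaps(maps, flow.frame_index)


def sequence_direction_maps(seq: PointLightSequence,
                            grid: GridSpec,
                            render: RenderConfig | None = None
                            ) -> list[DirectionMaps]:
    """Exact-mode direction maps for every consecutive frame pair."""
    return [local_response(f, grid) for f in exact_flow_sequence(seq, render)]
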