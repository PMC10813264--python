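"""Synthetic point-light kicking stimuli.

A point-light display shows only bright dots at the major joints of an actor
against a dark background.  The stimulus generated here is a stylized,
keyframed soccer kick: a 13-joint skeleton winds up, swings, and launches a
ball whose late-phase trajectory carries the left/right direction signal.
Leftward and rightward kicks at a given deviation are synthesized by rotating
one base kick about the vertical axis by a signed angle (yaw), exactly as a
goalkeeper would see a penalty kick aimed off-center.

Coordinate conventions
----------------------
World axes are Z-up (motion-capture convention): ``x`` points to the
observer's right, ``y`` is depth (away from the observer), ``z`` is up.
``rotate_z`` is a yaw about the vertical axis through the skeleton's root;
positive deviation angles send the ball to the observer's right.  Rendering
is an orthographic projection onto the (x, z) plane (depth dropped); image
rows increase downward, so world-up maps to decreasing row index.

The base kick is exactly mirror-symmetric about the vertical midplane
(x = 0), so that at 0 deg deviation the leftward and rightward stimuli are
indistinguishable and the two-alternative task is unbiased by construction.
Left-side stimuli are *defined* as the x-reflection of the corresponding
right-side stimuli, which makes the mirror property exact in floating point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Joint labels of the stylized 13-joint skeleton.  "L"/"R" prefixes refer to
#: the actor's left/right as seen by the observer (screen left/right).
JOINT_LABELS = (
    "head",
    "Lshoulder", "Rshoulder",
    "Lelbow", "Relbow",
    "Lwrist", "Rwrist",
    "pelvis",
    "Lknee", "Rknee",
    "Lankle", "Rankle",
    "ball",
)

#: label swap under x-reflection
_MIRROR_PAIRS = {
    "Lshoulder": "Rshoulder", "Rshoulder": "Lshoulder",
    "Lelbow": "Relbow", "Relbow": "Lelbow",
    "Lwrist": "Rwrist", "Rwrist": "Lwrist",
    "Lknee": "Rknee", "Rknee": "Lknee",
    "Lankle": "Rankle", "Rankle": "Lankle",
}


@dataclass(frozen=True)
class StimulusConfig:
    """Parameters of the synthetic kick.

    The defaults give a 90-frame, 4.5 s animation (20 frames/s).  Lengths are
    in arbitrary "body units" (the figure stands ~1.7 units tall); the
    world-to-degrees scale lives in :class:`RenderConfig`.  The action has
    four phases with continuous articulated motion throughout — approach
    (gait-like bobbing and limb pumping while closing on the ball), wind-up
    (crouch and backswing), swing (ballistic forward leg swing to contact)
    and follow-through with ball flight — so that every temporal window of
    the sequence carries distinctive optic flow.
    """

    n_frames: int = 90
    frame_rate: float = 20.0  # frames / s  (90 frames -> 4.5 s)
    approach_phase: float = 0.45   # fraction of the action spent approaching
    approach_dist: float = 1.35    # depth covered during the approach, units
    gait_hz: float = 1.8           # bob / limb-pump frequency during approach
    swing_phase: float = 0.62      # start of the forward swing
    contact_phase: float = 0.78    # fraction of the sequence at ball contact
    ball_speed: float = 2.2        # units / s along depth after contact
    ball_rise: float = 0.30        # units / s vertical after contact
    swing_amplitude: float = 0.38  # backswing depth of the ankles, units
    crouch_depth: float = 0.09     # pelvis dip during wind-up, units

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class RenderConfig:
    """Orthographic rendering of a sequence to image frames.

    ``deg_per_px`` fixes the angular scale: with the defaults the 72 px tall
    frame subtends 12 deg of visual angle, so the ~1.7-unit figure subtends
    roughly 10 deg (one body unit ~ 6 deg).
    """

    width: int = 62
    height: int = 72
    deg_per_px: float = 12.0 / 72.0
    units_to_deg: float = 6.0
    blob_sigma_px: float = 1.1
    #: world point (x, z) mapped to the image center
    center_world: tuple[float, float] = (0.0, 0.85)

    @property
    def px_per_unit(self) -> float:
        return self.units_to_deg / self.deg_per_px


@dataclass
class PointLightSequence:
    """Joint trajectories of one kick at one deviation angle.

    ``frames`` has shape (n_frames, n_joints, 3) with columns (x, y, z):
    x right, y depth, z up.  ``deviation_deg`` is signed (positive =
    rightward); ``side`` is the nominal response side of the kick.
    """

    joints: tuple[str, ...]
    frames: np.ndarray
    frame_rate: float
    deviation_deg: float
    side: str

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def copy(self) -> "PointLightSequence":
        return PointLightSequence(self.joints, self.frames.copy(),
                                  self.frame_rate, self.deviation_deg, self.side)

    def to_dataframe(self):
        """Long-format (frame, joint, x, y, z) table for CSV export."""
        import pandas as pd

        n_f, n_j, _ = self.frames.shape
        idx = np.repeat(np.arange(n_f), n_j)
        return pd.DataFrame({
            "frame": idx,
            "joint": np.tile(np.asarray(self.joints), n_f),
            "x": self.frames[:, :, 0].ravel(),
            "y": self.frames[:, :, 1].ravel(),
            "z": self.frames[:, :, 2].ravel(),
        })


@dataclass
class FrameStack:
    """Rendered stimulus: bright points on a dark background.

    ``frames``: (n_frames, height, width) intensities in [0, 1].
    """

    frames: np.ndarray
    deg_per_px: float


# ---------------------------------------------------------------------------
# keyframed kinematics of the symmetric base kick
# ---------------------------------------------------------------------------

def _smoothstep(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 0.0, 1.0)
    return p * p * (3.0 - 2.0 * p)


def _base_kick(config: StimulusConfig) -> np.ndarray:
    """Frames of the unrotated (0 deg) kick; exactly x-mirror-symmetric.

    The kick is stylized: all articulated motion lives in the depth-height
    plane and left/right limb pairs move in phase, so that the 0 deg
    stimulus carries no left/right information (the direction signal is
    introduced purely by the yaw rotation).  Every phase of the action has
    substantial motion — an approach with gait-like bobbing and limb
    pumping, a crouching wind-up with a two-leg backswing, a ballistic
    forward swing, and the ball's flight after contact — so no temporal
    window of the stimulus is degenerate (near-static).
    """
    n = config.n_frames
    p = np.linspace(0.0, 1.0, n)  # action phase in [0, 1]
    t = p * config.duration
    pa, ps, pc = config.approach_phase, config.swing_phase, config.contact_phase

    # --- approach: root closes in on the ball, gait bob + limb pumping ---
    adv = _smoothstep(p / pa)
    root_y = -config.approach_dist * (1.0 - adv)
    gait_env = np.clip(1.0 - (p - pa) / 0.12, 0.0, 1.0)  # fades after approach
    gait_env = np.minimum(gait_env, _smoothstep(p / 0.05 + 0.4))
    osc = np.sin(2.0 * np.pi * config.gait_hz * t)
    osc_q = np.sin(2.0 * np.pi * config.gait_hz * t + np.pi / 2.0)
    bob = 0.045 * gait_env * osc_q
    pump = gait_env * osc  # limb pumping along depth during the gait

    # --- wind-up: crouch + backswing between pa and ps ---
    wind = np.sin(np.pi * np.clip((p - pa) / (pc - pa), 0.0, 1.0)) ** 2
    fwd = _smoothstep((p - ps) / (pc - ps + 0.06))  # forward swing ramp
    back = _smoothstep((p - pa) / (ps - pa))        # backswing ramp
    leg_y = (-config.swing_amplitude * back * (1.0 - fwd) + 0.45 * fwd
             + 0.10 * pump)
    leg_lift = 0.18 * fwd * np.sin(np.pi * np.clip(
        (p - ps) / (1.0 - ps), 0.0, 1.0))
    knee_y = 0.55 * leg_y + 0.05 * gait_env * osc_q + 0.04
    knee_lift = 0.4 * leg_lift + 0.05 * gait_env * np.maximum(osc, 0.0)

    crouch = config.crouch_depth * wind
    lean = 0.06 * fwd
    arm = 0.22 * (fwd - 0.35 * wind) - 0.13 * pump  # counter-swing + pump

    f = np.empty((n, len(JOINT_LABELS), 3))

    def set_joint(name, x, y, z):
        f[:, JOINT_LABELS.index(name), 0] = x
        f[:, JOINT_LABELS.index(name), 1] = y + root_y
        f[:, JOINT_LABELS.index(name), 2] = z + bob

    zero = np.zeros(n)
    set_joint("pelvis", zero, 0.04 * fwd, 0.95 - crouch)
    set_joint("head", zero, lean, 1.68 - crouch)
    for sgn, side_lbl in ((-1.0, "L"), (1.0, "R")):
        set_joint(side_lbl + "shoulder", sgn * 0.21 + zero, lean - 0.01,
                  1.44 - crouch)
        set_joint(side_lbl + "elbow", sgn * 0.29 + zero, lean - 0.08 - arm,
                  1.18 - crouch)
        set_joint(side_lbl + "wrist", sgn * 0.32 + zero, lean - 0.12 - 1.8 * arm,
                  0.97 - crouch + 0.25 * arm)
        set_joint(side_lbl + "knee", sgn * 0.12 + zero, knee_y,
                  0.52 - 0.6 * crouch + knee_lift)
        set_joint(side_lbl + "ankle", sgn * 0.14 + zero, leg_y,
                  0.12 + leg_lift)

    # ball: resting on the midline ahead of the actor until contact, then
    # ballistic flight (the root has reached y = 0 by then, so the ball's
    # world position is fixed pre-contact)
    ball_y = np.full(n, 0.40) - root_y  # cancel the root offset: world-fixed
    ball_z = np.full(n, 0.06) - bob
    after = t > pc * config.duration
    dt_fl = t[after] - pc * config.duration
    ball_y[after] = 0.40 - root_y[after] + config.ball_speed * dt_fl
    ball_z[after] = 0.06 - bob[after] + config.ball_rise * dt_fl
    set_joint("ball", zero, ball_y, ball_z)

    return f


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def rotate_z(seq: PointLightSequence, angle_deg: float) -> PointLightSequence:
    """Rigid yaw of all joints about the vertical axis through the root.

    Positive angles rotate trajectories toward the observer's right (the
    depth axis acquires a positive x component).  ``deviation_deg`` is
    incremented by ``angle_deg``.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    th = np.deg2rad(angle_deg)
    c, s = np.cos(th), np.sin(th)
    xy = seq.frames[:, :, :2]
    out = seq.frames.copy()
    out[:, :, 0] = c * xy[:, :, 0] + s * xy[:, :, 1]
    out[:, :, 1] = -s * xy[:, :, 0] + c * xy[:, :, 1]
    return PointLightSequence(seq.joints, out, seq.frame_rate,
                              seq.deviation_deg + angle_deg, seq.side)


def mirror_x(seq: PointLightSequence, relabel_side: bool = True) -> PointLightSequence:
    """Exact reflection about the vertical midplane (x -> -x).

    Left/right joint labels are swapped so the skeleton stays consistent,
    and the nominal side flips.
    """
    order = [JOINT_LABELS.index(_MIRROR_PAIRS.get(j, j)) for j in seq.joints]
    out = seq.frames[:, order, :].copy()
    out[:, :, 0] = -out[:, :, 0]
    side = seq.side
    if relabel_side:
        side = {"left": "right", "right": "left"}.get(side, side)
    return PointLightSequence(seq.joints, out, seq.frame_rate,
                              -seq.deviation_deg, side)


def generate_kick(side: str, deviation_deg: float,
                  config: StimulusConfig | None = None) -> PointLightSequence:
    """Synthesize one kick of the given side and deviation angle.

    ``deviation_deg`` is the unsigned deviation magnitude in degrees; the
    stored signed deviation is positive for rightward kicks and negative for
    leftward ones.  Left kicks are the exact x-reflection of right kicks.
    Deviations beyond 20 deg are permitted with a warning (outside the
    calibrated training/testing range).
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if not np.isfinite(deviation_deg):
        raise ValueError("deviation angle must be finite")
    if abs(deviation_deg) > 20.0:
        logger.warning("deviation %.1f deg outside the 0-20 deg design range",
                       deviation_deg)
    config = config or StimulusConfig()
    base = PointLightSequence(JOINT_LABELS, _base_kick(config),
                              config.frame_rate, 0.0, "right")
    right = rotate_z(base, float(abs(deviation_deg)))
    if side == "right":
        return right
    return mirror_x(right)


def render(seq: PointLightSequence,
           config: RenderConfig | None = None) -> FrameStack:
    """Orthographic projection to Gaussian-blob frames.

    Each joint becomes an isotropic Gaussian blob of peak intensity 1;
    overlapping blobs combine by maximum so intensities stay in [0, 1].
    Joints projecting outside the frame are clipped with a logged warning.
    """
    config = config or RenderConfig()
    h, w, s = config.height, config.width, config.px_per_unit
    cx, cz = config.center_world
    # pixel centers, symmetric about the image midline
    col_x = (np.arange(w) + 0.5 - w / 2.0) / s + cx
    row_z = (h / 2.0 - (np.arange(h) + 0.5)) / s + cz  # rows grow downward

    px = (seq.frames[:, :, 0] - cx) * s + w / 2.0 - 0.5  # (n_frames, n_joints)
    pz = (cz - seq.frames[:, :, 2]) * s + h / 2.0 - 0.5
    out_of_frame = ((px < -0.5) | (px > w - 0.5) | (pz < -0.5) | (pz > h - 0.5))
    if np.any(out_of_frame):
        logger.warning("%d joint projections fall outside the frame and are "
                       "clipped", int(out_of_frame.sum()))

    if seq.frames.shape[1] == 0:
        return FrameStack(np.zeros((seq.n_frames, h, w)), config.deg_per_px)
    sig2 = 2.0 * config.blob_sigma_px ** 2
    xs = seq.frames[:, :, 0]  # world coords, (n_frames, n_joints)
    zs = seq.frames[:, :, 2]
    # squared distances from every pixel center to every joint, per frame
    dx2 = (col_x[None, None, :] - xs[:, :, None]) ** 2  # (f, j, w)
    dz2 = (row_z[None, None, :] - zs[:, :, None]) ** 2  # (f, j, h)
    # blob intensity: exp(-(dx2+dz2) * s^2 / sig2) in pixel units
    ex = np.exp(-dx2 * s * s / sig2)
    ez = np.exp(-dz2 * s * s / sig2)
    frames = np.max(ez[:, :, :, None] * ex[:, :, None, :], axis=1)
    return FrameStack(frames, config.deg_per_px)


def make_stimulus_set(angles, sides, reps: int, seed: int = 0,
                      config: StimulusConfig | None = None
                      ) -> list[PointLightSequence]:
    """Randomized list of |angles| * |sides| * reps kick sequences.

    The order is a seeded permutation; identical seeds give identical
    orders.  With the default two-alternative protocol (angles 2/4/8/15,
    both sides, 120 reps) this yields the full 960-trial set.
    """
    angles = list(angles)
    sides = list(sides)
    if not angles or not sides or reps < 1:
        raise ValueError("angles, sides must be non-empty and reps >= 1")
    conditions = [(s, a) for a in angles for s in sides for _ in range(reps)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(conditions))
    cache: dict[tuple[str, float], PointLightSequence] = {}
    out = []
    for i in order:
        s, a = conditions[i]
        key = (s, float(a))
        if key not in cache:
            cache[key] = generate_kick(s, a, config)
        out.append(cache[key].copy())
    return out
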