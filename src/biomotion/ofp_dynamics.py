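"""Level 3 (temporal) — optic-flow-pattern neuron dynamics.

The 18 template neurons form two independent 9-neuron chains (one per
direction) with asymmetric lateral connections: an active neuron excites
the neuron tuned to the *next* temporal window and inhibits the one tuned
to the *previous* window.  This makes the layer selective for evidence
arriving in the right temporal order — the signature of action sequence
recognition.  Each neuron integrates its feed-forward evidence G_i(t) with
a first-order neural-field dynamic,

    tau_ofp dH_i/dt = -H_i + G_i(t) + sum_m w(i - m) f(H_m(t)),

with tau_ofp = 150 ms, a compact kernel w(+1) > 0 (excite future),
w(-1) < 0 (inhibit past), and a step threshold f(H) = 1 if H > theta_f.
Integration uses the same classical RK4 scheme as the decision layer.

Internal noise enters at the neuron *outputs* only: the signal passed
downstream is drawn from N(H_i(t), dt * delta^2), so the latent H
trajectory itself is deterministic (the lower layers are noise-free).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayes_matching import N_TEMPLATES, N_WINDOWS
from .decision import rk4_step


@dataclass(frozen=True)
class OFPParams:
    tau_ofp: float = 0.150   # layer time constant, s
    w_excite: float = 0.5    # w(+1): drive onto the next window's neuron
    w_inhibit: float = 0.15  # |w(-1)|: suppression of the previous window
    theta_f: float = 0.5     # step-threshold of f(H)
    dt: float = 0.001        # integration step, s (tau_ofp / 150)
    #: 'source' applies f to the presynaptic neuron H_m (canonical
    #: neural-field form); 'self' applies it to H_i as printed in some
    #: formulations.
    lateral_arg: str = "source"
    #: 'independent' gates each chain by its own activities; 'shared' gates
    #: both chains by their mean (the temporal-order population is
    #: direction-agnostic, so the left/right activity difference stays
    #: purely evidence-driven)
    lateral_gate: str = "independent"

    def __post_init__(self):
        if self.tau_ofp <= 0 or self.dt <= 0:
            raise ValueError("tau_ofp and dt must be positive")
        if self.dt > self.tau_ofp / 10.0:
            raise ValueError("dt must be <= tau_ofp/10")
        if self.lateral_arg not in ("source", "self"):
            raise ValueError("lateral_arg must be 'source' or 'self'")
        if self.lateral_gate not in ("independent", "shared"):
            raise ValueError("lateral_gate must be 'independent' or 'shared'")


@dataclass(frozen=True)
class NoiseConfig:
    delta: float = 0.030  # internal-noise standard-deviation parameter
    seed: int = 0

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class OFPState:
    H: np.ndarray            # (18,) activities
    t: float
    params: OFPParams


def _f(H: np.ndarray, theta: float) -> np.ndarray:
    return (H > theta).astype(float)


def lateral_input(H: np.ndarray, params: OFPParams) -> np.ndarray:
    """Asymmetric within-chain lateral drive for all 18 neurons.

    Chains are the two 9-neuron direction populations (indices 0..8 and
    9..17); there is no cross-direction coupling.  With the default
    'source' form, neuron i receives w_excite * f(H_{i-1}) from its past
    neighbour and -w_inhibit * f(H_{i+1}) from its future neighbour.
    """
    H = np.asarray(H, dtype=float)
    if params.lateral_gate == "shared":
        shared = 0.5 * (H[..., :N_WINDOWS] + H[..., N_WINDOWS:])
        fH = np.concatenate([_f(shared, params.theta_f)] * 2, axis=-1)
    else:
        fH = _f(H, params.theta_f)
    out = np.zeros_like(H)
    for start in range(0, N_TEMPLATES, N_WINDOWS):
        chain = slice(start, start + N_WINDOWS)
        fc = fH[..., chain]
        lat = np.zeros_like(fc)
        if params.lateral_arg == "source":
            lat[..., 1:] += params.w_excite * fc[..., :-1]
            lat[..., :-1] -= params.w_inhibit * fc[..., 1:]
        else:  # printed 'self' variant: sum_m w(i-m) f(H_i)
            w_sum = np.zeros(N_WINDOWS)
            w_sum[1:] += params.w_excite   # neurons with a past neighbour
            w_sum[:-1] -= params.w_inhibit  # ... and a future neighbour
            lat = w_sum * fc
        out[..., chain] = lat
    return out


def step(state: OFPState, G_t: np.ndarray, dt: float | None = None) -> OFPState:
    """Advance the layer one RK4 step under piecewise-constant evidence."""
    G_t = np.asarray(G_t, dtype=float)
    if not np.all(np.isfinite(G_t)):
        raise ValueError("non-finite evidence input")
    p = state.params
    dt = p.dt if dt is None else dt

    def rhs(t, H):
        return (-H + G_t + lateral_input(H, p)) / p.tau_ofp

    H = rk4_step(rhs, state.H, state.t, dt)
    return OFPState(H, state.t + dt, p)


def run_ofp(G_stream: np.ndarray, params: OFPParams | None = None,
            duration: float = 4.5, frame_rate: float = 20.0) -> np.ndarray:
    """Integrate the layer over a full stimulus presentation.

    ``G_stream``: (n_pairs, 18) evidence per consecutive-frame pair.  The
    evidence is zero before the second frame appears and zero-order-held
    over each frame interval thereafter.  Returns the latent (noise-free)
    trajectory H with shape (n_steps + 1, 18), n_steps = duration / dt.
    """
    params = params or OFPParams()
    n_pairs = G_stream.shape[0]
    dt = params.dt
    n_steps = int(round(duration / dt))
    frame_dt = 1.0 / frame_rate
    H = np.zeros(N_TEMPLATES)
    traj = np.empty((n_steps + 1, N_TEMPLATES))
    traj[0] = H
    state = OFPState(H, 0.0, params)
    zeros = np.zeros(N_TEMPLATES)
    for s in range(n_steps):
        t = s * dt
        pair = int(t / frame_dt) - 1
        G_t = zeros if pair < 0 else G_stream[min(pair, n_pairs - 1)]
        state = step(state, G_t)
        traj[s + 1] = state.H
    return traj


def noisy_output(H, dt: float, noise: NoiseConfig,
                 rng: np.random.Generator | None = None):
    """Sample the neuron outputs: N(H, dt * delta^2) per component.

    With delta = 0 the output equals H exactly.  A fixed seed (when no
    generator is passed) gives a reproducible stream.
    """
    H = np.asarray(H, dtype=float)
    if noise.delta == 0:
        return H.copy()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    return H + rng.normal(0.0, noise.delta * np.sqrt(dt), size=H.shape)
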