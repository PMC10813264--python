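"""Level 4 — robust mutual-inhibition race with neural adaptation.

Two motion-pattern neurons (left and right) race to a decision.  Each
neuron's activity follows

    tau dT/dt = -T + S(P_T(D)) + DiS_T(t),
    tau dD/dt = -D + S(P_D(D, T)) + DiS_D(t),

where S is a modified Michaelis-Menten gain, S(x) = beta x / (gamma + x)
for x > 0 and 0 otherwise, and the information thresholds embed the
evidence drives and inhibition:

    P_T = g_T - k D - a T - theta_info,
    P_D = g_D - k T - a D - theta_info,

with mutual-inhibition gain k, auto-inhibition a, and an information
threshold offset theta_info: until the evidence drive carries enough
information to exceed the offset (plus the inhibition terms) the
information threshold is negative, the neuron's lateral drive is silent
(S clamps to zero) and the race stays quiescent — so the winner-take-all
competition engages only once real evidence arrives, not on noise at
stimulus onset.  Negative activities are clamped to zero after each full
integration step.  Together these constitute the "robust" rule (the
reconstruction of the predecessor's thresholds is guaranteed by contract:
robust non-negativity, k's role as the inhibitory feedback gain).

Disremembering / neural adaptation (switched on at t = tau_a):

    DiS_T = u(t - tau_a) [ T - S(P_T(D)) - k_T T ],

so that for t >= tau_a the dynamics reduce to tau dT/dt = -k_T T, a simple
exponential decline that drives the winner out of the excitation state and
bounds how long a decision persists.  For t < tau_a the adaptation input is
exactly zero, so traces with adaptation on and off are bit-identical there.

The system is integrated with a classical 4th-order Runge-Kutta scheme
(clamping applied after the full step, not inside stages).  The winner is
the first neuron to cross the decision criterion; the model reaction time
is the mean of the time points at which the winning signal is at its
maximum (motor time treated as zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UNDECIDED = "none"
RT_UNDEFINED = float("nan")


@dataclass(frozen=True)
class DecisionParams:
    tau: float = 0.030        # neuron time constant, s
    k_inhib: float = 4.0      # mutual-inhibition gain k, dimensionless
    tau_a: float = 1.22       # adaptation onset, s
    k_adapt: float = 1.0      # adaptation weighting coefficient k_T = k_D
    auto_inhib: float = 0.3   # auto-inhibition gain a
    info_threshold: float = 0.4  # information-threshold offset, drive units
    beta: float = 1.0         # Michaelis-Menten ceiling
    gamma: float = 0.25       # Michaelis-Menten half-saturation
    criterion: float = 0.40   # decision level on the winner's activity
    dt: float = 0.001         # integration step, s
    adaptation_enabled: bool = True

    def __post_init__(self):
        if self.tau <= 0 or self.dt <= 0:
            raise ValueError("tau and dt must be positive")
        if self.dt > self.tau / 10.0:
            raise ValueError("dt must be <= tau/10 for a stable race")
        if self.tau_a < 0 or self.criterion <= 0:
            raise ValueError("tau_a must be >= 0 and criterion > 0")


@dataclass
class DecisionTrace:
    """Time courses and outcome of one decision trial."""

    t: np.ndarray
    activity: np.ndarray        # (n_steps, 2), columns (left, right)
    winner: str                 # 'left' | 'right' | 'none'
    rt: float                   # s; NaN when undecided
    adaptation_onset_applied: bool


def S(x, beta: float = 1.0, gamma: float = 0.25):
    """Modified Michaelis-Menten gain: beta*max(x,0)/(gamma+max(x,0)).

    S(0) = 0, S(gamma) = beta/2, monotone non-decreasing, bounded by beta.
    """
    xp = np.maximum(x, 0.0)
    return beta * xp / (gamma + xp)


def derivatives(state, drives, t: float, params: DecisionParams):
    """(dT/dt, dD/dt) for activities ``state``=(T, D), drives (g_T, g_D).

    Vectorized: ``state`` and ``drives`` may be (..., 2) arrays.  For
    t >= tau_a (adaptation on) the stated substitution makes the lateral
    terms cancel exactly and each neuron relaxes as -k_adapt * activity.
    """
    state = np.asarray(state, dtype=float)
    drives = np.asarray(drives, dtype=float)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite decision state")
    T = state[..., 0]
    D = state[..., 1]
    p = params
    if p.adaptation_enabled and t >= p.tau_a:
        dT = -p.k_adapt * T
        dD = -p.k_adapt * D
    else:
        s_T = S(drives[..., 0] - p.k_inhib * D - p.auto_inhib * T
                - p.info_threshold, p.beta, p.gamma)
        s_D = S(drives[..., 1] - p.k_inhib * T - p.auto_inhib * D
                - p.info_threshold, p.beta, p.gamma)
        dT = -T + s_T
        dD = -D + s_D
    return np.stack([dT, dD], axis=-1) / p.tau


def rk4_step(deriv_fn, y, t: float, dt: float):
    """One classical 4th-order Runge-Kutta step of y' = deriv_fn(t, y)."""
    k1 = deriv_fn(t, y)
    k2 = deriv_fn(t + dt / 2.0, y + dt / 2.0 * k1)
    k3 = deriv_fn(t + dt / 2.0, y + dt / 2.0 * k2)
    k4 = deriv_fn(t + dt, y + dt * k3)
    return y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def run_decision(drives: np.ndarray, params: DecisionParams,
                 duration: float | None = None) -> DecisionTrace:
    """Integrate the race for one trial.

    ``drives``: (n_steps, 2) per-step evidence drives (g_left, g_right),
    zero-order-held within each step.  The winner is the first neuron to
    cross the criterion; simultaneous crossings within one step leave the
    trial undecided (recorded, never silently randomized).
    """
    drives = np.asarray(drives, dtype=float)
    n_steps = drives.shape[0]
    if duration is not None and n_steps * params.dt < duration - 1e-12:
        raise ValueError("evidence shorter than the simulation horizon")
    traces, winners, rts = run_decision_batch(drives[:, None, :], params)
    t = np.arange(n_steps + 1) * params.dt
    return DecisionTrace(t, traces[:, 0, :], winners[0], rts[0],
                         params.adaptation_enabled)


def run_decision_batch(drives: np.ndarray, params: DecisionParams):
    """Vectorized race over a batch of trials.

    ``drives``: (n_steps, n_trials, 2), columns (g_left, g_right).
    Returns (activity (n_steps+1, n_trials, 2), winners list, rts array).
    Activities are clamped non-negative after each full RK4 step.
    """
    p = params
    n_steps, n_trials, _ = drives.shape
    y = np.zeros((n_trials, 2))
    traj = np.empty((n_steps + 1, n_trials, 2))
    traj[0] = y
    crossed = np.full(n_trials, -1, dtype=int)   # winner index, -1 pending
    tie = np.zeros(n_trials, dtype=bool)
    cross_step = np.full(n_trials, -1, dtype=int)
    for s in range(n_steps):
        g = drives[s]
        t = s * p.dt

        # the vector field is autonomous within a step (zero-order-held
        # drives); evaluating all RK4 stages at the step-start time keeps
        # the adaptation switch aligned with step boundaries, so each step
        # integrates a smooth regime
        def rhs(tt, yy, g=g, t=t):
            return derivatives(yy, g, t, p)

        y = rk4_step(rhs, y, t, p.dt)
        y = np.maximum(y, 0.0)  # robust rule
        traj[s + 1] = y
        pending = crossed < 0
        if np.any(pending):
            above = y[pending] > p.criterion
            both = above[:, 0] & above[:, 1]
            one = above.any(axis=1) & ~both
            idx = np.flatnonzero(pending)
            tie[idx[both]] = True
            crossed[idx[both]] = -2
            win = idx[one]
            crossed[win] = np.argmax(y[win], axis=1)
            cross_step[win] = s + 1
    winners = []
    rts = np.full(n_trials, RT_UNDEFINED)
    names = ("left", "right")
    t_grid = np.arange(n_steps + 1) * p.dt
    for i in range(n_trials):
        if crossed[i] < 0 or tie[i]:
            winners.append(UNDECIDED)
            continue
        winners.append(names[crossed[i]])
        rts[i] = extract_rt_from_series(t_grid, traj[:, i, crossed[i]])
    return traj, winners, rts


DEFAULT_PLATEAU_EPS = 1e-6


def extract_rt_from_series(t: np.ndarray, w: np.ndarray,
                           eps_plateau: float = DEFAULT_PLATEAU_EPS) -> float:
    """Mean of the time points where ``w`` is within ``eps_plateau``
    (relative) of its global maximum."""
    m = float(np.max(w))
    if m <= 0:
        return RT_UNDEFINED
    at_max = w >= m * (1.0 - eps_plateau)
    return float(np.mean(t[at_max]))


def extract_rt(trace: DecisionTrace,
               eps_plateau: float = DEFAULT_PLATEAU_EPS) -> float:
    """Reaction time of a decided trial (undecided -> NaN sentinel)."""
    if trace.winner == UNDECIDED:
        return RT_UNDEFINED
    col = ("left", "right").index(trace.winner)
    return extract_rt_from_series(trace.t, trace.activity[:, col], eps_plateau)
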