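"""Decision race: gain function, dynamics, RK4, adaptation, RT extraction."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from biomotion import decision as dc


def params(**kw):
    base = dict(tau=0.030, k_inhib=4.0, tau_a=1.22, criterion=0.4, dt=0.001)
    base.update(kw)
    return dc.DecisionParams(**base)


# -- S gain -----------------------------------------------------------------

def test_S_identities():
    assert dc.S(0.0) == 0.0
    assert dc.S(-3.0) == 0.0
    assert dc.S(0.25, beta=1.0, gamma=0.25) == pytest.approx(0.5)
    assert dc.S(2.0, beta=0.7, gamma=0.25) <= 0.7


def test_S_monotone_on_dense_grid():
    x = np.linspace(-2, 5, 2001)
    s = dc.S(x)
    assert np.all(np.diff(s) >= 0)


# -- derivatives ------------------------------------------------------------

def test_quiescent_fixed_point():
    d = dc.derivatives(np.zeros(2), np.zeros(2), 0.0, params())
    assert np.all(d == 0.0)


def test_adaptation_inactive_before_onset():
    p_on = params(adaptation_enabled=True)
    p_off = params(adaptation_enabled=False)
    state = np.array([0.3, 0.2])
    g = np.array([0.9, 0.8])
    for t in (0.0, 0.5, 1.21):
        assert np.array_equal(dc.derivatives(state, g, t, p_on),
                              dc.derivatives(state, g, t, p_off))


def test_adaptation_reduces_to_exponential_decline():
    # after tau_a the lateral terms cancel and tau dT/dt = -k_adapt T
    p = params(k_adapt=1.0)
    state = np.array([0.6, 0.1])
    d = dc.derivatives(state, np.array([2.0, 2.0]), 1.5, p)
    np.testing.assert_allclose(d, -p.k_adapt * state / p.tau)


def test_nonfinite_state_rejected():
    with pytest.raises(ValueError):
        dc.derivatives(np.array([np.nan, 0.0]), np.zeros(2), 0.0, params())


def test_param_validation():
    with pytest.raises(ValueError):
        params(dt=0.02)
    with pytest.raises(ValueError):
        params(criterion=0.0)
    with pytest.raises(ValueError):
        params(tau=-1.0)


# -- RK4 --------------------------------------------------------------------

def test_rk4_single_step_matches_exponential():
    y = dc.rk4_step(lambda t, y: -y, 1.0, 0.0, 0.01)
    assert y == pytest.approx(np.exp(-0.01), abs=1e-10)


def test_rk4_zero_derivative_preserves_state():
    y0 = np.array([0.3, 0.7])
    y = dc.rk4_step(lambda t, y: np.zeros_like(y), y0, 0.0, 0.01)
    assert np.array_equal(y, y0)


def test_rk4_global_error_is_fourth_order():
    errs = []
    for dt in (0.02, 0.01):
        y = 1.0
        n = int(round(1.0 / dt))
        for i in range(n):
            y = dc.rk4_step(lambda t, y: -y, y, i * dt, dt)
        errs.append(abs(y - np.exp(-1.0)))
    order = np.log2(errs[0] / errs[1])
    assert 3.7 < order < 4.3


# -- full race --------------------------------------------------------------

def drives_const(gl, gr, n=2000):
    return np.tile(np.array([gl, gr]), (n, 1))


def test_symmetric_evidence_preserves_tie():
    trace = dc.run_decision(drives_const(1.0, 1.0), params())
    assert trace.winner == dc.UNDECIDED
    assert np.isnan(trace.rt)
    np.testing.assert_array_equal(trace.activity[:, 0], trace.activity[:, 1])


def test_strong_one_sided_evidence_wins_then_adapts():
    p = params(tau_a=0.8)
    trace = dc.run_decision(drives_const(0.1, 1.5, n=2500), p)
    assert trace.winner == "right"
    # adaptation drives the winner back below criterion
    assert trace.activity[-1, 1] < p.criterion
    assert np.isfinite(trace.rt) and trace.rt > 0


def test_swapping_evidence_swaps_winner_keeps_rt():
    p = params()
    a = dc.run_decision(drives_const(1.4, 0.2), p)
    b = dc.run_decision(drives_const(0.2, 1.4), p)
    assert a.winner == "left" and b.winner == "right"
    assert a.rt == b.rt
    np.testing.assert_array_equal(a.activity[:, 0], b.activity[:, 1])


def test_activities_stay_nonnegative(rng):
    p = params()
    drives = np.abs(rng.normal(0.6, 0.6, size=(3000, 2)))
    trace = dc.run_decision(drives, p)
    assert np.all(trace.activity >= 0.0)


def test_short_evidence_rejected():
    with pytest.raises(ValueError):
        dc.run_decision(drives_const(1, 1, n=100), params(), duration=4.5)


# -- RT extraction ----------------------------------------------------------

def test_rt_single_sharp_peak():
    t = np.linspace(0, 2, 2001)
    w = np.exp(-((t - 1.0) / 0.05) ** 2)
    assert dc.extract_rt_from_series(t, w) == pytest.approx(1.0, abs=1e-6)


def test_rt_symmetric_plateau_midpoint():
    t = np.linspace(0, 2, 2001)
    w = np.clip(1.0 - np.abs(t - 1.0), 0, None)
    w[(t >= 0.9) & (t <= 1.1)] = np.max(w)
    assert dc.extract_rt_from_series(t, w) == pytest.approx(1.0, abs=1e-3)


def test_rt_asymmetric_plateau_mean():
    t = np.round(np.arange(0, 2.0001, 0.001), 10)
    w = np.zeros_like(t)
    w[(t >= 1.0) & (t <= 1.4)] = 1.0
    assert dc.extract_rt_from_series(t, w) == pytest.approx(1.2, abs=1e-9)


def test_rt_of_undecided_trace_is_nan():
    t = np.linspace(0, 1, 100)
    trace = dc.DecisionTrace(t, np.zeros((100, 2)), dc.UNDECIDED,
                             dc.RT_UNDEFINED, True)
    assert np.isnan(dc.extract_rt(trace))


# -- oracle equivalence -----------------------------------------------------

def reference_trajectory(drives_fn, p, t_end):
    """High-accuracy adaptive reference for the same vector field,
    integrated piecewise around the adaptation switch."""

    def rhs(t, y):
        return dc.derivatives(y, drives_fn(t), t, p)

    ys = [np.zeros(2)]
    spans = ([(0.0, p.tau_a), (p.tau_a, t_end)]
             if 0 < p.tau_a < t_end else [(0.0, t_end)])
    y0 = ys[0]
    out_t, out_y = [0.0], [y0]
    for t0, t1 in spans:
        sol = solve_ivp(rhs, (t0, t1), y0, method="DOP853",
                        rtol=1e-11, atol=1e-13, dense_output=True)
        y0 = sol.y[:, -1]
        out_t.append(t1)
        out_y.append(y0)
    return np.array(out_t), np.array(out_y)


def test_race_matches_adaptive_reference_integrator(rng):
    """RK4 race trajectories agree with a high-accuracy adaptive solver to
    1e-6 relative across random parameterizations (smooth regime)."""
    for _ in range(5):
        # weak coupling and strong drives keep both information thresholds
        # positive, so the vector field stays smooth (no gain kink) and the
        # comparison probes pure integrator accuracy
        p = params(tau=float(rng.uniform(0.024, 0.05)),
                   k_inhib=float(rng.uniform(0.05, 0.3)),
                   tau_a=float(np.round(rng.uniform(0.3, 0.8), 3)),
                   criterion=10.0)
        gl, gr = 1.2 + rng.uniform(0, 0.3), 1.5 + rng.uniform(0, 0.4)
        t_end = 1.0
        n = int(round(t_end / p.dt))
        trace = dc.run_decision(drives_const(gl, gr, n=n), p)
        ts, ys = reference_trajectory(
            lambda t: np.array([gl, gr]), p, t_end)
        scale = np.max(np.abs(ys))
        idx = np.round(ts / p.dt).astype(int)
        err = np.max(np.abs(trace.activity[idx] - ys)) / scale
        assert err < 1e-6


# -- property tests ---------------------------------------------------------

try:
    from hypothesis import given, settings
    from hypothesis import strategies as st_h

    @given(x=st_h.floats(-10, 10), y=st_h.floats(-10, 10),
           gamma=st_h.floats(0.05, 2.0))
    @settings(deadline=None, derandomize=True)
    def test_S_monotone_property(x, y, gamma):
        lo, hi = sorted((x, y))
        assert dc.S(lo, 1.0, gamma) <= dc.S(hi, 1.0, gamma)

    @given(gl=st_h.floats(0, 2), gr=st_h.floats(0, 2))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_race_nonnegative_property(gl, gr):
        trace = dc.run_decision(drives_const(gl, gr, n=600), params())
        assert np.all(trace.activity >= 0.0)
except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass
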