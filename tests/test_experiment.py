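"""Protocol, psychometric fitting, tuning, and the reference analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import biomotion as bm
from biomotion import experiment as ex


# -- psychometric fitting ---------------------------------------------------

def bernoulli_table(rng, threshold=8.0, spread=2.0, reps=120,
                    angles=(2, 4, 8, 15)):
    rows = []
    for a in angles:
        p = 0.5 + 0.5 * expit((a - threshold) / spread)
        for side in ("left", "right"):
            correct = rng.random(reps) < p
            for c in correct:
                rows.append({"side": side, "deviation_deg": float(a),
                             "correct": bool(c), "rt": 1.0,
                             "undecided": False})
    return pd.DataFrame(rows)


def test_psychometric_recovery_single_fit(rng):
    fit = ex.fit_psychometric(bernoulli_table(rng))
    assert fit.converged
    assert abs(fit.threshold75 - 8.0) < 1.5
    assert fit.slope == pytest.approx(0.125 / 2.0, rel=0.5)
    assert fit.se_threshold > 0 and fit.se_slope > 0


def test_psychometric_se_scales_with_sample_size(rng):
    ses = []
    for reps in (120, 480):
        se = [ex.fit_psychometric(bernoulli_table(rng, reps=reps)
                                  ).se_threshold for _ in range(20)]
        ses.append(np.mean(se))
    assert ses[0] / ses[1] == pytest.approx(2.0, rel=0.25)


def test_psychometric_chance_data_flagged(rng):
    table = bernoulli_table(rng, threshold=500.0, spread=1.0)
    fit = ex.fit_psychometric(table)
    assert not fit.converged
    assert np.isnan(fit.threshold75)


def test_psychometric_requires_two_levels(rng):
    table = bernoulli_table(rng, angles=(8,))
    with pytest.raises(ValueError):
        ex.fit_psychometric(table)


# -- protocol ---------------------------------------------------------------

def test_reduced_block_counts_and_determinism(model):
    obs = bm.ObserverParams()
    proto = ex.Protocol(reps=5)
    t1 = ex.run_block(model, obs, proto, seed=11)
    t2 = ex.run_block(model, obs, proto, seed=11)
    assert len(t1) == 40
    pd.testing.assert_frame_equal(t1, t2)
    counts = t1.groupby(["side", "deviation_deg"]).size()
    assert (counts == 5).all()
    assert (t1["undecided"] == (t1["choice"] == "none")).all()


def test_block_randomized_order_differs_across_seeds(model):
    obs = bm.ObserverParams(delta=0.0)
    a = ex.run_block(model, obs, ex.Protocol(reps=3), seed=1)
    b = ex.run_block(model, obs, ex.Protocol(reps=3), seed=2)
    assert not (a["deviation_deg"].values == b["deviation_deg"].values).all()


def test_clean_observer_is_deterministic_and_correct(model):
    obs = bm.ObserverParams(delta=0.0)
    table = ex.run_block(model, obs, ex.Protocol(reps=2), seed=0)
    dec = table[~table["undecided"]]
    # without internal noise the pipeline is deterministic; large angles
    # must be decided correctly
    big = dec[dec["deviation_deg"] >= 8]
    assert (big["correct"]).all()


def test_simulate_conditions_matches_per_condition_batches(model):
    obs = bm.ObserverParams()
    conds = [("left", 4.0, 7, 123), ("right", 15.0, 5, 456)]
    w_fused, rt_fused = model.simulate_conditions(conds, obs)
    w_sep, rt_sep = [], []
    for side, angle, n, seed in conds:
        w, r = model.simulate_batch(side, angle, obs, n, seed)
        w_sep += list(w)
        rt_sep += list(r)
    assert w_fused == w_sep
    np.testing.assert_array_equal(rt_fused, np.array(rt_sep))


def test_mirror_balance_of_clean_pipeline(model):
    # with delta = 0, left and right trials are decided symmetrically
    obs = bm.ObserverParams(delta=0.0)
    for a in (4.0, 15.0):
        wl, rl = model.simulate_batch("left", a, obs, 1, seed=0)
        wr, rr = model.simulate_batch("right", a, obs, 1, seed=0)
        assert {wl[0], wr[0]} == {"left", "right"}
        assert rl[0] == pytest.approx(rr[0], abs=2 * model.ofp_params.dt)


def test_summarize_observer_reproducible(model):
    obs = bm.ObserverParams()
    proto = ex.Protocol(reps=10)
    s1 = ex.summarize_observer(model, obs, n_blocks=2, protocol=proto, seed=3)
    s2 = ex.summarize_observer(model, obs, n_blocks=2, protocol=proto, seed=3)
    assert s1.threshold75 == s2.threshold75
    assert s1.mean_rt == s2.mean_rt
    assert s1.mean_rt_se >= 0


# -- grid search ------------------------------------------------------------

def test_grid_search_self_consistency(model):
    proto = ex.Protocol(reps=15)
    true = bm.ObserverParams(delta=0.030, tau=0.030, k=4.0, tau_a=1.22)
    target_summary = ex.summarize_observer(model, true, n_blocks=2,
                                           protocol=proto, seed=77)
    target = {"threshold": target_summary.threshold75,
              "slope": target_summary.slope,
              "rt": target_summary.mean_rt}
    grid = [
        {"delta": 0.030, "tau": 0.030, "k": 4.0, "tau_a": 1.22},
        {"delta": 0.030, "tau": 0.030, "k": 4.0, "tau_a": 0.70},
    ]
    board = ex.grid_search(model, target, grid, protocol=proto,
                           n_blocks=2, seed=5)
    assert len(board) == 2
    assert board.iloc[0]["tau_a"] == 1.22  # planted parameters recovered
    # leaderboard invariant to grid order
    board_r = ex.grid_search(model, target, grid[::-1], protocol=proto,
                             n_blocks=2, seed=5)
    pd.testing.assert_frame_equal(board, board_r)


# -- reference table --------------------------------------------------------

def test_reference_table_shape_and_groups():
    ref = ex.load_reference_table()
    assert len(ref) == 36
    assert ref["subject"].is_unique
    # ditto rows repeat their group leader's simulated values
    grp = ref.groupby((ref["ditto"] == 0).cumsum())
    for _, g in grp:
        assert g["thr_sim"].nunique() == 1
        assert g["k"].nunique() == 1
    # the known suspect transcription is preserved verbatim and flagged
    a03 = ref[ref["subject"] == "A03"].iloc[0]
    assert a03["delta"] == 0.340 and a03["suspect"] == 1


def test_reference_lookup_b09():
    ref = ex.load_reference_table().set_index("subject")
    row = ref.loc["B09"]
    assert (row["thr_sim"], row["slope_sim"], row["rt_sim"]) == \
        (6.872, 0.180, 1.020)
    assert (row["k"], row["tau"], row["delta"], row["tau_a"]) == \
        (4, 0.025, 0.034, 1.22)


def test_correlation_identities():
    ref = ex.load_reference_table()
    self_ref = ref.copy()
    self_ref["thr_sim"] = self_ref["thr_exp"]
    rep = ex.correlate_reference(self_ref)
    thr = rep[rep["measure"] == "threshold"].iloc[0]
    assert thr["spearman_r"] == pytest.approx(1.0)
    rev = ref.copy()
    rev["thr_sim"] = (-ref["thr_exp"].rank()).values
    rep = ex.correlate_reference(rev)
    thr = rep[rep["measure"] == "threshold"].iloc[0]
    assert thr["spearman_r"] == pytest.approx(-1.0)


def test_correlation_rejects_missing_cells():
    ref = ex.load_reference_table()
    ref.loc[0, "rt_sim"] = np.nan
    with pytest.raises(ValueError):
        ex.correlate_reference(ref)


def test_sign_test():
    n_pos, n, p = ex.sign_test([1, 2, 3, 4, 5, -1, 0], "greater")
    assert (n_pos, n) == (5, 6)
    assert 0 < p < 1
    _, _, p_strong = ex.sign_test(np.ones(30), "greater")
    assert p_strong < 1e-8
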