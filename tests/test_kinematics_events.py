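"""Kinematic derivations, event detection, and behavioral summaries."""

import math

import numpy as np
import pytest

from epnpop.kinematics_events import (
    PsychometricModel,
    arena_corners,
    compute_kinematics,
    detect_events,
    fit_psychometric,
    prob_correct_by_rt,
    response_time_stats,
)
from epnpop.session_io import BODYPARTS, TrackingTable, TrialRecord


def _tracking_from_body(time, body, heading_deg):
    """Rigid mouse model around a body-center path (cm)."""
    h = np.radians(heading_deg)
    u = np.column_stack([np.cos(h), np.sin(h)])
    n = np.column_stack([-u[:, 1], u[:, 0]])
    coords = {
        "body_center": body,
        "head": body + 2.5 * u,
        "tail_base": body - 2.5 * u,
        "paw_FL": body + 1.0 * u + 1.2 * n,
        "paw_FR": body + 1.0 * u - 1.2 * n,
        "paw_HL": body - 1.0 * u + 1.2 * n,
        "paw_HR": body - 1.0 * u - 1.2 * n,
    }
    assert set(coords) == set(BODYPARTS)
    return TrackingTable(time=time, coords=coords)


def test_straight_constant_velocity_path():
    fs, v = 60.0, 12.0
    t = np.arange(0, 5, 1 / fs)
    body = np.column_stack([2.0 + v * t, np.full_like(t, 3.0)])
    tr = _tracking_from_body(t, body, np.zeros_like(t))
    kin = compute_kinematics(tr, arena_side=100.0)
    interior = slice(10, -10)
    np.testing.assert_allclose(kin["body_speed"][interior], v, rtol=1e-6)
    np.testing.assert_allclose(kin["angular_velocity"][interior], 0.0, atol=1e-6)
    np.testing.assert_allclose(kin["acceleration"][interior], 0.0, atol=1e-5)


def test_circular_path_angular_velocity_closed_form():
    fs, r, v = 60.0, 8.0, 10.0
    t = np.arange(0, 6, 1 / fs)
    omega = v / r  # rad/s
    ang = omega * t
    body = np.column_stack([20 + r * np.cos(ang), 20 + r * np.sin(ang)])
    heading = np.degrees(ang + np.pi / 2)  # tangent
    tr = _tracking_from_body(t, body, heading)
    kin = compute_kinematics(tr, arena_side=100.0)
    interior = slice(20, -20)
    expected = omega * 180.0 / math.pi
    np.testing.assert_allclose(
        np.abs(kin["angular_velocity"][interior]), expected, rtol=0.01
    )
    np.testing.assert_allclose(kin["body_speed"][interior], v, rtol=0.01)


def test_kinematics_rotation_invariance():
    fs = 60.0
    t = np.arange(0, 4, 1 / fs)
    rng = np.random.default_rng(0)
    base = np.cumsum(rng.normal(0, 0.05, (len(t), 2)), axis=0) + 15.0
    heading = np.linspace(0, 90, len(t))
    tr = _tracking_from_body(t, base, heading)
    kin = compute_kinematics(tr, arena_side=100.0)

    theta = np.radians(37.0)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    rotated = TrackingTable(
        time=t, coords={bp: xy @ R.T for bp, xy in tr.coords.items()}
    )
    kin_rot = compute_kinematics(rotated, arena_side=100.0)

    np.testing.assert_allclose(kin_rot["body_speed"], kin["body_speed"], atol=1e-8)
    np.testing.assert_allclose(
        kin_rot["angular_velocity"], kin["angular_velocity"], atol=1e-6
    )
    # heading shifts by the rotation angle
    dh = kin_rot["heading"] - kin["heading"]
    np.testing.assert_allclose(dh, 37.0, atol=1e-6)


def test_too_few_frames_rejected():
    t = np.arange(2) / 60.0
    body = np.zeros((2, 2))
    tr = _tracking_from_body(t, body, np.zeros(2))
    with pytest.raises(ValueError):
        compute_kinematics(tr)


def test_distance_to_goal_small_at_port_entry(small_session, small_session_events):
    cfg, bundle, _ = small_session
    kin, events, _ = small_session_events
    checked = 0
    for tr in bundle.trials[:40]:
        ev = events.get(tr.index)
        if ev is None:
            continue
        d = kin.interp("dist_goal", np.array([ev["port_entry"]]))[0]
        assert d < 1.5 + 0.5
        checked += 1
    assert checked > 10


def test_event_detection_invariant_to_time_translation(small_session):
    cfg, bundle, _ = small_session
    shift = 17.0
    tr = bundle.tracking
    shifted_tracking = TrackingTable(
        time=tr.time + shift, coords={k: v.copy() for k, v in tr.coords.items()}
    )
    shifted_trials = []
    for t in bundle.trials:
        shifted_trials.append(
            TrialRecord(
                index=t.index,
                delta_freq=t.delta_freq,
                instructed_side=t.instructed_side,
                choice=t.choice,
                outcome=t.outcome,
                events={k: v + shift for k, v in t.events.items()},
                rewarded=t.rewarded,
            )
        )
    from epnpop.session_io import LickEvents

    shifted_licks = {
        p: LickEvents(p, bundle.licks[p].head_entry_times + shift,
                      bundle.licks[p].lick_times + shift)
        for p in bundle.licks
    }
    kin0 = compute_kinematics(tr, bundle.trials, arena_side=cfg.arena_side)
    kin1 = compute_kinematics(shifted_tracking, shifted_trials, arena_side=cfg.arena_side)
    ev0, _ = detect_events(kin0, bundle.trials, bundle.licks)
    ev1, _ = detect_events(kin1, shifted_trials, shifted_licks)
    assert set(ev0) == set(ev1)
    for idx in list(ev0)[:30]:
        for name in ev0[idx]:
            assert abs(ev1[idx][name] - ev0[idx][name] - shift) < 1e-9


def test_flagged_when_arrival_threshold_never_crossed(small_session):
    cfg, bundle, _ = small_session
    from epnpop.session_io import AnalysisConfig

    kin = compute_kinematics(bundle.tracking, bundle.trials, arena_side=cfg.arena_side)
    strict = AnalysisConfig(arrival_threshold_cm=0.1)  # below the halt distance
    _, flagged = detect_events(kin, bundle.trials, bundle.licks, strict)
    assert len(flagged) == len(bundle.trials)


def test_turn_mid_is_half_of_turn(small_session, small_session_events):
    _, bundle, _ = small_session
    _, events, _ = small_session_events
    for idx, ev in list(events.items())[:30]:
        mid_frac = (ev["turn_mid"] - ev["turn_start"]) / (
            ev["turn_end"] - ev["turn_start"]
        )
        # 75 of 150 degrees happens at the symmetric midpoint of the turn
        assert abs(mid_frac - 0.5) < 0.1


# ---------------------------------------------------------------------------
# psychometrics and response times
# ---------------------------------------------------------------------------


def _simulated_trials(rng, n, slope, bias=0.0, lapse=0.0, levels=(-0.8, -0.6, -0.4, 0, 0.4, 0.6, 0.8)):
    trials = []
    for i in range(n):
        delta = float(rng.choice(levels))
        p = lapse + (1 - 2 * lapse) / (1 + math.exp(-slope * (delta - bias)))
        choice = "right" if rng.random() < p else "left"
        instructed = "none" if delta == 0 else ("right" if delta > 0 else "left")
        outcome = "correct" if (delta != 0 and choice == instructed) else "incorrect"
        rt = max(0.15, 0.45 - 0.25 * abs(delta) + rng.normal(0, 0.03))
        trials.append(
            TrialRecord(
                index=i, delta_freq=delta, instructed_side=instructed,
                choice=choice, outcome=outcome,
                events={"stim_onset": 10.0 * i, "turn_start": 10.0 * i + rt},
                rewarded=outcome == "correct",
            )
        )
    return trials


def test_psychometric_parameter_recovery(rng):
    # slope and lapse trade off at stimulus levels this shallow, so the
    # clean recovery check pins the lapse at its true value of zero
    slope = 3.0
    trials = _simulated_trials(rng, 2000, slope=slope, lapse=0.0)
    s, b, _, model = fit_psychometric(trials, fit_lapse=False)
    assert abs(s - slope) / slope < 0.15
    assert abs(b) < 0.1
    assert abs(model.predict_proba(np.array([0.0]))[0] - 0.5) < 0.06
    # with a free lapse the curve is still calibrated even if the slope
    # drifts: check predicted probabilities at the outer levels
    trials2 = _simulated_trials(rng, 2000, slope=slope, lapse=0.05)
    _, _, _, model2 = fit_psychometric(trials2, fit_lapse=True)
    p_hi = model2.predict_proba(np.array([0.8]))[0]
    true_hi = 0.05 + 0.9 / (1 + math.exp(-slope * 0.8))
    assert abs(p_hi - true_hi) < 0.05


def test_psychometric_symmetric_choices_zero_bias(rng):
    trials = _simulated_trials(rng, 3000, slope=2.0, bias=0.0)
    _, bias, _, _ = fit_psychometric(trials)
    assert abs(bias) < 0.08


def test_psychometric_degenerate_choices_raise():
    trials = []
    for i in range(40):
        trials.append(
            TrialRecord(index=i, delta_freq=0.4 if i % 2 else -0.4,
                        instructed_side="right" if i % 2 else "left",
                        choice="right", outcome="correct" if i % 2 else "incorrect",
                        events={}, rewarded=bool(i % 2))
        )
    with pytest.raises(ValueError):
        fit_psychometric(trials)


def test_response_time_perfectly_linear_gives_unit_correlation(rng):
    trials = []
    for i, delta in enumerate([-0.8, -0.4, 0.0, 0.4, 0.8] * 20):
        rt = 0.5 - 0.3 * abs(delta)
        trials.append(
            TrialRecord(index=i, delta_freq=delta, instructed_side="none",
                        choice="right", outcome="correct",
                        events={"stim_onset": 5.0 * i, "turn_start": 5.0 * i + rt},
                        rewarded=True)
        )
    res = response_time_stats(trials, n_perm=200, seed=0)
    assert abs(res["r"]) > 0.9999
    assert res["p"] <= 1 / 100


def test_response_time_permutation_p_oracle(rng):
    trials = _simulated_trials(rng, 60, slope=2.0)
    n_perm, seed = 300, 42
    res = response_time_stats(trials, n_perm=n_perm, seed=seed)
    # independent recomputation of the add-one permutation estimate
    delta = np.array([abs(t.delta_freq) for t in trials])
    rt = np.array([t.response_time for t in trials])
    r_obs = np.corrcoef(delta, rt)[0, 1]
    gen = np.random.default_rng(seed)
    count = sum(
        abs(np.corrcoef(delta, gen.permutation(rt))[0, 1]) >= abs(r_obs)
        for _ in range(n_perm)
    )
    assert res["p"] == (1 + count) / (1 + n_perm)
    assert np.isclose(res["r"], r_obs)


def test_response_time_type_i_error_calibrated(rng):
    rejections = 0
    n_rep = 100
    for k in range(n_rep):
        trials = []
        for i, delta in enumerate([-0.8, -0.4, 0.0, 0.4, 0.8] * 12):
            rt = 0.4 + rng.normal(0, 0.05)  # no difficulty dependence
            trials.append(
                TrialRecord(index=i, delta_freq=delta, instructed_side="none",
                            choice="left", outcome="incorrect",
                            events={"stim_onset": 5.0 * i, "turn_start": 5.0 * i + rt},
                            rewarded=False)
            )
        if response_time_stats(trials, n_perm=200, seed=k)["p"] <= 0.05:
            rejections += 1
    assert rejections <= 6  # >=94% non-rejections at alpha=0.05


def test_prob_correct_by_rt_hand_tally():
    trials = []
    spec = [
        # (delta, rt, correct) -> bins of width 0.075
        (0.4, 0.10, True), (0.4, 0.11, False), (0.4, 0.12, True),
        (0.4, 0.13, True), (0.4, 0.14, False),
        (0.4, 0.31, True), (0.4, 0.32, True), (0.4, 0.33, True),
        (0.4, 0.34, True), (0.4, 0.35, False),
        (0.0, 0.10, True), (0.0, 0.11, False), (0.0, 0.12, True),
        (0.0, 0.13, False), (0.0, 0.14, True),
        (0.8, 0.10, True), (0.8, 0.11, True),
        (0.8, 0.40, False), (0.8, 0.41, True), (0.8, 0.42, True),
    ]
    for i, (delta, rt, correct) in enumerate(spec):
        trials.append(
            TrialRecord(index=i, delta_freq=delta, instructed_side="right",
                        choice="right", outcome="correct" if correct else "incorrect",
                        events={"stim_onset": 3.0 * i, "turn_start": 3.0 * i + rt},
                        rewarded=correct)
        )
    table = prob_correct_by_rt(trials, bin_width=0.075, min_count=5)
    by_key = {(row.difficulty, round(row.rt_bin, 3)): row for row in table.itertuples()}
    # delta 0.4, first bin [0.075, 0.15): 5 trials, 3 correct
    assert by_key[(0.4, 0.075)].n == 5
    assert np.isclose(by_key[(0.4, 0.075)].p_correct, 3 / 5)
    # delta 0.4, bin [0.3, 0.375): 5 trials, 4 correct
    assert np.isclose(by_key[(0.4, 0.3)].p_correct, 4 / 5)
    # delta 0.8 bins have fewer than 5 trials -> masked
    assert np.isnan(by_key[(0.8, 0.075)].p_correct)


def test_arena_corner_geometry():
    c = arena_corners(35.0)
    assert np.allclose(c["wait"], [0, 0])
    assert np.allclose(np.linalg.norm(c["left"] - c["right"]), 35.0)
    assert np.allclose(np.linalg.norm(c["left"] - c["wait"]), 35.0)
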