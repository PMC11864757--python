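"""Kinematic/spatio-temporal variables, task-event detection, behavior summaries.

The tracking table yields two families of per-frame variables:

* kinematic — measured from the body of the animal: body speed, head speed,
  angular velocity (from the tail-base → head body axis), acceleration;
* spatio-temporal — measured in relation to the arena: distance to the
  waiting corner, distance to each reward port, distance to the current goal
  (waiting corner during Return, chosen port during Go), radial velocity away
  from the waiting corner, cumulative turn angle within the trial, and the
  elapsed fraction of the trial.

Event detection recovers the per-trial alignment events from kinematics
alone (plus the hardware stimulus-onset and lick-port head-entry sensor):
return start (onset of sustained movement toward the waiting corner), wait
arrival (corner distance below threshold), turn start (angular velocity
threshold crossing), turn mid/end (cumulative 75 deg / 150 deg of the turn)
and port entry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter1d

from .session_io import (
    AnalysisConfig,
    LickEvents,
    SessionBundle,
    TrackingTable,
    TrialRecord,
)

KINEMATIC_VARS = ("body_speed", "head_speed", "angular_velocity", "acceleration")
SPATIOTEMPORAL_VARS = ("dist_goal", "dist_wait", "vel_from_wait", "elapsed_frac")


def arena_corners(side: float) -> dict[str, np.ndarray]:
    """Corner coordinates of the equilateral triangular arena (cm).

    Origin at the waiting corner, x toward the right reward corner.
    """
    return {
        "wait": np.array([0.0, 0.0]),
        "right": np.array([side, 0.0]),
        "left": np.array([side / 2.0, side * math.sqrt(3.0) / 2.0]),
    }


@dataclass
class KinematicsTable:
    """Per-frame kinematic and spatio-temporal variables on the tracking grid."""

    frame: pd.DataFrame  # one row per tracking frame
    frame_interval: float

    @property
    def time(self) -> np.ndarray:
        return self.frame["time"].to_numpy()

    def __getitem__(self, key: str) -> np.ndarray:
        return self.frame[key].to_numpy()

    def interp(self, var: str, at: np.ndarray) -> np.ndarray:
        return np.interp(at, self.time, self[var])


def _xy_speed(xy: np.ndarray, dt: float) -> np.ndarray:
    vel = np.gradient(xy, dt, axis=0)
    return np.hypot(vel[:, 0], vel[:, 1])


def compute_kinematics(
    tracking: TrackingTable,
    trials: list[TrialRecord] | None = None,
    *,
    arena_side: float = 35.0,
    smooth_sigma_frames: float = 2.0,
) -> KinematicsTable:
    """Derive all per-frame variables from a tracking table.

    Derivatives use centered differences on Gaussian-smoothed positions
    (sigma in frames); a raw (unsmoothed) heading/angular-velocity pair is
    kept alongside for event detection, where kernel leakage would displace
    threshold crossings.
    """
    if tracking.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    t = tracking.time
    dt = tracking.frame_interval
    corners = arena_corners(arena_side)

    def smooth(xy: np.ndarray) -> np.ndarray:
        if smooth_sigma_frames <= 0:
            return xy
        return gaussian_filter1d(xy, smooth_sigma_frames, axis=0, mode="nearest")

    body_s = smooth(tracking.xy("body_center"))
    head_s = smooth(tracking.xy("head"))
    tail_s = smooth(tracking.xy("tail_base"))

    body_speed = _xy_speed(body_s, dt)
    head_speed = _xy_speed(head_s, dt)
    acceleration = np.gradient(body_speed, dt)

    axis = head_s - tail_s
    heading = np.degrees(np.unwrap(np.arctan2(axis[:, 1], axis[:, 0])))
    angular_velocity = np.gradient(heading, dt)

    axis_raw = tracking.xy("head") - tracking.xy("tail_base")
    heading_raw = np.degrees(np.unwrap(np.arctan2(axis_raw[:, 1], axis_raw[:, 0])))
    angvel_raw = np.gradient(heading_raw, dt)

    body_raw = tracking.xy("body_center")
    dist_wait = np.hypot(*(body_raw - corners["wait"]).T)
    dist_left = np.hypot(*(body_raw - corners["left"]).T)
    dist_right = np.hypot(*(body_raw - corners["right"]).T)
    dist_wait_s = np.hypot(*(body_s - corners["wait"]).T)
    vel_from_wait = np.gradient(dist_wait_s, dt)
    corner_vel_raw = np.gradient(dist_wait, dt)

    dist_goal = dist_wait.copy()
    elapsed_frac = np.zeros_like(t)
    cum_turn = np.zeros_like(t)
    if trials:
        for trial in trials:
            ev = trial.events
            if "return_start" in ev and "wait_arrival" in ev:
                m = (t >= ev["return_start"]) & (t < ev["wait_arrival"])
                dist_goal[m] = dist_wait[m]
            if "turn_start" in ev and "port_entry" in ev:
                m = (t >= ev["turn_start"]) & (t <= ev["port_entry"])
                target = dist_left if trial.choice == "left" else dist_right
                dist_goal[m] = target[m]
                i0 = int(np.searchsorted(t, ev["turn_start"]))
                cum_turn[m] = heading[m] - heading[min(i0, len(t) - 1)]
            if "return_start" in ev and "port_entry" in ev:
                span = ev["port_entry"] - ev["return_start"]
                if span > 0:
                    m = (t >= ev["return_start"]) & (t <= ev["port_entry"])
                    elapsed_frac[m] = (t[m] - ev["return_start"]) / span

    frame = pd.DataFrame(
        {
            "time": t,
            "body_speed": body_speed,
            "head_speed": head_speed,
            "angular_velocity": angular_velocity,
            "acceleration": acceleration,
            "heading": heading,
            "heading_raw": heading_raw,
            "angvel_raw": angvel_raw,
            "dist_wait": dist_wait,
            "dist_left": dist_left,
            "dist_right": dist_right,
            "dist_goal": dist_goal,
            "vel_from_wait": vel_from_wait,
            "corner_vel_raw": corner_vel_raw,
            "elapsed_frac": elapsed_frac,
            "cum_turn": cum_turn,
        }
    )
    return KinematicsTable(frame=frame, frame_interval=dt)


# ---------------------------------------------------------------------------
# event detection
# ---------------------------------------------------------------------------


def _first_sustained(mask: np.ndarray, start: int, stop: int, k: int) -> int | None:
    """First index in [start, stop) where ``mask`` holds for k consecutive frames."""
    run = 0
    for i in range(start, min(stop, len(mask))):
        run = run + 1 if mask[i] else 0
        if run >= k:
            return i - k + 1
    return None


def detect_events(
    kin: KinematicsTable,
    trials: list[TrialRecord],
    licks: dict[str, LickEvents],
    cfg: AnalysisConfig | None = None,
) -> tuple[dict[int, dict[str, float]], list[int]]:
    """Recover per-trial alignment events from kinematics and sensor times.

    Only hardware observables are read from the trial table: the stimulus
    onset (a digital event in the recording) and the ordering of trials.
    Port entries come from the lickometer head-entry sensor.  Returns
    ``(events_by_trial, flagged_trial_indices)``; flagged trials are those
    with missing or unordered detections.
    """
    cfg = cfg or AnalysisConfig()
    t = kin.time
    dt = kin.frame_interval
    k = cfg.persistence_frames
    corner_vel = kin["corner_vel_raw"]
    angvel = kin["angvel_raw"]
    heading = kin["heading_raw"]
    dist_wait = kin["dist_wait"]

    entries = np.sort(
        np.concatenate(
            [licks[p].head_entry_times for p in licks] or [np.empty(0)]
        )
    )

    out: dict[int, dict[str, float]] = {}
    flagged: list[int] = []
    prev_entry = float(t[0])
    for trial in trials:
        ev: dict[str, float] = {}
        ok = True
        w0 = int(np.searchsorted(t, prev_entry))
        # return start: onset of sustained approach toward the waiting corner
        approach = corner_vel < -cfg.corner_vel_threshold
        f = _first_sustained(approach, w0, len(t), k)
        if f is None:
            ok = False
        else:
            while f > w0 and corner_vel[f - 1] < -0.02:
                f -= 1
            ev["return_start"] = float(t[f])
            # wait arrival: corner distance first below threshold
            near = np.nonzero(dist_wait[f:] < cfg.arrival_threshold_cm)[0]
            if len(near) == 0:
                ok = False
            else:
                ia = f + int(near[0])
                ev["wait_arrival"] = float(t[ia])

        if "stim_onset" in trial.events:
            ev["stim_onset"] = float(trial.events["stim_onset"])
            search_t = ev["stim_onset"]
        elif ok:
            search_t = ev["wait_arrival"] + cfg.fa_turn_search_delay
        else:
            search_t = None

        if ok and search_t is not None:
            s0 = int(np.searchsorted(t, search_t))
            turning = np.abs(angvel) > cfg.angvel_threshold
            f = _first_sustained(turning, s0, len(t), k)
            if f is None:
                ok = False
            else:
                while f > s0 and np.abs(angvel[f - 1]) > cfg.angvel_threshold:
                    f -= 1
                ev["turn_start"] = float(t[f])
                cum = np.abs(heading[f:] - heading[f])
                mid = np.nonzero(cum >= 74.999)[0]
                end = np.nonzero(cum >= 0.995 * 150.0)[0]
                if len(mid) == 0 or len(end) == 0:
                    ok = False
                else:
                    ev["turn_mid"] = float(t[f + int(mid[0])])
                    ev["turn_end"] = float(t[f + int(end[0])])

        if ok:
            nxt = entries[np.searchsorted(entries, ev["turn_end"])
                          : np.searchsorted(entries, ev["turn_end"]) + 1]
            if len(nxt) == 0:
                ok = False
            else:
                ev["port_entry"] = float(nxt[0])

        if ok:
            ordered = [ev[n] for n in (
                "return_start", "wait_arrival", "turn_start",
                "turn_mid", "turn_end", "port_entry") if n in ev]
            if any(b < a for a, b in zip(ordered, ordered[1:])):
                ok = False
        if ok:
            out[trial.index] = ev
            prev_entry = ev["port_entry"]
        else:
            flagged.append(trial.index)
            hw = trial.events.get("port_entry")
            if hw is not None:
                prev_entry = float(hw)
    return out, flagged


# ---------------------------------------------------------------------------
# behavioral summaries
# ---------------------------------------------------------------------------


class PsychometricModel:
    """Lapse-corrected logistic psychometric curve, fit by maximum likelihood.

    P(choice = right | delta) = lapse + (1 - 2*lapse) / (1 + exp(-slope*(delta - bias)))

    Parameters
    ----------
    fit_lapse : bool
        If False the lapse rate is pinned at 0.

    Attributes (after ``fit``)
    --------------------------
    slope_, bias_, lapse_ : float
    levels_ : ndarray of distinct delta values
    proportions_ : empirical P(right) per level
    """

    def __init__(self, fit_lapse: bool = True):
        self.fit_lapse = fit_lapse

    def get_params(self, deep: bool = True) -> dict:
        return {"fit_lapse": self.fit_lapse}

    def set_params(self, **params) -> "PsychometricModel":
        for key, val in params.items():
            setattr(self, key, val)
        return self

    @staticmethod
    def _prob(delta: np.ndarray, slope: float, bias: float, lapse: float) -> np.ndarray:
        z = np.clip(slope * (delta - bias), -500, 500)
        return lapse + (1.0 - 2.0 * lapse) / (1.0 + np.exp(-z))

    def fit(self, delta: np.ndarray, choice_right: np.ndarray) -> "PsychometricModel":
        delta = np.asarray(delta, float)
        y = np.asarray(choice_right, float)
        levels = np.unique(delta)
        if len(levels) < 2:
            raise ValueError("need at least 2 distinct stimulus levels")
        if y.min() == y.max():
            raise ValueError("degenerate choices: all responses identical")

        def nll(params: np.ndarray) -> float:
            slope, bias, lapse = params
            p = np.clip(self._prob(delta, slope, bias, lapse), 1e-9, 1 - 1e-9)
            return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

        lapse_hi = 0.25 if self.fit_lapse else 1e-9
        best = None
        for s0 in (1.0, 4.0, 10.0):
            res = optimize.minimize(
                nll,
                x0=np.array([s0, 0.0, 0.02 if self.fit_lapse else 0.0]),
                bounds=[(1e-3, 200.0), (-1.0, 1.0), (0.0, lapse_hi)],
                method="L-BFGS-B",
            )
            if best is None or res.fun < best.fun:
                best = res
        self.slope_, self.bias_, self.lapse_ = map(float, best.x)
        self.levels_ = levels
        self.proportions_ = np.array([y[delta == lv].mean() for lv in levels])
        return self

    def predict_proba(self, delta: np.ndarray) -> np.ndarray:
        return self._prob(np.asarray(delta, float), self.slope_, self.bias_, self.lapse_)


def fit_psychometric(trials: list[TrialRecord], fit_lapse: bool = True):
    """Fit P(choice = right) vs delta-frequency; returns (slope, bias, lapse, model)."""
    stim = [tr for tr in trials if tr.outcome != "false_alarm"]
    levels = {}
    for tr in stim:
        levels.setdefault(tr.delta_freq, 0)
        levels[tr.delta_freq] += 1
    usable = [lv for lv, n in levels.items() if n >= 5]
    if len(usable) < 2:
        raise ValueError("need >=2 stimulus levels with >=5 trials each")
    sel = [tr for tr in stim if tr.delta_freq in usable]
    delta = np.array([tr.delta_freq for tr in sel])
    right = np.array([tr.choice == "right" for tr in sel], float)
    model = PsychometricModel(fit_lapse=fit_lapse).fit(delta, right)
    return model.slope_, model.bias_, model.lapse_, model


def response_time_stats(
    trials: list[TrialRecord],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Mean response time per stimulus plus a permutation-tested linear fit.

    Response time = turn start - stimulus onset.  The correlation is between
    per-trial |delta| and RT; its p-value is the add-one permutation estimate
    (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm) under RT shuffling.
    """
    rows = [
        (tr.delta_freq, tr.response_time)
        for tr in trials
        if tr.response_time is not None
    ]
    if not rows:
        raise ValueError("no stimulus trials with a response time")
    delta = np.array([r[0] for r in rows])
    rt = np.array([r[1] for r in rows])
    levels = np.unique(delta)
    mean_rt = {float(lv): float(rt[delta == lv].mean()) for lv in levels}

    x = np.abs(delta)
    if np.std(x) == 0 or np.std(rt) == 0:
        r_obs = 0.0
    else:
        r_obs = float(np.corrcoef(x, rt)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rp = rng.permutation(rt)
        r_null = np.corrcoef(x, rp)[0, 1] if np.std(rp) > 0 else 0.0
        if abs(r_null) >= abs(r_obs):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {"mean_rt": mean_rt, "r": r_obs, "p": p, "n": len(rt)}


def prob_correct_by_rt(
    trials: list[TrialRecord],
    bin_width: float = 0.075,
    min_count: int = 5,
) -> pd.DataFrame:
    """P(correct) per response-time bin, grouped by stimulus difficulty |delta|.

    Bins with fewer than ``min_count`` trials are masked (NaN probability).
    """
    rows = []
    for tr in trials:
        rtime = tr.response_time
        if rtime is None:
            continue
        rows.append((abs(tr.delta_freq), rtime, tr.outcome == "correct"))
    if not rows:
        return pd.DataFrame(columns=["difficulty", "rt_bin", "p_correct", "n"])
    df = pd.DataFrame(rows, columns=["difficulty", "rt", "correct"])
    df["rt_bin"] = np.floor(df["rt"] / bin_width) * bin_width
    out = (
        df.groupby(["difficulty", "rt_bin"])
        .agg(p_correct=("correct", "mean"), n=("correct", "size"))
        .reset_index()
    )
    out.loc[out["n"] < min_count, "p_correct"] = np.nan
    return out


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank statistic and two-sided p (zeroes dropped)."""
    res = stats.wilcoxon(a, b, zero_method="wilcox", method="auto")
    return float(res.statistic), float(res.pvalue)
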