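"""Synthetic 2AFC sessions with known ground-truth tuning.

The generator emulates the study conditions: a freely moving mouse in a
triangular arena shuttling between a waiting corner and two reward-port
corners.  Each trial is a Return trajectory to the waiting corner, a wait of
0.8-1.3 s, a 0.5 s frequency-modulated sweep (delta-frequency set
{0, +/-0.4, +/-0.6, +/-0.8} octaves), a 150-degree turn toward the chosen
port, a Go trajectory, and an evaluation period with a lick bout.  Choices
follow a lapse-corrected logistic psychometric in delta-frequency; response
times shrink with stimulus difficulty; false-alarm trials replicate the full
motor sequence without a stimulus.  Paw markers carry a gait oscillation
(default 4.5 Hz) during displacement; licks are emitted at the configured
lick rhythm (default 7 Hz).

Spikes are inhomogeneous-Poisson with a log-link rate:

    rate(t) = exp(b0 + sum_ctx coef . z(variable(t)) + reward kernel(t)
                  + kappa_gait * cos(phase_gait - mu) + kappa_lick * cos(phase_lick - mu))

with per-context (Return vs Go) kinematic and spatio-temporal coefficients,
reward-positive/negative box responses after port entry, and von-Mises-style
phase coupling to the gait and lick oscillators.  Everything is deterministic
given (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .kinematics_events import arena_corners, compute_kinematics
from .session_io import (
    LickEvents,
    SessionBundle,
    SpikeTrain,
    TrackingTable,
    TrialRecord,
)

# fixed z-scoring constants (center, scale) used inside the rate model so
# that coefficient magnitudes are comparable across variables
VARIABLE_NORMS = {
    "body_speed": (15.0, 12.0),
    "head_speed": (15.0, 12.0),
    "angular_velocity": (0.0, 150.0),
    "acceleration": (0.0, 40.0),
    "dist_goal": (15.0, 10.0),
    "dist_wait": (15.0, 10.0),
    "vel_from_wait": (0.0, 15.0),
    "elapsed_frac": (0.5, 0.3),
}

KIN_VARS = ("body_speed", "head_speed", "angular_velocity", "acceleration")
ST_VARS = ("dist_goal", "dist_wait", "vel_from_wait", "elapsed_frac")

# tuning saturates beyond this many normalization scales from the center,
# mimicking saturating tuning curves and bounding the peak firing rate
Z_CLIP = 2.5


class GenerationError(RuntimeError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions emulated by the generator (times s, lengths cm, Hz)."""

    n_trials: int = 220  # sessions in the study were selected for >220 trials
    n_units: int = 30
    false_alarm_rate: float = 0.08
    # psychometric P(right) = lapse + (1-2*lapse)*logistic(slope*(delta-bias))
    psych_slope: float = 2.5
    psych_bias: float = 0.0
    lapse: float = 0.08
    # response time: intercept - slope*|delta| + N(0, sd), floored
    rt_intercept: float = 0.45
    rt_difficulty_slope: float = 0.25
    rt_noise_sd: float = 0.05
    rt_min: float = 0.15
    wait_range: tuple[float, float] = (0.8, 1.3)
    fa_wait_range: tuple[float, float] = (0.8, 1.1)
    stimulus_set: tuple[float, ...] = (-0.8, -0.6, -0.4, 0.0, 0.4, 0.6, 0.8)
    stim_duration: float = 0.5
    arena_side: float = 35.0
    frame_rate: float = 60.0
    return_duration: tuple[float, float] = (1.8, 0.15)  # mean, sd
    go_duration: tuple[float, float] = (1.3, 0.10)
    turn_duration: float = 0.4
    orient_duration: float = 0.35
    eval_duration: float = 2.5
    gait_freq: float = 4.5
    gait_amp_hind: float = 1.2
    gait_amp_fore: float = 0.8
    lick_freq: float = 7.0
    lick_bout_mean: float = 10.0  # mean licks per rewarded bout
    tracking_noise_sd: float = 0.0  # smooth positional noise, cm
    # unit population composition
    prop_reward_positive: float = 0.40
    prop_reward_negative: float = 0.20
    prop_context_switch: float = 0.30
    prop_phase_locked: float = 0.60
    baseline_log_rate: tuple[float, float] = (math.log(15.0), 0.35)
    kin_coef_sd: float = 0.15
    st_coef_sd: float = 0.15
    reward_amp: float = 0.8
    reward_amp_sd: float = 0.15
    reward_kernel_dur: float = 0.25
    gait_kappa: float = 0.8
    lick_kappa: float = 0.8
    max_rate: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "false_alarm_rate",
            "lapse",
            "prop_reward_positive",
            "prop_reward_negative",
            "prop_context_switch",
            "prop_phase_locked",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.prop_reward_positive + self.prop_reward_negative > 1.0:
            raise ValueError("reward-positive + reward-negative proportions exceed 1")
        for name in ("gait_freq", "lick_freq", "frame_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        deltas = sorted(self.stimulus_set)
        if any(abs(a + b) > 1e-12 for a, b in zip(deltas, reversed(deltas))):
            raise ValueError("stimulus set must be symmetric about 0")
        min_traverse = self.arena_side / 60.0  # would need > 60 cm/s mean speed
        if self.return_duration[0] < min_traverse or self.go_duration[0] < min_traverse:
            raise ValueError(
                "segment duration too short to traverse the arena at plausible speed"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class UnitGroundTruth:
    unit_id: str
    hemisphere: str
    b0: float
    kin_coefs: dict[str, np.ndarray]  # context -> coefficients over KIN_VARS
    st_coefs: dict[str, np.ndarray]  # context -> coefficients over ST_VARS
    reward_class: str  # {positive, negative, none}
    reward_amp: float
    context_switch: bool
    gait_kappa: float
    gait_phase: float
    lick_kappa: float
    lick_phase: float


@dataclass
class GroundTruth:
    units: list[UnitGroundTruth]
    config: GeneratorConfig

    def unit(self, unit_id: str) -> UnitGroundTruth:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    def to_json(self) -> str:
        payload = []
        for u in self.units:
            d = asdict(u)
            d["kin_coefs"] = {k: list(map(float, v)) for k, v in u.kin_coefs.items()}
            d["st_coefs"] = {k: list(map(float, v)) for k, v in u.st_coefs.items()}
            payload.append(d)
        return json.dumps(
            {"units": payload, "config": self.config.to_dict()},
            indent=2,
            sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _stratified_classes(
    n: int, proportions: dict[str, float], rng: np.random.Generator
) -> list[str]:
    """Assign class labels with counts matching proportions exactly (+-1)."""
    labels: list[str] = []
    remaining = n
    items = list(proportions.items())
    for name, p in items[:-1]:
        k = int(round(p * n))
        k = min(k, remaining)
        labels += [name] * k
        remaining -= k
    labels += [items[-1][0]] * remaining
    order = rng.permutation(n)
    return [labels[i] for i in order]


def make_ground_truth(cfg: GeneratorConfig, seed: int | None = None) -> GroundTruth:
    """Draw per-unit tuning parameters; deterministic given (config, seed)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    reward_classes = _stratified_classes(
        cfg.n_units,
        {
            "positive": cfg.prop_reward_positive,
            "negative": cfg.prop_reward_negative,
            "none": 1.0 - cfg.prop_reward_positive - cfg.prop_reward_negative,
        },
        rng,
    )
    switch_flags = _stratified_classes(
        cfg.n_units,
        {"switch": cfg.prop_context_switch, "shared": 1.0 - cfg.prop_context_switch},
        rng,
    )
    locked_flags = _stratified_classes(
        cfg.n_units,
        {"locked": cfg.prop_phase_locked, "free": 1.0 - cfg.prop_phase_locked},
        rng,
    )

    # log-rate budget keeping the worst-case peak under max_rate: with
    # z-variables saturating at |z| <= Z_CLIP, b0 + coef budget + kappa +
    # reward amplitude must stay below log(max_rate)
    coef_budget = 0.4
    kappa_cap = 1.0
    amp_cap = 1.0
    b0_hi = math.log(cfg.max_rate) - Z_CLIP * coef_budget - kappa_cap

    units = []
    for i in range(cfg.n_units):
        b0 = float(np.clip(rng.normal(*cfg.baseline_log_rate), math.log(5.0), b0_hi))
        kin_ret = rng.normal(0.0, cfg.kin_coef_sd, len(KIN_VARS))
        st_ret = rng.normal(0.0, cfg.st_coef_sd, len(ST_VARS))
        if switch_flags[i] == "switch":
            kin_go = -kin_ret + rng.normal(0.0, 0.02, len(KIN_VARS))
            st_go = -st_ret + rng.normal(0.0, 0.02, len(ST_VARS))
        else:
            kin_go = kin_ret + rng.normal(0.0, 0.02, len(KIN_VARS))
            st_go = st_ret + rng.normal(0.0, 0.02, len(ST_VARS))
        kin_coefs = {"Return": kin_ret, "Go": kin_go}
        st_coefs = {"Return": st_ret, "Go": st_go}
        for ctx in ("Return", "Go"):
            total = float(np.abs(kin_coefs[ctx]).sum() + np.abs(st_coefs[ctx]).sum())
            if total > coef_budget:
                kin_coefs[ctx] = kin_coefs[ctx] * (coef_budget / total)
                st_coefs[ctx] = st_coefs[ctx] * (coef_budget / total)
        locked = locked_flags[i] == "locked"
        units.append(
            UnitGroundTruth(
                unit_id=f"unit{i:03d}",
                hemisphere="right",
                b0=b0,
                kin_coefs=kin_coefs,
                st_coefs=st_coefs,
                reward_class=reward_classes[i],
                reward_amp=(
                    0.0
                    if reward_classes[i] == "none"
                    else float(
                        np.clip(
                            abs(rng.normal(cfg.reward_amp, cfg.reward_amp_sd)),
                            0.2,
                            amp_cap,
                        )
                    )
                ),
                context_switch=switch_flags[i] == "switch",
                gait_kappa=(
                    float(np.clip(abs(rng.normal(cfg.gait_kappa, 0.3)), 0.0, kappa_cap))
                    if locked
                    else 0.0
                ),
                gait_phase=float(rng.uniform(-np.pi, np.pi)),
                lick_kappa=(
                    float(np.clip(abs(rng.normal(cfg.lick_kappa, 0.3)), 0.0, kappa_cap))
                    if locked
                    else 0.0
                ),
                lick_phase=float(rng.uniform(-np.pi, np.pi)),
            )
        )
    return GroundTruth(units=units, config=cfg)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------


def _minjerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile: 0 -> 1 with zero end velocities."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _heading_unit(h_deg: np.ndarray) -> np.ndarray:
    rad = np.radians(h_deg)
    return np.column_stack([np.cos(rad), np.sin(rad)])


def generate_behavior(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[TrackingTable, list[TrialRecord], dict[str, LickEvents]]:
    """Simulate the behavioral session: tracking, trial/event table, licks.

    All event times fall exactly on the tracking frame grid.  Ground-truth
    ``wait_arrival`` is the definitional corner-distance threshold crossing
    (1.5 cm) of the noiseless trajectory; the remaining events are segment
    boundaries of the simulated motion plan.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fr = cfg.frame_rate
    dt = 1.0 / fr
    corners = arena_corners(cfg.arena_side)
    centroid = np.mean([corners[c] for c in corners], axis=0)

    def stop_point(corner: str, pull: float) -> np.ndarray:
        """Body-center halt position, pulled in from the corner toward the
        arena centroid so the head (2.5 cm ahead) stays within bounds."""
        c = corners[corner]
        inward = (centroid - c) / np.linalg.norm(centroid - c)
        return c + pull * inward

    stops = {
        "wait": stop_point("wait", 1.45),
        "left": stop_point("left", 1.4),
        "right": stop_point("right", 1.4),
    }

    def frames(duration: float) -> int:
        return max(2, int(round(duration * fr)))

    # --- draw trial scalars -------------------------------------------------
    plans = []
    for k in range(cfg.n_trials):
        is_fa = rng.random() < cfg.false_alarm_rate
        if is_fa:
            delta = 0.0
            instructed = "none"
            choice = "right" if rng.random() < 0.5 else "left"
            outcome = "false_alarm"
            rewarded = False
        else:
            delta = float(rng.choice(cfg.stimulus_set))
            instructed = "none" if delta == 0 else ("right" if delta > 0 else "left")
            z = cfg.psych_slope * (delta - cfg.psych_bias)
            p_right = cfg.lapse + (1 - 2 * cfg.lapse) / (1 + math.exp(-z))
            choice = "right" if rng.random() < p_right else "left"
            if delta == 0:
                rewarded = bool(rng.random() < 0.5)
                outcome = "correct" if rewarded else "incorrect"
            else:
                outcome = "correct" if choice == instructed else "incorrect"
                rewarded = outcome == "correct"
        ret_f = frames(max(1.0, rng.normal(*cfg.return_duration)))
        go_f = frames(max(0.8, rng.normal(*cfg.go_duration)))
        turn_f = frames(cfg.turn_duration)
        turn_f += turn_f % 2  # even so the 75-degree midpoint lands on a frame
        if is_fa:
            wait_f = frames(rng.uniform(*cfg.fa_wait_range))
            rt_f = 0
        else:
            wait_f = frames(rng.uniform(*cfg.wait_range))
            rt = max(
                cfg.rt_min,
                cfg.rt_intercept
                - cfg.rt_difficulty_slope * abs(delta)
                + rng.normal(0.0, cfg.rt_noise_sd),
            )
            rt_f = frames(rt)
        plans.append(
            dict(
                index=k,
                is_fa=is_fa,
                delta=delta,
                instructed=instructed,
                choice=choice,
                outcome=outcome,
                rewarded=rewarded,
                ret_f=ret_f,
                wait_f=wait_f,
                rt_f=rt_f,
                turn_f=turn_f,
                go_f=go_f,
            )
        )

    eval_f = frames(cfg.eval_duration)
    start_pad_f = frames(1.0)
    n_frames = start_pad_f + sum(
        p["ret_f"] + p["wait_f"] + p["rt_f"] + p["turn_f"] + p["go_f"] + eval_f
        for p in plans
    ) + frames(0.5)
    t = np.arange(n_frames) * dt

    def angle_of(vec: np.ndarray) -> float:
        return math.degrees(math.atan2(vec[1], vec[0]))

    body = np.zeros((n_frames, 2))
    heading = np.zeros(n_frames)
    prev_port = "right"
    body[:start_pad_f] = stops[prev_port]
    heading[:start_pad_f] = angle_of(stops[prev_port] - stops["wait"])

    trials: list[TrialRecord] = []
    lick_times = {"left": [], "right": []}
    head_entries = {"left": [], "right": []}
    cursor = start_pad_f
    for p in plans:
        origin = stops[prev_port]
        # Return: straight minimum-jerk path to the waiting corner
        f0 = cursor
        fr_end = f0 + p["ret_f"]
        tau = np.arange(p["ret_f"] + 1) / p["ret_f"]
        path = origin + _minjerk(tau)[:, None] * (stops["wait"] - origin)
        body[f0 : fr_end + 1] = path
        travel_dir = angle_of(stops["wait"] - origin)
        heading[f0 : fr_end + 1] = travel_dir

        go_dir = angle_of(stops[p["choice"]] - stops["wait"])
        sign = 1.0 if p["choice"] == "left" else -1.0
        pre_turn = go_dir - sign * 150.0

        # orient in the waiting corner during early wait
        orient_f = frames(cfg.orient_duration)
        fo_end = min(fr_end + orient_f, n_frames - 1)
        tau = np.arange(fo_end - fr_end + 1) / max(orient_f, 1)
        heading[fr_end : fo_end + 1] = travel_dir + _minjerk(tau) * (
            pre_turn - travel_dir
        )
        wait_end = fr_end + p["wait_f"]
        heading[fo_end : wait_end + 1] = pre_turn
        body[fr_end : wait_end + 1] = stops["wait"]

        turn_start_f = wait_end + p["rt_f"]
        body[wait_end : turn_start_f + 1] = stops["wait"]
        heading[wait_end : turn_start_f + 1] = pre_turn
        turn_end_f = turn_start_f + p["turn_f"]
        tau = np.arange(p["turn_f"] + 1) / p["turn_f"]
        heading[turn_start_f : turn_end_f + 1] = pre_turn + _minjerk(tau) * sign * 150.0
        body[turn_start_f : turn_end_f + 1] = stops["wait"]

        go_end_f = turn_end_f + p["go_f"]
        tau = np.arange(p["go_f"] + 1) / p["go_f"]
        target = stops[p["choice"]]
        body[turn_end_f : go_end_f + 1] = (
            stops["wait"] + _minjerk(tau)[:, None] * (target - stops["wait"])
        )
        heading[turn_end_f : go_end_f + 1] = go_dir

        eval_end_f = go_end_f + eval_f
        body[go_end_f : eval_end_f + 1] = target
        heading[go_end_f : eval_end_f + 1] = go_dir

        # ground-truth events
        seg = body[f0 : fr_end + 1]
        dist = np.hypot(*(seg - corners["wait"]).T)
        arrival_idx = f0 + int(np.argmax(dist < 1.5))
        events = {
            "return_start": t[f0],
            "wait_arrival": t[arrival_idx],
            "turn_start": t[turn_start_f],
            "turn_mid": t[turn_start_f + p["turn_f"] // 2],
            "turn_end": t[turn_end_f],
            "port_entry": t[go_end_f],
        }
        if not p["is_fa"]:
            events["stim_onset"] = t[wait_end]
        trials.append(
            TrialRecord(
                index=p["index"],
                delta_freq=p["delta"],
                instructed_side=p["instructed"],
                choice=p["choice"],
                outcome=p["outcome"],
                events={k: float(v) for k, v in events.items()},
                rewarded=p["rewarded"],
            )
        )

        head_entries[p["choice"]].append(t[go_end_f])
        # lick bout locked to the global lick oscillator (phase 0 at licks)
        if p["rewarded"]:
            n_licks = 3 + int(rng.geometric(1.0 / max(cfg.lick_bout_mean - 2.0, 1.0)))
        else:
            n_licks = int(rng.integers(3, 5))
        bout_start = t[go_end_f] + 0.15
        first = math.ceil(bout_start * cfg.lick_freq) / cfg.lick_freq
        bout_end_limit = t[go_end_f] + cfg.eval_duration - 0.1
        lt = first + np.arange(n_licks) / cfg.lick_freq
        lt = lt[lt < bout_end_limit]
        lick_times[p["choice"]].extend(lt.tolist())

        cursor = eval_end_f
        prev_port = p["choice"]

    body[cursor:] = body[cursor]
    heading[cursor:] = heading[cursor]

    # --- bodyparts ----------------------------------------------------------
    u = _heading_unit(heading)
    nvec = np.column_stack([-u[:, 1], u[:, 0]])  # left normal
    speed = np.hypot(*np.gradient(body, dt, axis=0).T)
    gate = np.clip(speed / 8.0, 0.0, 1.0)
    gait_phase = 2 * np.pi * cfg.gait_freq * t

    coords = {
        "body_center": body,
        "head": body + 2.5 * u,
        "tail_base": body - 2.5 * u,
    }
    paw_spec = {
        "paw_FL": (1.0, 1.2, cfg.gait_amp_fore, 0.0),
        "paw_FR": (1.0, -1.2, cfg.gait_amp_fore, np.pi),
        "paw_HL": (-1.0, 1.2, cfg.gait_amp_hind, np.pi),
        "paw_HR": (-1.0, -1.2, cfg.gait_amp_hind, 0.0),
    }
    for name, (long0, lat, amp, ph) in paw_spec.items():
        osc = long0 + amp * gate * np.sin(gait_phase + ph)
        coords[name] = body + osc[:, None] * u + lat * nvec

    if cfg.tracking_noise_sd > 0:
        from scipy.ndimage import gaussian_filter1d

        for name in coords:
            noise = rng.normal(0.0, cfg.tracking_noise_sd, (n_frames, 2))
            coords[name] = coords[name] + gaussian_filter1d(noise, 3.0, axis=0)

    tracking = TrackingTable(time=t, coords=coords)
    licks = {
        port: LickEvents(
            port=port,
            head_entry_times=np.asarray(head_entries[port], float),
            lick_times=np.asarray(sorted(lick_times[port]), float),
        )
        for port in ("left", "right")
    }
    return tracking, trials, licks


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------


def _context_masks(t: np.ndarray, trials: list[TrialRecord]) -> dict[str, np.ndarray]:
    masks = {
        "Return": np.zeros(len(t), bool),
        "Go": np.zeros(len(t), bool),
        "Lick": np.zeros(len(t), bool),
    }
    for tr in trials:
        ev = tr.events
        masks["Return"] |= (t >= ev["return_start"]) & (t < ev["wait_arrival"])
        masks["Go"] |= (t >= ev["turn_start"]) & (t < ev["port_entry"])
        masks["Lick"] |= (t >= ev["port_entry"] + 0.1) & (
            t < ev["port_entry"] + 2.4
        )
    return masks


def unit_log_rate(
    unit: UnitGroundTruth,
    t: np.ndarray,
    variables: dict[str, np.ndarray],
    masks: dict[str, np.ndarray],
    trials: list[TrialRecord],
    cfg: GeneratorConfig,
) -> np.ndarray:
    """Ground-truth log firing rate of one unit on the frame grid."""
    z = {
        name: np.clip(
            (variables[name] - VARIABLE_NORMS[name][0]) / VARIABLE_NORMS[name][1],
            -Z_CLIP,
            Z_CLIP,
        )
        for name in (*KIN_VARS, *ST_VARS)
    }
    log_rate = np.full(len(t), unit.b0)
    for ctx in ("Return", "Go"):
        contrib = np.zeros(len(t))
        for j, name in enumerate(KIN_VARS):
            contrib += unit.kin_coefs[ctx][j] * z[name]
        for j, name in enumerate(ST_VARS):
            contrib += unit.st_coefs[ctx][j] * z[name]
        log_rate += np.where(masks[ctx], contrib, 0.0)

    if unit.reward_class != "none":
        amp = unit.reward_amp if unit.reward_class == "positive" else -unit.reward_amp
        for tr in trials:
            if not tr.rewarded:
                continue
            pe = tr.events["port_entry"]
            m = (t >= pe) & (t < pe + cfg.reward_kernel_dur)
            log_rate[m] += amp

    if unit.gait_kappa > 0:
        gait_phase = 2 * np.pi * cfg.gait_freq * t
        move = masks["Return"] | masks["Go"]
        log_rate += np.where(
            move, unit.gait_kappa * np.cos(gait_phase - unit.gait_phase), 0.0
        )
    if unit.lick_kappa > 0:
        lick_phase = 2 * np.pi * cfg.lick_freq * t
        log_rate += np.where(
            masks["Lick"], unit.lick_kappa * np.cos(lick_phase - unit.lick_phase), 0.0
        )
    return log_rate


def generate_spikes(
    tracking: TrackingTable,
    trials: list[TrialRecord],
    gt: GroundTruth,
    seed: int | None = None,
    oversample: int = 10,
) -> list[SpikeTrain]:
    """Inhomogeneous-Poisson spike trains for every ground-truth unit."""
    cfg = gt.config
    kin = compute_kinematics(
        tracking, trials, arena_side=cfg.arena_side, smooth_sigma_frames=2.0
    )
    t = kin.time
    variables = {name: kin[name] for name in (*KIN_VARS, *ST_VARS)}
    masks = _context_masks(t, trials)

    dt_fine = 1.0 / (cfg.frame_rate * oversample)
    t_fine = np.arange(t[0], t[-1], dt_fine)

    ss = np.random.SeedSequence(cfg.seed + 1 if seed is None else seed)
    child_seeds = ss.spawn(len(gt.units))
    spikes = []
    for unit, child in zip(gt.units, child_seeds):
        log_rate = unit_log_rate(unit, t, variables, masks, trials, cfg)
        rate = np.exp(log_rate)
        if rate.max() > cfg.max_rate:
            raise GenerationError(
                f"{unit.unit_id}: peak rate {rate.max():.1f} Hz exceeds the "
                f"{cfg.max_rate:.0f} Hz bound"
            )
        rng = np.random.default_rng(child)
        rate_fine = np.interp(t_fine, t, rate)
        counts = rng.poisson(rate_fine * dt_fine)
        idx = np.repeat(np.arange(len(t_fine)), counts)
        times = t_fine[idx] + rng.uniform(0.0, dt_fine, len(idx))
        spikes.append(
            SpikeTrain(unit.unit_id, np.sort(times), hemisphere=unit.hemisphere)
        )
    return spikes


def generate_session(
    cfg: GeneratorConfig, seed: int | None = None
) -> tuple[SessionBundle, GroundTruth]:
    """Full synthetic session: behavior plus spikes plus ground truth."""
    base = cfg.seed if seed is None else seed
    gt = make_ground_truth(cfg, seed=base)
    tracking, trials, licks = generate_behavior(cfg, seed=base + 1)
    spikes = generate_spikes(tracking, trials, gt, seed=base + 2)
    bundle = SessionBundle(
        tracking=tracking,
        spikes=spikes,
        trials=trials,
        licks=licks,
        meta={
            "animal_id": "synthetic",
            "arena_side_cm": cfg.arena_side,
            "frame_rate_hz": cfg.frame_rate,
            "generator_seed": base,
        },
    )
    return bundle, gt
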