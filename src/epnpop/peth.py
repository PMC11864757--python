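"""Peri-event time histograms: kernel rate estimates, trial time-rescaling,
the pseudo-simultaneous condition tensor, z-scoring and epoch comparisons.

Single-trial firing rates are Gaussian-kernel estimates (sigma = 25 ms by
default, kernel integrating to one so values are in Hz).  Because the animal
moves freely, trials differ in segment durations; each trial is rescaled by
a piecewise-linear time map sending its event boundaries onto the session's
average segment durations, and the rescaled rates are averaged per condition.

The pseudo-simultaneous population tensor has axes
``units x side x difficulty x outcome x time`` (N x S x D x C x T): side is
the direction of the turn (choice), difficulty the absolute stimulus
delta-frequency ({0, 0.4, 0.6, 0.8} octaves), outcome correct vs incorrect.
Units lacking the minimum number of trials in any condition cell are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .session_io import AnalysisConfig, SessionBundle, SpikeTrain, TrialRecord

SIDES = ("left", "right")
DIFFICULTIES = (0.0, 0.4, 0.6, 0.8)
OUTCOMES = ("correct", "incorrect")

#: event landmarks bounding the canonical trial segments of the condition tensor
TENSOR_SEGMENTS = ("pre_turn", "turn", "go", "evaluation")


@dataclass
class PETHTensor:
    """Condition-averaged pseudo-population firing, units x S x D x C x T."""

    data: np.ndarray  # (N, 2, 4, 2, T)
    time: np.ndarray  # canonical time grid, s, 0 at turn start
    landmarks: dict[str, int]  # landmark name -> index into the time grid
    counts: np.ndarray  # (N, 2, 4, 2) trials per cell
    unit_ids: list[str]
    units_excluded: list[str] = field(default_factory=list)
    units_flagged: list[str] = field(default_factory=list)  # zero-variance units
    units_axis_meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[-1]

    def copy_with(self, data: np.ndarray, **kw) -> "PETHTensor":
        out = PETHTensor(
            data=data,
            time=self.time,
            landmarks=dict(self.landmarks),
            counts=self.counts,
            unit_ids=list(self.unit_ids),
            units_excluded=list(self.units_excluded),
            units_flagged=list(self.units_flagged),
        )
        for key, val in kw.items():
            setattr(out, key, val)
        return out


def rate_estimate(
    spike_times: np.ndarray,
    grid: np.ndarray,
    sigma: float = 0.025,
) -> np.ndarray:
    """Gaussian-kernel firing-rate estimate on a uniform grid (Hz).

    rate(t) = sum_spikes N(t - t_spike; sigma), each kernel integrating to 1.
    The kernel is truncated at +-6 sigma (relative error < 1e-8).
    """
    spike_times = np.asarray(spike_times, float)
    rate = np.zeros(len(grid))
    if len(spike_times) == 0 or len(grid) == 0:
        return rate
    step = grid[1] - grid[0] if len(grid) > 1 else sigma
    half = 6.0 * sigma
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for ts in spike_times:
        i0 = int(np.searchsorted(grid, ts - half, "left"))
        i1 = int(np.searchsorted(grid, ts + half, "right"))
        if i1 > i0:
            d = grid[i0:i1] - ts
            rate[i0:i1] += norm * np.exp(-0.5 * (d / sigma) ** 2)
    return rate


def segment_boundaries(events: dict[str, float], cfg: AnalysisConfig) -> list[float]:
    """Trial boundaries of the tensor window: 0.3 s before turn start,
    turn start, turn end, port entry, and 2.5 s after port entry."""
    return [
        events["turn_start"] - cfg.pre_turn_window,
        events["turn_start"],
        events["turn_end"],
        events["port_entry"],
        events["port_entry"] + cfg.post_entry_window,
    ]


def mean_segment_durations(
    trials: list[TrialRecord], cfg: AnalysisConfig
) -> np.ndarray:
    """Average duration of each canonical segment over trials with full events."""
    durs = []
    for tr in trials:
        ev = tr.events
        if not {"turn_start", "turn_end", "port_entry"} <= ev.keys():
            continue
        b = segment_boundaries(ev, cfg)
        durs.append(np.diff(b))
    if not durs:
        raise ValueError("no trials with complete tensor events")
    return np.mean(durs, axis=0)


def canonical_grid(
    mean_durations: np.ndarray, step: float
) -> tuple[np.ndarray, dict[str, int]]:
    """Uniform canonical time grid (0 at turn start) plus landmark indices."""
    bounds = np.concatenate([[0.0], np.cumsum(mean_durations)])
    t = np.arange(0.0, bounds[-1] + step / 2, step)
    names = ("window_start", "turn_start", "turn_end", "port_entry", "window_end")
    landmarks = {
        name: int(np.clip(round(b / step), 0, len(t) - 1))
        for name, b in zip(names, bounds)
    }
    return t - bounds[1], landmarks  # time 0 at turn start


def rescale_trial(
    rate: np.ndarray,
    rate_time: np.ndarray,
    trial_boundaries: list[float],
    mean_durations: np.ndarray,
    step: float,
) -> np.ndarray:
    """Piecewise-linearly warp one trial's rate onto the canonical grid.

    The time map sends each trial segment boundary onto the corresponding
    canonical boundary; rate values are linearly interpolated at the warped
    sample points, so landmarks are preserved exactly and constant rates are
    invariant.
    """
    tb = np.asarray(trial_boundaries, float)
    if np.any(np.diff(tb) <= 0):
        raise ValueError("zero-length or negative trial segment")
    cb = np.concatenate([[0.0], np.cumsum(mean_durations)])
    t_canon = np.arange(0.0, cb[-1] + step / 2, step)
    # map canonical time -> trial time (piecewise linear through boundaries)
    t_trial = np.interp(t_canon, cb, tb)
    return np.interp(t_trial, rate_time, rate)


def _condition_index(trial: TrialRecord) -> tuple[int, int, int] | None:
    try:
        s = SIDES.index(trial.choice)
        d = DIFFICULTIES.index(round(abs(trial.delta_freq), 1))
        c = OUTCOMES.index(trial.outcome)
    except ValueError:
        return None
    return s, d, c


def session_condition_averages(
    bundle: SessionBundle,
    events: dict[int, dict[str, float]],
    cfg: AnalysisConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, int], list[str]]:
    """Per-unit condition-averaged rescaled rates for one session.

    Returns (data (n_units, 2, 4, 2, T), counts, time, landmarks, unit_ids).
    """
    usable: list[tuple[TrialRecord, list[float]]] = []
    for tr in bundle.trials:
        ev = events.get(tr.index)
        if ev is None or not {"turn_start", "turn_end", "port_entry"} <= ev.keys():
            continue
        if _condition_index(tr) is None:
            continue
        b = segment_boundaries(ev, cfg)
        if any(d2 - d1 <= 0 for d1, d2 in zip(b, b[1:])):
            continue
        usable.append((tr, b))
    if not usable:
        raise ValueError("no usable trials for tensor construction")

    mean_dur = np.mean([np.diff(b) for _, b in usable], axis=0)
    t_canon, landmarks = canonical_grid(mean_dur, cfg.peth_step)
    n_t = len(t_canon)

    n_units = bundle.n_units
    sums = np.zeros((n_units, 2, 4, 2, n_t))
    counts = np.zeros((n_units, 2, 4, 2), int)
    pad = 6 * cfg.smoothing_sigma
    for ui, st in enumerate(bundle.spikes):
        for tr, b in usable:
            grid = np.arange(b[0] - pad, b[-1] + pad, cfg.peth_step)
            sel = st.times[(st.times >= grid[0] - pad) & (st.times <= grid[-1] + pad)]
            rate = rate_estimate(sel, grid, cfg.smoothing_sigma)
            warped = rescale_trial(rate, grid - b[0], np.array(b) - b[0], mean_dur, cfg.peth_step)
            s, d, c = _condition_index(tr)
            sums[ui, s, d, c] += warped[:n_t]
            counts[ui, s, d, c] += 1
    data = np.divide(
        sums,
        np.maximum(counts, 1)[..., None],
        out=np.zeros_like(sums),
        where=counts[..., None] > 0,
    )
    return data, counts, t_canon, landmarks, [s.unit_id for s in bundle.spikes]


def build_peth_tensor(
    sessions: list[tuple[SessionBundle, dict[int, dict[str, float]]]],
    cfg: AnalysisConfig | None = None,
) -> PETHTensor:
    """Pool units across sessions into the pseudo-simultaneous tensor.

    Every session is rescaled onto its own mean segment durations and then
    resampled onto the first session's canonical grid length.  Units with
    fewer than ``cfg.min_trials_per_condition`` trials in any condition cell
    are excluded (and listed on the tensor).
    """
    cfg = cfg or AnalysisConfig()
    blocks = []
    all_counts = []
    ids: list[str] = []
    excluded: list[str] = []
    ref_time = ref_landmarks = None
    for si, (bundle, events) in enumerate(sessions):
        data, counts, t_canon, landmarks, unit_ids = session_condition_averages(
            bundle, events, cfg
        )
        if ref_time is None:
            ref_time, ref_landmarks = t_canon, landmarks
        elif len(t_canon) != len(ref_time):
            # resample this session's canonical grid onto the reference length
            x_new = np.linspace(0, 1, len(ref_time))
            x_old = np.linspace(0, 1, len(t_canon))
            data = np.apply_along_axis(
                lambda row: np.interp(x_new, x_old, row), -1, data
            )
        keep = counts.min(axis=(1, 2, 3)) >= cfg.min_trials_per_condition
        for ui, ok in enumerate(keep):
            uid = f"s{si}:{unit_ids[ui]}"
            if ok:
                ids.append(uid)
            else:
                excluded.append(uid)
        blocks.append(data[keep])
        all_counts.append(counts[keep])
    data = np.concatenate(blocks, axis=0) if blocks else np.empty((0,))
    if data.size == 0 or data.shape[0] == 0:
        raise ValueError("zero eligible units after the minimum-trial rule")
    return PETHTensor(
        data=data,
        time=ref_time,
        landmarks=ref_landmarks,
        counts=np.concatenate(all_counts, axis=0),
        unit_ids=ids,
        units_excluded=excluded,
    )


def zscore_tensor(tensor: PETHTensor) -> PETHTensor:
    """Z-score each unit across all of its condition x time entries.

    Zero-variance units are flagged and left at zero rather than divided.
    """
    data = tensor.data
    flat = data.reshape(data.shape[0], -1)
    mean = flat.mean(axis=1)
    sd = flat.std(axis=1)
    flagged = [tensor.unit_ids[i] for i in np.nonzero(sd == 0)[0]]
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (flat - mean[:, None]) / safe_sd[:, None]
    z[sd == 0] = 0.0
    return tensor.copy_with(z.reshape(data.shape), units_flagged=flagged)


# ---------------------------------------------------------------------------
# epoch comparisons
# ---------------------------------------------------------------------------

EPOCH_DEFS = {
    "return": ("return_start", "wait_arrival"),
    "wait": ("wait_arrival", "stim_onset"),
    "go": ("turn_start", "port_entry"),
    "turn": ("turn_start", "turn_end"),
}


def epoch_mean_rates(
    bundle: SessionBundle,
    events: dict[int, dict[str, float]],
    cfg: AnalysisConfig | None = None,
    hemisphere_side: str = "right",
) -> pd.DataFrame:
    """Per-unit mean firing rate (spike count / duration) in each task epoch.

    Epochs: return, wait, go, ipsi/contra turn (relative to the recorded
    hemisphere), and evaluation split by outcome (correct = rewarded).
    """
    cfg = cfg or AnalysisConfig()
    rows = []
    for st in bundle.spikes:
        acc: dict[str, list[float]] = {}
        for tr in bundle.trials:
            ev = events.get(tr.index)
            if ev is None:
                continue
            spans: dict[str, tuple[float, float]] = {}
            for name, (a, b) in EPOCH_DEFS.items():
                if a in ev and b in ev:
                    spans[name] = (ev[a], ev[b])
            if "turn" in spans:
                ipsi = tr.choice == st.hemisphere
                spans["turn_ipsi" if ipsi else "turn_contra"] = spans.pop("turn")
            if "port_entry" in ev:
                label = (
                    "evaluation_correct" if tr.outcome == "correct" else "evaluation_incorrect"
                )
                spans[label] = (ev["port_entry"], ev["port_entry"] + cfg.post_entry_window)
            for name, (a, b) in spans.items():
                if b > a:
                    n = np.count_nonzero((st.times >= a) & (st.times < b))
                    acc.setdefault(name, []).append(n / (b - a))
        row = {"unit_id": st.unit_id}
        row.update({k: float(np.mean(v)) for k, v in acc.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("unit_id")


def compare_epoch_activity(
    epoch_rates: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank tests between epoch mean rates over units."""
    cols = [c for c in epoch_rates.columns]
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    out = []
    n = len(epoch_rates)
    for a, b in pairs:
        sub = epoch_rates[[a, b]].dropna()
        diff = sub[a] - sub[b]
        if len(sub) < 6:
            out.append({"epoch_a": a, "epoch_b": b, "n": len(sub),
                        "statistic": np.nan, "p": np.nan, "note": "underpowered"})
            continue
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(sub[a], sub[b], zero_method="wilcox")
            stat, p = float(res.statistic), float(res.pvalue)
        out.append({"epoch_a": a, "epoch_b": b, "n": len(sub),
                    "statistic": stat, "p": p, "note": ""})
    return pd.DataFrame(out)
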