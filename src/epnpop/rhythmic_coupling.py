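"""Spike coupling to cyclic behaviors: gait strides and licking.

Strides are peaks of the paw position projected onto the animal's
longitudinal (tail-base to head) axis, taken from the hindpaw contralateral
to the recorded hemisphere; trajectories with fewer than four strides are
excluded.  The instantaneous phase of a cyclic signal comes from a
zero-phase band-pass filter (gait 3-6 Hz, licking 4-10 Hz) followed by the
analytic-signal (Hilbert) phase, so phase 0 sits at signal peaks.  Spike
phases are gathered in a 400 ms window around each event (about two cycles),
summarized by the mean resultant vector and tested for directional bias with
the Rayleigh test.  Lick-bout analyses correlate the instantaneous firing
rate with the instantaneous lick rate, with significance from circular
rotations of the rate trace (preserving autocorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, find_peaks, hilbert, sosfiltfilt

from .session_io import AnalysisConfig, LickEvents, SpikeTrain, TrackingTable


@dataclass
class StrideSet:
    """Stride peak times per trajectory (context window)."""

    strides: list[dict]  # {trial_index, context, peak_times}
    excluded: list[int] = field(default_factory=list)

    def events_by_index(self, max_strides: int = 8) -> dict[int, list[float]]:
        """Pool stride times across trajectories by within-trajectory index."""
        out: dict[int, list[float]] = {}
        for rec in self.strides:
            for k, tpeak in enumerate(rec["peak_times"][:max_strides]):
                out.setdefault(k + 1, []).append(float(tpeak))
        return out


@dataclass
class PhaseSeries:
    time: np.ndarray
    phase: np.ndarray  # radians in [-pi, pi)
    band: tuple[float, float]
    _unwrapped: np.ndarray | None = field(default=None, repr=False, compare=False)

    def at(self, times: np.ndarray) -> np.ndarray:
        """Phase at arbitrary times via interpolation of the unwrapped phase."""
        if self._unwrapped is None:
            self._unwrapped = np.unwrap(self.phase)
        ph = np.interp(times, self.time, self._unwrapped)
        return np.angle(np.exp(1j * ph))


@dataclass
class PhaseLockResult:
    mean_angle: float
    resultant: float
    n_spikes: int
    p: float
    event_label: str = ""
    flagged_low_n: bool = False


def longitudinal_paw_position(
    tracking: TrackingTable, paw: str = "paw_HL"
) -> np.ndarray:
    """Paw position projected onto the instantaneous body axis (cm)."""
    axis = tracking.xy("head") - tracking.xy("tail_base")
    norm = np.linalg.norm(axis, axis=1)
    norm[norm == 0] = 1.0
    u = axis / norm[:, None]
    rel = tracking.xy(paw) - tracking.xy("body_center")
    return np.einsum("ij,ij->i", rel, u)


def extract_strides(
    tracking: TrackingTable,
    context_windows: list[tuple[int, str, float, float]],
    paw: str = "paw_HL",
    min_strides: int = 4,
    max_stride_freq: float = 6.0,
) -> StrideSet:
    """Stride peaks of the longitudinal paw signal within context windows.

    ``context_windows``: (trial_index, context, t_start, t_stop) per
    trajectory.  Peak detection enforces a minimum inter-peak interval of
    one period at the top of the gait band; trajectories with fewer than
    ``min_strides`` peaks are excluded.
    """
    signal = longitudinal_paw_position(tracking, paw)
    t = tracking.time
    fs = 1.0 / tracking.frame_interval
    min_dist = max(1, int(fs / max_stride_freq))
    strides, excluded = [], []
    for trial_index, context, a, b in context_windows:
        i0, i1 = np.searchsorted(t, [a, b])
        seg = signal[i0:i1]
        if len(seg) < min_dist * 2:
            excluded.append(trial_index)
            continue
        prom = 0.25 * max(np.ptp(seg), 1e-9)
        peaks, _ = find_peaks(seg, distance=min_dist, prominence=prom)
        if len(peaks) < min_strides:
            excluded.append(trial_index)
            continue
        strides.append(
            {
                "trial_index": trial_index,
                "context": context,
                "peak_times": t[i0 + peaks],
            }
        )
    return StrideSet(strides=strides, excluded=excluded)


def phase_series(
    signal: np.ndarray,
    fs: float,
    band: tuple[float, float],
    time: np.ndarray | None = None,
    order: int = 4,
) -> PhaseSeries:
    """Instantaneous phase of a band-limited signal.

    Zero-phase band-pass (forward-backward Butterworth of the given order)
    followed by the Hilbert-transform analytic phase; phase 0 at peaks.
    """
    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band top {hi} Hz is at or above Nyquist ({fs / 2} Hz)")
    sos = butter(order, [lo, hi], btype="band", fs=fs, output="sos")
    filtered = sosfiltfilt(sos, signal - np.mean(signal))
    phase = np.angle(hilbert(filtered))
    t = time if time is not None else np.arange(len(signal)) / fs
    return PhaseSeries(time=t, phase=phase, band=band)


def resultant_vector(phases: np.ndarray) -> tuple[float, float]:
    """Mean angle and resultant length of circular data."""
    if len(phases) == 0:
        return 0.0, 0.0
    z = np.exp(1j * np.asarray(phases)).mean()
    return float(np.angle(z)), float(np.abs(z))


def rayleigh_test(phases: np.ndarray) -> float:
    """Rayleigh test of circular non-uniformity.

    Uses the standard closed-form approximation
    p = exp(sqrt(1 + 4n + 4(n^2 - Rn^2)) - (1 + 2n)) with Rn = n * R.
    Requires n >= 5 (raises otherwise).
    """
    n = len(phases)
    if n < 5:
        raise ValueError("Rayleigh test needs at least 5 phases")
    _, R = resultant_vector(phases)
    Rn = n * R
    p = np.exp(np.sqrt(1.0 + 4 * n + 4.0 * (n**2 - Rn**2)) - (1.0 + 2 * n))
    return float(min(max(p, np.finfo(float).tiny), 1.0))


def spike_phase_vector(
    spikes: SpikeTrain | np.ndarray,
    phase: PhaseSeries,
    event_times: np.ndarray,
    window: float = 0.4,
    event_label: str = "",
    min_spikes: int = 10,
) -> PhaseLockResult:
    """Mean spike-phase vector over windows centered on events.

    Spike phases are collected within +-window/2 of every event, pooled, and
    summarized by the mean resultant vector with a Rayleigh p.
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
    half = window / 2.0
    events = np.sort(np.atleast_1d(event_times))
    i0 = np.searchsorted(times, events - half, "left")
    i1 = np.searchsorted(times, events + half, "right")
    collected = [times[a:b] for a, b in zip(i0, i1) if b > a]
    if not collected:
        return PhaseLockResult(0.0, 0.0, 0, 1.0, event_label, flagged_low_n=True)
    phases = phase.at(np.concatenate(collected))
    angle, R = resultant_vector(phases)
    flagged = len(phases) < min_spikes
    p = rayleigh_test(phases) if len(phases) >= 5 else 1.0
    return PhaseLockResult(angle, R, len(phases), p, event_label, flagged)


# ---------------------------------------------------------------------------
# licking
# ---------------------------------------------------------------------------


@dataclass
class LickBout:
    port: str
    lick_times: np.ndarray
    start: float
    end: float


def segment_lick_bouts(
    licks: LickEvents, max_gap: float = 0.5, min_licks: int = 3
) -> list[LickBout]:
    """Split a port's licks into bouts at inter-lick gaps above ``max_gap``."""
    t = np.asarray(licks.lick_times)
    if len(t) == 0:
        return []
    breaks = np.nonzero(np.diff(t) > max_gap)[0]
    bouts = []
    start = 0
    for b in np.append(breaks, len(t) - 1):
        chunk = t[start : b + 1]
        if len(chunk) >= min_licks:
            bouts.append(
                LickBout(licks.port, chunk, float(chunk[0]), float(chunk[-1]))
            )
        start = b + 1
    return bouts


def instantaneous_rate(
    event_times: np.ndarray, grid: np.ndarray, sigma: float = 0.05
) -> np.ndarray:
    """Gaussian-kernel rate of point events on a grid (Hz)."""
    from .peth import rate_estimate

    return rate_estimate(np.asarray(event_times), grid, sigma)


def lick_rate_correlation(
    spikes: SpikeTrain,
    bouts: list[LickBout],
    cfg: AnalysisConfig | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float, bool]:
    """Pearson correlation between firing rate and lick rate within bouts.

    Each bout's rate traces are linearly rescaled to the average bout
    duration and averaged; significance uses circular rotations of the
    firing-rate trace (add-one estimator).  Returns (r, p, flagged); flagged
    when fewer than 3 bouts are available.
    """
    cfg = cfg or AnalysisConfig()
    if len(bouts) < 3:
        return 0.0, 1.0, True
    mean_dur = float(np.mean([b.end - b.start for b in bouts]))
    grid = np.arange(0.0, mean_dur + cfg.peth_step / 2, cfg.peth_step)
    fr_acc = np.zeros(len(grid))
    lr_acc = np.zeros(len(grid))
    for b in bouts:
        span = max(b.end - b.start, 1e-3)
        warped = b.start + (grid / mean_dur) * span
        pad = 0.3
        local = np.arange(b.start - pad, b.end + pad, cfg.peth_step)
        fr = instantaneous_rate(
            spikes.times[(spikes.times > b.start - 1) & (spikes.times < b.end + 1)],
            local,
            cfg.smoothing_sigma,
        )
        lr = instantaneous_rate(b.lick_times, local, 0.05)
        fr_acc += np.interp(warped, local, fr)
        lr_acc += np.interp(warped, local, lr)
    fr_acc /= len(bouts)
    lr_acc /= len(bouts)
    if fr_acc.std() == 0 or lr_acc.std() == 0:
        return 0.0, 1.0, True
    n = len(grid)
    a = (fr_acc - fr_acc.mean()) / fr_acc.std()
    b = (lr_acc - lr_acc.mean()) / lr_acc.std()
    # correlation at every circular shift in one pass (circular
    # cross-correlation via FFT); shift 0 is the observed correlation
    r_all = np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n) / n
    r_obs = float(r_all[0])
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, n, size=n_perm)
    count = int(np.sum(np.abs(r_all[shifts]) >= abs(r_obs) - 1e-12))
    p = (1 + count) / (1 + n_perm)
    return r_obs, p, False


def lick_phase_series(
    lick_times: np.ndarray,
    session_span: tuple[float, float],
    fs: float = 200.0,
    band: tuple[float, float] = (4.0, 10.0),
    sigma: float = 0.02,
) -> PhaseSeries:
    """Lick-cycle phase from the lick-probability signal (kernel rate of
    lick times, band-passed and Hilbert-transformed)."""
    t = np.arange(session_span[0], session_span[1], 1.0 / fs)
    prob = instantaneous_rate(np.asarray(lick_times), t, sigma)
    return phase_series(prob, fs, band, time=t)


# ---------------------------------------------------------------------------
# population summaries
# ---------------------------------------------------------------------------


def population_phase_summary(
    results: dict[str, list[PhaseLockResult]], alpha: float = 0.001
) -> dict[str, dict]:
    """Per event label: fraction of modulated units and the population vector.

    The population vector averages the per-unit mean-vector x and y
    components; its angle and magnitude summarize the population phase
    preference.  Modulated units are those with Rayleigh p < alpha.
    """
    out = {}
    for label, res_list in results.items():
        tested = [r for r in res_list if r.n_spikes >= 5]
        if not tested:
            out[label] = {
                "fraction_modulated": 0.0,
                "mean_phase": 0.0,
                "magnitude": 0.0,
                "n_units": 0,
            }
            continue
        frac = float(np.mean([r.p < alpha for r in tested]))
        x = float(np.mean([r.resultant * np.cos(r.mean_angle) for r in tested]))
        y = float(np.mean([r.resultant * np.sin(r.mean_angle) for r in tested]))
        out[label] = {
            "fraction_modulated": frac,
            "mean_phase": float(np.arctan2(y, x)),
            "magnitude": float(np.hypot(x, y)),
            "n_units": len(tested),
        }
    return out
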