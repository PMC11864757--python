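"""Canonical session data model, on-disk formats, validation and configuration.

A *session* bundles everything recorded in one behavioral/electrophysiology
sitting: a pose-tracking table (uniformly sampled x/y per bodypart, in arena
cm), sorted spike-timestamp lists per unit, a trial/event table, and lick-port
events.  All times are seconds from session start; all positions are cm with
the origin at the waiting corner and x pointing toward the right reward
corner.

On disk a session is a directory of plain delimited text files plus a JSON
manifest — diffable, language agnostic, and byte-deterministic for a given
bundle (times written to 1e-6 s, positions to 1e-4 cm).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

BODYPARTS = (
    "head",
    "body_center",
    "tail_base",
    "paw_FL",
    "paw_FR",
    "paw_HL",
    "paw_HR",
)

EVENT_NAMES = (
    "return_start",
    "wait_arrival",
    "stim_onset",
    "turn_start",
    "turn_mid",
    "turn_end",
    "port_entry",
)

TIME_DECIMALS = 6  # seconds
POS_DECIMALS = 4  # cm


class SessionLoadError(RuntimeError):
    """A required file is missing or unreadable."""


class SessionValidationError(ValueError):
    """A bundle violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TrackingTable:
    """Uniformly sampled pose table: ``time`` plus x/y per bodypart (cm)."""

    time: np.ndarray
    coords: dict[str, np.ndarray]  # bodypart -> (n, 2) array of x, y

    @property
    def frame_interval(self) -> float:
        return float(np.median(np.diff(self.time)))

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def xy(self, bodypart: str) -> np.ndarray:
        return self.coords[bodypart]

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.time}
        for bp in BODYPARTS:
            data[f"{bp}_x"] = self.coords[bp][:, 0]
            data[f"{bp}_y"] = self.coords[bp][:, 1]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrackingTable":
        coords = {
            bp: np.column_stack(
                [df[f"{bp}_x"].to_numpy(float), df[f"{bp}_y"].to_numpy(float)]
            )
            for bp in BODYPARTS
        }
        return cls(time=df["time"].to_numpy(float), coords=coords)


@dataclass
class SpikeTrain:
    unit_id: str
    times: np.ndarray  # seconds, sorted ascending
    hemisphere: str = "right"  # {left, right}


@dataclass
class TrialRecord:
    index: int
    delta_freq: float  # octaves, signed
    instructed_side: str  # {left, right, none}
    choice: str  # {left, right}
    outcome: str  # {correct, incorrect, false_alarm}
    events: dict[str, float]  # event name -> seconds (stim_onset absent on FA)
    rewarded: bool

    @property
    def difficulty(self) -> float:
        return abs(self.delta_freq)

    @property
    def response_time(self) -> float | None:
        if "stim_onset" in self.events and "turn_start" in self.events:
            return self.events["turn_start"] - self.events["stim_onset"]
        return None


@dataclass
class LickEvents:
    port: str  # {left, right}
    head_entry_times: np.ndarray
    lick_times: np.ndarray


@dataclass
class SessionBundle:
    tracking: TrackingTable
    spikes: list[SpikeTrain]
    trials: list[TrialRecord]
    licks: dict[str, LickEvents]  # port -> events
    meta: dict = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    @property
    def span(self) -> float:
        return float(self.tracking.time[-1])

    def unit(self, unit_id: str) -> SpikeTrain:
        for s in self.spikes:
            if s.unit_id == unit_id:
                return s
        raise KeyError(unit_id)


@dataclass
class AnalysisConfig:
    """Every tunable of the analysis pipeline with its default.

    Durations are seconds, frequencies Hz, distances cm.
    """

    smoothing_sigma: float = 0.025  # spike-rate Gaussian kernel
    peth_step: float = 0.010  # canonical PETH grid step
    design_window: float = 0.2  # encoding-model sliding window
    design_step: float = 0.05
    folds: int = 10
    permutations: int = 1000
    alpha: float = 0.01
    alpha_strict: float = 0.001
    trajectory_r_min: float = 0.75
    gait_band: tuple[float, float] = (3.0, 6.0)
    lick_band: tuple[float, float] = (4.0, 10.0)
    phase_window: float = 0.4  # spike-phase gathering window around events
    reward_window: float = 0.25  # post head-entry window for reward auROC
    min_trials_per_condition: int = 2
    pre_turn_window: float = 0.3  # tensor starts this long before turn start
    post_entry_window: float = 2.5  # tensor ends this long after port entry
    rt_bin: float = 0.075  # response-time bin for P(correct | RT)
    # event detection
    arrival_threshold_cm: float = 1.5
    angvel_threshold: float = 0.01  # deg/s
    corner_vel_threshold: float = 0.5  # cm/s (magnitude, for sustained approach)
    persistence_frames: int = 3
    smooth_sigma_frames: float = 2.0
    fa_turn_search_delay: float = 0.75  # s after wait arrival on no-stimulus trials
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "smoothing_sigma",
            "peth_step",
            "design_window",
            "design_step",
            "phase_window",
            "reward_window",
            "rt_bin",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("alpha", "alpha_strict"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gait_band"] = list(self.gait_band)
        d["lick_band"] = list(self.lick_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = dict(d)
        for key in ("gait_band", "lick_band"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


@dataclass
class Violation:
    code: str
    locator: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, code: str, locator: str, message: str) -> None:
        self.violations.append(Violation(code, locator, message))

    def __iter__(self) -> Iterator[Violation]:
        return iter(self.violations)

    def __len__(self) -> int:
        return len(self.violations)

    def summary(self) -> str:
        if self.ok:
            return "OK: no invariant violations"
        lines = [f"{len(self.violations)} violation(s):"]
        lines += [f"  [{v.code}] {v.locator}: {v.message}" for v in self.violations]
        return "\n".join(lines)


def validate_session(bundle: SessionBundle) -> ValidationReport:
    """Check every structural invariant of a bundle; report, never raise."""
    rep = ValidationReport()
    tr = bundle.tracking

    dt = np.diff(tr.time)
    if np.any(dt <= 0):
        idx = int(np.argmax(dt <= 0))
        rep.add("tracking.time", f"frame {idx}", "time not strictly increasing")
    elif len(dt):
        # tolerance: declared interval constancy (1e-6 s) plus the rounding
        # granularity of the on-disk representation
        dt0 = float(np.median(dt))
        bad = np.abs(dt - dt0) > 1e-6 + 1e-9
        if np.any(bad):
            idx = int(np.argmax(bad))
            rep.add(
                "tracking.interval",
                f"frame {idx}",
                f"frame interval {dt[idx]:.6g} differs from {dt0:.6g} by >1e-6 s",
            )
    side = float(bundle.meta.get("arena_side_cm", 35.0))
    # bounding box of the triangular arena plus margin
    lo, hi = -2.0, side + 2.0
    for bp in BODYPARTS:
        xy = tr.coords[bp]
        if not np.all(np.isfinite(xy)):
            rep.add("tracking.finite", bp, "non-finite coordinate")
            continue
        if xy.min() < lo or xy.max() > hi:
            rep.add(
                "tracking.bounds",
                bp,
                f"coordinate outside arena bounding box [{lo}, {hi}] cm",
            )

    span = bundle.span
    for st in bundle.spikes:
        t = st.times
        if len(t) and (np.any(np.diff(t) < 0)):
            rep.add("spikes.sorted", st.unit_id, "spike times not sorted")
        if len(t) and t[0] < 0:
            rep.add("spikes.nonneg", st.unit_id, f"negative spike time {t[0]:.6f}")
        if len(t) and t[-1] > span + 1e-6:
            rep.add("spikes.span", st.unit_id, "spike beyond session span")
        if st.hemisphere not in ("left", "right"):
            rep.add("spikes.hemisphere", st.unit_id, f"bad hemisphere {st.hemisphere!r}")

    for trial in bundle.trials:
        loc = f"trial {trial.index}"
        present = [(n, trial.events[n]) for n in EVENT_NAMES if n in trial.events]
        times = [t for _, t in present]
        if any(b < a for a, b in zip(times, times[1:])):
            rep.add("trials.order", loc, "event times out of canonical order")
        if trial.rewarded and trial.outcome != "correct":
            rep.add("trials.reward", loc, "rewarded trial with non-correct outcome")
        if trial.outcome == "false_alarm" and "stim_onset" in trial.events:
            rep.add("trials.fa", loc, "false-alarm trial carries a stimulus onset")
        if times and (times[0] < tr.time[0] - 1e-6 or times[-1] > span + 1e-6):
            rep.add("trials.span", loc, "trial events outside tracking span")

    for port, ev in bundle.licks.items():
        for name, arr in (("head_entry", ev.head_entry_times), ("lick", ev.lick_times)):
            if len(arr) and np.any(np.diff(arr) < 0):
                rep.add("licks.sorted", f"{port}/{name}", "times not sorted")
            if len(arr) and (arr[0] < 0 or arr[-1] > span + 1e-6):
                rep.add("licks.span", f"{port}/{name}", "time outside session span")
    return rep


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_TIME_FMT = f"%.{TIME_DECIMALS}f"
_POS_FMT = f"%.{POS_DECIMALS}f"


def save_session(bundle: SessionBundle, path: str | Path) -> None:
    """Write a bundle to ``path`` as CSV files plus ``manifest.json``.

    Identical bundles produce byte-identical directories.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    df = bundle.tracking.to_frame()
    fmts = {"time": _TIME_FMT}
    for col in df.columns[1:]:
        fmts[col] = _POS_FMT
    with open(path / "tracking.csv", "w", newline="") as fh:
        fh.write(",".join(df.columns) + "\n")
        cols = [df[c].to_numpy(float) for c in df.columns]
        fmt_list = [fmts[c] for c in df.columns]
        for row in zip(*cols):
            fh.write(",".join(f % v for f, v in zip(fmt_list, row)) + "\n")

    spikes_dir = path / "spikes"
    spikes_dir.mkdir(exist_ok=True)
    for st in bundle.spikes:
        np.savetxt(spikes_dir / f"{st.unit_id}.csv", st.times, fmt=_TIME_FMT)

    rows = []
    for t in bundle.trials:
        row = {
            "index": t.index,
            "delta_freq": t.delta_freq,
            "instructed_side": t.instructed_side,
            "choice": t.choice,
            "outcome": t.outcome,
            "rewarded": int(t.rewarded),
        }
        for name in EVENT_NAMES:
            row[name] = (
                _TIME_FMT % t.events[name] if name in t.events else ""
            )
        rows.append(row)
    trials_df = pd.DataFrame(rows)
    trials_df.to_csv(path / "trials.csv", index=False, float_format="%.4f")

    for port in ("left", "right"):
        ev = bundle.licks.get(
            port, LickEvents(port, np.empty(0), np.empty(0))
        )
        with open(path / f"licks_{port}.csv", "w", newline="") as fh:
            fh.write("kind,time\n")
            for t in ev.head_entry_times:
                fh.write("head_entry," + (_TIME_FMT % t) + "\n")
            for t in ev.lick_times:
                fh.write("lick," + (_TIME_FMT % t) + "\n")

    manifest = {
        "format": "epnpop-session-v1",
        "meta": dict(sorted(bundle.meta.items())),
        "units": [
            {"unit_id": s.unit_id, "hemisphere": s.hemisphere, "n_spikes": len(s.times)}
            for s in bundle.spikes
        ],
        "n_trials": len(bundle.trials),
        "checksums": {},
    }
    for rel in sorted(
        p.relative_to(path).as_posix()
        for p in path.rglob("*.csv")
    ):
        digest = hashlib.sha256((path / rel).read_bytes()).hexdigest()
        manifest["checksums"][rel] = digest
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_session(path: str | Path) -> SessionBundle:
    """Load and validate a session directory written by :func:`save_session`."""
    path = Path(path)
    for required in ("tracking.csv", "trials.csv", "manifest.json"):
        if not (path / required).exists():
            raise SessionLoadError(f"missing required file: {path / required}")
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)

    tracking = TrackingTable.from_frame(pd.read_csv(path / "tracking.csv"))

    spikes = []
    for entry in manifest.get("units", []):
        uid = entry["unit_id"]
        fpath = path / "spikes" / f"{uid}.csv"
        if not fpath.exists():
            raise SessionLoadError(f"missing spike file: {fpath}")
        times = np.loadtxt(fpath, ndmin=1) if fpath.stat().st_size else np.empty(0)
        spikes.append(SpikeTrain(uid, np.asarray(times, float), entry["hemisphere"]))

    trials = []
    tdf = pd.read_csv(path / "trials.csv")
    for _, row in tdf.iterrows():
        events = {
            name: float(row[name])
            for name in EVENT_NAMES
            if name in row and pd.notna(row[name]) and row[name] != ""
        }
        trials.append(
            TrialRecord(
                index=int(row["index"]),
                delta_freq=float(row["delta_freq"]),
                instructed_side=str(row["instructed_side"]),
                choice=str(row["choice"]),
                outcome=str(row["outcome"]),
                events=events,
                rewarded=bool(row["rewarded"]),
            )
        )

    licks = {}
    for port in ("left", "right"):
        fpath = path / f"licks_{port}.csv"
        if not fpath.exists():
            raise SessionLoadError(f"missing lick file: {fpath}")
        ldf = pd.read_csv(fpath)
        licks[port] = LickEvents(
            port=port,
            head_entry_times=ldf.loc[ldf["kind"] == "head_entry", "time"]
            .to_numpy(float),
            lick_times=ldf.loc[ldf["kind"] == "lick", "time"].to_numpy(float),
        )

    bundle = SessionBundle(
        tracking=tracking,
        spikes=spikes,
        trials=trials,
        licks=licks,
        meta=manifest.get("meta", {}),
    )
    report = validate_session(bundle)
    if not report.ok:
        first = report.violations[0]
        raise SessionValidationError(
            f"invalid session at {path}: {first.locator}: {first.message} "
            f"({len(report)} violation(s) total)"
        )
    return bundle
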