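"""End-to-end session analysis pipeline.

Stages (each writing deterministic artifacts under ``<out>/``):

* ``events``   — kinematics + event detection (``kinematics.csv``, ``events.csv``)
* ``peth``     — condition tensor in Hz and z-units (``tensor_*.npy`` + manifest)
* ``geometry`` — variance traces, cosine similarity, PCA/dPCA with shuffle
  significance, trajectory matching and the context tensor
* ``encoding`` — per-unit LASSO family fits, context transfer, partial
  correlations, delta-R^2, reward auROC classes (``encoding_results.csv``)
* ``phase``    — stride/lick phase locking and lick-rate correlations
* ``decode``   — population decoders with permutation nulls

Given (session, config, seed) every artifact is byte-reproducible: all
randomness flows from the seed, and output files carry no timestamps.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    encoding_models as enc,
    kinematics_events as ke,
    peth as peth_mod,
    population_decoding as dec,
    population_geometry as geo,
    rhythmic_coupling as rc,
)
from .session_io import AnalysisConfig, SessionBundle, load_session

ALL_STAGES = ("events", "peth", "geometry", "encoding", "phase", "decode")


def _write_df(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


class SessionPipeline:
    """Run analysis stages over one session, keeping intermediates in memory."""

    def __init__(
        self,
        bundle: SessionBundle,
        cfg: AnalysisConfig | None = None,
        out_dir: str | Path = "results",
    ):
        self.bundle = bundle
        self.cfg = cfg or AnalysisConfig()
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict[str, object] = {}

    # -- events --------------------------------------------------------------

    def run_events(self) -> None:
        cfg = self.cfg
        side = float(self.bundle.meta.get("arena_side_cm", 35.0))
        kin = ke.compute_kinematics(
            self.bundle.tracking,
            self.bundle.trials,
            arena_side=side,
            smooth_sigma_frames=cfg.smooth_sigma_frames,
        )
        events, flagged = ke.detect_events(kin, self.bundle.trials, self.bundle.licks, cfg)
        self.artifacts["kin"] = kin
        self.artifacts["events"] = events
        self.artifacts["flagged"] = flagged

        _write_df(kin.frame, self.out / "kinematics.csv")
        rows = []
        for idx in sorted(events):
            row = {"trial_index": idx}
            row.update({k: events[idx].get(k, np.nan) for k in
                        ("return_start", "wait_arrival", "stim_onset",
                         "turn_start", "turn_mid", "turn_end", "port_entry")})
            rows.append(row)
        _write_df(pd.DataFrame(rows), self.out / "events.csv")

        stim_trials = [t for t in self.bundle.trials if t.outcome != "false_alarm"]
        summary: dict[str, object] = {"n_flagged_trials": len(flagged)}
        try:
            slope, bias, lapse, _ = ke.fit_psychometric(stim_trials)
            summary["psychometric"] = {"slope": slope, "bias": bias, "lapse": lapse}
        except ValueError as err:
            summary["psychometric"] = {"error": str(err)}
        try:
            summary["response_time"] = ke.response_time_stats(
                stim_trials, n_perm=self.cfg.permutations, seed=self.cfg.seed
            )
        except ValueError as err:
            summary["response_time"] = {"error": str(err)}
        (self.out / "behavior_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
        )
        pcr = ke.prob_correct_by_rt(stim_trials, bin_width=self.cfg.rt_bin)
        _write_df(pcr, self.out / "prob_correct_by_rt.csv")

    # -- peth ----------------------------------------------------------------

    def run_peth(self) -> None:
        events = self.artifacts["events"]
        try:
            tensor = peth_mod.build_peth_tensor([(self.bundle, events)], self.cfg)
        except ValueError as err:
            # a session without full condition coverage cannot support the
            # condition-tensor analyses; record and let later stages skip
            (self.out / "tensor_manifest.json").write_text(
                json.dumps({"error": str(err)}, indent=2, sort_keys=True) + "\n"
            )
            return
        ztensor = peth_mod.zscore_tensor(tensor)
        self.artifacts["tensor"] = tensor
        self.artifacts["ztensor"] = ztensor
        np.save(self.out / "tensor_hz.npy", tensor.data)
        np.save(self.out / "tensor_z.npy", ztensor.data)
        manifest = {
            "axes": ["unit", "side", "difficulty", "outcome", "time"],
            "sides": list(peth_mod.SIDES),
            "difficulties": list(peth_mod.DIFFICULTIES),
            "outcomes": list(peth_mod.OUTCOMES),
            "time": [float(tensor.time[0]), float(tensor.time[-1]), len(tensor.time)],
            "landmarks": tensor.landmarks,
            "unit_ids": tensor.unit_ids,
            "units_excluded": tensor.units_excluded,
        }
        (self.out / "tensor_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        rates = peth_mod.epoch_mean_rates(self.bundle, events, self.cfg)
        self.artifacts["epoch_rates"] = rates
        _write_df(rates.reset_index(), self.out / "epoch_rates.csv")
        _write_df(peth_mod.compare_epoch_activity(rates), self.out / "epoch_tests.csv")

    # -- geometry ------------------------------------------------------------

    def run_geometry(self) -> None:
        cfg = self.cfg
        ztensor = self.artifacts.get("ztensor")
        if ztensor is None:
            (self.out / "geometry_summary.json").write_text(
                json.dumps({"skipped": "no condition tensor"}, indent=2) + "\n"
            )
            return
        traces = geo.variance_traces(ztensor)
        var_df = pd.DataFrame({"time": ztensor.time, **traces})
        _write_df(var_df, self.out / "variance_traces.csv")

        cs = geo.cosine_self_similarity(ztensor, demean=True)
        np.save(self.out / "cosine_similarity.npy", cs)

        n_sh = max(100, cfg.permutations)
        pca = geo.ConditionPCA(
            n_shuffles=n_sh, alpha=cfg.alpha, random_state=cfg.seed
        ).fit(ztensor.data)
        dresult = geo.dpca(
            ztensor,
            n_shuffles=n_sh,
            alpha=cfg.alpha,
            random_state=cfg.seed,
        )
        self.artifacts["pca"] = pca
        self.artifacts["dpca"] = dresult
        geom = {
            "pca_explained_variance_ratio": pca.explained_variance_ratio_[:10].tolist(),
            "pca_n_significant": int(pca.significant_.sum()),
            "dpca_etv": {k: v[:5].tolist() for k, v in dresult.etv.items()},
            "dpca_n_significant": {
                k: int(v.sum()) for k, v in dresult.significant.items()
            },
            "dpca_ranking_top5": dresult.ranking()[:5],
        }

        kin, events = self.artifacts["kin"], self.artifacts["events"]
        try:
            match = geo.match_trajectories(
                self.bundle, events, kin, r_min=cfg.trajectory_r_min
            )
            ctx_tensor, _ = geo.build_context_tensor(self.bundle, events, match, cfg)
            zc = ctx_tensor - ctx_tensor.mean(axis=(1, 2, 3), keepdims=True)
            sd = ctx_tensor.reshape(len(ctx_tensor), -1).std(axis=1)
            sd[sd == 0] = 1.0
            zc = zc / sd[:, None, None, None]
            ctx_dpca = geo.DemixedPCA(
                n_shuffles=0, random_state=cfg.seed
            ).fit(zc, geo.CONTEXT_AXES)
            self.artifacts["context_tensor"] = zc
            self.artifacts["context_dpca"] = ctx_dpca.result_
            geom["context_dpca_etv"] = {
                k: v[:3].tolist() for k, v in ctx_dpca.result_.etv.items()
            }
            geom["n_matched"] = {k: len(v) for k, v in match.selected.items()}
        except ValueError as err:
            geom["context_dpca_error"] = str(err)
        (self.out / "geometry_summary.json").write_text(
            json.dumps(geom, indent=2, sort_keys=True, default=float) + "\n"
        )

    # -- encoding ------------------------------------------------------------

    def run_encoding(self, delta_r2_vars: tuple[str, ...] = ("dist_goal", "angular_velocity")) -> None:
        cfg = self.cfg
        kin, events = self.artifacts["kin"], self.artifacts["events"]
        rows = []
        family_r2: dict[str, dict[str, float]] = {}
        for st in self.bundle.spikes:
            design = enc.build_design_matrix(self.bundle, kin, events, st, cfg)
            fam_scores = {}
            for fam, cols in enc.FAMILIES.items():
                fit = enc.fit_lasso_cv(
                    design, cols, context=None, folds=cfg.folds, random_state=cfg.seed
                )
                fam_scores[fam] = fit.cv_r2
            family_r2[st.unit_id] = fam_scores

            mixed = enc.KINEMATIC_COLUMNS + enc.SPATIOTEMPORAL_COLUMNS
            fits = {}
            for ctx in ("Return", "Go"):
                fits[ctx] = enc.fit_lasso_cv(
                    design, mixed, context=ctx, folds=cfg.folds, random_state=cfg.seed
                )
            transfer = {
                "Return": enc.cross_context_transfer(fits["Return"], design, "Go"),
                "Go": enc.cross_context_transfer(fits["Go"], design, "Return"),
            }
            for ctx in ("Return", "Go"):
                row = {
                    "unit_id": st.unit_id,
                    "context": ctx,
                    "cv_r2_mixed": fits[ctx].cv_r2,
                    "transfer_r2": transfer[ctx],
                    "alpha": fits[ctx].alpha,
                }
                row.update(
                    {f"beta_{k}": v for k, v in fits[ctx].coefficients.items()}
                )
                for var in enc.REDUCED_MODEL_RULES:
                    pc = enc.partial_correlation(
                        design, var, context=ctx,
                        n_perm=cfg.permutations, seed=cfg.seed,
                    )
                    row[f"partial_r_{var}"] = pc.r
                    row[f"partial_p_{var}"] = pc.p
                rows.append(row)
            for var in delta_r2_vars:
                dr2 = enc.delta_r2(
                    design, var, context=None, n_shuffles=2,
                    folds=cfg.folds, seed=cfg.seed,
                )
                rows[-1][f"delta_r2_{var}"] = dr2

        fam_df = pd.DataFrame(family_r2).T.rename_axis("unit_id").reset_index()
        _write_df(fam_df, self.out / "encoding_families.csv")
        _write_df(
            enc.model_family_comparison(fam_df.set_index("unit_id")),
            self.out / "encoding_family_tests.csv",
        )
        _write_df(pd.DataFrame(rows), self.out / "encoding_results.csv")

        reward = enc.classify_reward_units(
            self.bundle, events, cfg, n_perm=cfg.permutations, seed=cfg.seed
        )
        _write_df(
            pd.DataFrame([vars(r) for r in reward]), self.out / "reward_classes.csv"
        )
        self.artifacts["family_r2"] = fam_df
        self.artifacts["reward_classes"] = reward

    # -- phase ---------------------------------------------------------------

    def _stride_windows(self) -> list[tuple[int, str, float, float]]:
        events = self.artifacts["events"]
        windows = []
        for tr in self.bundle.trials:
            ev = events.get(tr.index)
            if ev is None:
                continue
            if "return_start" in ev and "wait_arrival" in ev:
                windows.append((tr.index, "Return", ev["return_start"], ev["wait_arrival"]))
            if "turn_end" in ev and "port_entry" in ev:
                windows.append((tr.index, "Go", ev["turn_end"], ev["port_entry"]))
        return windows

    def run_phase(self) -> None:
        cfg = self.cfg
        tracking = self.bundle.tracking
        fs = 1.0 / tracking.frame_interval
        # hindpaw contralateral to the recorded hemisphere (right -> left paw)
        hemis = self.bundle.spikes[0].hemisphere if self.bundle.spikes else "right"
        paw = "paw_HL" if hemis == "right" else "paw_HR"
        strides = rc.extract_strides(tracking, self._stride_windows(), paw=paw)
        signal = rc.longitudinal_paw_position(tracking, paw)
        gait_phase = rc.phase_series(signal, fs, cfg.gait_band, time=tracking.time)

        by_index = strides.events_by_index(max_strides=8)
        phase_rows = []
        gait_results: dict[str, list[rc.PhaseLockResult]] = {}
        for k in sorted(by_index):
            label = f"stride_{k}"
            evs = np.asarray(by_index[k])
            for st in self.bundle.spikes:
                res = rc.spike_phase_vector(
                    st, gait_phase, evs, window=cfg.phase_window, event_label=label
                )
                gait_results.setdefault(label, []).append(res)
                phase_rows.append(
                    {"unit_id": st.unit_id, "event": label, "n_spikes": res.n_spikes,
                     "angle": res.mean_angle, "R": res.resultant, "p": res.p}
                )

        all_licks = np.sort(np.concatenate(
            [self.bundle.licks[p].lick_times for p in self.bundle.licks]
        ))
        lick_rows = []
        if len(all_licks) >= 10:
            lick_phase = rc.lick_phase_series(
                all_licks, (float(tracking.time[0]), float(tracking.time[-1])),
                band=cfg.lick_band,
            )
            for st in self.bundle.spikes:
                res = rc.spike_phase_vector(
                    st, lick_phase, all_licks, window=cfg.phase_window,
                    event_label="lick",
                )
                gait_results.setdefault("lick", []).append(res)
                phase_rows.append(
                    {"unit_id": st.unit_id, "event": "lick", "n_spikes": res.n_spikes,
                     "angle": res.mean_angle, "R": res.resultant, "p": res.p}
                )
            bouts = []
            for port in self.bundle.licks:
                bouts.extend(rc.segment_lick_bouts(self.bundle.licks[port]))
            for st in self.bundle.spikes:
                r, p, flagged = rc.lick_rate_correlation(
                    st, bouts, cfg, n_perm=cfg.permutations, seed=cfg.seed
                )
                lick_rows.append(
                    {"unit_id": st.unit_id, "r": r, "p": p, "flagged": flagged}
                )

        _write_df(pd.DataFrame(phase_rows), self.out / "phase_results.csv")
        _write_df(pd.DataFrame(lick_rows), self.out / "lick_corr.csv")
        summary = rc.population_phase_summary(gait_results, alpha=cfg.alpha_strict)
        (self.out / "phase_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n"
        )
        self.artifacts["phase_summary"] = summary
        self.artifacts["strides"] = strides

    # -- decode --------------------------------------------------------------

    def run_decode(self, n_perm: int | None = None) -> None:
        cfg = self.cfg
        n_perm = n_perm if n_perm is not None else min(cfg.permutations, 200)
        rows = []
        zc = self.artifacts.get("context_tensor")
        if zc is not None:
            n_units = zc.shape[0]
            X, ctx_labels, side_labels, groups = [], [], [], []
            for ci, ctx in enumerate(("Return", "Go")):
                for si, side in enumerate(("left", "right")):
                    block = zc[:, ci, si, :].T  # (T, N)
                    X.append(block)
                    ctx_labels.extend([ctx] * len(block))
                    side_labels.extend([side] * len(block))
                    groups.extend(np.arange(len(block)) % cfg.folds + 100 * (ci * 2 + si))
            X = np.vstack(X)
            for name, labels in (("context", ctx_labels), ("side", side_labels)):
                m = dec.LabeledPopulationMatrix(X, np.asarray(labels), np.asarray(groups))
                res = dec.permutation_null(
                    m, n_perm=n_perm, folds=cfg.folds, random_state=cfg.seed
                )
                rows.append(
                    {"variable": name, "accuracy": res.accuracy,
                     "null_mean": float(res.null_accuracies.mean()),
                     "p": res.p, "n_rows": res.n_rows, "n_classes": res.n_classes}
                )
        if rows:
            _write_df(pd.DataFrame(rows), self.out / "decoding_results.csv")
            self.artifacts["decoding"] = rows

    # -- driver --------------------------------------------------------------

    STAGE_DEPS = {
        "events": (),
        "peth": ("events",),
        "geometry": ("events", "peth"),
        "encoding": ("events",),
        "phase": ("events",),
        "decode": ("events", "peth", "geometry"),
    }

    def run(self, stages: tuple[str, ...] = ALL_STAGES) -> dict:
        wanted = list(ALL_STAGES) if "all" in stages else list(stages)
        done: set[str] = set()

        def ensure(stage: str) -> None:
            if stage in done:
                return
            for dep in self.STAGE_DEPS[stage]:
                ensure(dep)
            getattr(self, f"run_{stage}")()
            done.add(stage)

        t0 = time.time()
        for stage in wanted:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            ensure(stage)
        manifest = {
            "stages": sorted(done),
            "config_hash": self.cfg.config_hash(),
            "config": self.cfg.to_dict(),
            "seed": self.cfg.seed,
            "n_units": self.bundle.n_units,
            "n_trials": len(self.bundle.trials),
        }
        (self.out / "pipeline_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return {"elapsed_s": time.time() - t0, "stages": sorted(done)}


def run_pipeline(
    session_dir: str | Path,
    cfg: AnalysisConfig | None = None,
    stages: tuple[str, ...] = ("all",),
    out_dir: str | Path | None = None,
) -> dict:
    """Load a session directory and run the requested stages."""
    session_dir = Path(session_dir)
    bundle = load_session(session_dir)
    out = Path(out_dir) if out_dir else session_dir / "results"
    pipe = SessionPipeline(bundle, cfg, out)
    return pipe.run(tuple(stages))
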