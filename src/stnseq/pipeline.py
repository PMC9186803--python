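"""Reproducible simulate -> fit -> spectral -> stats -> coherence runs.

A run is driven by a plain-dict (or YAML) config with sections ``task``,
``agent``, ``neural``, ``spectral``, ``stats`` and ``connectivity``.  Every
stochastic stage derives its seed deterministically from the global seed and
the stage name, so rerunning a config is bit-identical; a manifest records
the config hash, per-stage seeds and the checksum of every artifact.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .accumulators import AccumulatorParams, commitment_regression, select_model
from .bayes_norm import regressor_table
from .cluster_glm import (
    build_design,
    glm_cluster_test,
    group_cluster_test,
    same_different_contrast,
)
from .connectivity import carryover_pairs, debiased_wpli, sliding_cross_spectra, time_resolved_coherence
from .io import (
    load_recording,
    read_trials_csv,
    save_recording,
    write_fits_json,
    write_trials_csv,
)
from .spectral import continuous_band_power, epoch_power, highpass_power
from .synth import AgentSpec, NeuralSimSpec, simulate_behavior, simulate_recording
from .task import TaskConfig, summarize_behavior

__all__ = ["DEFAULT_CONFIG", "derive_seed", "load_config", "run_pipeline", "STAGES"]

DEFAULT_CONFIG: dict = {
    "n_trials": 200,
    "n_subjects": 1,
    "task": {"validity": 0.7, "max_cues": 10},
    "agent": {
        "model_id": "M1",
        "lam": 0.0,
        "omega": 0.0,
        "stop_rule": "threshold",
        "threshold": 3.0,
    },
    "neural": {},  # NeuralSimSpec field overrides
    "spectral": {"band": "beta", "mode": "center"},
    "stats": {"n_perm": 500, "cluster_alpha": 0.05, "alpha": 0.05},
    "connectivity": {"enabled": True, "n_perm": 300},
}

STAGES = (
    "behavior",
    "fits",
    "regressors",
    "recording",
    "bandpower",
    "glm",
    "contrast",
    "coherence",
)


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (stable across runs and platforms)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _task(cfg) -> TaskConfig:
    return TaskConfig(**cfg["task"])


def _agent(cfg) -> AgentSpec:
    a = dict(cfg["agent"])
    params = AccumulatorParams(
        model_id=a.pop("model_id", "M1"), lam=a.pop("lam", 0.0), omega=a.pop("omega", 0.0)
    )
    return AgentSpec(params=params, **a)


def _winning_params(outdir: Path) -> AccumulatorParams:
    fits = json.loads((outdir / "fits.json").read_text())
    best = fits[0]["params"]
    return AccumulatorParams(model_id=best["model_id"], lam=best["lam"], omega=best["omega"])


def run_pipeline(
    config,
    seed: int,
    outdir: str | Path,
    *,
    stages=STAGES,
    resume: bool = False,
) -> dict:
    """Execute the requested stages for every synthetic subject.

    Returns the manifest dict (also written to ``manifest.json``).  With
    ``resume=True`` a stage whose outputs already exist is skipped, making
    partial runs restartable per stage.
    """
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    task = _task(cfg)
    stats_cfg = cfg["stats"]
    n_subjects = int(cfg["n_subjects"])
    timings: dict[str, float] = {}
    stage_seeds: dict[str, int] = {}

    subject_dirs = [outdir / f"subj{s + 1:02d}" for s in range(n_subjects)]
    subject_traces = []

    for s, sdir in enumerate(subject_dirs):
        sdir.mkdir(exist_ok=True)
        tag = f"subj{s + 1:02d}"

        def want(stage, *outputs):
            if stage not in stages:
                return False
            if resume and all((sdir / o).exists() for o in outputs):
                return False
            return True

        t0 = time.perf_counter()
        if want("behavior", "behavior.csv"):
            sd = derive_seed(seed, f"{tag}:behavior")
            stage_seeds[f"{tag}:behavior"] = sd
            trials = simulate_behavior(task, _agent(cfg), int(cfg["n_trials"]), sd)
            write_trials_csv(trials, sdir / "behavior.csv")
            summ = summarize_behavior(trials, task)
            (sdir / "behavior_summary.json").write_text(
                json.dumps(
                    {
                        "accuracy": summ.accuracy,
                        "ideal_accuracy": summ.ideal_accuracy,
                        "mean_n_sampled": summ.mean_n_sampled,
                        "mean_rt": summ.mean_rt,
                        "frac_same_end": summ.frac_same_end,
                        "n_trials": summ.n_trials,
                        "n_incomplete": summ.n_incomplete,
                    },
                    indent=1,
                )
            )
        timings[f"{tag}:behavior"] = time.perf_counter() - t0

        needs_trials = any(st in stages for st in ("fits", "regressors"))
        trials = read_trials_csv(sdir / "behavior.csv") if needs_trials else None

        t0 = time.perf_counter()
        if want("fits", "fits.json"):
            fits = select_model(trials)
            write_fits_json(fits, sdir / "fits.json")
            commit = commitment_regression(trials)
            (sdir / "commitment.json").write_text(
                json.dumps(
                    {
                        "coef_evidence": commit.coef_evidence,
                        "coef_same": commit.coef_same,
                        "p_evidence": commit.p_evidence,
                        "p_same": commit.p_same,
                        "classification": commit.classification,
                        "separation": commit.separation,
                    },
                    indent=1,
                )
            )
        timings[f"{tag}:fits"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        if want("regressors", "regressors.csv"):
            params = _winning_params(sdir)
            reg = regressor_table(trials, params, task.validity)
            reg.to_csv(sdir / "regressors.csv", index=False)
        timings[f"{tag}:regressors"] = time.perf_counter() - t0

        needs_reg = any(
            st in stages for st in ("recording", "glm", "contrast", "coherence")
        )
        reg = pd.read_csv(sdir / "regressors.csv") if needs_reg else None

        t0 = time.perf_counter()
        if want("recording", "recording.f32"):
            sd = derive_seed(seed, f"{tag}:recording")
            stage_seeds[f"{tag}:recording"] = sd
            spec = NeuralSimSpec(soa=task.soa, **cfg["neural"])
            rec = simulate_recording(trials, reg, spec, sd)
            save_recording(rec, sdir / "recording.f32")
        timings[f"{tag}:recording"] = time.perf_counter() - t0

        needs_power = any(st in stages for st in ("bandpower", "glm", "contrast"))
        if needs_power:
            rec = load_recording(sdir / "recording.f32")
            sp = cfg["spectral"]
            pts = continuous_band_power(rec, sp.get("band", "beta"), mode=sp.get("mode", "center"))
            pts = highpass_power(pts)
            epochs = epoch_power(pts, rec.markers, channel="stn")

        t0 = time.perf_counter()
        if want("bandpower", "band_power_epochs.csv"):
            df = pd.DataFrame(
                epochs.data, columns=[f"t{int(round(t * 1000)):+d}ms" for t in epochs.times]
            )
            pd.concat([epochs.info.reset_index(drop=True), df], axis=1).to_csv(
                sdir / "band_power_epochs.csv", index=False
            )
        timings[f"{tag}:bandpower"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        if want("glm", "glm_clusters.json"):
            sd = derive_seed(seed, f"{tag}:glm")
            stage_seeds[f"{tag}:glm"] = sd
            Y, X, names = build_design(epochs, reg)
            out = {}
            for j, name in enumerate(names):
                res = glm_cluster_test(
                    Y, X, j,
                    n_perm=int(stats_cfg["n_perm"]),
                    cluster_alpha=float(stats_cfg["cluster_alpha"]),
                    rng=np.random.default_rng(sd + j),
                    names=names,
                )
                out[name] = res.to_dict(times=epochs.times)
            (sdir / "glm_clusters.json").write_text(json.dumps(out, indent=1))
        timings[f"{tag}:glm"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        if want("contrast", "contrast.json"):
            sd = derive_seed(seed, f"{tag}:contrast")
            stage_seeds[f"{tag}:contrast"] = sd
            res = same_different_contrast(
                epochs, reg,
                n_perm=int(stats_cfg["n_perm"]),
                cluster_alpha=float(stats_cfg["cluster_alpha"]),
                rng=sd,
            )
            (sdir / "contrast.json").write_text(
                json.dumps(res.cluster.to_dict(times=res.times), indent=1)
            )
            pd.DataFrame(
                {
                    "time_s": res.times,
                    "difference": res.difference,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                }
            ).to_csv(sdir / "contrast_trace.csv", index=False)
            subject_traces.append(res.difference)
        timings[f"{tag}:contrast"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        if cfg["connectivity"].get("enabled", True) and want("coherence", "coherence.json"):
            sd = derive_seed(seed, f"{tag}:coherence")
            stage_seeds[f"{tag}:coherence"] = sd
            rec = load_recording(sdir / "recording.f32")
            cs = sliding_cross_spectra(rec)
            paired = carryover_pairs(cs, reg)
            labels = paired.info["condition_different"].to_numpy()
            n_perm_c = int(cfg["connectivity"].get("n_perm", 300))
            coh = time_resolved_coherence(paired, labels, n_perm=n_perm_c, rng=sd)
            dw = debiased_wpli(paired, labels, n_perm=n_perm_c, rng=sd + 1)
            payload = {
                "coherence": coh.cluster.to_dict(),
                "dwpli": dw.cluster.to_dict(),
                "n_epochs": coh.n_epochs,
                "freqs": list(map(float, coh.freqs)),
                "times_s": list(map(float, coh.times)),
            }
            (sdir / "coherence.json").write_text(json.dumps(payload, indent=1))
            for nm, grid in (("coherence", coh), ("dwpli", dw)):
                rows = []
                for cond, arr in grid.per_condition.items():
                    t_idx, f_idx = np.meshgrid(
                        np.arange(len(grid.times)), np.arange(len(grid.freqs)), indexing="ij"
                    )
                    rows.append(
                        pd.DataFrame(
                            {
                                "condition": cond,
                                "time_s": grid.times[t_idx.ravel()],
                                "freq_hz": grid.freqs[f_idx.ravel()],
                                "value": np.asarray(arr).ravel(),
                            }
                        )
                    )
                pd.concat(rows).to_csv(sdir / f"{nm}_grid.csv", index=False)
        timings[f"{tag}:coherence"] = time.perf_counter() - t0

    if n_subjects > 1 and len(subject_traces) == n_subjects and "contrast" in stages:
        sd = derive_seed(seed, "group:contrast")
        stage_seeds["group:contrast"] = sd
        res = group_cluster_test(
            np.asarray(subject_traces), n_perm=int(stats_cfg["n_perm"]), rng=sd
        )
        (outdir / "group_contrast.json").write_text(json.dumps(res.to_dict(), indent=1))

    artifacts = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "seed": int(seed),
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "stage_seeds": stage_seeds,
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "artifacts": artifacts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
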