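"""Deterministic end-to-end orchestration of the analysis stages.

A single top-level seed is expanded into independent per-stage streams so
each stage is reproducible regardless of execution order.  The manifest
records the configuration, seeds, and a hash of every written artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .design import StudyDesign, EffectSpec
from .synth import gen_behavior, gen_pupil_est, gen_plrt, gen_meg
from .pupil_preprocess import CleanConfig, preprocess_session
from .plr_metrics import extract_plr
from .artifact_interp import ArtifactConfig, clean_session
from .spectral import SpectralConfig, fft_power, group_average
from .mixed_models import fit_mixed, odds_ratio
from .cbpt import PermScheme, cbpt_paired

log = logging.getLogger("phasicvns")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "phasicvns_run"
    seed: int = 0
    design: StudyDesign = field(default_factory=lambda: StudyDesign(n_subjects=8, n_blocks_est=1))
    effects: EffectSpec = field(default_factory=EffectSpec)
    clean: CleanConfig = field(default_factory=CleanConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    n_perm: int = 500
    stages: tuple = ("simulate", "behavior", "pupil", "plr", "meg")


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages in dependency order; returns the manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cfg.seed, "stages": {}, "outputs": {},
                "design": asdict(cfg.design), "effects": cfg.effects.to_dict()}
    results: dict = {}

    if "simulate" in cfg.stages or "behavior" in cfg.stages:
        behavior = gen_behavior(cfg.design, cfg.effects,
                                _stage_seed(cfg.seed, "behavior"))
        pio.write_tsv(behavior, out / "behavior.tsv")
        manifest["stages"]["simulate_behavior"] = {"n_trials": len(behavior)}

    if "behavior" in cfg.stages:
        behavior["intensity_c"] = behavior["intensity_ma"] - behavior["intensity_ma"].mean()
        fit = fit_mixed(
            behavior,
            "correct ~ trial + face + intensity_c + stimulation * congruency",
            groups="subject", re_formula="1", family="binomial")
        coefs = {k: {"beta": float(v), "or": odds_ratio(float(v))}
                 for k, v in fit.params.items()}
        pio.write_json({"coefficients": coefs, "converged": fit.converged,
                        "loglik": fit.loglik}, out / "behavior_fit.json")
        results["behavior"] = coefs
        manifest["stages"]["behavior"] = {"converged": fit.converged}
        log.info("behavior GLMM: congruency OR=%.2f",
                 coefs.get("congruency", {}).get("or", float("nan")))

    if "pupil" in cfg.stages:
        sim = gen_pupil_est(cfg.design, cfg.effects, _stage_seed(cfg.seed, "pupil"))
        per_subj = {}
        n_rej = 0
        for (subj, stim), trace in sim.traces.items():
            ev = sim.events.query("subject == @subj and stimulation == @stim")
            eps, report = preprocess_session(trace, ev, cfg.clean.epoch_est_s, cfg.clean)
            n_rej += report["n_rejected_missing"]
            per_subj.setdefault(subj, {})[stim] = np.nanmean(eps.data, axis=0)
        subs = sorted(per_subj)
        a = np.array([per_subj[s][1] for s in subs])
        b = np.array([per_subj[s][0] for s in subs])
        clusters = cbpt_paired(a, b, PermScheme(n_perm=cfg.n_perm,
                                                seed=_stage_seed(cfg.seed, "pupil-perm")))
        pio.clusters_to_json(clusters, out / "pupil_est_clusters.json")
        results["pupil_clusters"] = clusters
        manifest["stages"]["pupil"] = {"n_rejected": n_rej,
                                       "n_clusters": len(clusters)}

    if "plr" in cfg.stages:
        sim = gen_plrt(cfg.design, cfg.effects, _stage_seed(cfg.seed, "plr"))
        rows = []
        for (subj, stim), trace in sim.traces.items():
            ev = sim.events.query("subject == @subj and stimulation == @stim")
            eps, _ = preprocess_session(trace, ev, cfg.clean.epoch_plrt_s, cfg.clean)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                avg = np.nanmean(eps.data, axis=0)
            try:
                m = extract_plr(eps.times, avg)
            except Exception as exc:
                log.warning("PLR extraction failed for subject %s/%s: %s",
                            subj, stim, exc)
                continue
            rows.append({"subject": subj, "stimulation": stim} | m.as_dict())
        metrics = pd.DataFrame(rows)
        pio.write_tsv(metrics, out / "plr_metrics.tsv")
        results["plr_metrics"] = metrics
        lat = metrics.groupby("stimulation")["onset_latency_ms"].mean()
        manifest["stages"]["plr"] = {"latency_sham_ms": float(lat.get(0, np.nan)),
                                     "latency_tavns_ms": float(lat.get(1, np.nan))}
        log.info("PLR onset latency sham=%.1f ms, taVNS=%.1f ms",
                 lat.get(0, np.nan), lat.get(1, np.nan))

    if "meg" in cfg.stages:
        sim = gen_meg(cfg.design, cfg.effects, _stage_seed(cfg.seed, "meg"))
        scfg = SpectralConfig()
        per_subj: dict = {}
        for (subj, stim), sig in sim.signals.items():
            ev = sim.events.query("subject == @subj and stimulation == @stim")
            eps = clean_session(sig, ev, cfg.artifact)
            power = fft_power(eps, scfg)      # (ch, trial, freq)
            keep = eps.retained()
            for grp in ("fm", "om"):
                names = [c for c in eps.channels if c.startswith(grp)]
                gp = group_average(power, eps.channels, names)[keep].mean(axis=0)
                per_subj.setdefault(grp, {}).setdefault(subj, {})[stim] = gp
        spec_clusters = {}
        for grp, subj_map in per_subj.items():
            subs = sorted(subj_map)
            a = np.array([subj_map[s][1] for s in subs])
            b = np.array([subj_map[s][0] for s in subs])
            cl = cbpt_paired(a, b, PermScheme(n_perm=cfg.n_perm,
                                              seed=_stage_seed(cfg.seed, f"meg-{grp}")))
            pio.clusters_to_json(cl, out / f"meg_{grp}_clusters.json")
            spec_clusters[grp] = cl
        results["meg_clusters"] = spec_clusters
        manifest["stages"]["meg"] = {g: len(c) for g, c in spec_clusters.items()}

    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _hash_file(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["manifest"] = manifest
    return results
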