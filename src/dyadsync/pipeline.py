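"""End-to-end orchestration: simulate -> score -> fit -> report.

A run is described by a :class:`RunConfig` (YAML-serializable nested
dict).  ``run_pipeline`` executes the stages in dependency order into a
run directory, records a manifest (stage outputs, SHA-256 hashes, seeds,
package version) and reuses cached stage outputs on re-runs when both
the stage configuration and the recorded file hashes still match; a file
that no longer matches its manifest hash aborts the run rather than
silently propagating a corrupted intermediate.  ``report`` renders the
run's tables to markdown.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .behaviour import (descriptive_stats, fit_ce_model, fit_rt_ce_model,
                        fit_rt_model)
from .fnirs import default_montage, first_level
from .inference import (contrast_marginal, fit_difference_model,
                        fit_multivariate_model, hbo_hbr_difference)
from .pose import dyad_similarity
from .synthetic import (BehaviourParams, MotionParams, generate_behaviour,
                        generate_dyad_motion, generate_task_schedule,
                        simulate_fnirs_cohort)

__all__ = ["RunConfig", "run_pipeline", "report", "StageError"]

log = logging.getLogger("dyadsync")

STAGES = ("schedule", "similarity", "behaviour", "behaviour_fits",
          "fnirs_first_level", "group_inference")


class StageError(RuntimeError):
    """A pipeline stage failed or found a corrupted cached intermediate."""


@dataclasses.dataclass
class RunConfig:
    """Full pipeline configuration with per-stage sections.

    Every stochastic stage derives its seed from ``seed`` plus a fixed
    stage offset, so one integer reproduces the whole run.
    """

    seed: int = 0
    stages: tuple = STAGES
    n_blocks: int = 20
    motion: dict = dataclasses.field(default_factory=lambda: dict(
        n_dyads=3, duration_s=60.0))
    behaviour: dict = dataclasses.field(default_factory=lambda: dict(
        n_per_group=12))
    fnirs: dict = dataclasses.field(default_factory=lambda: dict(
        n_per_group=6, long_per_roi=1, n_short=2))
    sampler: dict = dataclasses.field(default_factory=lambda: dict(
        n_draws=1000))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _cfg_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


class _Runner:
    def __init__(self, config: RunConfig, out_dir):
        self.cfg = config
        self.dir = Path(out_dir)
        self.dir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.dir / "manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"version": __version__, "stages": {}}

    def _save_manifest(self):
        self.manifest["version"] = __version__
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def cached(self, stage: str, cfg_piece) -> bool:
        entry = self.manifest["stages"].get(stage)
        if entry is None or entry.get("config_hash") != _cfg_hash(cfg_piece):
            return False
        for rel, digest in entry["files"].items():
            p = self.dir / rel
            if not p.exists():
                return False
            if _sha256(p) != digest:
                raise StageError(
                    f"stage '{stage}': cached output {rel} does not match "
                    "its manifest hash (corrupted intermediate)")
        log.info("stage %s: cached outputs reused", stage)
        return True

    def record(self, stage: str, cfg_piece, files: dict, seed: int):
        self.manifest["stages"][stage] = {
            "config_hash": _cfg_hash(cfg_piece),
            "seed": seed,
            "files": {rel: _sha256(self.dir / rel) for rel in files},
        }
        self._save_manifest()

    def read(self, rel: str) -> pd.DataFrame:
        p = self.dir / rel
        if not p.exists():
            raise StageError(f"missing upstream output: {rel}")
        entry = None
        for st in self.manifest["stages"].values():
            if rel in st["files"]:
                entry = st["files"][rel]
        if entry is not None and _sha256(p) != entry:
            raise StageError(f"{rel} does not match its manifest hash "
                             "(corrupted intermediate)")
        return pd.read_csv(p)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the configured stages into ``out_dir``; returns the path.

    Stage outputs (all CSV/JSON) land in the run directory and are listed
    in ``manifest.json``.  A failing stage halts downstream stages with a
    :class:`StageError` naming the stage.
    """
    r = _Runner(config, out_dir)
    cfg = config
    (r.dir / "config.yaml").write_text(
        yaml.safe_dump(cfg.to_dict(), sort_keys=True))

    if "schedule" in cfg.stages:
        piece = dict(seed=cfg.seed, n_blocks=cfg.n_blocks)
        if not r.cached("schedule", piece):
            sched = generate_task_schedule(cfg.seed, n_blocks=cfg.n_blocks)
            _write_csv(sched.trials, r.dir / "schedule_trials.csv")
            _write_csv(sched.blocks, r.dir / "schedule_blocks.csv")
            r.record("schedule", piece,
                     {"schedule_trials.csv": 0, "schedule_blocks.csv": 0},
                     cfg.seed)

    if "similarity" in cfg.stages:
        piece = dict(seed=cfg.seed, **cfg.motion)
        if not r.cached("similarity", piece):
            rows = []
            for regime in ("synchronized", "control"):
                for d in range(int(cfg.motion["n_dyads"])):
                    mp = MotionParams(
                        regime=regime,
                        duration_s=float(cfg.motion["duration_s"]),
                        seed=cfg.seed * 1000 + d
                        + (0 if regime == "synchronized" else 500))
                    a, b = generate_dyad_motion(mp)
                    tr = dyad_similarity(a, b)
                    rows.append(dict(regime=regime, dyad=d, mean=tr.mean,
                                     sd=tr.sd, n_frames=tr.n_frames))
            _write_csv(pd.DataFrame(rows), r.dir / "similarity.csv")
            r.record("similarity", piece, {"similarity.csv": 0}, cfg.seed)

    sched = None

    def need_schedule():
        nonlocal sched
        if sched is None:
            sched = generate_task_schedule(cfg.seed, n_blocks=cfg.n_blocks)
        return sched

    if "behaviour" in cfg.stages:
        piece = dict(seed=cfg.seed, n_blocks=cfg.n_blocks, **cfg.behaviour)
        if not r.cached("behaviour", piece):
            bp = BehaviourParams(n_per_group=int(cfg.behaviour["n_per_group"]),
                                 seed=cfg.seed + 1)
            trials = generate_behaviour(bp, need_schedule())
            _write_csv(trials, r.dir / "trials.csv")
            r.record("behaviour", piece, {"trials.csv": 0}, cfg.seed + 1)

    if "behaviour_fits" in cfg.stages:
        piece = dict(seed=cfg.seed, sampler=cfg.sampler)
        if not r.cached("behaviour_fits", piece):
            trials = r.read("trials.csv")
            nd = int(cfg.sampler["n_draws"])
            frames = []
            for name, fitter in (("rt", fit_rt_model), ("ce", fit_ce_model),
                                 ("rtce", fit_rt_ce_model)):
                res = fitter(trials, n_draws=nd, seed=cfg.seed + 2)
                eff = res.effects_frame()
                eff.insert(0, "model", name)
                frames.append(eff)
            _write_csv(pd.concat(frames, ignore_index=True),
                       r.dir / "behaviour_effects.csv")
            desc = descriptive_stats(trials)
            _write_csv(desc["reaction_times"], r.dir / "descriptives_rt.csv")
            _write_csv(desc["commission_errors"],
                       r.dir / "descriptives_ce.csv")
            r.record("behaviour_fits", piece,
                     {"behaviour_effects.csv": 0, "descriptives_rt.csv": 0,
                      "descriptives_ce.csv": 0}, cfg.seed + 2)

    if "fnirs_first_level" in cfg.stages:
        piece = dict(seed=cfg.seed, n_blocks=cfg.n_blocks, **cfg.fnirs)
        if not r.cached("fnirs_first_level", piece):
            mont = default_montage(int(cfg.fnirs["long_per_roi"]),
                                   int(cfg.fnirs["n_short"]))
            rows = []
            for pid, group, raw, _truth in simulate_fnirs_cohort(
                    int(cfg.fnirs["n_per_group"]), need_schedule(), mont,
                    seed=cfg.seed + 3):
                _, roi = first_level(raw)
                roi["participant_id"] = pid
                roi["group"] = group
                rows.append(roi)
            _write_csv(pd.concat(rows, ignore_index=True),
                       r.dir / "roi_estimates.csv")
            r.record("fnirs_first_level", piece, {"roi_estimates.csv": 0},
                     cfg.seed + 3)

    if "group_inference" in cfg.stages:
        piece = dict(seed=cfg.seed, sampler=cfg.sampler)
        if not r.cached("group_inference", piece):
            roi_est = r.read("roi_estimates.csv")
            nd = int(cfg.sampler["n_draws"])
            mv = fit_multivariate_model(roi_est, n_draws=nd,
                                        seed=cfg.seed + 4)
            parts = [contrast_marginal(mv, "allgo_minus_mixed"),
                     contrast_marginal(mv, "control_minus_synchronized")]
            diffs = hbo_hbr_difference(roi_est)
            dm = fit_difference_model(diffs, filter="negative_only",
                                      n_draws=nd, seed=cfg.seed + 5)
            parts += [contrast_marginal(dm, "allgo_minus_mixed"),
                      contrast_marginal(dm, "control_minus_synchronized")]
            _write_csv(pd.concat(parts, ignore_index=True),
                       r.dir / "contrasts.csv")
            _write_csv(diffs, r.dir / "hbo_hbr_difference.csv")
            r.record("group_inference", piece,
                     {"contrasts.csv": 0, "hbo_hbr_difference.csv": 0},
                     cfg.seed + 4)

    return r.dir


def _md_table(df: pd.DataFrame, floatfmt="%.3f") -> str:
    df = df.copy()
    for c in df.columns:
        if pd.api.types.is_float_dtype(df[c]):
            df[c] = df[c].map(lambda v: floatfmt % v)
    header = "| " + " | ".join(map(str, df.columns)) + " |"
    sep = "|" + "|".join("---" for _ in df.columns) + "|"
    body = "\n".join("| " + " | ".join(map(str, row)) + " |"
                     for row in df.itertuples(index=False))
    return "\n".join([header, sep, body])


def report(run_dir) -> str:
    """Render a completed run to markdown (also written to report.md).

    Sections whose stage output is missing are replaced by a notice
    rather than failing the whole report; an empty or non-run directory
    raises.
    """
    run_dir = Path(run_dir)
    if not (run_dir / "manifest.json").exists():
        raise ValueError(f"{run_dir} is not a completed run directory")
    parts = [f"# dyadsync run report\n\nrun directory: `{run_dir}`\n"]

    def section(title, rel, render):
        p = run_dir / rel
        parts.append(f"\n## {title}\n")
        if not p.exists():
            parts.append(f"_section omitted: missing {rel}_\n")
            return
        parts.append(render(pd.read_csv(p)))
        parts.append("\n")

    section("Movement similarity (manipulation check)", "similarity.csv",
            lambda df: _md_table(
                df.groupby("regime")["mean"]
                .agg(mean_similarity="mean", sd="std", n_dyads="size")
                .reset_index()))
    section("Behavioural descriptives: reaction times (ms)",
            "descriptives_rt.csv", _md_table)
    section("Behavioural descriptives: commission errors",
            "descriptives_ce.csv", _md_table)
    section("Behavioural model effects", "behaviour_effects.csv", _md_table)
    section("Haemodynamic contrasts", "contrasts.csv", _md_table)
    section("HbO-HbR difference classes", "hbo_hbr_difference.csv",
            lambda df: _md_table(
                df.groupby(["roi", "condition"])["corr_class"]
                .apply(lambda s: (s == "negative").mean())
                .rename("negative_fraction").reset_index()))
    text = "".join(parts)
    (run_dir / "report.md").write_text(text)
    return text
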