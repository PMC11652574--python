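"""End-to-end orchestration: simulate → fuse → describe → timelock → dwell →
shiftfun → infer, with a manifest recording seeds and parameters.

Every stage writes plain CSV/JSON artifacts; every figure rendered by
:func:`render_report` is backed by a CSV written here, so no number exists
only in a figure. Stages are individually skippable and reruns with an
identical configuration produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import describe_dataset, read_dataset, write_dataset
from .episode_stats import dwell_table, group_dwell_summary
from .errors import DyadGazeError
from .fusion import fuse_session
from .inference import evaluate_all_models
from .robust_stats import shift_function
from .synthetic import GeneratorConfig, generate_dataset
from .timelock import extract_onsets, timelock_proportions

log = logging.getLogger("dyadgaze")

ALL_STAGES = ("simulate", "fuse", "describe", "timelock", "dwell", "shiftfun", "infer")

#: default onset-locked analyses: all four own actions plus the partner's
DEFAULT_TIMELOCK = tuple(
    [("action", t, "own") for t in ("grab", "place", "remove", "drop")]
    + [("action", t, "other") for t in ("grab", "place", "remove", "drop")]
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run; round-trips through YAML."""

    out_dir: str = "artifacts"
    in_dir: str | None = None  # read sessions from here instead of simulating
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 1
    nboot: int = 2000
    alpha: float = 0.05
    ci_method: str = "normal"
    timelock_events: tuple = DEFAULT_TIMELOCK
    dwell_aoi: str = "face"
    dwell_stream: str = "gesture"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = self.generator.to_dict()
        d["stages"] = list(self.stages)
        d["timelock_events"] = [list(e) for e in self.timelock_events]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "timelock_events" in d:
            d["timelock_events"] = tuple(tuple(e) for e in d["timelock_events"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as f:
            return cls.from_dict(yaml.safe_load(f))


def _params_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the artifact directory.

    A failing stage aborts with the stage named; artifacts of completed
    stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise DyadGazeError(f"unknown stage(s) {sorted(unknown)}")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "generator_seed": config.generator.seed,
        "params_hash": _params_hash(config),
        "stages": list(stages),
        "completed": [],
    }
    config.to_yaml(out / "config.yaml")

    sessions = None
    fused = None
    stage = None
    try:
        if "simulate" in stages:
            stage = "simulate"
            log.info("stage simulate: %d dyads", config.generator.n_dyads)
            gen = dataclasses.replace(config.generator)
            sessions = generate_dataset(gen)
            write_dataset(sessions, out / "data")
        elif config.in_dir is not None:
            sessions = read_dataset(config.in_dir)

        def need_sessions():
            if sessions is None:
                raise DyadGazeError(
                    "no input data: enable the simulate stage or set in_dir"
                )
            return sessions

        def need_fused():
            nonlocal fused
            if fused is None:
                fused = [fuse_session(s) for s in need_sessions()]
            return fused

        if "fuse" in stages:
            stage = "fuse"
            log.info("stage fuse")
            frames = [ft.to_frame() for sess in need_fused() for ft in sess]
            pd.concat(frames, ignore_index=True).to_csv(
                out / "fused.csv", index=False, float_format="%.6f"
            )

        if "describe" in stages:
            stage = "describe"
            log.info("stage describe")
            describe_dataset(need_sessions()).to_csv(
                out / "descriptives.csv", float_format="%.6f"
            )

        if "timelock" in stages:
            stage = "timelock"
            log.info("stage timelock")
            flat = [ft for sess in need_fused() for ft in sess]
            frames = []
            for stream, event_type, source in config.timelock_events:
                onsets = extract_onsets(flat, stream, event_type, source)
                if len(onsets) == 0:
                    log.warning("no %s/%s onsets; skipped", stream, event_type)
                    continue
                curves = timelock_proportions(
                    onsets, ci_method=config.ci_method, alpha=config.alpha
                )
                frames.append(curves.to_frame())
            pd.concat(frames, ignore_index=True).to_csv(
                out / "timelock.csv", index=False, float_format="%.6f"
            )

        if "dwell" in stages:
            stage = "dwell"
            log.info("stage dwell")
            frames = []
            for source in ("own", "other"):
                frames.append(
                    dwell_table(
                        need_fused(),
                        target_aoi=config.dwell_aoi,
                        stream=config.dwell_stream,
                        source=source,
                    )
                )
            dwell = pd.concat(frames, ignore_index=True)
            dwell.to_csv(out / "dwell.csv", index=False, float_format="%.6f")
            summaries = []
            for source, grp in dwell.groupby("source"):
                s = group_dwell_summary(grp)
                s.insert(0, "source", source)
                summaries.append(s)
            pd.concat(summaries, ignore_index=True).to_csv(
                out / "dwell_summary.csv", index=False, float_format="%.6f"
            )

        if "shiftfun" in stages:
            stage = "shiftfun"
            log.info("stage shiftfun")
            dwell = dwell_table(
                need_fused(),
                target_aoi=config.dwell_aoi,
                stream=config.dwell_stream,
                source="own",
            )
            rows = []
            base = dwell[dwell["category"] == "none"]["mean"].dropna().to_numpy()
            for cat in ("ask", "point"):
                other = dwell[dwell["category"] == cat]["mean"].dropna().to_numpy()
                if len(other) < 5 or len(base) < 5:
                    log.warning("shiftfun %s vs none skipped: too few participants", cat)
                    continue
                res = shift_function(
                    base, other, nboot=config.nboot, alpha=config.alpha,
                    seed=config.seed,
                )
                frame = res.to_frame()
                frame.insert(0, "comparison", f"{cat}_vs_none")
                rows.append(frame)
            if rows:
                pd.concat(rows, ignore_index=True).to_csv(
                    out / "shiftfun.csv", index=False, float_format="%.6f"
                )

        if "infer" in stages:
            stage = "infer"
            log.info("stage infer: 6 models, leave-one-pair-out")
            results = evaluate_all_models(need_fused())
            frames = []
            summary = {}
            for name, res in results.items():
                sc = res.scores.copy()
                sc.insert(0, "model", name)
                frames.append(sc)
                summary[name] = {
                    "grand_mean": res.grand_mean,
                    "benchmark_grand_mean": res.benchmark_grand_mean,
                    "advantage": res.advantage,
                    "se": None if math.isnan(res.se) else res.se,
                    "n_pairs": res.n_pairs,
                }
            pd.concat(frames, ignore_index=True).to_csv(
                out / "inference.csv", index=False, float_format="%.6f"
            )
            (out / "summary.json").write_text(json.dumps(summary, indent=2))

        manifest["completed"] = [s for s in stages]
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise DyadGazeError(f"stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
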