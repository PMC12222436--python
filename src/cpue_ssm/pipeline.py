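"""End-to-end pipeline driver: simulate -> prepare -> fit -> summarize -> traits."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import inference, io, model, synthetic, traits
from .sampler import SamplerConfig

__all__ = ["run_pipeline", "demo_config"]

log = logging.getLogger("cpue_ssm")


def demo_config(reduced: bool = True) -> dict:
    """A self-contained demo: group-structured simulation + reduced sampler."""
    cfg: dict[str, Any] = {
        "simulate": {"preset": "group_structured"},
        "sampler": {
            "n_chains": 4,
            "n_warmup": 500 if reduced else 1000,
            "n_draws": 2000 if reduced else 100_000,
            "thin": 1 if reduced else 100,
        },
        "floor": 50.0,
        "traits": "example",
    }
    return cfg


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: Mapping, out_dir: str | Path, seed: int = 0) -> dict:
    """Execute all stages, writing artifacts and a manifest to ``out_dir``.

    ``config`` keys: ``simulate`` (preset or omitted when ``data_dir``
    points at existing CSVs), ``data_dir``, ``period4_starts``, ``floor``,
    ``sampler``, ``traits`` ("example", a CSV path, or absent).
    Any stage failure halts with a stage-labelled error; earlier outputs
    are preserved.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": int(seed),
        "config_hash": _config_hash(config),
        "stages": {},
        "outputs": {},
    }
    stage_t0 = time.perf_counter()

    def done(stage: str) -> None:
        nonlocal stage_t0
        dt = time.perf_counter() - stage_t0
        manifest["stages"][stage] = round(dt, 3)
        log.info("stage %s finished in %.2fs", stage, dt)
        stage_t0 = time.perf_counter()

    def fail(stage: str, exc: Exception) -> Exception:
        err = RuntimeError(f"pipeline stage {stage!r} failed: {exc}")
        err.__cause__ = exc
        return err

    period4_starts: dict[str, int] = dict(config.get("period4_starts", {}))

    # -- simulate / load ---------------------------------------------------
    try:
        if "simulate" in config:
            sim_spec = dict(config["simulate"])
            preset = sim_spec.pop("preset", "group_structured")
            if preset != "group_structured":
                raise ValueError(f"unknown simulation preset {preset!r}")
            sim_cfg = synthetic.group_structured_config(**sim_spec)
            syn = synthetic.simulate_community(sim_cfg, seed)
            panel = syn.panel
            period4_starts = dict(sim_cfg.period4_starts)
            data_dir = out_dir / "data"
            io.write_panel(panel, data_dir)
            (data_dir / "truth.json").write_text(syn.truth_json())
            panel = io.read_panel(data_dir)  # round-trip through the writers
            manifest["outputs"]["data"] = str(data_dir)
        else:
            data_dir = Path(config["data_dir"])
            panel = io.read_panel(data_dir)
    except Exception as exc:  # noqa: BLE001
        raise fail("simulate/load", exc)
    done("simulate/load")

    # -- preprocess --------------------------------------------------------
    try:
        unknown = [t for t in period4_starts if t not in panel.taxa]
        if unknown:
            raise ValueError(f"period scheme references unknown taxa {unknown}")
        prepared = model.prepare(
            panel, floor=float(config.get("floor", 50.0)), period4_starts=period4_starts
        )
    except Exception as exc:  # noqa: BLE001
        raise fail("preprocess", exc)
    done("preprocess")

    # -- fit ---------------------------------------------------------------
    try:
        sampler_cfg = SamplerConfig(**config.get("sampler", {}))
        post = inference.fit(prepared, sampler_config=sampler_cfg, seed=seed)
        post.save(out_dir / "posterior.npz")
        post.rhat_table.to_csv(out_dir / "rhat.csv", index=False)
        manifest["outputs"]["posterior"] = "posterior.npz"
        manifest["outputs"]["rhat"] = "rhat.csv"
        manifest["max_rhat"] = float(post.rhat_table["rhat"].max())
        manifest["converged"] = bool(post.converged)
    except Exception as exc:  # noqa: BLE001
        raise fail("fit", exc)
    done("fit")

    # -- summarize ---------------------------------------------------------
    try:
        growth = inference.derive_period_growth(post)
        community = inference.derive_community_growth(post)
        trajectories = inference.cpue_trajectory(post)
        growth.to_csv(out_dir / "growth_summary.csv", index=False)
        community.to_csv(out_dir / "community_summary.csv", index=False)
        trajectories.to_csv(out_dir / "trajectories.csv", index=False)
        manifest["outputs"].update(
            {
                "growth_summary": "growth_summary.csv",
                "community_summary": "community_summary.csv",
                "trajectories": "trajectories.csv",
            }
        )
        if config.get("plots", False):
            from . import plots

            plots.plot_trajectories(trajectories, out_dir / "trajectories.png")
            plots.plot_period_growth(growth, out_dir / "growth.png")
            plots.plot_climate_effects(post, out_dir / "climate.png")
    except Exception as exc:  # noqa: BLE001
        raise fail("summarize", exc)
    done("summarize")

    # -- traits ------------------------------------------------------------
    trait_spec = config.get("traits")
    if trait_spec:
        try:
            if trait_spec == "example":
                trait_table = traits.load_example_traits()
            else:
                trait_table = pd.read_csv(trait_spec)
            known = set(trait_table["taxon_id"])
            usable = [t for t in panel.taxa if t in known]
            if len(usable) == len(panel.taxa):
                groups = traits.assign_groups(growth)
                results = traits.compare_traits(trait_table, groups)
                results.to_csv(out_dir / "trait_results.csv", index=False)
                groups.to_frame().to_csv(out_dir / "groups.csv")
                manifest["outputs"]["trait_results"] = "trait_results.csv"
            else:
                manifest["outputs"]["trait_results"] = None
                log.warning("trait table does not cover all taxa; stage skipped")
        except Exception as exc:  # noqa: BLE001
            raise fail("traits", exc)
        done("traits")

    manifest["output_hashes"] = {
        name: _file_hash(out_dir / rel)
        for name, rel in manifest["outputs"].items()
        if rel and (out_dir / str(rel)).is_file()
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
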