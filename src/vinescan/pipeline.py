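"""End-to-end orchestration: simulate -> register -> filter -> volume -> report.

One flat YAML config with a section per stage drives a reproducible run; all
randomness flows from a single master seed split per stage.  Every stage
writes its artifact into the output directory and the run manifest records
the config snapshot, seeds, per-file checksums and record counts so that a
re-run with the same manifest reproduces identical outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alphashape import alpha_complex, select_alpha, volume_without_structures
from .filters import (FilterConfig, crop_batch, cut_below_height,
                      mask_training_structures, sor_filter, structure_masks)
from .io import PointCloud, write_cloud, write_nmea, write_scan_log
from .register import georeference
from .scene import SceneSpec, batch_truth, build_scene
from .simulate import SensorConfig, TrajectorySpec, simulate_run
from .stats import BatchRecord, anova, fits_by_group, records_to_frame

__all__ = ["ConfigError", "default_config", "load_config", "merge_with_defaults",
           "validate_config", "run_pipeline", "process_batches"]

log = logging.getLogger(__name__)

REQUIRED_SECTIONS = ("scene", "sensor", "trajectory", "filter", "alpha")


class ConfigError(ValueError):
    """A pipeline config is missing sections or holds invalid values."""


def default_config() -> dict:
    """The reference study conditions; override any subset via YAML."""
    return {
        "seed": 20180125,
        "origin_lla": [40.1333, -3.3667, 750.0],
        "scene": {},  # SceneSpec defaults
        "sensor": {},  # SensorConfig defaults
        "trajectory": {
            "speed": 0.5,
            "gnss_rate_hz": 10.0,
            "gnss_noise_sd": 0.02,
            "lead": 0.5,  # m of straight run before/after the row
        },
        "register": {"attitude": "travel", "heading_window": 21, "shear": [0.0, 0.0]},
        "filter": {"k_neighbors": 64, "nsigma": 1.0, "bud_height": 1.0,
                   "mask_margin": 0.05, "mask_wires": False},
        "alpha": {"candidates": [0.1, 0.3, 0.5, 0.7, 0.9],
                  "coverage_frac": 0.99, "fixed": None},
        "stats": {"biomass_cv": 0.10, "predictors": ["n_scans", "volume_total",
                                                     "volume_no_structures"],
                  "make_plots": True},
    }


def merge_with_defaults(user: dict) -> dict:
    """Validate required sections, then fill unset keys from the defaults."""
    validate_config(user)
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key] = {**cfg[key], **val}
        else:
            cfg[key] = val
    return cfg


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return merge_with_defaults(user)


def validate_config(cfg: dict) -> None:
    missing = [s for s in REQUIRED_SECTIONS if s not in cfg]
    if missing:
        raise ConfigError(f"config missing sections: {', '.join(missing)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def process_batches(cloud: PointCloud, scene, cfg: dict,
                    ) -> tuple[list[dict], list[PointCloud]]:
    """Filter + alpha-volume per batch; returns batch summaries + shoot clouds.

    Stage order: crop -> bud-height cut -> structure masking -> SOR ->
    alpha selection/volume.  The working alpha is selected on the shoot
    cloud; post/marker returns get their own complex at the same alpha and
    their volume is subtracted from the total, as in the field workflow.
    """
    fcfg = cfg["filter"]
    acfg = cfg["alpha"]
    masks = structure_masks(scene, margin=fcfg.get("mask_margin", 0.05),
                            include_wires=fcfg.get("mask_wires", False))
    FilterConfig(k_neighbors=fcfg["k_neighbors"], nsigma=fcfg["nsigma"],
                 bud_height=fcfg["bud_height"], masks=masks)  # validation
    summaries, shoot_clouds = [], []
    for batch in scene.batches:
        stage = {"batch": f"{batch.treatment}-{batch.plot}"}
        c0 = crop_batch(cloud, (batch.x0, batch.x1))
        stage["n_cropped"] = len(c0)
        c1 = cut_below_height(c0, fcfg["bud_height"])
        stage["n_above_buds"] = len(c1)
        shoots, structures = mask_training_structures(c1, masks)
        stage["n_structure_points"] = len(structures)
        if len(shoots) >= 2:
            shoots, removed = sor_filter(shoots, fcfg["k_neighbors"], fcfg["nsigma"])
        else:
            removed = 0
        stage["n_sor_removed"] = removed
        stage["n_shoot_points"] = len(shoots)

        if acfg.get("fixed"):
            alpha = float(acfg["fixed"])
            result = alpha_complex(shoots.points, alpha) if len(shoots) >= 4 else None
            sweep = {alpha: result} if result else {}
        elif len(shoots) >= 4:
            alpha, sweep = select_alpha(shoots.points, acfg["candidates"],
                                        acfg.get("coverage_frac", 0.99))
            result = sweep[alpha]
        else:
            alpha, sweep, result = float(acfg["candidates"][0]), {}, None
        v_shoots = result.volume if result else 0.0
        v_struct = (alpha_complex(structures.points, alpha).volume
                    if len(structures) >= 4 else 0.0)
        v_total = v_shoots + v_struct
        stage.update({
            "alpha": alpha,
            "volume_total": v_total,
            "volume_structures": v_struct,
            "volume_no_structures": volume_without_structures(v_total, v_struct),
            "n_components": result.n_components if result else 0,
            "coverage": result.coverage if result else 0.0,
            "n_scans": int(len(np.unique(shoots.scan_index))),
            "sweep": {f"{a:g}": {"volume": r.volume,
                                 "n_components": r.n_components,
                                 "coverage": r.coverage}
                      for a, r in sorted(sweep.items())},
        })
        summaries.append(stage)
        shoot_clouds.append(shoots)
    return summaries, shoot_clouds


def run_pipeline(config: dict | str | Path, out_dir: str | Path,
                 seed: int | None = None) -> Path:
    """Run every stage on a synthetic scene; returns the output directory."""
    cfg = (load_config(config) if isinstance(config, (str, Path))
           else merge_with_defaults(config))
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    s_scene, s_traj, s_bio = (int(s) % (2 ** 31)
                              for s in np.random.SeedSequence(seed).generate_state(3))

    scene = build_scene(SceneSpec(**cfg["scene"]), s_scene)
    sensor = SensorConfig(**cfg["sensor"])
    tcfg = dict(cfg["trajectory"])
    lead = float(tcfg.pop("lead", 0.5))
    x0, x1 = scene.x_extent
    traj = TrajectorySpec(row_length=(x1 - x0) + 2 * lead, start_x=x0 - lead,
                          seed=s_traj, **tcfg)
    origin_lla = tuple(cfg.get("origin_lla", (40.1333, -3.3667, 750.0)))

    log.info("simulating %d batches over %.1f m", len(scene.batches), x1 - x0)
    run = simulate_run(scene, sensor, traj, origin_lla)
    write_scan_log(run.frames, out / "scans.csv")
    write_nmea(run.sentences, out / "fixes.nmea")

    rcfg = cfg.get("register", {})
    cloud = georeference(run.frames, run.fixes, sensor,
                         attitude=rcfg.get("attitude", "travel"),
                         heading_window=rcfg.get("heading_window", 21),
                         shear=tuple(rcfg.get("shear", (0.0, 0.0))),
                         frame_labels=run.hit_tags)
    write_cloud(cloud, out / "cloud.ply")

    summaries, shoot_clouds = process_batches(cloud, scene, cfg)
    for s, sc in zip(summaries, shoot_clouds):
        write_cloud(sc, out / f"shoots_{s['batch']}.ply")

    truths = {(t.treatment, t.plot): t for t in batch_truth(scene)}
    bio_rng = np.random.default_rng(s_bio)
    cv = float(cfg.get("stats", {}).get("biomass_cv", 0.0))
    records = []
    for batch, s in zip(scene.batches, summaries):
        truth = truths[(batch.treatment, batch.plot)]
        biomass = truth.true_biomass * max(0.0, 1.0 + cv * bio_rng.standard_normal())
        records.append(BatchRecord(batch.treatment, batch.plot, s["n_scans"],
                                   s["n_shoot_points"], s["volume_total"],
                                   s["volume_no_structures"], biomass))
        s["true_shoot_volume"] = truth.true_shoot_volume
        s["biomass"] = biomass

    (out / "volume.json").write_text(json.dumps({"batches": summaries}, indent=2))
    report = _stats_report(records, cfg, out)
    (out / "report.json").write_text(json.dumps(report, indent=2))

    manifest = {
        "version": __version__,
        "seed": seed,
        "stage_seeds": {"scene": s_scene, "trajectory": s_traj, "biomass": s_bio},
        "config": cfg,
        "counts": {"frames": len(run.frames), "fixes": len(run.fixes),
                   "points": len(cloud),
                   "batches": len(scene.batches)},
        "checksums": {p.name: _sha256(p) for p in sorted(out.glob("*"))
                      if p.name != "manifest.json" and p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def _stats_report(records: list[BatchRecord], cfg: dict, out: Path) -> dict:
    """Pooled/per-treatment fits and ANOVA where the design allows them."""
    scfg = cfg.get("stats", {})
    report: dict = {"records": [asdict(r) for r in records]}
    df = records_to_frame(records)
    if len(df) < 3:
        report["note"] = "fewer than 3 batches: no regression layer"
        return report
    for predictor in scfg.get("predictors", ["volume_total"]):
        try:
            table = fits_by_group(records, predictor)
        except ValueError as exc:
            report[predictor] = {"error": str(exc)}
            continue
        table.to_csv(out / f"fits_{predictor}.csv", index=False)
        report[predictor] = {"fits": table.to_dict(orient="records")}
        if df["treatment"].nunique() >= 2:
            try:
                report[predictor]["anova"] = json.loads(
                    anova(records, predictor).to_json(orient="index"))
            except ValueError as exc:
                report[predictor]["anova_error"] = str(exc)
        if scfg.get("make_plots", False):
            _scatter(df, predictor, out / f"scatter_{predictor}.png")
    return report


def _scatter(df, predictor: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, sub in df.groupby("treatment"):
        ax.scatter(sub[predictor], sub["biomass"], label=str(label), s=22)
    ax.set_xlabel(predictor)
    ax.set_ylabel("dry biomass (kg)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
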