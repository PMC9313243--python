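"""End-to-end orchestration: simulate -> boundary map -> spots -> coloc -> stats.

A run is driven by one config (JSON or YAML) holding a top-level seed, the
per-module parameter blocks, and a group manifest (group label -> number of
scenes and ground-truth boundary fraction).  Every intermediate artifact is
written into the run directory together with the resolved config and a log;
rerunning the same config reproduces every output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .simulate import (CellNetworkSpec, ImagingSpec, SpotPlacementSpec,
                       make_scene, split_seed)
from .boundary_map import (predict_probability_map, ridge_probability_map,
                           sample_training_from_mask, train_pixel_classifier)
from .spots import detect_spots, refine_centroids
from .coloc import ColocConfig, colocalize, compare_groups

log = logging.getLogger("qdcoloc.pipeline")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "network": {},          # CellNetworkSpec overrides
    "imaging": {},          # ImagingSpec overrides
    "placement": {},        # SpotPlacementSpec overrides (f_boundary set per group)
    "boundary_method": "ridge",       # or "classifier"
    "classifier": {"n_per_class": 2000, "n_estimators": 50},
    "detection": {"detection_threshold": 5.0, "min_separation_px": 5.0,
                  "window_radius_px": 5},
    "coloc": {},            # ColocConfig overrides
    "groups": {"QD-MEL": {"n_images": 3, "f_boundary": 0.3},
               "QD-MEL+RAM": {"n_images": 3, "f_boundary": 0.85}},
    "comparison": {"n_permutations": 9999, "units": ["image", "spot"]},
}

FIG4_DEMO = DEFAULT_CONFIG  # groups above emulate conjugate alone vs +agonist


def load_config(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    cfg = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    return merge_config(cfg)


def merge_config(overrides: dict[str, Any] | None) -> dict[str, Any]:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict) and key != "groups":
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def config_hash(cfg: dict[str, Any]) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict[str, Any] | None = None,
                 out_dir: str | Path = "qdcoloc_run") -> Path:
    """Execute all stages and write ``report.json`` into the run directory."""
    cfg = merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(cfg, indent=2, sort_keys=True))
    chash = config_hash(cfg)
    seed = int(cfg["seed"])
    t0 = time.time()

    network = CellNetworkSpec(**{**cfg["network"], "rng_seed": 0})
    imaging = ImagingSpec(**{**cfg["imaging"], "rng_seed": 0})
    coloc_cfg = ColocConfig(**cfg["coloc"])
    det = cfg["detection"]

    classifier = None
    if cfg["boundary_method"] == "classifier":
        t = time.time()
        train_scene = make_scene(network, SpotPlacementSpec(**cfg["placement"]),
                                 imaging, seed=split_seed(seed, 9000))
        train = sample_training_from_mask(
            train_scene.boundary_channel, train_scene.boundary_mask,
            n_per_class=cfg["classifier"]["n_per_class"],
            rng_seed=split_seed(seed, 9001))
        classifier = train_pixel_classifier(
            train, n_estimators=cfg["classifier"]["n_estimators"],
            rng_seed=split_seed(seed, 9002))
        log.info("trained pixel classifier in %.1fs", time.time() - t)
    elif cfg["boundary_method"] != "ridge":
        raise ValueError(f"unknown boundary_method: {cfg['boundary_method']!r}")

    results_by_group: dict[str, list] = {}
    image_records = []
    for gi, (group, gcfg) in enumerate(cfg["groups"].items()):
        results_by_group[group] = []
        for i in range(int(gcfg["n_images"])):
            t = time.time()
            image_id = f"{group}_{i}"
            scene_seed = split_seed(seed, 100 * (gi + 1) + i)
            placement = SpotPlacementSpec(**{**cfg["placement"],
                                             "f_boundary": float(gcfg["f_boundary"])})
            scene = make_scene(network, placement, imaging, seed=scene_seed)
            img_dir = out / "images" / image_id
            scene.save(img_dir, prefix="scene")

            if classifier is not None:
                pmap = predict_probability_map(scene.boundary_channel,
                                               classifier, source_id=image_id)
            else:
                pmap = ridge_probability_map(scene.boundary_channel,
                                             source_id=image_id)
            pmap.save(img_dir / "boundary_probability.tif",
                      extra={"config_hash": chash, "version": __version__})

            cand = detect_spots(scene.qd_channel,
                                psf_sigma_px=imaging.psf_sigma_px,
                                detection_threshold=det["detection_threshold"],
                                min_separation_px=det["min_separation_px"],
                                source_id=image_id)
            refined = refine_centroids(scene.qd_channel, cand,
                                       window_radius_px=det["window_radius_px"])
            refined.save(img_dir / "spots.csv")

            result = colocalize(refined, pmap, coloc_cfg)
            result.to_json(img_dir / "coloc.json")
            results_by_group[group].append(result)
            image_records.append({
                "image_id": image_id, "group": group,
                "true_boundary_fraction": scene.true_boundary_fraction,
                "n_spots_true": len(scene.spots_truth),
                "n_spots_detected": len(refined),
                "boundary_fraction": result.boundary_fraction,
            })
            log.info("image %s: fraction=%.3f (%.1fs)", image_id,
                     result.boundary_fraction, time.time() - t)

    comparisons = []
    groups = list(results_by_group)
    comp_cfg = cfg["comparison"]
    for a, b in zip(groups[1:], groups[:1] * (len(groups) - 1)):
        for unit in comp_cfg.get("units", ["image"]):
            gc = compare_groups({a: results_by_group[a], b: results_by_group[b]},
                                n_permutations=int(comp_cfg["n_permutations"]),
                                rng_seed=split_seed(seed, 8000), unit=unit)
            comparisons.append(dataclasses.asdict(gc))

    report = {
        "version": __version__,
        "config_hash": chash,
        "seed": seed,
        "boundary_method": cfg["boundary_method"],
        "images": image_records,
        "comparisons": comparisons,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    log.info("run complete in %.1fs -> %s", time.time() - t0, out / "report.json")
    return out
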