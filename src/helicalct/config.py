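"""YAML configuration schema, stage hashing, and the cached pipeline.

A run config has five blocks — ``seed``, ``phantom``, ``geometry``,
``simulate``, ``reconstruct``, ``evaluate`` — validated with explicit field
paths.  ``run_pipeline`` executes phantom -> simulate -> reconstruct ->
evaluate, caching each stage in a directory keyed by the content hash of
its own config plus its upstream hashes, and records everything in a
manifest JSON.  The single global seed fans out to per-stage child seeds by
a fixed hash derivation so stages stay independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as hio
from .errors import ValidationError
from .geometry import FanDetector, HelixGeometry, TableSpeed, uniform_phases
from .metrics import dice, threshold_segment
from .phantom import AnalyticPhantom, ground_truth_masks, make_knee_phantom
from .projector import simulate_projections
from .volume import reconstruct_volume

logger = logging.getLogger("helicalct")

__all__ = ["load_config", "validate_config", "build_geometry", "child_seed", "run_pipeline", "make_fixtures"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "phantom": {"jitter": 0.0},
    "geometry": {
        "rho": 300.0,
        "omega": 2 * np.pi,
        "n_sources": 2,
        "pitch": 12.0,
        "detector": {"n_gamma": 65, "fan_half_angle": 0.38, "n_rows": 2, "row_pitch": 3.0},
    },
    "simulate": {"turns": 4, "n_beta_per_turn": 72, "noise": None},
    "reconstruct": {
        "z_start": 8.0,
        "z_stop": 12.0,
        "slice_interval": 0.5,
        "mode": "fixed",
        "filter": "ramp",
        "shape": [96, 96],
        "spacing": [2.0, 2.0],
    },
    "evaluate": {"threshold": 0.035},
}


def _require(cond: bool, path: str, msg: str) -> None:
    if not cond:
        raise ValidationError(f"config field '{path}': {msg}")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return validate_config(cfg)


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def validate_config(cfg: dict) -> dict:
    cfg = _merge(DEFAULT_CONFIG, cfg)
    g = cfg["geometry"]
    _require(g["rho"] > 0, "geometry.rho", "must be positive")
    _require(g["omega"] > 0, "geometry.omega", "must be positive")
    if "phases" not in g:
        _require(int(g["n_sources"]) >= 1, "geometry.n_sources", "must be >= 1")
    det = g["detector"]
    _require(int(det["n_gamma"]) >= 2, "geometry.detector.n_gamma", "must be >= 2")
    _require(det["fan_half_angle"] > 0, "geometry.detector.fan_half_angle", "must be positive")
    _require(int(det["n_rows"]) >= 1, "geometry.detector.n_rows", "must be >= 1")
    _require(det["row_pitch"] > 0, "geometry.detector.row_pitch", "must be positive")
    if "table_speed" in g:
        ts = g["table_speed"]
        _require(len(ts["beta_grid"]) == len(ts["h_values"]), "geometry.table_speed", "grids must match")
    else:
        _require(g["pitch"] > 0, "geometry.pitch", "must be positive")
    s = cfg["simulate"]
    _require(int(s["turns"]) >= 1, "simulate.turns", "must be >= 1")
    _require(int(s["n_beta_per_turn"]) >= 4, "simulate.n_beta_per_turn", "must be >= 4")
    if s.get("noise"):
        _require(s["noise"].get("i0", 0) > 0, "simulate.noise.i0", "must be positive")
    r = cfg["reconstruct"]
    _require(r["slice_interval"] > 0, "reconstruct.slice_interval", "must be positive")
    _require(r["z_stop"] >= r["z_start"], "reconstruct.z_stop", "must be >= z_start")
    _require(r["mode"] in ("fixed", "variable"), "reconstruct.mode", "must be 'fixed' or 'variable'")
    _require(r["filter"] in ("ramp", "hann"), "reconstruct.filter", "must be 'ramp' or 'hann'")
    return cfg


def build_geometry(gcfg: dict) -> HelixGeometry:
    det = gcfg["detector"]
    detector = FanDetector.equiangular(
        n_gamma=int(det["n_gamma"]),
        fan_half_angle=float(det["fan_half_angle"]),
        n_rows=int(det["n_rows"]),
        row_pitch=float(det["row_pitch"]),
    )
    phases = tuple(gcfg["phases"]) if "phases" in gcfg else uniform_phases(int(gcfg["n_sources"]))
    if "table_speed" in gcfg:
        ts = gcfg["table_speed"]
        pitch = TableSpeed(
            np.asarray(ts["beta_grid"], dtype=float), np.asarray(ts["h_values"], dtype=float)
        )
    else:
        pitch = float(gcfg["pitch"])
    return HelixGeometry(
        rho=float(gcfg["rho"]), omega=float(gcfg["omega"]), phases=phases,
        pitch=pitch, detector=detector,
    )


def child_seed(seed: int, stage: str) -> int:
    """Fixed per-stage seed derivation from the global seed (< 2**31)."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _stage_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=float).encode()).hexdigest()[:12]


def run_pipeline(config_path, out_dir, seed: Optional[int] = None) -> Path:
    """Run phantom -> simulate -> reconstruct -> evaluate with per-stage
    content-hash caching; returns the artifact directory."""
    cfg = load_config(config_path)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "stages": {}}
    t_all = time.time()

    # -- phantom stage (geometry of the object; seed affects jitter only)
    ph_seed = child_seed(cfg["seed"], "phantom")
    ph_hash = _stage_hash({"phantom": cfg["phantom"], "seed": ph_seed})
    ph_dir = out / f"phantom_{ph_hash}"
    ph_path = ph_dir / "phantom.yaml"
    cached = ph_path.exists()
    if not cached:
        ph_dir.mkdir(exist_ok=True)
        t0 = time.time()
        phantom = make_knee_phantom(cfg["phantom"], seed=ph_seed)
        phantom.to_yaml(ph_path)
        logger.info("phantom stage: %.2fs", time.time() - t0)
    phantom = AnalyticPhantom.from_yaml(ph_path)
    manifest["stages"]["phantom"] = {"hash": ph_hash, "cached": cached, "path": str(ph_path)}

    # -- simulate stage
    sim_seed = child_seed(cfg["seed"], "simulate")
    sim_hash = _stage_hash(
        {"geometry": cfg["geometry"], "simulate": cfg["simulate"], "seed": sim_seed, "upstream": ph_hash}
    )
    sim_dir = out / f"simulate_{sim_hash}"
    sino_path = sim_dir / "sinograms.h5"
    geom = build_geometry(cfg["geometry"])
    cached = sino_path.exists()
    if not cached:
        sim_dir.mkdir(exist_ok=True)
        t0 = time.time()
        s = cfg["simulate"]
        n_beta = int(s["turns"]) * int(s["n_beta_per_turn"])
        beta_grid = np.linspace(0.0, 2 * np.pi * int(s["turns"]), n_beta, endpoint=False)
        noise = None
        if s.get("noise"):
            noise = (float(s["noise"]["i0"]), sim_seed)
        sinos = simulate_projections(phantom, geom, beta_grid, noise=noise)
        hio.save_sinograms(sino_path, sinos, geom)
        logger.info("simulate stage: %.2fs", time.time() - t0)
    manifest["stages"]["simulate"] = {"hash": sim_hash, "cached": cached, "path": str(sino_path)}

    # -- reconstruct stage
    rec_hash = _stage_hash({"reconstruct": cfg["reconstruct"], "upstream": sim_hash})
    rec_dir = out / f"reconstruct_{rec_hash}"
    vol_path = rec_dir / "volume.nii.gz"
    cached = vol_path.exists()
    if not cached:
        rec_dir.mkdir(exist_ok=True)
        t0 = time.time()
        sinos, geom2 = hio.load_sinograms(sino_path)
        r = cfg["reconstruct"]
        vol = reconstruct_volume(
            sinos, geom2, r["z_start"], r["z_stop"], r["slice_interval"],
            mode=r["mode"], shape=tuple(r["shape"]), spacing=tuple(r["spacing"]),
            filter_name=r["filter"],
        )
        hio.save_volume_nifti(vol_path, vol)
        hio.save_png_preview(rec_dir / "slice0.png", vol.values[:, :, 0])
        logger.info("reconstruct stage: %.2fs", time.time() - t0)
    manifest["stages"]["reconstruct"] = {"hash": rec_hash, "cached": cached, "path": str(vol_path)}

    # -- evaluate stage
    ev_hash = _stage_hash({"evaluate": cfg["evaluate"], "upstream": rec_hash})
    ev_dir = out / f"evaluate_{ev_hash}"
    report_path = ev_dir / "report.json"
    cached = report_path.exists()
    if not cached:
        ev_dir.mkdir(exist_ok=True)
        t0 = time.time()
        vol = hio.load_volume_nifti(vol_path)
        seg = threshold_segment(vol, float(cfg["evaluate"]["threshold"]))
        masks = ground_truth_masks(phantom, vol.shape, vol.spacing, vol.origin)
        report = {
            "dice_bone": dice(masks["bone"], seg),
            "segmented_voxels": int(seg.values.sum()),
            "bone_voxels": int(masks["bone"].values.sum()),
        }
        hio.save_mask_nifti(ev_dir / "segmentation.nii.gz", seg)
        report_path.write_text(json.dumps(report, indent=2))
        logger.info("evaluate stage: %.2fs", time.time() - t0)
    manifest["stages"]["evaluate"] = {"hash": ev_hash, "cached": cached, "path": str(report_path)}

    manifest["elapsed_s"] = time.time() - t_all
    manifest["seed"] = cfg["seed"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return out


def make_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the small deterministic fixtures the test suite reuses:
    a phantom YAML, a tiny sinogram HDF5, and a documented Dice mask pair
    (|M| = 100, |N| = 50, overlap 25 -> Dice = 1/3)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    phantom = make_knee_phantom({"jitter": 1.0}, seed=seed)
    paths["phantom"] = out / "phantom.yaml"
    phantom.to_yaml(paths["phantom"])

    geom = build_geometry(
        _merge(DEFAULT_CONFIG["geometry"], {"detector": {"n_gamma": 17, "fan_half_angle": 0.38}})
    )
    beta_grid = np.linspace(0.0, 4 * np.pi, 72, endpoint=False)
    sinos = simulate_projections(phantom, geom, beta_grid)
    paths["sinograms"] = out / "sinograms.h5"
    hio.save_sinograms(paths["sinograms"], sinos, geom)

    m = np.zeros((20, 20), dtype=bool)
    n = np.zeros((20, 20), dtype=bool)
    m.flat[:100] = True
    n.flat[75:125] = True  # overlap with M on flat indices 75..99 = 25 pixels
    np.savez(out / "dice_pair.npz", m=m, n=n)
    paths["dice_pair"] = out / "dice_pair.npz"
    return paths
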