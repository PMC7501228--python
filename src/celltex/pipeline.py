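"""Configuration, orchestration and file I/O: the runnable pipeline.

A YAML config drives simulate → map → reduce → pole figure → metrics; all
artifacts (TIFF frames, CSV profiles, pole-figure CSV, metrics JSON) land
under the output directory together with a machine-readable run record
(timestamp, package version, config hash, seeds, derived scale factors and
metrics) and a plain-text log.  Given (config, seed), the pipeline is
fully deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from . import __version__
from .errors import ConfigError
from .optics import (
    BeamSpec,
    DetectorGeometry,
    beam_from_config,
    build_qchi_map,
    geometry_from_config,
)
from .polefigure import (
    DEFAULT_Q_BAND,
    giwaxs_branch,
    oriented_fraction,
    rocking_branch,
    segal_ci,
    stitch,
    texture_width,
)
from .reduction import sector_profile
from .simulate import (
    PRESET_NAMES,
    default_detector,
    render_giwaxs,
    render_rocking_series,
    render_transmission,
    scene_presets,
)

__all__ = ["RunConfig", "RunRecord", "run_pipeline", "make_fixtures", "DEFAULT_CONFIG"]

logger = logging.getLogger("celltex")

_SCHEMA: dict = {
    "beam": {"energy_keV", "incidence_deg"},
    "geometry": {
        "distance_mm",
        "pixel_mm",
        "center_row",
        "center_col",
        "rows",
        "cols",
        "orientation",
    },
    "scene": {
        "preset",
        "sigma_chi_deg",
        "cellulose_scale",
        "wax_scale",
        "background",
        "exposure",
    },
    "rocking": {"n_frames", "half_range_deg"},
    "reduction": {
        "out_of_plane_sector_deg",
        "in_plane_sector_deg",
        "q_min",
        "q_max",
        "q_step",
        "chi_step_deg",
    },
    "polefigure": {
        "q_band",
        "giwaxs_background_band",
        "rocking_background_band",
        "match_chi_deg",
        "weighting",
        "chi0_deg",
    },
    "seed": None,
    "noiseless": None,
    "outdir": None,
}

DEFAULT_CONFIG: dict = {
    "beam": {"energy_keV": 10.0, "incidence_deg": 0.15},
    "geometry": {
        "distance_mm": 120.0,
        "pixel_mm": 0.172,
        "center_row": 502.0,
        "center_col": 256.0,
        "rows": 512,
        "cols": 512,
        "orientation": "up_row0",
    },
    "scene": {"preset": "unextracted", "sigma_chi_deg": 20.0},
    "rocking": {"n_frames": 11, "half_range_deg": 0.75},
    "reduction": {
        "out_of_plane_sector_deg": [-17.0, 17.0],
        "in_plane_sector_deg": [78.0, 88.0],
        "q_min": 0.4,
        "q_max": 1.75,
        "q_step": 0.005,
        "chi_step_deg": 1.0,
    },
    "polefigure": {
        "q_band": list(DEFAULT_Q_BAND),
        "giwaxs_background_band": [0.5, 0.6],
        "rocking_background_band": [2.0, 2.2],
        "match_chi_deg": 7.5,
        "weighting": "sin_chi",
        "chi0_deg": 34.0,
    },
    "seed": 0,
    "noiseless": False,
}


def _validate(config: dict, schema: dict = _SCHEMA, path: str = "") -> None:
    if not isinstance(config, dict):
        raise ConfigError(f"config section {path or '<root>'} must be a mapping")
    for key, value in config.items():
        where = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown config key: {where}")
        allowed = schema[key]
        if isinstance(allowed, set):
            if not isinstance(value, dict):
                raise ConfigError(f"config section {where} must be a mapping")
            for sub in value:
                if sub not in allowed:
                    raise ConfigError(f"unknown config key: {where}.{sub}")


def _merge(base: dict, override: dict) -> dict:
    out = {}
    for key, value in base.items():
        if isinstance(value, dict):
            out[key] = _merge(value, override.get(key, {}) if override else {})
        else:
            out[key] = override.get(key, value) if override else value
    for key in override or {}:
        if key not in base:
            out[key] = override[key]
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (defaults merged in)."""

    raw: dict
    beam: BeamSpec
    geometry: DetectorGeometry
    seed: int = 0
    noiseless: bool = False
    outdir: Path = Path("celltex_run")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        _validate(data)
        merged = _merge(DEFAULT_CONFIG, data)
        _validate(merged)
        beam = beam_from_config(merged["beam"])
        geometry = geometry_from_config(merged["geometry"])
        return cls(
            raw=merged,
            beam=beam,
            geometry=geometry,
            seed=int(merged.get("seed", 0)),
            noiseless=bool(merged.get("noiseless", False)),
            outdir=Path(merged.get("outdir", "celltex_run")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunRecord:
    """Machine-readable record of one pipeline run."""

    timestamp: str
    version: str
    config_hash: str
    seed: int
    scale_factor: float
    metrics: dict
    outputs: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        tmp.replace(path)  # atomic at run end


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> RunRecord:
    """Execute simulate → map → reduce → pole figure → metrics."""
    cfg = config.raw
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    outputs: list[str] = []
    try:
        stage = "simulate"
        logger.info("run start: config hash %s, seed %d", config.config_hash, config.seed)
        scene_cfg = cfg["scene"]
        scene = scene_presets(
            scene_cfg["preset"],
            sigma_chi_deg=float(scene_cfg.get("sigma_chi_deg", 20.0)),
            cellulose_scale=float(scene_cfg.get("cellulose_scale", 3000.0)),
            wax_scale=float(scene_cfg.get("wax_scale", 1200.0)),
            background=float(scene_cfg.get("background", 2.0)),
            exposure=float(scene_cfg.get("exposure", 1.0)),
        )
        logger.info("scene preset %s (seed %d)", scene_cfg["preset"], config.seed)
        frame = render_giwaxs(
            scene, config.geometry, config.beam, seed=config.seed, noiseless=config.noiseless
        )
        q_band = tuple(cfg["polefigure"]["q_band"])
        mid_q = 0.5 * (q_band[0] + q_band[1])
        theta_b = float(np.degrees(np.arcsin(mid_q / (2.0 * config.beam.k_a))))
        half = float(cfg["rocking"]["half_range_deg"])
        series = render_rocking_series(
            scene,
            config.geometry,
            config.beam,
            (theta_b - half, theta_b + half),
            int(cfg["rocking"]["n_frames"]),
            seed=config.seed + 1,
            q_band=q_band,
            noiseless=config.noiseless,
        )
        path = outdir / "giwaxs.tiff"
        tifffile.imwrite(path, frame.astype(np.float32))
        outputs.append(str(path))
        manifest_lines = ["frame,theta_deg"]
        for i, (theta_s, rocking_frame) in enumerate(
            zip(series.sample_angles_deg, series.frames)
        ):
            path = outdir / f"rocking_{i:03d}.tiff"
            tifffile.imwrite(path, rocking_frame.astype(np.float32))
            outputs.append(str(path))
            manifest_lines.append(f"rocking_{i:03d}.tiff,{theta_s:.5f}")
        (outdir / "rocking_manifest.csv").write_text("\n".join(manifest_lines) + "\n")
        outputs.append(str(outdir / "rocking_manifest.csv"))

        stage = "map"
        qcmap = build_qchi_map(config.geometry, config.beam)

        stage = "reduce"
        red = cfg["reduction"]
        q_grid = np.arange(red["q_min"], red["q_max"] + red["q_step"] / 2, red["q_step"])
        for label, sector in (
            ("out_of_plane", tuple(red["out_of_plane_sector_deg"])),
            ("in_plane", tuple(red["in_plane_sector_deg"])),
        ):
            profile = sector_profile(frame, qcmap, sector, q_grid)
            profile.meta["config_hash"] = config.config_hash
            path = outdir / f"profile_{label}.csv"
            profile.to_csv(path)
            outputs.append(str(path))
            if label == "out_of_plane":
                out_of_plane = profile

        stage = "polefigure"
        chi_step = float(red["chi_step_deg"])
        chi_grid = np.arange(-90 + chi_step / 2, 90, chi_step)
        pf_cfg = cfg["polefigure"]
        g_branch = giwaxs_branch(
            frame,
            qcmap,
            chi_grid,
            q_band=q_band,
            background_band=tuple(pf_cfg["giwaxs_background_band"]),
            min_abs_chi_deg=float(pf_cfg["match_chi_deg"]),
        )
        r_branch = rocking_branch(
            series,
            config.geometry,
            config.beam,
            chi_grid,
            background_band=tuple(pf_cfg["rocking_background_band"]),
        )
        pf = stitch(g_branch, r_branch, match_chi_deg=float(pf_cfg["match_chi_deg"]))
        pf.meta["config_hash"] = config.config_hash
        pf.meta["weighting"] = pf_cfg["weighting"]
        path = outdir / "pole_figure.csv"
        pf.to_csv(path)
        outputs.append(str(path))
        logger.info("stitch scale factor %.5g", pf.scale_factor)

        stage = "metrics"
        chi0 = float(pf_cfg["chi0_deg"])
        metrics = {
            "oriented_fraction_sin": oriented_fraction(pf, chi0, "sin_chi"),
            "oriented_fraction_flat": oriented_fraction(pf, chi0, "flat"),
            "chi0_deg": chi0,
            "texture_fwhm_deg": texture_width(pf),
            "segal_ci_percent": segal_ci(out_of_plane),
            "stitch_scale_factor": pf.scale_factor,
        }
        path = outdir / "metrics.json"
        path.write_text(json.dumps(metrics, indent=2))
        outputs.append(str(path))
        logger.info("metrics: %s", metrics)

        record = RunRecord(
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            version=__version__,
            config_hash=config.config_hash,
            seed=config.seed,
            scale_factor=pf.scale_factor,
            metrics=metrics,
            outputs=outputs,
        )
        record.write(outdir / "run_record.json")
        logger.info("run complete: %d artifacts", len(outputs))
        return record
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def make_fixtures(outdir, seed: int = 0) -> dict[str, str]:
    """Write the five preset frames, one transmission frame and one rocking
    series as small TIFF fixtures, plus a checksum manifest.

    Deterministic given ``seed``: reruns produce bit-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    beam = BeamSpec(10.0, 0.15)
    geometry = default_detector()
    checksums: dict[str, str] = {}

    def _write(name: str, array: np.ndarray) -> None:
        path = outdir / name
        tifffile.imwrite(path, array.astype(np.float32))
        checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    for i, preset in enumerate(PRESET_NAMES):
        scene = scene_presets(preset)
        _write(f"{preset}.tiff", render_giwaxs(scene, geometry, beam, seed=seed + i))
    scene = scene_presets("unextracted")
    from .simulate import default_transmission_detector

    _write(
        "unextracted_transmission.tiff",
        render_transmission(scene, default_transmission_detector(), beam, seed=seed + 50),
    )
    theta_b = float(np.degrees(np.arcsin(1.15 / (2.0 * beam.k_a))))
    series = render_rocking_series(
        scene, geometry, beam, (theta_b - 0.75, theta_b + 0.75), 5, seed=seed + 100
    )
    for i, rocking_frame in enumerate(series.frames):
        _write(f"rocking_{i:03d}.tiff", rocking_frame)
    lines = ["file,theta_deg,sha256"]
    for i, theta_s in enumerate(series.sample_angles_deg):
        lines.append(f"rocking_{i:03d}.tiff,{theta_s:.5f},{checksums[f'rocking_{i:03d}.tiff']}")
    for name, digest in checksums.items():
        if not name.startswith("rocking_"):
            lines.append(f"{name},,{digest}")
    (outdir / "manifest.csv").write_text("\n".join(lines) + "\n")
    return checksums
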