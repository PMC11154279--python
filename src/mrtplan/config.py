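"""Run configuration and the end-to-end pipeline.

A run is described by a small YAML (or TOML) file with ``geometry``,
``spectrum``, ``phantom``, ``plan`` and ``execution`` blocks.  Every run
emits a manifest (config hash, seed, package version) next to its outputs,
and all randomness flows from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__
from .beam_geometry import BeamGeometry, Collimator, FocalSpot
from .materials import Spectrum, generate_spectrum
from .phantom import (
    VoxelPhantom,
    load_ct_volume,
    make_mouse_head_phantom,
    make_slab_phantom,
)
from .planning import Plan, compute_plan, depth_dose_report
from .planning import compute_dose  # noqa: F401  (re-exported for the CLI)

INCOMPLETE_MARKER = "INCOMPLETE"


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Parsed configuration plus the raw dict it came from."""

    raw: dict
    geometry: BeamGeometry
    spectrum: Spectrum
    phantom: VoxelPhantom
    plan: Plan
    seed: int
    histories: int
    engine: str
    gap_mm: float
    output_factor: float
    output_dir: Path
    voxel_mm: float = 1.0

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()


def _load_raw(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".toml",):
        import tomllib

        return tomllib.loads(text)
    import yaml

    return yaml.safe_load(text)


def _build_geometry(block: dict) -> BeamGeometry:
    coll = Collimator(
        slit_width_um=float(block.get("slit_um", 30.0)),
        ctc_um=float(block.get("ctc_um", 400.0)),
        leakage=block.get("leakage"),
    )
    field_mm = block.get("field_mm", [20.0, 20.0])
    if np.isscalar(field_mm):
        field_mm = [field_mm, field_mm]
    return BeamGeometry(
        sd_mm=float(block.get("sd_mm", 212.0)),
        field_mm=(float(field_mm[0]), float(field_mm[1])),
        focal_spot=FocalSpot(float(block.get("sigma_mm", 0.58))),
        collimator=coll,
    )


def _build_phantom(block: dict) -> VoxelPhantom:
    kind = block.get("kind", "slab")
    voxel = float(block.get("voxel_mm", 1.0))
    if kind == "slab":
        ph = make_slab_phantom(
            tuple(block.get("dims_mm", [20.0, 40.0, 20.0])),
            material=block.get("material", "pmma"),
            voxel_mm=voxel,
        )
        depth_range = block.get("roi_depth_mm")
        if depth_range:
            depth = ph.depth_grid_mm()
            mask = np.zeros(ph.shape, dtype=bool)
            mask[(depth >= depth_range[0]) & (depth <= depth_range[1])] = True
            lateral = block.get("roi_lateral_mm")
            if lateral is not None:
                _, ny, nx = ph.shape
                yc = (np.arange(ny) + 0.5 - ny / 2.0) * voxel
                xc = (np.arange(nx) + 0.5 - nx / 2.0) * voxel
                box = np.outer(
                    np.abs(yc) <= lateral / 2.0, np.abs(xc) <= lateral / 2.0
                )
                mask &= box[None, :, :]
            ph.roi["target"] = mask
        return ph
    if kind == "mouse_head":
        return make_mouse_head_phantom(voxel_mm=voxel)
    if kind == "file":
        path = Path(block["path"])
        if not path.exists():
            raise ConfigError(f"phantom file not found: {path}")
        return load_ct_volume(path)
    raise ConfigError(f"unknown phantom kind {kind!r}")


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = _load_raw(path)
    geometry = _build_geometry(raw.get("geometry", {}))
    sp = raw.get("spectrum", {})
    if "path" in sp:
        spectrum = Spectrum.from_csv(sp["path"])
    else:
        spectrum = generate_spectrum(
            float(sp.get("kvp", 225.0)), float(sp.get("filtration_mm_al", 1.0))
        )
    phantom = _build_phantom(raw.get("phantom", {}))
    plan_block = raw.get("plan", {})
    roi = plan_block.get("roi")
    if roi is None:
        roi = "brain" if "brain" in phantom.roi else next(iter(phantom.roi), "target")
    plan = Plan(
        geometry=geometry,
        prescription_peak_dose_gy=float(plan_block.get("prescription_gy", 20.0)),
        roi=roi,
        beam_offset_mm=tuple(plan_block.get("beam_offset_mm", [0.0, 0.0])),
        couch_angle_deg=float(plan_block.get("couch_angle_deg", 0.0)),
    )
    ex = raw.get("execution", {})
    return RunConfig(
        raw=raw,
        geometry=geometry,
        spectrum=spectrum,
        phantom=phantom,
        plan=plan,
        seed=int(ex.get("seed", 1)),
        histories=int(ex.get("histories", 200_000)),
        engine=ex.get("engine", "mc"),
        gap_mm=float(ex.get("gap_mm", 4.0)),
        output_factor=float(ex.get("output_factor", 1.0)),
        output_dir=Path(raw.get("output_dir", "mrtplan_out")),
        voxel_mm=float(raw.get("phantom", {}).get("voxel_mm", 1.0)),
    )


def run_pipeline(config: RunConfig, out_dir: Path | None = None) -> dict:
    """Execute simulate -> reconstruct -> plan -> report.

    Idempotent for identical config + seed; a partial failure leaves an
    ``INCOMPLETE`` marker file in the output directory.
    """
    out = Path(out_dir) if out_dir is not None else config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    marker = out / INCOMPLETE_MARKER
    marker.write_text("run in progress or failed\n")
    try:
        report = compute_plan(
            config.phantom,
            config.plan,
            config.spectrum,
            n_histories=config.histories,
            seed=config.seed,
            gap_mm=config.gap_mm,
            engine=config.engine,
            output_factor=config.output_factor,
        )
        dose = compute_dose(
            config.phantom,
            config.geometry,
            config.spectrum,
            n_histories=config.histories,
            seed=config.seed,
            gap_mm=config.gap_mm,
            engine=config.engine,
        )
        table = depth_dose_report(
            dose, config.geometry, config.phantom, spectrum=config.spectrum
        )
        report_dict = report.to_dict()
        report_dict["valley_maxima_depth_mm"] = table.attrs[
            "valley_maxima_depth_mm"
        ]
        (out / "report.json").write_text(
            json.dumps(report_dict, indent=2, sort_keys=True) + "\n"
        )
        table.drop(columns=["valley_smoothed"]).to_csv(
            out / "depth_table.csv", index=False
        )
        manifest = {
            "config_hash": config.config_hash,
            "seed": config.seed,
            "histories": config.histories,
            "engine": config.engine,
            "package_version": __version__,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    except Exception:
        raise
    else:
        marker.unlink(missing_ok=True)
    return report_dict
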