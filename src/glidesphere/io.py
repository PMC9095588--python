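"""File readers/writers and run configuration.

Formats: multi-page TIFF for voxel stacks and equirectangular map
sequences (metadata in a YAML sidecar — no TIFF-tag parsing guarantees),
CSV for track tables and derived series (comma separated, ``.`` decimal,
mandatory header row, ``#`` comment lines for metadata/provenance), JSON
for defect lists, YAML for run configuration.  Units on disk: um,
seconds, radians; speeds in nm/s.

Internally everything is um and seconds; nm/s appears only at
presentation boundaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .defects import Defect, DefectConfiguration, format_charge, parse_charge
from .geometry import SphereGeometry
from .projection import EquirectMap, VoxelStack

TRACK_COLUMNS = {
    "equirect": ["track_id", "frame", "time_s", "phi_rad", "theta_rad"],
    "confocal": ["track_id", "frame", "time_s", "x_um", "y_um", "hemisphere"],
}


def provenance_header(seed=None, config_hash=None, **extra) -> str:
    parts = [f"glidesphere v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash is not None:
        parts.append(f"config_sha={config_hash}")
    parts += [f"{k}={v}" for k, v in extra.items()]
    return "# " + " ".join(parts)


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_voxel_stack(path, stack: VoxelStack, seed=None) -> None:
    """16/32-bit friendly TIFF + YAML sidecar (voxel sizes, origin, dt)."""
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32),
                     photometric="minisblack")
    meta = {"kind": "voxel", "voxel_um": list(stack.voxel_um),
            "origin_um": [float(v) for v in stack.origin],
            "frame_interval_s": stack.frame_interval_s,
            "provenance": provenance_header(seed=seed)}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def write_map_sequence(path, maps: list, seed=None) -> None:
    """Equirectangular map sequence as a multi-page TIFF + sidecar."""
    path = Path(path)
    data = np.stack([m.data for m in maps]).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    g = maps[0].geometry
    times = [m.time_s for m in maps]
    meta = {"kind": "equirect", "radius_um": float(g.radius),
            "center_um": [float(v) for v in g.center],
            "times_s": [None if t is None else float(t) for t in times],
            "provenance": provenance_header(seed=seed)}
    _sidecar_path(path).write_text(yaml.safe_dump(meta))


def read_tiff_stack(path, sidecar: dict | None = None, *, voxel_um=None,
                    origin_um=None, frame_interval_s=None, radius_um=None,
                    center_um=None, times_s=None, kind: str | None = None):
    """Read a TIFF written by this package (or with explicit metadata).

    Metadata comes from the YAML ``sidecar`` dict, the on-disk
    ``<path>.yaml`` sidecar, or the keyword overrides — in that priority
    order per field.  Returns a :class:`VoxelStack` (kind 'voxel') or a
    list of :class:`EquirectMap` (kind 'equirect').  Missing metadata
    raises with a remediation hint.
    """
    path = Path(path)
    data = np.asarray(tifffile.imread(path), dtype=float)
    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta.update(yaml.safe_load(sc.read_text()) or {})
    if sidecar:
        meta.update(sidecar)
    overrides = {"voxel_um": voxel_um, "origin_um": origin_um,
                 "frame_interval_s": frame_interval_s,
                 "radius_um": radius_um, "center_um": center_um,
                 "times_s": times_s, "kind": kind}
    meta.update({k: v for k, v in overrides.items() if v is not None})
    kind = meta.get("kind")
    if kind == "voxel":
        if "voxel_um" not in meta:
            raise ValueError(
                "missing voxel size metadata; supply a YAML sidecar with "
                "'voxel_um' or pass voxel_um=... explicitly")
        return VoxelStack(data=data, voxel_um=meta["voxel_um"],
                          origin=np.asarray(meta.get("origin_um", [0, 0, 0]),
                                            dtype=float),
                          frame_interval_s=meta.get("frame_interval_s"))
    if kind == "equirect":
        if "radius_um" not in meta:
            raise ValueError(
                "missing sphere metadata; supply a sidecar with 'radius_um' "
                "(and optionally 'center_um') or pass radius_um=...")
        g = SphereGeometry(np.asarray(meta.get("center_um", [0, 0, 0]),
                                      dtype=float), float(meta["radius_um"]))
        if data.ndim == 2:
            data = data[None]
        times = meta.get("times_s") or [None] * data.shape[0]
        return [EquirectMap(frame, g, time_s=t)
                for frame, t in zip(data, times)]
    raise ValueError(
        "unknown or missing stack kind; sidecar must set kind to "
        "'voxel' or 'equirect'")


def write_tracks_csv(path, df: pd.DataFrame, mode: str = "equirect",
                     seed=None, **meta) -> None:
    cols = TRACK_COLUMNS[mode]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, mode=mode, **meta) + "\n")
        df[cols].to_csv(fh, index=False)


def read_tracks_csv(path, mode: str = "equirect") -> dict:
    """Validated track tables, one DataFrame per track_id.

    Schema (equirect): track_id, frame, time_s, phi_rad, theta_rad;
    (confocal): track_id, frame, time_s, x_um, y_um, hemisphere.
    Problems (unknown columns, non-monotone frames) are collected and
    reported together.
    """
    df = pd.read_csv(path, comment="#")
    cols = TRACK_COLUMNS[mode]
    problems = []
    missing = set(cols) - set(df.columns)
    if missing:
        problems.append(f"missing columns: {sorted(missing)}")
    unknown = set(df.columns) - set(cols)
    if unknown:
        problems.append(f"unknown columns: {sorted(unknown)}")
    tracks = {}
    if not missing:
        for tid, grp in df.groupby("track_id"):
            if np.any(np.diff(grp["frame"].to_numpy()) <= 0):
                problems.append(f"track_id {tid}: frames not strictly increasing")
            tracks[tid] = grp.reset_index(drop=True)
    if problems:
        raise ValueError("invalid track file:\n  " + "\n  ".join(problems))
    return tracks


def write_defects_json(path, configs: list, seed=None) -> None:
    """Defect configurations as a JSON list of per-defect records."""
    records = []
    for cfg in configs:
        from .geometry import cartesian_to_spherical
        for d in cfg.defects:
            th, ph = cartesian_to_spherical(d.position, cfg.geometry)
            records.append({"time_s": d.time_s,
                            "charge": format_charge(d.charge),
                            "phi_rad": ph, "theta_rad": th})
    payload = {"provenance": provenance_header(seed=seed),
               "covers_full_surface": bool(configs[0].covers_full_surface),
               "radius_um": float(configs[0].geometry.radius),
               "center_um": [float(v) for v in configs[0].geometry.center],
               "defects": records}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_defects_json(path) -> list:
    """Inverse of :func:`write_defects_json`; one configuration per time."""
    from .geometry import spherical_to_cartesian

    payload = json.loads(Path(path).read_text())
    g = SphereGeometry(np.asarray(payload.get("center_um", [0, 0, 0]),
                                  dtype=float), float(payload["radius_um"]))
    covers = bool(payload.get("covers_full_surface", True))
    by_time: dict = {}
    for rec in payload["defects"]:
        pos = spherical_to_cartesian(rec["theta_rad"], rec["phi_rad"], g)
        d = Defect(pos, parse_charge(rec["charge"]),
                   time_s=float(rec["time_s"]))
        by_time.setdefault(float(rec["time_s"]), []).append(d)
    return [DefectConfiguration(tuple(by_time[t]), g,
                                covers_full_surface=covers)
            for t in sorted(by_time)]


def write_series_csv(path, df: pd.DataFrame, seed=None, **meta) -> None:
    """Generic derived-series CSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, **meta) + "\n")
        df.to_csv(fh, index=False)


@dataclass
class RunConfig:
    """Configuration of a pipeline run (see :mod:`glidesphere.pipeline`)."""

    seed: int = 0
    out_dir: str = "glidesphere_out"
    radius_um: float = 18.0
    dt_s: float = 60.0
    n_frames: int = 8
    map_n_theta: int = 120
    map_n_phi: int = 240
    scene_label: str = "vortex"
    stages: tuple = ("simulate", "speeds", "msd", "defects", "classify")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)
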