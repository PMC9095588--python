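"""End-to-end pipelines tying the analysis modules together.

``run_pipeline`` executes the configured stages on a synthetic scene
(simulate -> speeds -> msd -> defects -> classify), writing every
artifact with a provenance header (package version, config hash, seed);
re-running with the same config and seed reproduces the numeric content
exactly.  ``evaluate_fixture`` is the harness used to score the
classifier against generator labels: it renders the scene, measures
structure and defect speeds from the ground-truth tracks, and feeds the
classifier exactly what a user analysing a real vesicle would have.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .defects import configuration_series, validate_poincare_hopf
from .dynamics import angular_msd, instantaneous_speeds, mean_speed
from .geometry import cartesian_to_spherical
from .io import (RunConfig, write_defects_json, write_map_sequence,
                 write_series_csv, write_tracks_csv)
from .patterns import ClassifierConfig, classify_pattern
from .synthetic import Fixture, fixture_suite, render_scene_maps


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def evaluate_fixture(fixture: Fixture, n_theta: int = 120, n_phi: int = 240,
                     config: ClassifierConfig | None = None):
    """Render a labelled fixture and classify it.

    Structure and defect speeds are measured with the arc-length speed
    pipeline from the generator's ground-truth tracks (the classifier
    never sees the labels).  Returns the :class:`PatternResult`.
    """
    maps = render_scene_maps(fixture.scene, n_theta, n_phi)
    speeds = [mean_speed(instantaneous_speeds(tr))[0]
              for tr in fixture.trajectories if len(tr) >= 2]
    defects = fixture.defect_configuration(0)
    defect_speeds = None
    if fixture.defect_tracks:
        defect_speeds = [mean_speed(instantaneous_speeds(tr))[0]
                         for tr in fixture.defect_tracks]
    return classify_pattern(maps, speeds, defects=defects,
                            defect_speeds_nm_s=defect_speeds, config=config)


def _tracks_frame(fixture: Fixture) -> pd.DataFrame:
    rows = []
    for tid, tr in enumerate(fixture.trajectories):
        theta, phi = cartesian_to_spherical(tr.positions, tr.geometry)
        theta = np.atleast_1d(theta)
        phi = np.atleast_1d(phi)
        for k in range(len(tr)):
            rows.append({"track_id": tid, "frame": k,
                         "time_s": tr.times[k], "phi_rad": phi[k],
                         "theta_rad": theta[k]})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; returns the artifact directory.

    Any stage failure aborts with :class:`PipelineError` naming the
    stage.  Validation (e.g. an unknown scene label) happens before any
    stage executes.
    """
    if config.scene_label not in ("stream", "vortex", "band",
                                  "partially_jammed", "globally_jammed"):
        raise ValueError(f"unknown scene label {config.scene_label!r}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sha = config.config_hash()
    meta = {"seed": config.seed, "config_hash": sha}

    suite = fixture_suite(seed=config.seed, n_per_class=1,
                          n_frames=config.n_frames, dt_s=config.dt_s,
                          radius_um=config.radius_um)
    fixture = next(f for f in suite if f.label == config.scene_label)

    maps = None
    if "simulate" in config.stages:
        try:
            maps = render_scene_maps(fixture.scene, config.map_n_theta,
                                     config.map_n_phi)
            write_map_sequence(out / "maps.tif", maps, seed=config.seed)
            write_tracks_csv(out / "tracks.csv", _tracks_frame(fixture),
                             seed=config.seed, config_sha=sha)
            if fixture.defect_tracks:
                configs = [fixture.defect_configuration(k)
                           for k in range(fixture.scene.n_frames)]
                write_defects_json(out / "defects.json", configs,
                                   seed=config.seed)
        except Exception as exc:  # noqa: BLE001 - stage attribution
            raise PipelineError("simulate", exc) from exc

    if "speeds" in config.stages:
        try:
            rows = []
            for tid, tr in enumerate(fixture.trajectories):
                series = instantaneous_speeds(tr)
                for t, v in zip(series.times, series.speeds):
                    rows.append({"track_id": tid, "time_s": t,
                                 "speed_nm_s": v})
            write_series_csv(out / "speeds.csv", pd.DataFrame(rows),
                             radius_um=config.radius_um, dt_s=config.dt_s,
                             **meta)
        except Exception as exc:
            raise PipelineError("speeds", exc) from exc

    if "msd" in config.stages:
        try:
            rows = []
            for tid, tr in enumerate(fixture.trajectories):
                m = angular_msd(tr)
                for lag, mt, mp in zip(m.lags, m.msd_theta, m.msd_phi):
                    rows.append({"track_id": tid, "lag_s": lag,
                                 "msd_theta_rad2": mt, "msd_phi_rad2": mp})
            write_series_csv(out / "msd.csv", pd.DataFrame(rows), **meta)
        except Exception as exc:
            raise PipelineError("msd", exc) from exc

    if "defects" in config.stages and len(fixture.defect_tracks) >= 2:
        try:
            series = configuration_series(list(fixture.defect_tracks))
            df = pd.DataFrame({"time_s": series.times,
                               "mean_pair_angle_deg": series.mean_angle_deg})
            write_series_csv(out / "pair_angles.csv", df, **meta)
            ph = validate_poincare_hopf(fixture.defect_configuration(0))
            (out / "poincare_hopf.txt").write_text(
                f"{'PASS' if ph.ok else 'FAIL'}: {ph.message}\n")
        except Exception as exc:
            raise PipelineError("defects", exc) from exc

    if "classify" in config.stages:
        try:
            result = evaluate_fixture(fixture, config.map_n_theta,
                                      config.map_n_phi)
            df = pd.DataFrame([{"label": result.label, **result.features}])
            write_series_csv(out / "classification.csv", df, **meta)
        except Exception as exc:
            raise PipelineError("classify", exc) from exc
    return out
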