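"""Trajectory dynamics: speeds, angular MSDs, feature tracking, mean flow.

Speeds are arc-length speeds on the sphere, v = R * dtheta / dt, reported
in nm/s (the scale of the phenomena: free streams and vortices circulate
at 40-50 nm/s, jammed defects creep below ~5-10 nm/s).

The angular mean squared displacement is computed component-wise from the
angular position (theta, phi):

    MSD_theta(tau) = <(theta(t+tau) - theta(t))^2>
    MSD_phi(tau)   = <(phi(t+tau) - phi(t))^2>

time-averaged over all overlapping windows of one trajectory, with the
azimuth unwrapped before differencing so the 0/2pi seam does not inject
jumps.  No metric (sin theta) correction is applied to the phi component;
that is a deliberate fidelity choice (see the methods note), with the
metric-corrected variant available via ``metric_corrected=True``.

Feature tracking on equirectangular map sequences is a deterministic
patch tracker: features seed at local intensity maxima and are followed
frame-to-frame by maximizing the normalized cross-correlation of a patch
inside a search window (periodic in phi), with parabolic sub-pixel peak
refinement.  It is a reference backend with a deliberately small contract,
not a dense optical-flow method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template, peak_local_max

from .geometry import (SphereGeometry, Trajectory, arc_speed,
                       central_angle, confocal_to_sphere,
                       spherical_to_cartesian, unwrap_azimuth)
from .projection import EquirectMap

UM_PER_S_TO_NM_PER_S = 1000.0


@dataclass(frozen=True)
class SpeedSeries:
    """Instantaneous arc-length speeds (nm/s); one value per frame pair."""

    times: np.ndarray   # (n-1,) s, right edge of each interval
    speeds: np.ndarray  # (n-1,) nm/s

    def __len__(self) -> int:
        return self.speeds.size


@dataclass(frozen=True)
class AngularMSD:
    lags: np.ndarray        # (n_lags,) s
    msd_theta: np.ndarray   # rad^2
    msd_phi: np.ndarray     # rad^2
    counts: np.ndarray      # windows per lag


@dataclass(frozen=True)
class FeatureTrack:
    """One tracked feature on an equirectangular map sequence.

    ``phi`` is stored unwrapped (continuous across the 0/2pi seam).
    """

    track_id: int
    frames: np.ndarray
    times: np.ndarray
    theta: np.ndarray
    phi: np.ndarray

    def __len__(self) -> int:
        return self.frames.size

    def to_trajectory(self, geometry: SphereGeometry) -> Trajectory:
        return Trajectory(self.times,
                          spherical_to_cartesian(self.theta,
                                                 np.mod(self.phi, 2 * np.pi),
                                                 geometry),
                          geometry)


def ingest_track(rows, mode: str, geometry: SphereGeometry) -> Trajectory:
    """Build an on-sphere trajectory from a table of tracked positions.

    ``rows`` is a pandas DataFrame (or mapping of columns).  ``mode``:

    * ``"equirect"`` — columns ``time_s, phi_rad, theta_rad``; positions
      re-projected via r = R(cos phi sin theta, sin phi sin theta, cos theta);
    * ``"confocal"`` — columns ``time_s, x_um, y_um, hemisphere``
      (coordinates relative to the sphere centre), lifted via
      r = (x, y, +-sqrt(R^2 - x^2 - y^2)).

    Confocal points outside the projected disk raise with the row index.
    """
    import pandas as pd

    df = pd.DataFrame(rows)
    if mode == "equirect":
        pos = spherical_to_cartesian(df["theta_rad"].to_numpy(),
                                     df["phi_rad"].to_numpy(), geometry)
    elif mode == "confocal":
        pos = np.empty((len(df), 3))
        for k, row in enumerate(df.itertuples(index=False)):
            try:
                pos[k] = confocal_to_sphere(row.x_um, row.y_um, geometry,
                                            hemisphere=row.hemisphere)
            except ValueError as exc:
                raise ValueError(f"row {k}: {exc}") from exc
    else:
        raise ValueError(f"mode must be 'equirect' or 'confocal', got {mode!r}")
    return Trajectory(df["time_s"].to_numpy(dtype=float), pos, geometry)


def instantaneous_speeds(traj: Trajectory) -> SpeedSeries:
    """Arc-length speed of each consecutive frame pair, in nm/s."""
    if len(traj) < 2:
        raise ValueError("need at least 2 points for speeds")
    dt = traj.dt  # raises on irregular sampling
    v = arc_speed(traj.positions[:-1], traj.positions[1:], dt, traj.geometry,
                  check=False)
    return SpeedSeries(times=traj.times[1:],
                       speeds=np.atleast_1d(v) * UM_PER_S_TO_NM_PER_S)


def mean_speed(series: SpeedSeries, window: tuple | None = None):
    """Mean and standard deviation (nm/s) over a time window (default: all)."""
    if window is None:
        sel = np.ones(len(series), dtype=bool)
    else:
        t0, t1 = window
        sel = (series.times >= t0) & (series.times <= t1)
    if not np.any(sel):
        raise ValueError("empty averaging window")
    v = series.speeds[sel]
    return float(np.mean(v)), float(np.std(v))


def angular_msd(traj: Trajectory, max_lag: int | None = None,
                metric_corrected: bool = False) -> AngularMSD:
    """Time-averaged angular MSD per component at lags tau = k * dt.

    The azimuth series is unwrapped before differencing.  With
    ``metric_corrected=True`` azimuthal increments are scaled by
    sin(theta) at the window start, giving arc-like units instead of the
    raw coordinate increments.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 points for an MSD")
    dt = traj.dt
    theta, phi = traj.angles()
    phi = unwrap_azimuth(phi)
    n = len(traj)
    kmax = max_lag if max_lag is not None else n - 1
    kmax = min(kmax, n - 1)
    lags = np.arange(1, kmax + 1) * dt
    msd_t = np.empty(kmax)
    msd_p = np.empty(kmax)
    counts = np.empty(kmax, dtype=int)
    for k in range(1, kmax + 1):
        dth = theta[k:] - theta[:-k]
        dph = phi[k:] - phi[:-k]
        if metric_corrected:
            dph = dph * np.sin(theta[:-k])
        msd_t[k - 1] = np.mean(dth ** 2)
        msd_p[k - 1] = np.mean(dph ** 2)
        counts[k - 1] = dth.size
    return AngularMSD(lags=lags, msd_theta=msd_t, msd_phi=msd_p, counts=counts)


def msd_scaling_exponent(msd: AngularMSD, component: str = "phi",
                         lag_range: tuple | None = None) -> float:
    """Least-squares slope of log(MSD) vs log(tau) over a lag range.

    ``lag_range=(tau_min, tau_max)`` in seconds; default is the first
    quartile of available lags (the short-time regime, where ballistic
    motion shows slope 2 and diffusive motion slope 1).
    """
    values = {"theta": msd.msd_theta, "phi": msd.msd_phi}[component]
    if lag_range is None:
        n = max(3, int(np.ceil(msd.lags.size / 4)))
        sel = np.zeros(msd.lags.size, dtype=bool)
        sel[:n] = True
    else:
        sel = (msd.lags >= lag_range[0]) & (msd.lags <= lag_range[1])
    if np.count_nonzero(sel) < 3:
        raise ValueError("need at least 3 lags in range for a scaling fit")
    v = values[sel]
    if np.any(v <= 0):
        raise ValueError("zero MSD values in range: log-log fit undefined")
    slope, _ = np.polyfit(np.log(msd.lags[sel]), np.log(v), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# feature tracking on equirectangular map sequences

@dataclass(frozen=True)
class TrackerParams:
    """Reference patch-tracker parameters.

    patch_size: odd template side (px); search_radius: max displacement per
    frame (px); min_response: seeding intensity floor; corr_floor: tracks
    terminate when the best normalized cross-correlation drops below it.
    """

    patch_size: int = 15
    search_radius: int = 10
    min_response: float = 0.5
    corr_floor: float = 0.5


def _extract_patch(img: np.ndarray, row: int, col: int, half: int) -> np.ndarray:
    """Patch centred at (row, col); rows edge-clamped, columns wrapped."""
    rows = np.clip(np.arange(row - half, row + half + 1), 0, img.shape[0] - 1)
    cols = np.arange(col - half, col + half + 1) % img.shape[1]
    return img[np.ix_(rows, cols)]


def _parabolic_offset(c_m: float, c_0: float, c_p: float) -> float:
    denom = c_m - 2 * c_0 + c_p
    if denom >= 0:  # not a local max in this axis; keep integer peak
        return 0.0
    off = 0.5 * (c_m - c_p) / denom
    return float(np.clip(off, -0.5, 0.5))


def track_features(maps: list[EquirectMap], params: TrackerParams | None = None,
                   times: np.ndarray | None = None) -> list[FeatureTrack]:
    """Track bright features through an equirectangular map sequence.

    Features seed at local maxima of the first frame above
    ``params.min_response``; each is followed by normalized
    cross-correlation of a ``patch_size`` template within
    ``+-search_radius``, with phi-periodic wrapping and parabolic
    sub-pixel refinement of the correlation peak.  A track ends when the
    peak correlation falls below ``params.corr_floor``.  Featureless
    frames simply produce an empty track list.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 frames to track")
    p = params or TrackerParams()
    if p.patch_size % 2 != 1:
        raise ValueError("patch_size must be odd")
    frames = np.stack([m.data for m in maps])
    n_t, n_theta, n_phi = frames.shape
    if times is None:
        times = np.array([m.time_s if m.time_s is not None else float(k)
                          for k, m in enumerate(maps)])
    half = p.patch_size // 2
    margin = half + p.search_radius
    seeds = peak_local_max(frames[0], min_distance=p.patch_size,
                           threshold_abs=p.min_response,
                           exclude_border=(margin + 1, 0))
    tracks: list[FeatureTrack] = []
    for tid, (r0, c0) in enumerate(seeds):
        rows = [float(r0)]
        cols = [float(c0)]  # continuous (unwrapped) column coordinate
        fidx = [0]
        alive = True
        for t in range(1, n_t):
            ri = int(round(rows[-1]))
            ci = int(round(cols[-1])) % n_phi
            if ri < margin or ri >= n_theta - margin:
                break  # too close to a pole row to correlate
            template = _extract_patch(frames[t - 1], ri, ci, half)
            window = _extract_patch(frames[t], ri, ci, half + p.search_radius)
            corr = match_template(window, template)  # (2s+1, 2s+1)
            pk = np.unravel_index(np.argmax(corr), corr.shape)
            if corr[pk] < p.corr_floor:
                break
            dr = pk[0] - p.search_radius
            dc = pk[1] - p.search_radius
            sub_r = sub_c = 0.0
            if 0 < pk[0] < corr.shape[0] - 1:
                sub_r = _parabolic_offset(corr[pk[0] - 1, pk[1]], corr[pk],
                                          corr[pk[0] + 1, pk[1]])
            if 0 < pk[1] < corr.shape[1] - 1:
                sub_c = _parabolic_offset(corr[pk[0], pk[1] - 1], corr[pk],
                                          corr[pk[0], pk[1] + 1])
            rows.append(rows[-1] + dr + sub_r)
            cols.append(cols[-1] + dc + sub_c)
            fidx.append(t)
        if len(fidx) >= 2:
            fidx_arr = np.array(fidx)
            theta = (np.array(rows) + 0.5) * np.pi / n_theta
            phi = (np.array(cols) + 0.5) * 2 * np.pi / n_phi
            tracks.append(FeatureTrack(track_id=tid, frames=fidx_arr,
                                       times=np.asarray(times)[fidx_arr],
                                       theta=theta, phi=phi))
    return tracks


# ---------------------------------------------------------------------------
# time-averaged flow

@dataclass(frozen=True)
class FlowField:
    """Mean intensity plus per-cell mean tangential velocity (nm/s).

    ``v_theta``/``v_phi`` are the colatitudinal/azimuthal components on a
    coarse (theta, phi) grid; cells never visited by a track hold NaN.
    """

    mean_intensity: np.ndarray       # (n_theta, n_phi) mean over frames
    theta_edges: np.ndarray
    phi_edges: np.ndarray
    v_theta: np.ndarray              # (n_cells_theta, n_cells_phi) nm/s
    v_phi: np.ndarray
    speed: np.ndarray                # mean arc speed per cell, nm/s
    counts: np.ndarray

    def mean_track_speed(self) -> float:
        """Count-weighted mean arc speed (nm/s) over all visited cells."""
        ok = self.counts > 0
        if not np.any(ok):
            return float("nan")
        return float(np.sum(self.speed[ok] * self.counts[ok])
                     / np.sum(self.counts[ok]))


def time_averaged_flow(maps: list[EquirectMap], tracks: list[FeatureTrack],
                       geometry: SphereGeometry,
                       grid_shape: tuple = (6, 12)) -> FlowField:
    """Average track-step velocities on a coarse (theta, phi) grid.

    Each track step is mapped to Cartesian positions on the sphere, its
    arc-length speed computed, and its direction taken as the tangential
    unit vector of the step at the step midpoint, decomposed on the local
    (e_theta, e_phi) frame.  Steps accumulate in the grid cell of their
    starting angular position.
    """
    if not tracks:
        raise ValueError("no tracks supplied")
    n_ct, n_cp = grid_shape
    theta_edges = np.linspace(0, np.pi, n_ct + 1)
    phi_edges = np.linspace(0, 2 * np.pi, n_cp + 1)
    sum_vt = np.zeros(grid_shape)
    sum_vp = np.zeros(grid_shape)
    sum_sp = np.zeros(grid_shape)
    counts = np.zeros(grid_shape, dtype=int)
    for tr in tracks:
        phi_w = np.mod(tr.phi, 2 * np.pi)
        pos = spherical_to_cartesian(tr.theta, phi_w, geometry)
        for k in range(len(tr) - 1):
            dt = tr.times[k + 1] - tr.times[k]
            if dt <= 0:
                raise ValueError("non-increasing track times")
            v_nm = arc_speed(pos[k], pos[k + 1], dt, geometry,
                             check=False) * UM_PER_S_TO_NM_PER_S
            step = geometry.to_centered(pos[k + 1]) - geometry.to_centered(pos[k])
            mid = geometry.to_centered(pos[k]) + 0.5 * step
            nmid = np.linalg.norm(mid)
            if nmid == 0:
                continue
            u = mid / nmid
            tang = step - (step @ u) * u
            norm = np.linalg.norm(tang)
            th, ph = tr.theta[k], phi_w[k]
            if norm > 0:
                d = tang / norm
                e_th = np.array([np.cos(th) * np.cos(ph),
                                 np.cos(th) * np.sin(ph), -np.sin(th)])
                e_ph = np.array([-np.sin(ph), np.cos(ph), 0.0])
                vt, vp = v_nm * (d @ e_th), v_nm * (d @ e_ph)
            else:
                vt = vp = 0.0
            i = min(np.searchsorted(theta_edges, th, side="right") - 1, n_ct - 1)
            j = min(np.searchsorted(phi_edges, ph, side="right") - 1, n_cp - 1)
            sum_vt[i, j] += vt
            sum_vp[i, j] += vp
            sum_sp[i, j] += v_nm
            counts[i, j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        v_theta = np.where(counts > 0, sum_vt / counts, np.nan)
        v_phi = np.where(counts > 0, sum_vp / counts, np.nan)
        speed = np.where(counts > 0, sum_sp / counts, np.nan)
    mean_intensity = np.mean([m.data for m in maps], axis=0)
    return FlowField(mean_intensity=mean_intensity, theta_edges=theta_edges,
                     phi_edges=phi_edges, v_theta=v_theta, v_phi=v_phi,
                     speed=speed, counts=counts)
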