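"""Pattern taxonomy and density criteria for vesicle-bound filament systems.

Five polar pattern classes are distinguished on a vesicle: *streams*
(elongated, partial-coverage motile structures), *vortices* (closed
defect-free loops circulating at a fixed latitude between equator and
pole), *bands* (surface-spanning equatorial rings with two +1 pole
defects), *partially jammed* (a pinned +1/2 defect coexisting with moving
structures) and *globally jammed* (four frozen +1/2 defects, no coherent
motion).  Classification in the laboratory is by eye; here it is
operationalized as an auditable decision rule over measurable features
(sphere-area coverage, latitude profile, ridge closure, speeds, defect
counts), with every threshold exposed in :class:`ClassifierConfig`.

Density criteria: for hard rods of length L, the Onsager isotropic-nematic
transition sits at the critical surface density rho* = 3*pi / (2*L^2);
encapsulated actin concentration converts to a membrane surface density

    rho = c_A * N_A * (4/3 pi R^3) / (monomers_per_um * L_eff) / (4 pi R^2)
        = c_A * N_A * R / (3 * monomers_per_um * L_eff)

assuming every filament is membrane-bound, and to a packing fraction
phi = rho * L * w (rod rectangle approximation, width w).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .defects import DefectConfiguration, total_charge
from .projection import EquirectMap, latitude_intensity_profile

AVOGADRO = 6.02214076e23

PATTERN_LABELS = ("stream", "vortex", "band", "partially_jammed",
                  "globally_jammed", "empty")


@dataclass(frozen=True)
class DensityParams:
    """Concentration-to-density conversion parameters.

    c_A_nM: encapsulated actin concentration; R_um: vesicle radius;
    L_mode_um: mode of the log-normal filament length distribution;
    L_eff_um: effective per-filament length used in the monomer budget
    (the value reconciling the printed density, packing-fraction and
    critical-density figures; see methods note); monomers_per_um: actin
    monomers per um of filament; width_nm: filament width.
    """

    c_A_nM: float
    R_um: float = 18.0
    L_mode_um: float = 0.6
    L_eff_um: float = 0.55
    monomers_per_um: float = 370.0
    width_nm: float = 7.0

    def __post_init__(self) -> None:
        for name in ("R_um", "L_mode_um", "L_eff_um", "monomers_per_um",
                     "width_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.c_A_nM < 0:
            raise ValueError("c_A_nM must be non-negative")


def surface_density(params: DensityParams) -> float:
    """Membrane surface density (filaments/um^2) from encapsulated c_A.

    All filaments are assumed membrane-bound: the monomer content of the
    vesicle volume is divided into filaments of length ``L_eff_um`` and
    spread over the sphere surface.
    """
    monomers_per_um3 = params.c_A_nM * 1e-9 * 1e-15 * AVOGADRO  # nM -> mol/um^3
    monomers_per_um2 = monomers_per_um3 * params.R_um / 3.0     # volume/area
    return monomers_per_um2 / (params.monomers_per_um * params.L_eff_um)


def packing_fraction(rho_per_um2: float, L_um: float = 0.55,
                     width_nm: float = 7.0) -> float:
    """Surface packing fraction phi = rho * L * w (rectangle approximation)."""
    if rho_per_um2 < 0:
        raise ValueError("rho must be non-negative")
    if L_um <= 0 or width_nm <= 0:
        raise ValueError("L and width must be positive")
    return rho_per_um2 * L_um * width_nm * 1e-3


def onsager_critical_density(L_um: float) -> float:
    """Critical surface density rho* = 3*pi / (2*L^2) (filaments/um^2)."""
    if L_um <= 0:
        raise ValueError("L must be positive")
    return 3 * np.pi / (2 * L_um ** 2)


def coverage_fraction(emap: EquirectMap, threshold: float) -> float:
    """Fraction of sphere *area* with map intensity above ``threshold``.

    Equirectangular pixels are weighted by sin(theta), so the value is a
    true area fraction in [0, 1] despite the polar stretch of the map.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    w = np.sin(emap.theta_centers)[:, None] * np.ones((1, emap.n_phi))
    above = emap.data > threshold
    return float(np.sum(w * above) / np.sum(w))


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision-rule thresholds (all tunable).

    Speeds in nm/s, motivated by the measured scales: moving structures
    at 40-50, jammed ones at 5-10.  ``intensity_threshold_rel`` sets the
    occupancy threshold as a fraction of the time-mean map maximum.
    """

    coverage_empty: float = 0.005
    coverage_full: float = 0.8
    v_jam_nm_s: float = 15.0
    v_move_nm_s: float = 25.0
    equator_band_deg: float = 15.0
    intensity_threshold_rel: float = 0.2
    ridge_occupancy: float = 0.9
    ridge_latitude_std_deg: float = 12.0


@dataclass(frozen=True)
class PatternResult:
    label: str
    features: dict
    warnings: tuple = ()


def _half_charges(defects: DefectConfiguration | None) -> int:
    if defects is None:
        return 0
    return sum(1 for d in defects.defects if abs(d.charge) == Fraction(1, 2))


def _plus_one_charges(defects: DefectConfiguration | None) -> int:
    if defects is None:
        return 0
    return sum(1 for d in defects.defects if d.charge == Fraction(1))


def classify_pattern(maps: list[EquirectMap],
                     structure_speeds_nm_s,
                     defects: DefectConfiguration | None = None,
                     defect_speeds_nm_s=None,
                     config: ClassifierConfig | None = None) -> PatternResult:
    """Classify one vesicle's pattern from maps, speeds and defect input.

    ``structure_speeds_nm_s`` holds one mean speed per tracked structure;
    ``defect_speeds_nm_s`` (optional, parallel to ``defects.defects``)
    carries each defect's local speed, needed to recognize the pinned
    defect of a partially jammed state.  Returns the label plus the full
    feature vector for auditability; contradictory defect input (full
    coverage with total charge != +2) is reported as a warning, never an
    exception.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 frames to classify")
    cfg = config or ClassifierConfig()
    mean_map = EquirectMap(np.mean([m.data for m in maps], axis=0),
                           maps[0].geometry)
    peak = float(mean_map.data.max())
    thr = cfg.intensity_threshold_rel * peak
    coverage = coverage_fraction(mean_map, thr) if peak > 0 else 0.0

    # ridge geometry: per-phi-column occupancy and intensity-weighted latitude
    above = mean_map.data > thr
    col_occ = above.any(axis=0)
    occupancy = float(np.mean(col_occ))
    theta_c = mean_map.theta_centers
    ridge_theta = np.full(mean_map.n_phi, np.nan)
    for j in np.nonzero(col_occ)[0]:
        w = np.where(above[:, j], mean_map.data[:, j], 0.0)
        ridge_theta[j] = float(np.sum(w * theta_c) / np.sum(w))
    ridge_std_deg = (float(np.degrees(np.nanstd(ridge_theta)))
                     if np.any(col_occ) else float("nan"))

    if peak > 0:
        profile = latitude_intensity_profile(mean_map)
        peak_lat_deg = float(np.degrees(profile.peak_theta()))
    else:
        peak_lat_deg = float("nan")

    speeds = np.atleast_1d(np.asarray(structure_speeds_nm_s, dtype=float))
    median_speed = float(np.median(speeds)) if speeds.size else float("nan")
    has_moving = bool(speeds.size and np.any(speeds >= cfg.v_move_nm_s))
    n_half = _half_charges(defects)
    n_plus1 = _plus_one_charges(defects)
    d_speeds = (np.atleast_1d(np.asarray(defect_speeds_nm_s, dtype=float))
                if defect_speeds_nm_s is not None else None)
    pinned_half = bool(
        defects is not None and d_speeds is not None and any(
            abs(d.charge) == Fraction(1, 2) and v < cfg.v_jam_nm_s
            for d, v in zip(defects.defects, d_speeds)))

    warnings = []
    if defects is not None and len(defects) and defects.covers_full_surface:
        q = total_charge(defects)
        if q != 2:
            warnings.append(
                f"full-coverage defect input has total charge {q}, expected +2")

    features = {
        "coverage": coverage,
        "peak_latitude_deg": peak_lat_deg,
        "phi_occupancy": occupancy,
        "ridge_latitude_std_deg": ridge_std_deg,
        "median_structure_speed_nm_s": median_speed,
        "has_moving_structure": has_moving,
        "n_half_charge_defects": n_half,
        "n_plus_one_defects": n_plus1,
        "pinned_half_defect": pinned_half,
    }

    near_equator = (np.isfinite(peak_lat_deg)
                    and abs(peak_lat_deg - 90.0) <= cfg.equator_band_deg)
    closed_ridge = (occupancy >= cfg.ridge_occupancy
                    and np.isfinite(ridge_std_deg)
                    and ridge_std_deg <= cfg.ridge_latitude_std_deg)

    if coverage < cfg.coverage_empty:
        label = "empty"
    elif (coverage >= cfg.coverage_full and median_speed < cfg.v_jam_nm_s
          and n_half >= 4):
        label = "globally_jammed"
    elif (coverage >= cfg.coverage_full and median_speed >= cfg.v_move_nm_s
          and (n_plus1 == 2 or (defects is None and near_equator
                                and occupancy >= cfg.ridge_occupancy))):
        label = "band"
    elif pinned_half and has_moving:
        label = "partially_jammed"
    elif (closed_ridge and coverage < cfg.coverage_full
          and median_speed >= cfg.v_move_nm_s):
        label = "vortex"
    else:
        label = "stream"
    return PatternResult(label=label, features=features,
                         warnings=tuple(warnings))
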