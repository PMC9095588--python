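"""Topological defect bookkeeping on the vesicle sphere.

A polar pattern covering the whole sphere must carry total topological
charge +2 (Poincaré–Hopf); full-coverage patterns accommodate this either
as two +1 pole defects (bands) or four +1/2 defects (globally jammed
states).  Patterns covering only part of the surface — streams, vortices,
partially jammed states — are not bound by the constraint.

The geometric descriptor of a four-defect state is the set of six pair
angles theta_ij between the radii to defects i and j; their mean is
109.47 deg (arccos(-1/3)) for a regular tetrahedral arrangement and
120 deg for four defects equally spaced on a great circle.

Charges are stored as exact rationals (``fractions.Fraction``) so that
charge sums are never subject to floating-point error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np

from .geometry import SphereGeometry, Trajectory, central_angle

TETRAHEDRAL_ANGLE_DEG = float(np.degrees(np.arccos(-1.0 / 3.0)))  # 109.47...
PLANAR_ANGLE_DEG = 120.0

#: defect charges observed in vesicle-bound polar patterns
ALLOWED_CHARGES = (Fraction(1, 2), Fraction(-1, 2), Fraction(1), Fraction(-1))


def parse_charge(value) -> Fraction:
    """Parse a charge given as Fraction, number, or string like '+1/2'."""
    if isinstance(value, Fraction):
        q = value
    elif isinstance(value, str):
        q = Fraction(value.replace(" ", ""))
    else:
        q = Fraction(value).limit_denominator(2)
        if float(q) != float(value):
            raise ValueError(f"charge {value!r} is not a half-integer")
    if q not in ALLOWED_CHARGES:
        raise ValueError(f"charge {value!r} not in allowed set "
                         f"{{+1/2, -1/2, +1, -1}}")
    return q


def format_charge(q: Fraction) -> str:
    return f"{'+' if q > 0 else ''}{q}"


@dataclass(frozen=True)
class Defect:
    """A charged point defect on the sphere at one time."""

    position: np.ndarray  # lab-frame Cartesian, um, on sphere
    charge: Fraction
    time_s: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position",
                           np.asarray(self.position, dtype=float))
        object.__setattr__(self, "charge", parse_charge(self.charge))


@dataclass(frozen=True)
class DefectConfiguration:
    """Set of defects at a common time on one vesicle.

    ``covers_full_surface`` is a ground-truth/user flag: only patterns that
    span the whole sphere are bound by the +2 charge requirement.
    """

    defects: tuple
    geometry: SphereGeometry
    covers_full_surface: bool = True

    def __post_init__(self) -> None:
        defects = tuple(self.defects)
        times = {d.time_s for d in defects}
        if len(times) > 1:
            raise ValueError(f"defects span multiple times: {sorted(times)}")
        object.__setattr__(self, "defects", defects)

    def __len__(self) -> int:
        return len(self.defects)

    @property
    def positions(self) -> np.ndarray:
        return np.array([d.position for d in self.defects])


@dataclass(frozen=True)
class PairAngleSeries:
    """Per-frame pair angles (deg) of a tracked defect set."""

    times: np.ndarray                 # (n_t,) s
    pair_angles_deg: np.ndarray       # (n_t, n_pairs), lexicographic pair order
    mean_angle_deg: np.ndarray        # (n_t,)

    @property
    def temporal_std_deg(self) -> float:
        """Std of the per-frame mean pair angle over time (stability metric)."""
        return float(np.std(self.mean_angle_deg))


def pair_angles(config: DefectConfiguration) -> np.ndarray:
    """Central angles (deg) of every unordered defect pair, lexicographic."""
    if len(config) < 2:
        raise ValueError("need at least 2 defects for pair angles")
    pos = config.positions
    out = [central_angle(pos[i], pos[j], config.geometry)
           for i, j in combinations(range(len(config)), 2)]
    return np.degrees(np.array(out))


def mean_pair_angle(config: DefectConfiguration) -> float:
    """Arithmetic mean (deg) of the n(n-1)/2 pair angles."""
    return float(np.mean(pair_angles(config)))


def total_charge(config: DefectConfiguration) -> Fraction:
    """Exact rational sum of defect charges."""
    if len(config) == 0:
        raise ValueError("empty configuration")
    return sum((d.charge for d in config.defects), Fraction(0))


@dataclass(frozen=True)
class PoincareHopfResult:
    ok: bool
    message: str
    total_charge: Fraction | None = None


def validate_poincare_hopf(config: DefectConfiguration) -> PoincareHopfResult:
    """Check the +2 total-charge requirement for full-coverage patterns.

    Configurations with ``covers_full_surface=False`` always pass: partial
    patterns (streams, vortices, partial jams) are not topologically bound
    and may be entirely defect-free.
    """
    if not config.covers_full_surface:
        return PoincareHopfResult(
            True, "partial coverage: no topological charge constraint",
            total_charge(config) if len(config) else None)
    q = total_charge(config)
    if q == 2:
        return PoincareHopfResult(
            True, f"full coverage with total charge {format_charge(q)}", q)
    return PoincareHopfResult(
        False,
        f"full-coverage pattern has total charge {format_charge(q)}, "
        "but a sphere-spanning orientation field requires +2", q)


def classify_configuration(mean_angle_deg: float, tol_deg: float = 2.0) -> str:
    """Label a 4-defect arrangement tetrahedral / planar / intermediate.

    ``tol_deg`` must be smaller than half the gap between the tetrahedral
    (109.47 deg) and planar (120 deg) references, else the classes overlap.
    """
    half_gap = (PLANAR_ANGLE_DEG - TETRAHEDRAL_ANGLE_DEG) / 2
    if not 0 < tol_deg < half_gap:
        raise ValueError(
            f"tol_deg must lie in (0, {half_gap:.2f}) to keep the "
            "tetrahedral and planar classes disjoint")
    if abs(mean_angle_deg - TETRAHEDRAL_ANGLE_DEG) <= tol_deg:
        return "tetrahedral"
    if abs(mean_angle_deg - PLANAR_ANGLE_DEG) <= tol_deg:
        return "planar"
    return "intermediate"


def configuration_series(tracks: list[Trajectory],
                         geometry: SphereGeometry | None = None) -> PairAngleSeries:
    """Pair-angle time series of simultaneously tracked defects.

    All tracks must share one time base.  Returns per-frame pair angles and
    their mean; the temporal std of the mean is the stability metric (a
    jammed state holds its configuration, an active nematic oscillates).
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 defect tracks")
    geometry = geometry or tracks[0].geometry
    times = tracks[0].times
    for k, tr in enumerate(tracks[1:], start=1):
        if tr.times.shape != times.shape or not np.allclose(tr.times, times):
            raise ValueError(f"track {k} has a mismatched time base")
    pos = np.stack([tr.positions for tr in tracks], axis=1)  # (n_t, n_d, 3)
    pairs = list(combinations(range(len(tracks)), 2))
    ang = np.empty((times.size, len(pairs)))
    for c, (i, j) in enumerate(pairs):
        ang[:, c] = np.degrees(central_angle(pos[:, i], pos[:, j], geometry))
    return PairAngleSeries(times=times, pair_angles_deg=ang,
                           mean_angle_deg=ang.mean(axis=1))
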