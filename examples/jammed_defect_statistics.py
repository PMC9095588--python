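"""Pair-angle statistics and topological bookkeeping of jammed defects.

A globally jammed vesicle carries four +1/2 defects (total charge +2, as
any full-coverage orientation field on a sphere must).  Their geometry is
summarized by the mean of the six pair angles: 109.5 deg for a
tetrahedral arrangement, 120 deg for a planar one.  A jammed state holds
its configuration; this script measures that stability.
"""

import numpy as np

from glidesphere import SphereGeometry, classify_configuration, \
    configuration_series, mean_pair_angle, total_charge, validate_poincare_hopf
from glidesphere.synthetic import SceneSpec, make_jammed_scene

geometry = SphereGeometry(np.zeros(3), 18.0)
scene = SceneSpec(geometry=geometry, dt_s=60.0, n_frames=30, seed=1)
jam = make_jammed_scene(scene, D_um2_s=1e-4)

cfg0 = jam.configuration_at(0)
print(f"total charge: {total_charge(cfg0)} "
      f"({validate_poincare_hopf(cfg0).message})")

m0 = mean_pair_angle(cfg0)
print(f"initial mean pair angle: {m0:.2f} deg -> "
      f"{classify_configuration(m0, tol_deg=2.0)}")

series = configuration_series(list(jam.trajectories))
print(f"over {scene.n_frames} frames (30 min): mean pair angle "
      f"{series.mean_angle_deg.mean():.2f} deg, temporal std "
      f"{series.temporal_std_deg:.3f} deg — the configuration is frozen, "
      "unlike the tetrahedral/planar oscillations of active nematic shells")
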