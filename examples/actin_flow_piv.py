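"""Quantify actin-flow directionality in the nuclear region.

Simulates a 2D actin texture inside the lamina disc in which 70% of the
regions move toward the nuclear centre, runs three-pass PIV on
consecutive frames, and classifies every vector inside the lamina
contour by its angle to the centre (0° = inward).
"""

import numpy as np

from ooclust import (
    OocyteScenario,
    classify_directions,
    generate_flow_frames,
    piv_multipass,
    segment_lamina_contour,
)

scenario = OocyteScenario(
    nucleus_radius=20.0, frame_interval=0.5, actin_inward_fraction=0.7, seed=2
)
series, truth = generate_flow_frames(scenario, n_frames=3)
px = series.voxel_size[2]

contour = segment_lamina_contour(
    np.asarray(series.channel("lamina", 0)[0], float), px, expansion=1.5
)
print(f"lamina contour: mean radius {contour.mean_radius():.1f} µm, "
      f"centre {np.round(contour.centre_of_mass, 1)} µm")

for t in range(2):
    field = piv_multipass(
        series.channel("actin", t)[0], series.channel("actin", t + 1)[0],
        px, series.frame_interval,
    )
    summary = classify_directions(field, contour.centre_of_mass, contour,
                                  speed_floor=1.8)
    f = summary.category_fractions
    print(f"frame {t}->{t+1}: {summary.n_vectors} vectors | "
          f"inward {f['inward']:.2f} outward {f['outward']:.2f} | "
          f"mean direction {summary.mean_direction:.0f}° "
          f"(CI {summary.ci95[0]:.0f}°–{summary.ci95[1]:.0f}°), "
          f"mean speed {summary.mean_speed:.1f} µm/min")
print("-> the inward fraction is far above the isotropic expectation of 1/3;")
print("   with ~35 vectors per frame pair it scatters around its expected value")
print("   of 0.8 = 0.7 + 0.3/3 (imposed bias plus isotropic spill-over), and a")
print("   mean direction near 0° confirms net centripetal flow")
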