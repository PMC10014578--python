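"""Kinetochore–actin interaction fraction with a mirrored-signal control.

Renders an airyscan-style volume with an actin cable network and 40
kinetochore spots, 18% of which are placed on a cable.  Spots are
measured against the Otsu-segmented, 30–1,000 µm³-gated actin surface
with the shortest-distance statistic; mirroring the spots along x serves
as the specificity control.
"""

import numpy as np

from ooclust import (
    detect_spots,
    generate_kinetochore_actin_volume,
    interaction_fraction,
    mirrored_control,
    segment_surface,
    shortest_distance_spot_surface,
)

series, truth = generate_kinetochore_actin_volume(
    n_spots=40, contact_prob=0.18, seed=1
)
surface = segment_surface(series.channel("actin", 0), series.voxel_size,
                          volume_gate=(30.0, 1000.0))
spots = detect_spots(series.channel("kinetochores", 0), series.voxel_size,
                     target_count=40)

frac = interaction_fraction(spots, surface, cutoff=0.25)

print(f"actin surface components (µm³): {np.round(surface.component_volumes, 1)}")
print(f"kinetochores detected: {len(spots)}")
print(f"interacting fraction (<=0.25 µm): {100 * frac:.1f}% "
      f"(programmed {100 * truth.spot_in_contact.mean():.1f}%)")

# the mirrored control is informative when a signal is strongly
# colocalized: reflecting the spots along x destroys the association
series_hi, truth_hi = generate_kinetochore_actin_volume(
    n_spots=40, contact_prob=0.8, seed=1
)
surface_hi = segment_surface(series_hi.channel("actin", 0), series_hi.voxel_size)
spots_hi = detect_spots(series_hi.channel("kinetochores", 0), series_hi.voxel_size,
                        target_count=40)
real = shortest_distance_spot_surface(spots_hi, surface_hi).distances
extent = (series_hi.data.shape[-1] - 1) * series_hi.voxel_size[2]
mirrored = shortest_distance_spot_surface(
    mirrored_control(spots_hi, extent), surface_hi, source="mirrored"
).distances
print(f"strongly colocalized scene: median distance real {np.median(real):.2f} µm "
      f"vs mirrored control {np.median(mirrored):.2f} µm")
print("-> the recovered interacting percentage matches the programmed rate, and")
print("   mirroring a colocalized signal pushes its distances away from zero")
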