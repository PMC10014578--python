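"""Measure chromosome clustering speed on a simulated porcine oocyte.

Generates a live-regime time-lapse (20 µm nucleus, 12 chromatin blobs,
5-min frames) whose largest pairwise chromatin distance truly shrinks at
0.43 µm/min after NEBD, segments the chromatin channel per frame and
reports the recovered clustering read-outs.
"""

import numpy as np

from ooclust import (
    OocyteScenario,
    clustering_speed,
    generate_oocyte_series,
    kinetics_from_foci_series,
    segment_chromatin_foci,
)

scenario = OocyteScenario(seed=1)
series, truth = generate_oocyte_series(scenario)

foci = [
    segment_chromatin_foci(series.channel("chromatin", t), series.voxel_size, frame=t)
    for t in range(series.n_frames)
]
kin = kinetics_from_foci_series(foci, series.times(), truth.nebd_time)

speed = clustering_speed(kin, (0.0, 30.0))
print(f"foci per frame:        {kin.n_foci.tolist()}")
print(f"largest pairwise distance (µm): {np.round(kin.largest_pairwise_distance, 1).tolist()}")
print(f"clustering speed 0-30 min: {speed:.3f} µm/min (generative rate 0.43)")
print("-> the distance between the two most separated chromosome surfaces")
print("   shrinks at ~0.43 µm/min while the chromosomes converge into a cluster")
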