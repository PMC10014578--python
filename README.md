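# ooclust

Quantitative 3D+t fluorescence-microscopy analysis of **chromosome
clustering in mammalian oocytes**.

After nuclear envelope breakdown (NEBD), human and porcine oocytes pull
their dispersed chromosomes into a single compact cluster before the
acentrosomal spindle assembles — a safeguard against chromosome loss
during the long gap phase of meiosis.  The early phase of clustering is
driven by a network of actin cables that forms in the disassembling
nucleus and migrates centripetally, dragging chromosomes by their arms
and kinetochores.  `ooclust` packages the bespoke image-analysis
procedures needed to quantify this process, together with a
ground-truthed synthetic microscopy generator so every stage is testable
without any microscope data.

## What it computes

| stage | read-out |
| --- | --- |
| `synthetic` | multi-channel 3D+t volumes (chromatin, kinetochores, actin, lamina, dextran, membrane) with exact ground truth |
| `segmentation` | Otsu/26-connectivity chromatin foci, band-pass spot detection, 30–1,000 µm³-gated actin surfaces, periodic-fit lamina contour |
| `kinetics` | largest pairwise distance *D*(t) between all chromosome surface points, clustering speed −Δ*D*/Δt, convex-hull volume, time to a single focus, 30 µm³ fragment classes, distance to the membrane |
| `nebd` | automatic NEBD trigger: mean dextran intensity in a 10 µm probe sphere vs an adaptive threshold median(history) + *k*·sd(history) |
| `flow` | translation stabilization, three-pass PIV (64→32→24 px windows, 50 % overlap), vector classification relative to the nuclear centre (inward/outward/sideways), circular mean ± 95 % CI |
| `coloc` | spot-to-surface shortest distances, interaction fractions, mirrored-signal specificity control, expected random overlap *f*<sub>a</sub>·*f*<sub>b</sub> |

The central statistic is the **largest pairwise distance**

&nbsp;&nbsp;&nbsp;&nbsp;*D*(t) = max<sub>i,j</sub> ‖x<sub>i</sub>(t) − x<sub>j</sub>(t)‖

over all chromosome surface points x; the clustering speed over a window
[t₀, t₁) is the mean of −Δ*D*/Δt between consecutive frames, reported
positive while chromosomes converge.

## Worked example

```bash
python examples/clustering_kinetics.py
```

```
foci per frame:        [12, 12, 12, 12, 11, 11, 11, 11, 10, 11]
largest pairwise distance (µm): [34.9, 34.7, 34.7, 34.4, 31.5, 28.6, 27.9, 24.3, 22.6, 21.6]
clustering speed 0-30 min: 0.402 µm/min (generative rate 0.43)
```

Twelve chromatin blobs are dispersed in a 20 µm-radius nucleus; after
NEBD (frame 2) the largest pairwise distance falls linearly and the
per-frame segmentation recovers the imposed 0.43 µm/min convergence rate
within a few per cent on this single oocyte (and to ~1 % when averaged
over 20 oocytes).  The other scripts in `examples/` demonstrate NEBD
detection (`nebd_detection.py`), PIV flow directionality
(`actin_flow_piv.py`), kinetochore–actin contact fractions with the
mirrored control (`kinetochore_actin_contacts.py`) and chromatin
fragment classification (`fragment_clustering.py`).

A thin CLI ties the stages into reproducible runs
(`ooclust simulate | segment | nebd | kinetics | flow | coloc | run-all`,
YAML config, exit code 2 signalling "no NEBD event" for pipeline
chaining); outputs are CSV tables stamped with a config manifest hash,
and identical config + seed reproduces them byte for byte.

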