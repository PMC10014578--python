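"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes the requested stages in dependency order
(segment → nebd → kinetics → flow → coloc) on either a loaded TIFF
series or a freshly simulated scenario, writing CSV outputs, a YAML run
manifest and a log.  Given identical config and seed the outputs are
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import interaction_fraction, shortest_distance_spot_surface
from .flow import classify_directions, piv_multipass, stabilize_translation
from .io import RunConfig, load_series, save_series, write_csv_with_manifest
from .kinetics import clustering_speed, kinetics_from_foci_series
from .nebd import detect_nebd
from .segmentation import (
    SegmentationSettings,
    assign_kinetochores,
    detect_spots,
    segment_chromatin_foci,
    segment_lamina_contour,
    segment_surface,
)
from .synthetic import OocyteScenario, generate_oocyte_series
from .types import VolumeSeries

__all__ = ["run_pipeline", "PipelineResult"]

log = logging.getLogger("ooclust")

STAGE_ORDER = ("segment", "nebd", "kinetics", "flow", "coloc")


class StageError(RuntimeError):
    """Raised when a stage fails; names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


class PipelineResult(dict):
    """Dict of per-stage results plus output paths."""


def _get_series(config: RunConfig) -> VolumeSeries:
    if config.input_path:
        return load_series(
            config.input_path,
            voxel_size=config.voxel_size,
            frame_interval=config.frame_interval,
        )
    scenario = OocyteScenario(seed=config.seed, **config.scenario)
    series, truth = generate_oocyte_series(scenario)
    return series


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the configured stages and write all outputs.

    Outputs land in ``config.output_dir``: per-stage CSV tables (each
    stamped with the manifest hash), ``manifest.yaml`` (config echo,
    package version, seed) and ``run.log``.  Stage failures abort with
    the failing stage named; outputs of completed stages are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    mh = config.manifest_hash()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    result = PipelineResult()
    try:
        series = _get_series(config)
        result["series"] = series
        log.info("series: %d frames, channels %s", series.n_frames, series.channels)

        stages = [s for s in STAGE_ORDER if s in config.stages]
        foci_series = None
        nebd_time = None

        for stage in stages:
            try:
                if stage == "segment":
                    foci_series = []
                    settings = SegmentationSettings(
                        min_volume_um3=config.min_focus_volume_um3
                    )
                    for t in range(series.n_frames):
                        foci = segment_chromatin_foci(
                            series.channel("chromatin", t),
                            series.voxel_size,
                            settings,
                            frame=t,
                        )
                        if "kinetochores" in series.channels:
                            spots = detect_spots(
                                series.channel("kinetochores", t), series.voxel_size
                            )
                            foci = assign_kinetochores(foci, spots)
                        foci_series.append(foci)
                    rows = []
                    for foci in foci_series:
                        for i in range(foci.n_foci):
                            z, y, x = foci.centroids[i]
                            rows.append(
                                dict(
                                    frame=foci.frame,
                                    id=i + 1,
                                    z_um=z,
                                    y_um=y,
                                    x_um=x,
                                    volume_um3=foci.volumes[i],
                                    has_kinetochore=bool(foci.has_kinetochore[i]),
                                )
                            )
                    write_csv_with_manifest(pd.DataFrame(rows), out / "objects.csv", mh)
                    result["foci_series"] = foci_series

                elif stage == "nebd":
                    event, nebd_log = detect_nebd(
                        series,
                        k=config.nebd_k,
                        min_history=config.nebd_min_history,
                        diameter=config.probe_diameter_um,
                    )
                    write_csv_with_manifest(nebd_log, out / "nebd_log.csv", mh)
                    result["nebd_event"] = event
                    if event.triggered:
                        nebd_time = event.trigger_time

                elif stage == "kinetics":
                    if foci_series is None:
                        raise ValueError("kinetics requires the segment stage")
                    if config.nebd_frame is not None:
                        nebd_time = config.nebd_frame * series.frame_interval
                    if nebd_time is None:
                        raise ValueError(
                            "kinetics requires an NEBD time (nebd stage or "
                            "nebd_frame override)"
                        )
                    kin = kinetics_from_foci_series(
                        foci_series,
                        series.times(),
                        nebd_time,
                        use_vertices=config.use_vertices,
                    )
                    table = pd.DataFrame(
                        dict(
                            frame=np.arange(series.n_frames),
                            t_min=kin.time_from_nebd,
                            lpd_um=kin.largest_pairwise_distance,
                            hull_um3=kin.convex_hull_volume,
                            n_foci=kin.n_foci,
                        )
                    )
                    write_csv_with_manifest(table, out / "kinetics.csv", mh)
                    speeds = []
                    for lo, hi in config.speed_intervals:
                        try:
                            v = clustering_speed(kin, (lo, hi))
                        except ValueError:
                            v = np.nan
                        speeds.append(
                            dict(interval_start=lo, interval_end=hi, speed_um_per_min=v)
                        )
                    write_csv_with_manifest(pd.DataFrame(speeds), out / "speeds.csv", mh)
                    result["kinetics"] = kin
                    result["speeds"] = speeds

                elif stage == "flow":
                    if "actin" not in series.channels or "lamina" not in series.channels:
                        raise ValueError("flow requires actin and lamina channels")
                    stab, shifts = stabilize_translation(series, "lamina")
                    mid_z = stab.shape_zyx[0] // 2
                    px = stab.voxel_size[2]
                    contour = segment_lamina_contour(
                        np.asarray(stab.channel("lamina", 0)[mid_z], dtype=float),
                        px,
                        expansion=config.lamina_expansion_um,
                    )
                    rows, summaries = [], []
                    for t in range(stab.n_frames - 1):
                        fld = piv_multipass(
                            stab.channel("actin", t)[mid_z],
                            stab.channel("actin", t + 1)[mid_z],
                            px,
                            stab.frame_interval,
                        )
                        summ = classify_directions(
                            fld,
                            contour.centre_of_mass,
                            contour,
                            speed_floor=config.speed_floor_um_min,
                            seed=config.seed,
                        )
                        summaries.append(summ)
                        for p, v, ok in zip(fld.positions, fld.vectors, fld.valid):
                            rows.append(
                                dict(
                                    frame=t,
                                    y_um=p[0],
                                    x_um=p[1],
                                    vy=v[0],
                                    vx=v[1],
                                    speed=float(np.hypot(v[0], v[1])),
                                    valid=bool(ok),
                                )
                            )
                    write_csv_with_manifest(pd.DataFrame(rows), out / "vectors.csv", mh)
                    write_csv_with_manifest(
                        pd.DataFrame(
                            dict(
                                frame=np.arange(len(summaries)),
                                mean_direction_deg=[s.mean_direction for s in summaries],
                                mean_speed_um_min=[s.mean_speed for s in summaries],
                                inward=[s.category_fractions["inward"] for s in summaries],
                                outward=[s.category_fractions["outward"] for s in summaries],
                            )
                        ),
                        out / "flow_summary.csv",
                        mh,
                    )
                    result["flow_summaries"] = summaries

                elif stage == "coloc":
                    needed = {"actin", "kinetochores"}
                    if not needed <= set(series.channels):
                        raise ValueError("coloc requires actin and kinetochore channels")
                    surface = segment_surface(
                        series.channel("actin", 0),
                        series.voxel_size,
                        volume_gate=config.surface_gate_um3,
                    )
                    spots = detect_spots(
                        series.channel("kinetochores", 0), series.voxel_size
                    )
                    dist = shortest_distance_spot_surface(spots, surface)
                    frac = interaction_fraction(
                        spots, surface, cutoff=config.interaction_cutoff_um
                    )
                    table = pd.DataFrame(
                        dict(
                            spot_id=np.arange(len(spots)),
                            z=spots.points[:, 0],
                            y=spots.points[:, 1],
                            x=spots.points[:, 2],
                            distance_um=dist.distances,
                            source=dist.source,
                        )
                    )
                    write_csv_with_manifest(table, out / "distances.csv", mh)
                    write_csv_with_manifest(
                        pd.DataFrame(
                            [dict(cutoff_um=config.interaction_cutoff_um, fraction=frac)]
                        ),
                        out / "fractions.csv",
                        mh,
                    )
                    result["interaction_fraction"] = frac

                log.info("stage %s done", stage)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                log.error("stage %s failed: %s", stage, exc)
                raise StageError(stage, exc) from exc

        manifest = dict(
            config=config.to_dict(),
            version=__version__,
            seed=config.seed,
            manifest_hash=mh,
        )
        import yaml as _yaml

        (out / "manifest.yaml").write_text(_yaml.safe_dump(manifest, sort_keys=True))
        result["output_dir"] = str(out)
        return result
    finally:
        log.removeHandler(handler)
        handler.close()
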