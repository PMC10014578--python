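"""TIFF/OME-TIFF reading and writing plus run configuration.

Volumes are stored as OME-TIFF with TZCYX axis order and physical
calibration in the OME metadata; ground-truth tables and all analysis
outputs are plain CSV.  ``RunConfig`` gathers every stage parameter and
round-trips losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .types import VolumeSeries

__all__ = ["RunConfig", "load_series", "save_series", "write_csv_with_manifest"]

log = logging.getLogger("ooclust")


@dataclass
class RunConfig:
    """Configuration of a reproducible analysis run."""

    input_path: str | None = None
    output_dir: str = "ooclust_out"
    channel_map: dict[str, int] = field(default_factory=dict)
    voxel_size: tuple[float, float, float] = (3.0, 0.5, 0.5)
    frame_interval: float = 5.0
    nebd_frame: int | None = None  # manual override; None = auto-detect
    seed: int = 0
    stages: tuple[str, ...] = ("segment", "nebd", "kinetics")
    # stage parameters (defaults mirror the analysis modules)
    min_focus_volume_um3: float = 0.5
    nebd_k: float = 6.0
    nebd_min_history: int = 6
    probe_diameter_um: float = 10.0
    speed_intervals: tuple[tuple[float, float], ...] = ((0.0, 30.0), (30.0, 50.0))
    surface_gate_um3: tuple[float, float] = (30.0, 1000.0)
    interaction_cutoff_um: float = 0.25
    speed_floor_um_min: float = 1.8
    lamina_expansion_um: float = 1.5
    use_vertices: bool = True
    # scenario overrides for simulated runs (passed to OocyteScenario)
    scenario: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = list(self.channel_map.values())
        if len(set(idx)) != len(idx):
            raise ValueError("channel indices must be unique")
        if min(self.voxel_size) <= 0:
            raise ValueError("voxel sizes must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # tuples → lists for YAML friendliness (restored on load)
        return yaml.safe_load(yaml.safe_dump(_listify(d)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("voxel_size", "stages", "surface_gate_um3"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "speed_intervals" in d and d["speed_intervals"] is not None:
            d["speed_intervals"] = tuple(tuple(i) for i in d["speed_intervals"])
        return cls(**d)

    def manifest_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


# ---------------------------------------------------------------------------
# TIFF IO


def save_series(series: VolumeSeries, path: str | Path) -> None:
    """Write a series as OME-TIFF with TZCYX axis order and calibration."""
    data = np.moveaxis(series.data, 1, 2)  # TCZYX → TZCYX
    vz, vy, vx = series.voxel_size
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "TZCYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "TimeIncrement": series.frame_interval,
            "TimeIncrementUnit": "min",
            "Channel": {"Name": list(series.channels)},
        },
    )


def load_series(
    path: str | Path,
    channels: tuple[str, ...] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    frame_interval: float | None = None,
    axes: str | None = None,
) -> VolumeSeries:
    """Read a TIFF/OME-TIFF stack into a calibrated series.

    Axis order is taken from the file metadata (or ``axes`` override);
    missing T/C/Z axes are treated as singletons.  Calibration missing
    from the metadata falls back to the supplied values with a logged
    warning; if neither is available an error names the ambiguity.
    """
    with tifffile.TiffFile(str(path)) as tf:
        s = tf.series[0]
        arr = s.asarray()
        file_axes = axes or s.axes
        meta_voxel = meta_dt = None
        meta_channels = None
        if tf.ome_metadata:
            meta_voxel, meta_dt, meta_channels = _parse_ome(tf.ome_metadata)

    file_axes = file_axes.upper().replace("S", "C").replace("Q", "T")
    unknown = set(file_axes) - set("TZCYX")
    if unknown or "Y" not in file_axes or "X" not in file_axes:
        raise ValueError(
            f"cannot resolve axes {file_axes!r} of {path}: expected a "
            "combination of T, Z, C, Y, X"
        )
    # expand to full TZCYX then reorder to TCZYX
    for ax in "TZC":
        if ax not in file_axes:
            arr = arr[np.newaxis]
            file_axes = ax + file_axes
    order = [file_axes.index(ax) for ax in "TCZYX"]
    arr = np.transpose(arr, order)

    vs = meta_voxel or voxel_size
    if vs is None:
        raise ValueError("voxel size missing from metadata and config")
    if meta_voxel is None and voxel_size is not None:
        log.warning("voxel size missing from %s metadata; using config value", path)
    dt = meta_dt or frame_interval
    if dt is None:
        if arr.shape[0] > 1:
            raise ValueError("frame interval missing from metadata and config")
        dt = 1.0
    ch = channels or meta_channels or tuple(f"ch{i}" for i in range(arr.shape[1]))
    return VolumeSeries(arr, tuple(ch), tuple(vs), float(dt))


def _parse_ome(ome_xml: str):
    """Extract (z, y, x) voxel size, frame interval and channel names."""
    import re

    def grab(attr):
        m = re.search(rf'{attr}="([0-9.eE+-]+)"', ome_xml)
        return float(m.group(1)) if m else None

    vz, vy, vx = grab("PhysicalSizeZ"), grab("PhysicalSizeY"), grab("PhysicalSizeX")
    voxel = (vz, vy, vx) if None not in (vz, vy, vx) else None
    dt = grab("TimeIncrement")
    names = re.findall(r'<Channel[^>]*Name="([^"]+)"', ome_xml) or None
    return voxel, dt, tuple(names) if names else None


def write_csv_with_manifest(df, path: str | Path, manifest_hash: str) -> None:
    """Write a CSV whose first line records the run-manifest hash."""
    with open(path, "w", newline="") as f:
        f.write(f"# manifest_hash={manifest_hash}\n")
        df.to_csv(f, index=False)
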