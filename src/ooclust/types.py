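"""Core in-memory containers shared across the analysis stages.

Conventions
-----------
* Arrays are indexed ``(t, c, z, y, x)`` for series and ``(z, y, x)`` for
  single volumes; 2D frames are ``(y, x)``.
* All physical coordinates and sizes are micrometres (µm), times are
  minutes, intensities are arbitrary units (a.u.).
* ``voxel_size`` is ``(z, y, x)`` µm.  Voxel *centres* sit at
  ``index * voxel_size`` so index 0 maps to 0 µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VolumeSeries",
    "LabeledFoci",
    "SpotSet",
    "SurfaceMask",
    "LaminaContour",
    "VelocityField",
    "DirectionSummary",
    "ClusterKinetics",
    "NebdEvent",
    "IntensityHistory",
]


@dataclass
class VolumeSeries:
    """A time-ordered multi-channel 3D intensity series with calibration.

    Parameters
    ----------
    data
        Array of shape ``(T, C, Z, Y, X)``.
    channels
        Channel names, one per ``C`` index (e.g. ``"chromatin"``,
        ``"dextran"``).
    voxel_size
        ``(z, y, x)`` voxel edge lengths in µm.
    frame_interval
        Time between consecutive frames in minutes.
    """

    data: np.ndarray
    channels: tuple[str, ...]
    voxel_size: tuple[float, float, float]
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"VolumeSeries data must be (T, C, Z, Y, X); got {self.data.shape}"
            )
        if self.data.shape[1] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel names for C={self.data.shape[1]}"
            )
        self.channels = tuple(self.channels)
        vz, vy, vx = self.voxel_size
        if min(vz, vy, vx) <= 0:
            raise ValueError("voxel sizes must be positive")
        self.voxel_size = (float(vz), float(vy), float(vx))

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in {self.channels}") from None

    def channel(self, name: str, frame: int | None = None) -> np.ndarray:
        """Return one channel: a ``(T, Z, Y, X)`` stack or one ``(Z, Y, X)`` frame."""
        c = self.channel_index(name)
        if frame is None:
            return self.data[:, c]
        return self.data[frame, c]

    def times(self) -> np.ndarray:
        """Frame acquisition times in minutes from frame 0."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval


@dataclass
class LabeledFoci:
    """Segmented chromatin objects of one timepoint.

    ``labels`` is an integer 3D map with contiguous positive labels and
    background 0; per-object tables are aligned with label order (label
    ``i`` is row ``i - 1``).
    """

    frame: int
    labels: np.ndarray
    centroids: np.ndarray  # (N, 3) µm, (z, y, x), intensity-weighted
    volumes: np.ndarray  # (N,) µm³
    has_kinetochore: np.ndarray  # (N,) bool
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if self.centroids.size == 0:
            self.centroids = self.centroids.reshape(0, 3)
        self.volumes = np.asarray(self.volumes, dtype=float).ravel()
        self.has_kinetochore = np.asarray(self.has_kinetochore, dtype=bool).ravel()

    @property
    def n_foci(self) -> int:
        return len(self.volumes)

    def surface_points(self) -> np.ndarray:
        """µm coordinates (z, y, x) of all labelled voxels (object "vertices")."""
        idx = np.argwhere(self.labels > 0)
        return idx * np.asarray(self.voxel_size)


@dataclass
class SpotSet:
    """Point detections (e.g. kinetochores, Formin-2 puncta) in µm."""

    points: np.ndarray  # (N, 3) µm, (z, y, x)
    channel: str = ""
    truncated: bool = False  # fewer maxima than the requested target count

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class SurfaceMask:
    """Binary mask of volume-gated segmented structures."""

    mask: np.ndarray  # bool (Z, Y, X)
    voxel_size: tuple[float, float, float]
    component_volumes: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def voxel_volume(self) -> float:
        vz, vy, vx = self.voxel_size
        return vz * vy * vx

    @property
    def total_volume(self) -> float:
        return float(self.mask.sum()) * self.voxel_volume


@dataclass
class LaminaContour:
    """Closed boundary of the nuclear region in one 2D frame.

    ``polyline`` is ``(M, 2)`` in µm, ``(y, x)``, with the first point
    repeated last (closed); ``expansion`` is the outward margin already
    applied to the fitted radius.
    """

    polyline: np.ndarray
    centre_of_mass: tuple[float, float]
    expansion: float

    def contains(self, points_yx: np.ndarray) -> np.ndarray:
        """Vectorised point-in-polygon test (µm coordinates)."""
        from matplotlib.path import Path as _MplPath  # lazy, optional

        try:
            path = _MplPath(self.polyline)
            return path.contains_points(np.atleast_2d(points_yx))
        except Exception:  # pragma: no cover - matplotlib always present in practice
            return _points_in_polygon(np.atleast_2d(points_yx), self.polyline)

    def mean_radius(self) -> float:
        cy, cx = self.centre_of_mass
        d = self.polyline[:-1] - np.array([cy, cx])
        return float(np.hypot(d[:, 0], d[:, 1]).mean())


def _points_in_polygon(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Ray-casting fallback for point-in-polygon."""
    y, x = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    py, px = poly[:-1, 0], poly[:-1, 1]
    qy, qx = np.roll(py, -1), np.roll(px, -1)
    for i in range(len(py)):
        cond = (py[i] > y) != (qy[i] > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = (qx[i] - px[i]) * (y - py[i]) / (qy[i] - py[i]) + px[i]
        inside ^= cond & (x < xint)
    return inside


@dataclass
class VelocityField:
    """2D velocity vectors on a regular grid.

    Positions are window centres in µm ``(y, x)``; vectors are µm/min.
    ``valid`` flags vectors whose correlation peak passed the quality
    floor; ``inside_nucleus`` additionally restricts to the lamina
    contour and is always a subset of ``valid``.
    """

    positions: np.ndarray  # (N, 2) µm
    vectors: np.ndarray  # (N, 2) µm/min (vy, vx)
    valid: np.ndarray  # (N,) bool
    inside_nucleus: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.inside_nucleus is not None:
            self.inside_nucleus = np.asarray(self.inside_nucleus, dtype=bool) & self.valid

    @property
    def speeds(self) -> np.ndarray:
        return np.hypot(self.vectors[:, 0], self.vectors[:, 1])


@dataclass
class DirectionSummary:
    """Circular summary of flow directions relative to the nuclear centre.

    Angles are degrees with 0° = toward the centre.  Category fractions
    are computed over classified vectors and sum to 1 (``empty`` is set
    when no vector passes the speed/validity filters).
    """

    mean_direction: float
    ci95: tuple[float, float]
    mean_speed: float
    category_fractions: dict[str, float]
    n_vectors: int
    resultant_length: float
    empty: bool = False
    mean_undefined: bool = False


@dataclass
class ClusterKinetics:
    """Per-frame chromosome clustering read-outs.

    ``time_from_nebd`` in min; ``largest_pairwise_distance`` µm;
    ``convex_hull_volume`` µm³; optional ``mean_distance_to_membrane`` µm.
    """

    time_from_nebd: np.ndarray
    largest_pairwise_distance: np.ndarray
    convex_hull_volume: np.ndarray
    n_foci: np.ndarray
    mean_distance_to_membrane: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_from_nebd = np.asarray(self.time_from_nebd, dtype=float)
        self.largest_pairwise_distance = np.asarray(
            self.largest_pairwise_distance, dtype=float
        )
        self.convex_hull_volume = np.asarray(self.convex_hull_volume, dtype=float)
        self.n_foci = np.asarray(self.n_foci, dtype=int)


@dataclass
class NebdEvent:
    """Result of nuclear-envelope-breakdown detection."""

    triggered: bool
    trigger_frame: int | None = None
    trigger_time: float | None = None  # min from frame 0
    threshold_at_trigger: float | None = None
    intensity_at_trigger: float | None = None


@dataclass
class IntensityHistory:
    """Probe-sphere mean dextran intensity per frame."""

    frames: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
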