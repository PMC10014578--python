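"""Chromosome-clustering read-outs from segmented foci over time.

The central quantity is the *largest pairwise distance* between all
chromosome surface points (or centroids): its decrease per unit time is
the clustering speed, reported positive while chromosomes converge.
Complementary read-outs are the convex-hull volume enclosing all
chromosomes, the focus count, time to complete clustering, fragment
size/kinetochore classes and the mean distance to the cell membrane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .types import ClusterKinetics, LabeledFoci, SurfaceMask

__all__ = [
    "largest_pairwise_distance",
    "clustering_speed",
    "convex_hull_volume",
    "time_to_complete_clustering",
    "ClusteringOutcome",
    "classify_fragments",
    "mean_distance_to_membrane",
    "kinetics_from_foci_series",
]


def _foci_points(foci: LabeledFoci, use_vertices: bool) -> np.ndarray:
    if use_vertices:
        pts = foci.surface_points()
        if len(pts):
            return pts
    return foci.centroids


def largest_pairwise_distance(
    foci: LabeledFoci, use_vertices: bool = True
) -> float:
    """Maximum Euclidean distance (µm) over all pairs of focus points.

    With ``use_vertices`` the distance is taken over all labelled
    voxels (the discrete analogue of isosurface vertices); otherwise
    over intensity-weighted centroids.  Zero or one focus gives 0.
    """
    if foci.n_foci <= 1:
        return 0.0
    pts = _foci_points(foci, use_vertices)
    if len(pts) < 2:
        return 0.0
    # reduce to hull vertices first: the diameter is attained on the hull
    if len(pts) > 64:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    return float(pdist(pts).max())


def clustering_speed(
    kinetics: ClusterKinetics,
    interval: tuple[float, float],
    method: str = "mean_diff",
) -> float:
    """Mean clustering speed (µm/min) over a post-NEBD time interval.

    ``mean_diff`` (default) averages −Δd/Δt between consecutive frames
    whose midpoints fall in the half-open window ``[start, end)``;
    ``slope`` instead fits a least-squares line to d(t) over frames in
    the window and negates its slope.  Positive values mean converging
    chromosomes.
    """
    t = kinetics.time_from_nebd
    d = kinetics.largest_pairwise_distance
    start, end = interval
    if method == "slope":
        sel = (t >= start) & (t < end)
        if sel.sum() < 2:
            raise ValueError("insufficient frames in interval")
        coeff = np.polyfit(t[sel], d[sel], 1)
        return float(-coeff[0])
    if ((t >= start) & (t < end)).sum() < 2:
        raise ValueError("insufficient frames in interval")
    mids = 0.5 * (t[1:] + t[:-1])
    rates = -np.diff(d) / np.diff(t)
    sel = (mids >= start) & (mids < end)
    if sel.sum() < 1:
        raise ValueError("insufficient frames in interval")
    return float(rates[sel].mean())


def convex_hull_volume(foci: LabeledFoci, use_vertices: bool = True) -> float:
    """Volume (µm³) of the 3D convex hull of all focus points.

    Degenerate inputs (fewer than four points, or coplanar/collinear
    sets) return 0.
    """
    pts = _foci_points(foci, use_vertices)
    if len(pts) < 4:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)
    except QhullError:  # coplanar / collinear
        return 0.0


@dataclass(frozen=True)
class ClusteringOutcome:
    """Result of the time-to-complete-clustering rule."""

    clustered: bool
    time_min: float | None  # from NEBD
    frame: int | None
    non_monotone: bool  # focus count rose again after first reaching one


def time_to_complete_clustering(
    n_foci: np.ndarray, time_from_nebd: np.ndarray
) -> ClusteringOutcome:
    """Time from NEBD to the first frame with exactly one chromatin focus.

    If the count later rises again the first such frame is still
    reported, flagged ``non_monotone``; if the count never reaches one
    the outcome is not-clustered.
    """
    n = np.asarray(n_foci, dtype=int)
    t = np.asarray(time_from_nebd, dtype=float)
    if len(n) == 0:
        raise ValueError("empty focus-count series")
    ones = np.flatnonzero(n == 1)
    if len(ones) == 0:
        return ClusteringOutcome(False, None, None, False)
    first = int(ones[0])
    non_monotone = bool(np.any(n[first:] > 1))
    return ClusteringOutcome(True, float(t[first]), first, non_monotone)


_FRAGMENT_CLASSES = ("small_KT", "small_KT_free", "large_KT", "large_KT_free")


def classify_fragments(
    foci: LabeledFoci, size_threshold: float = 30.0
) -> list[str]:
    """Classify each focus by size and kinetochore content.

    Volumes strictly below ``size_threshold`` (µm³; default 30) are
    "small", at or above it "large"; the kinetochore flag splits each
    size class, giving {small_KT, small_KT_free, large_KT, large_KT_free}.
    """
    out = []
    for v, kt in zip(foci.volumes, foci.has_kinetochore):
        size = "small" if v < size_threshold else "large"
        out.append(f"{size}_KT" if kt else f"{size}_KT_free")
    return out


def mean_distance_to_membrane(foci: LabeledFoci, membrane: SurfaceMask) -> float:
    """Mean shortest Euclidean distance (µm) from focus centroids to the
    cell-membrane surface voxels."""
    if not membrane.mask.any():
        raise ValueError("empty membrane mask")
    if foci.n_foci == 0:
        raise ValueError("no foci")
    dist = ndimage.distance_transform_edt(
        ~membrane.mask, sampling=membrane.voxel_size
    )
    vs = np.asarray(membrane.voxel_size)
    idx = np.round(foci.centroids / vs).astype(int)
    idx = np.clip(idx, 0, np.array(membrane.mask.shape) - 1)
    return float(np.mean(dist[tuple(idx.T)]))


def kinetics_from_foci_series(
    foci_series: list[LabeledFoci],
    frame_times: np.ndarray,
    nebd_time: float,
    use_vertices: bool = True,
    membrane: SurfaceMask | None = None,
) -> ClusterKinetics:
    """Assemble the per-frame kinetics table from segmented foci.

    ``frame_times`` are acquisition times in minutes from the start of
    the series; output times are re-based to NEBD (0 = NEBD).
    """
    lpd, hull, counts, memb = [], [], [], []
    for foci in foci_series:
        lpd.append(largest_pairwise_distance(foci, use_vertices))
        hull.append(convex_hull_volume(foci, use_vertices))
        counts.append(foci.n_foci)
        if membrane is not None and foci.n_foci > 0:
            memb.append(mean_distance_to_membrane(foci, membrane))
        elif membrane is not None:
            memb.append(np.nan)
    return ClusterKinetics(
        time_from_nebd=np.asarray(frame_times, dtype=float) - nebd_time,
        largest_pairwise_distance=np.array(lpd),
        convex_hull_volume=np.array(hull),
        n_foci=np.array(counts),
        mean_distance_to_membrane=np.array(memb) if membrane is not None else None,
    )
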