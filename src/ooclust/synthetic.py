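"""Ground-truthed synthetic 3D(+t) fluorescence volumes of oocyte meiosis.

The generator emulates the geometry and statistics the analysis stages
assume, so every stage can be verified without real microscopy data:

* dispersed chromatin blobs that converge centripetally after a
  programmable NEBD time, with the *largest pairwise centroid distance*
  decreasing linearly at a programmable rate (µm/min) until the cluster
  has formed;
* a nuclear-lamina shell that persists and slowly compacts after NEBD;
* a dextran channel that is excluded from the nucleus before NEBD and
  floods it within two frames afterwards;
* kinetochore spots on a programmable fraction of chromatin foci;
* a 2D actin texture inside the lamina disc whose motion is inward
  toward the disc centre for a programmable fraction of regions and
  isotropic for the rest;
* zeocin-style fragmentation into kinetochore-containing and
  kinetochore-free chromatin fragments of given volumes.

All randomness flows from ``OocyteScenario.seed``; the same scenario is
bit-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import VolumeSeries

__all__ = [
    "OocyteScenario",
    "GroundTruth",
    "generate_oocyte_series",
    "generate_flow_frames",
    "generate_fragments",
    "generate_kinetochore_actin_volume",
]

_FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Live time-lapse calibration: confocal z-stacks every few minutes.
LIVE_VOXEL = (3.0, 0.5, 0.5)
#: Fixed / airyscan calibration: fine isotropic voxels.
AIRYSCAN_VOXEL = (0.19, 0.19, 0.19)


@dataclass(frozen=True)
class OocyteScenario:
    """Parameters of one simulated oocyte.

    Defaults describe a live porcine oocyte imaged through meiotic
    resumption: a ~20 µm-radius germinal vesicle inside a larger cell,
    12 chromatin blobs, 5-minute frames at 0.5 × 0.5 × 3 µm voxels and
    a post-NEBD convergence of the largest pairwise chromatin distance
    of 0.43 µm/min.
    """

    cell_radius: float = 28.0  # µm
    nucleus_radius: float = 20.0  # µm
    n_chromosomes: int = 12
    chromosome_radius: float = 2.0  # µm, FWHM of a rendered blob
    nebd_time: float = 10.0  # min from the start of the series
    convergence_speed: float = 0.43  # µm/min decrease of largest pairwise distance
    actin_inward_fraction: float = 0.7
    kinetochore_fraction: float = 1.0
    fragment_mode: bool = False
    fragment_volumes: tuple[float, ...] = ()
    fragment_kinetochore: tuple[bool, ...] | None = None
    small_fragment_speed_factor: float = 0.4  # KT-free small fragments converge slower
    noise_gaussian_sd: float = 4.0  # a.u. additive read noise
    noise_poisson_scale: float = 0.05  # counts per a.u.; 0 disables shot noise
    voxel_size: tuple[float, float, float] = LIVE_VOXEL
    frame_interval: float = 5.0  # min
    n_frames: int = 10
    seed: int = 0
    # Free texture parameters (cable density/thickness are not constrained
    # by any measured value; exposed for sensitivity checks).
    actin_speed: float = 3.0  # µm/min imposed texture speed in flow scenes
    actin_particle_density: float = 0.05  # particles per px² in flow scenes
    flow_patch_px: int = 32  # motion-coherence patch size in flow scenes
    chromatin_peak: float = 400.0  # a.u.
    cytoplasm_level: float = 120.0  # a.u. dextran level in the cytoplasm

    def validate(self) -> None:
        if not 0 < self.nucleus_radius < self.cell_radius:
            raise ValueError("need 0 < nucleus_radius < cell_radius")
        if not 0 <= self.actin_inward_fraction <= 1:
            raise ValueError("actin_inward_fraction must be in [0, 1]")
        if not 0 <= self.kinetochore_fraction <= 1:
            raise ValueError("kinetochore_fraction must be in [0, 1]")
        if self.convergence_speed < 0:
            raise ValueError("convergence_speed must be >= 0")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if min(self.voxel_size) <= 0 or self.frame_interval <= 0:
            raise ValueError("voxel sizes and frame interval must be positive")
        if self.fragment_mode:
            if len(self.fragment_volumes) == 0:
                raise ValueError("fragment_mode requires fragment_volumes")
            if any(v <= 0 for v in self.fragment_volumes):
                raise ValueError("fragment volumes must be positive")
            if self.fragment_kinetochore is not None and len(
                self.fragment_kinetochore
            ) != len(self.fragment_volumes):
                raise ValueError("fragment_kinetochore length mismatch")


@dataclass
class GroundTruth:
    """Everything the generator imposed, for oracle-style checks.

    ``centroids`` has shape ``(T, N, 3)`` in µm ``(z, y, x)``;
    ``largest_pairwise_distance`` is the true centroid-based value per
    frame.  Flow truths are per coherent motion region and per frame
    pair.
    """

    nebd_frame: int
    nebd_time: float
    centroids: np.ndarray = field(default_factory=lambda: np.empty((0, 0, 3)))
    volumes: np.ndarray = field(default_factory=lambda: np.empty(0))
    has_kinetochore: np.ndarray = field(default_factory=lambda: np.empty(0, bool))
    largest_pairwise_distance: np.ndarray = field(default_factory=lambda: np.empty(0))
    nucleus_centre: np.ndarray | None = None  # µm (z, y, x)
    # flow truth (2D scenes)
    flow_positions: np.ndarray | None = None  # (P, 2) µm (y, x) region centres
    flow_vectors: np.ndarray | None = None  # (P, 2) µm/min (vy, vx)
    flow_angles_to_centre: np.ndarray | None = None  # (P,) degrees, 0 = inward
    flow_is_inward: np.ndarray | None = None  # (P,) bool, imposed inward motion
    # colocalization truth
    spot_points: np.ndarray | None = None  # (S, 3) µm
    spot_in_contact: np.ndarray | None = None  # (S,) bool

    def to_table(self) -> pd.DataFrame:
        """Long-format truth table (frame, object_id, z, y, x, volume, KT)."""
        rows = []
        n_frames, n_obj = self.centroids.shape[:2]
        for t in range(n_frames):
            for i in range(n_obj):
                z, y, x = self.centroids[t, i]
                rows.append(
                    {
                        "frame": t,
                        "object_id": i,
                        "z": z,
                        "y": y,
                        "x": x,
                        "volume_um3": float(self.volumes[i]),
                        "has_kinetochore": bool(self.has_kinetochore[i]),
                    }
                )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# geometry helpers


def _grid_coords_um(shape, voxel_size):
    """1D voxel-centre coordinate arrays (µm) along z, y, x."""
    return [np.arange(n) * v for n, v in zip(shape, voxel_size)]


def _place_dispersed(rng, n, max_radius, min_sep, max_tries=2000):
    """Dart-throwing placement of n points in a sphere with min separation."""
    for _ in range(max_tries):
        pts = []
        tries = 0
        while len(pts) < n and tries < 200 * n:
            tries += 1
            p = rng.uniform(-1, 1, 3) * max_radius
            if np.linalg.norm(p) > max_radius:
                continue
            if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < min_sep:
                continue
            pts.append(p)
        if len(pts) == n:
            return np.array(pts)
    raise ValueError(
        f"cannot place {n} chromosomes of separation {min_sep} µm "
        f"inside a {max_radius} µm sphere without overlap"
    )


def _add_gaussian_blob(vol, coords_um, centre_um, sigma_um, amplitude):
    """Accumulate an anisotropy-aware 3D Gaussian into ``vol`` (local patch)."""
    zc, yc, xc = coords_um
    slabs, axes_1d = [], []
    for c, centre, sigma in zip(coords_um, centre_um, np.broadcast_to(sigma_um, (3,))):
        step = c[1] - c[0] if len(c) > 1 else 1.0
        lo = int(np.clip(np.floor((centre - 4 * sigma) / step), 0, len(c) - 1))
        hi = int(np.clip(np.ceil((centre + 4 * sigma) / step) + 1, 1, len(c)))
        slabs.append(slice(lo, hi))
        axes_1d.append(np.exp(-((c[lo:hi] - centre) ** 2) / (2 * sigma**2)))
    gz, gy, gx = axes_1d
    vol[slabs[0], slabs[1], slabs[2]] += (
        amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )


def _add_solid_sphere(vol, coords_um, centre_um, radius_um, amplitude):
    zc, yc, xc = coords_um
    dz2 = (zc - centre_um[0])[:, None, None] ** 2
    dy2 = (yc - centre_um[1])[None, :, None] ** 2
    dx2 = (xc - centre_um[2])[None, None, :] ** 2
    vol[dz2 + dy2 + dx2 <= radius_um**2] += amplitude


def _shell(coords_um, centre_um, radius_um, thickness_um, amplitude):
    zc, yc, xc = coords_um
    r = np.sqrt(
        (zc - centre_um[0])[:, None, None] ** 2
        + (yc - centre_um[1])[None, :, None] ** 2
        + (xc - centre_um[2])[None, None, :] ** 2
    )
    return amplitude * np.exp(-((r - radius_um) ** 2) / (2 * thickness_um**2))


def _sphere_mask(coords_um, centre_um, radius_um):
    zc, yc, xc = coords_um
    return (
        (zc - centre_um[0])[:, None, None] ** 2
        + (yc - centre_um[1])[None, :, None] ** 2
        + (xc - centre_um[2])[None, None, :] ** 2
    ) <= radius_um**2


def _apply_noise(data, rng, gaussian_sd, poisson_scale):
    """Shot noise on signal, then additive Gaussian read noise."""
    out = data
    if poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * poisson_scale) / poisson_scale
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=data.shape)
    return out.astype(np.float32)


# ---------------------------------------------------------------------------
# main generators

CHANNELS = ("chromatin", "kinetochores", "actin", "lamina", "dextran", "membrane")


def _centroid_trajectories(scenario: OocyteScenario, rng) -> tuple[np.ndarray, np.ndarray]:
    """True centroids per frame via uniform contraction toward the centre.

    Scaling every initial offset by the same factor makes the largest
    pairwise distance decrease *exactly* linearly at ``convergence_speed``
    until all pairwise distances drop below 2 × chromosome_radius (the
    formed-cluster floor), where motion stops.
    """
    s = scenario
    p0 = _place_dispersed(
        rng,
        s.n_chromosomes,
        max(s.nucleus_radius - s.chromosome_radius, s.chromosome_radius),
        2.0 * s.chromosome_radius,
    )
    times = np.arange(s.n_frames) * s.frame_interval
    if s.n_chromosomes == 1:
        centroids = np.repeat(p0[None], s.n_frames, axis=0)
        return centroids, np.zeros(s.n_frames)

    from scipy.spatial.distance import pdist

    d0 = float(pdist(p0).max())
    floor_scale = min(1.0, 2.0 * s.chromosome_radius / d0)
    scales = np.ones(s.n_frames)
    post = times > s.nebd_time
    dt_post = np.clip(times - s.nebd_time, 0, None)
    with np.errstate(invalid="ignore"):
        scales[post] = np.maximum(floor_scale, (d0 - s.convergence_speed * dt_post[post]) / d0)
    centroids = scales[:, None, None] * p0[None]
    lpd = scales * d0
    return centroids, lpd


def generate_oocyte_series(scenario: OocyteScenario) -> tuple[VolumeSeries, GroundTruth]:
    """Render a full multi-channel time-lapse of chromosome clustering.

    Returns the series (channels ``chromatin``, ``kinetochores``,
    ``actin``, ``lamina``, ``dextran``, ``membrane``) and the imposed
    ground truth.  Centroid coordinates in the truth are µm relative to
    the volume origin (voxel 0 centre).
    """
    s = scenario
    s.validate()
    rng = np.random.default_rng(s.seed)

    span = 2.0 * s.cell_radius + 2.0  # µm, one-µm margin per side
    shape = tuple(int(np.ceil(span / v)) for v in s.voxel_size)
    coords = _grid_coords_um(shape, s.voxel_size)
    centre = np.array([c[-1] / 2 for c in coords])

    rel_centroids, lpd = _centroid_trajectories(s, rng)
    centroids = rel_centroids + centre  # absolute µm

    sigma_blob = s.chromosome_radius / _FWHM_PER_SIGMA
    kt_sigma = np.array([max(0.8, s.voxel_size[0] / 2), 0.4, 0.4])
    n_kt = int(round(s.kinetochore_fraction * s.n_chromosomes))
    kt_flags = np.zeros(s.n_chromosomes, dtype=bool)
    kt_flags[rng.permutation(s.n_chromosomes)[:n_kt]] = True

    cell_mask = _sphere_mask(coords, centre, s.cell_radius)
    # first frame acquired at or after the NEBD time
    nebd_frame = int(
        np.searchsorted(np.arange(s.n_frames) * s.frame_interval, s.nebd_time, "left")
    )

    lamina_shells = {}
    data = np.zeros((s.n_frames, len(CHANNELS), *shape), dtype=np.float32)
    times = np.arange(s.n_frames) * s.frame_interval
    # static channels
    membrane = _shell(coords, centre, s.cell_radius, 1.0, 200.0).astype(np.float32)

    for t in range(s.n_frames):
        chromatin = np.zeros(shape, dtype=np.float32)
        kineto = np.zeros(shape, dtype=np.float32)
        for i in range(s.n_chromosomes):
            _add_gaussian_blob(chromatin, coords, centroids[t, i], sigma_blob, s.chromatin_peak)
            if kt_flags[i]:
                _add_gaussian_blob(kineto, coords, centroids[t, i], kt_sigma, 300.0)

        # lamina persists and compacts slowly after NEBD
        dt_post = max(0.0, times[t] - s.nebd_time)
        lam_r = s.nucleus_radius * max(0.7, 1.0 - 0.003 * dt_post)
        key = round(lam_r, 3)
        if key not in lamina_shells:
            lamina_shells[key] = _shell(coords, centre, lam_r, 0.8, 250.0).astype(np.float32)
        lamina = lamina_shells[key]

        # dextran: cytoplasmic always; nuclear zero pre-NEBD, full within 2 frames
        nuc_mask = _sphere_mask(coords, centre, lam_r)
        dextran = np.where(cell_mask & ~nuc_mask, s.cytoplasm_level, 0.0)
        if t >= nebd_frame:
            fill = min(1.0, (t - nebd_frame + 1) / 2.0)
            dextran = np.where(nuc_mask, fill * s.cytoplasm_level, dextran)

        # actin: granular cytoplasmic texture, enriched in the nuclear region post-NEBD
        from scipy.ndimage import gaussian_filter

        tex = rng.normal(0, 1, shape)
        tex = gaussian_filter(tex, sigma=(0.5, 1.5, 1.5))
        tex = 40.0 * (tex - tex.min()) / max(float(np.ptp(tex)), 1e-9)
        actin = np.where(cell_mask, tex, 0.0)
        if times[t] > s.nebd_time:
            actin = np.where(nuc_mask, actin * 1.5, actin)

        for c, img in zip(
            CHANNELS, (chromatin, kineto, actin, lamina, dextran, membrane)
        ):
            data[t, CHANNELS.index(c)] = _apply_noise(
                img, rng, s.noise_gaussian_sd, s.noise_poisson_scale
            )

    blob_volume = 4.0 / 3.0 * math.pi * (s.chromosome_radius / 2.0) ** 3
    truth = GroundTruth(
        nebd_frame=nebd_frame,
        nebd_time=s.nebd_time,
        centroids=centroids,
        volumes=np.full(s.n_chromosomes, blob_volume),
        has_kinetochore=kt_flags,
        largest_pairwise_distance=lpd,
        nucleus_centre=centre,
    )
    series = VolumeSeries(data, CHANNELS, s.voxel_size, s.frame_interval)
    return series, truth


# ---------------------------------------------------------------------------
# 2D flow scenes


def generate_flow_frames(
    scenario: OocyteScenario,
    n_frames: int | None = None,
    uniform_shift_px: tuple[float, float] | None = None,
) -> tuple[VolumeSeries, GroundTruth]:
    """Render a 2D+t actin texture inside a lamina disc with known motion.

    The disc is tiled into square patches (``flow_patch_px``); with
    probability ``actin_inward_fraction`` a patch's texture moves toward
    the disc centre at ``actin_speed`` µm/min, otherwise in a uniformly
    random direction at the same speed.  ``uniform_shift_px`` overrides
    all motion with one global translation per frame (px/frame) — handy
    for PIV oracles.

    Returns a Z=1 series with channels ``("actin", "lamina")`` and a
    truth record per patch inside the disc.
    """
    s = scenario
    s.validate()
    rng = np.random.default_rng(s.seed)
    n_frames = n_frames if n_frames is not None else s.n_frames
    px = s.voxel_size[1]  # isotropic in-plane pixels assumed for flow scenes
    size = int(np.ceil(2.6 * s.nucleus_radius / px))
    size = max(size, 160)  # room for the 64-px first PIV pass
    centre_px = np.array([size / 2, size / 2])

    patch = s.flow_patch_px
    n_patch = int(np.ceil(size / patch))
    patch_centres = (
        np.stack(
            np.meshgrid(np.arange(n_patch), np.arange(n_patch), indexing="ij"), -1
        ).reshape(-1, 2)
        * patch
        + patch / 2.0
    )

    # assign a velocity (px/frame) to every patch
    speed_px = s.actin_speed * s.frame_interval / px
    vel = np.zeros((len(patch_centres), 2))
    inward_flag = np.zeros(len(patch_centres), dtype=bool)
    for i, pc in enumerate(patch_centres):
        to_centre = centre_px - pc
        nrm = np.linalg.norm(to_centre)
        u_in = to_centre / nrm if nrm > 1e-9 else np.array([0.0, 1.0])
        if rng.random() < s.actin_inward_fraction:
            vel[i] = speed_px * u_in
            inward_flag[i] = True
        else:
            a = rng.uniform(0, 2 * np.pi)
            vel[i] = speed_px * np.array([np.sin(a), np.cos(a)])
    if uniform_shift_px is not None:
        vel[:] = np.asarray(uniform_shift_px, dtype=float)
        inward_flag[:] = False

    # particles carry the texture; each inherits its initial patch's velocity.
    # A margin beyond the frame keeps inflow at the borders consistent with
    # the imposed motion over the rendered frames.
    margin = 16.0
    n_particles = max(
        200, int(s.actin_particle_density * (size + 2 * margin) ** 2)
    )
    pos0 = rng.uniform(-margin, size + margin, (n_particles, 2))
    amp = rng.uniform(120, 255, n_particles)
    p_idx = (
        np.clip((pos0[:, 0] // patch).astype(int), 0, n_patch - 1) * n_patch
        + np.clip((pos0[:, 1] // patch).astype(int), 0, n_patch - 1)
    )
    p_vel = vel[p_idx]

    yy, xx = np.mgrid[0:size, 0:size]
    r_px = np.hypot(yy - centre_px[0], xx - centre_px[1])
    lamina_img = 220.0 * np.exp(-((r_px * px - s.nucleus_radius) ** 2) / (2 * 0.8**2))

    sigma_dot = 1.5  # px
    frames = np.zeros((n_frames, 2, 1, size, size), dtype=np.float32)
    for t in range(n_frames):
        pos = pos0 + t * p_vel
        img = np.zeros((size, size), dtype=np.float32)
        # render particles as Gaussian dots via local patches
        for (py, pxx), a in zip(pos, amp):
            iy, ix = int(round(py)), int(round(pxx))
            lo_y, hi_y = max(iy - 4, 0), min(iy + 5, size)
            lo_x, hi_x = max(ix - 4, 0), min(ix + 5, size)
            if lo_y >= hi_y or lo_x >= hi_x:
                continue
            gy = np.exp(-((np.arange(lo_y, hi_y) - py) ** 2) / (2 * sigma_dot**2))
            gx = np.exp(-((np.arange(lo_x, hi_x) - pxx) ** 2) / (2 * sigma_dot**2))
            img[lo_y:hi_y, lo_x:hi_x] += a * gy[:, None] * gx[None, :]
        frames[t, 0, 0] = _apply_noise(img, rng, s.noise_gaussian_sd, s.noise_poisson_scale)
        frames[t, 1, 0] = _apply_noise(
            lamina_img, rng, s.noise_gaussian_sd, s.noise_poisson_scale
        )

    # truth restricted to patches inside the disc
    inside = (
        np.hypot(*(patch_centres - centre_px).T) * px < s.nucleus_radius * 0.95
    )
    pc_um = patch_centres[inside] * px
    v_umpm = vel[inside] * px / s.frame_interval
    centre_um = centre_px * px
    to_c = centre_um - pc_um
    ang_in = np.degrees(np.arctan2(to_c[:, 0], to_c[:, 1]))
    ang_v = np.degrees(np.arctan2(v_umpm[:, 0], v_umpm[:, 1]))
    rel = (ang_v - ang_in + 180.0) % 360.0 - 180.0

    truth = GroundTruth(
        nebd_frame=0,
        nebd_time=0.0,
        nucleus_centre=np.array([0.0, *centre_um]),
        flow_positions=pc_um,
        flow_vectors=v_umpm,
        flow_angles_to_centre=rel,
        flow_is_inward=inward_flag[inside],
    )
    series = VolumeSeries(
        frames, ("actin", "lamina"), (1.0, px, px), s.frame_interval
    )
    return series, truth


# ---------------------------------------------------------------------------
# fragmentation scenes


def generate_fragments(scenario: OocyteScenario) -> tuple[VolumeSeries, GroundTruth]:
    """Render chromatin fragments of specified volumes with kinetochore flags.

    Fragments are solid spheres whose radii realise ``fragment_volumes``
    (µm³).  If ``fragment_kinetochore`` is not given, fragments of at
    least 30 µm³ carry a kinetochore and smaller ones do not.  Each
    fragment drifts radially toward the nucleus centre; kinetochore-free
    fragments below 30 µm³ move at ``small_fragment_speed_factor`` times
    the base rate, emulating their slower clustering.
    """
    s = scenario
    if not s.fragment_mode:
        raise ValueError("fragment_mode must be enabled")
    s.validate()
    rng = np.random.default_rng(s.seed)

    vols = np.asarray(s.fragment_volumes, dtype=float)
    radii = (3.0 * vols / (4.0 * math.pi)) ** (1.0 / 3.0)
    n = len(vols)
    if s.fragment_kinetochore is None:
        kt = vols >= 30.0
    else:
        kt = np.asarray(s.fragment_kinetochore, dtype=bool)

    span = 2.0 * s.cell_radius + 2.0
    shape = tuple(int(np.ceil(span / v)) for v in s.voxel_size)
    coords = _grid_coords_um(shape, s.voxel_size)
    centre = np.array([c[-1] / 2 for c in coords])

    max_r = max(s.nucleus_radius - radii.max(), radii.max())
    p0 = _place_dispersed(rng, n, max_r, 2.0 * radii.max())
    times = np.arange(s.n_frames) * s.frame_interval

    base_v = s.convergence_speed
    speeds = np.where(~kt & (vols < 30.0), base_v * s.small_fragment_speed_factor, base_v)

    centroids = np.zeros((s.n_frames, n, 3))
    for t, tt in enumerate(times):
        dt_post = max(0.0, tt - s.nebd_time)
        for i in range(n):
            r0 = np.linalg.norm(p0[i])
            u = p0[i] / r0 if r0 > 1e-9 else np.zeros(3)
            r_t = max(radii[i], r0 - speeds[i] * dt_post)
            centroids[t, i] = centre + u * r_t

    data = np.zeros((s.n_frames, 2, *shape), dtype=np.float32)
    kt_sigma = np.array([max(0.8, s.voxel_size[0] / 2), 0.4, 0.4])
    for t in range(s.n_frames):
        chrom = np.zeros(shape, dtype=np.float32)
        kin = np.zeros(shape, dtype=np.float32)
        for i in range(n):
            _add_solid_sphere(chrom, coords, centroids[t, i], radii[i], s.chromatin_peak)
            if kt[i]:
                _add_gaussian_blob(kin, coords, centroids[t, i], kt_sigma, 300.0)
        data[t, 0] = _apply_noise(chrom, rng, s.noise_gaussian_sd, s.noise_poisson_scale)
        data[t, 1] = _apply_noise(kin, rng, s.noise_gaussian_sd, s.noise_poisson_scale)

    from scipy.spatial.distance import pdist

    lpd = np.array(
        [pdist(centroids[t]).max() if n > 1 else 0.0 for t in range(s.n_frames)]
    )
    truth = GroundTruth(
        nebd_frame=int(np.searchsorted(times, s.nebd_time, "left")),
        nebd_time=s.nebd_time,
        centroids=centroids,
        volumes=vols,
        has_kinetochore=kt,
        largest_pairwise_distance=lpd,
        nucleus_centre=centre,
    )
    series = VolumeSeries(data, ("chromatin", "kinetochores"), s.voxel_size, s.frame_interval)
    return series, truth


# ---------------------------------------------------------------------------
# kinetochore–actin contact scenes (fixed/airyscan regime)


def generate_kinetochore_actin_volume(
    n_spots: int = 40,
    contact_prob: float = 0.18,
    contact_cutoff: float = 0.25,
    extent_um: float = 12.0,
    voxel_size: tuple[float, float, float] = AIRYSCAN_VOXEL,
    n_cables: int = 6,
    cable_radius: float = 0.5,
    noise_gaussian_sd: float = 3.0,
    seed: int = 0,
) -> tuple[VolumeSeries, GroundTruth]:
    """Render an actin cable network plus kinetochore spots with a
    programmed contact probability.

    A bundle of ``n_cables`` crossing cylindrical cables forms one
    connected actin structure (total volume inside the standard
    30–1,000 µm³ surface gate).  Each of the ``n_spots`` kinetochores is
    placed *on* a cable (true distance 0 ≤ cutoff) with probability
    ``contact_prob``, otherwise at least 1 µm away from every cable.
    The truth records each spot position and its contact flag, so the
    recovered interaction fraction can be compared with the binomial
    expectation.
    """
    if not 0 <= contact_prob <= 1:
        raise ValueError("contact_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = tuple(int(np.ceil(extent_um / v)) for v in voxel_size)
    coords = _grid_coords_um(shape, voxel_size)
    centre = np.array([c[-1] / 2 for c in coords])

    # cable skeleton: segments through a ball around the centre
    zz = coords[0][:, None, None]
    yy = coords[1][None, :, None]
    xx = coords[2][None, None, :]
    pts = np.stack(np.broadcast_arrays(zz, yy, xx), axis=-1)
    cable_mask = np.zeros(shape, dtype=bool)
    half_len = 0.42 * extent_um
    for _ in range(n_cables):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        offset = rng.uniform(-1.0, 1.0, 3)
        a = centre + offset - half_len * d
        ab = 2 * half_len * d
        ap = pts - a
        tproj = np.clip(np.einsum("zyxk,k->zyx", ap, ab) / (ab @ ab), 0, 1)
        closest = a + tproj[..., None] * ab
        dist = np.linalg.norm(pts - closest, axis=-1)
        cable_mask |= dist <= cable_radius

    from scipy.ndimage import distance_transform_edt, gaussian_filter

    dist_to_cable = distance_transform_edt(~cable_mask, sampling=voxel_size)

    # spot placement with programmed contact
    cable_idx = np.argwhere(cable_mask)
    far_idx = np.argwhere(dist_to_cable > 1.0)
    # contact flags are drawn once per spot so the realised rate is an
    # unbiased Bernoulli(contact_prob) sample; only positions are resampled
    contact = rng.random(n_spots) < contact_prob
    spot_pts: list[np.ndarray] = []
    min_sep = 0.8  # µm between spots so detection resolves them
    for on_cable in contact:
        pool = cable_idx if on_cable else far_idx
        for _ in range(5_000):
            idx = pool[rng.integers(len(pool))]
            p = idx * np.asarray(voxel_size)
            if np.any(np.abs(p - centre) > extent_um / 2 - 1.0):
                continue
            if spot_pts and np.min(
                np.linalg.norm(np.array(spot_pts) - p, axis=1)
            ) < min_sep:
                continue
            spot_pts.append(p)
            break
        else:
            raise RuntimeError("could not place all kinetochore spots")
    spot_pts = np.array(spot_pts)

    actin = np.where(cable_mask, 260.0, 0.0).astype(np.float32)
    actin = gaussian_filter(actin, sigma=0.5)
    kineto = np.zeros(shape, dtype=np.float32)
    for p in spot_pts:
        _add_gaussian_blob(kineto, coords, p, np.array([0.25, 0.2, 0.2]), 400.0)

    data = np.zeros((1, 2, *shape), dtype=np.float32)
    data[0, 0] = _apply_noise(actin, rng, noise_gaussian_sd, 0.05)
    data[0, 1] = _apply_noise(kineto, rng, noise_gaussian_sd, 0.05)

    truth = GroundTruth(
        nebd_frame=0,
        nebd_time=0.0,
        nucleus_centre=centre,
        spot_points=spot_pts,
        spot_in_contact=contact,
    )
    series = VolumeSeries(data, ("actin", "kinetochores"), voxel_size, 1.0)
    return series, truth
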