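"""Synthetic fluorescence data with exact ground truth.

Every quantitative procedure in this package is exercised on simulated data
for which the truth is known: tubular terminal axon branches with an
adjacent glial sheath and stochastic fragmentation gaps, muscle-fiber fields
with nuclei, perinuclear ubiquitin rings and larger dispersed puncta with a
partially colocalized P62 channel, and behavioral cohorts of groups of six
flies.

Fragmentation gaps are modeled as a marked Poisson process along branch arc
length: gap starts arrive at ``gap_rate_per_um`` per µm and gap lengths are
Gaussian (truncated at zero); overlapping gaps are merged.  Axon and glia
gap processes are independent by default with an optional coupling
probability.  Rendering uses an isotropic Gaussian PSF approximation and
mixed Poisson-Gaussian noise — sufficient structure for scorer testing, with
no attempt at photorealistic tissue texture.

All randomness flows from a single integer seed through a named generator
stream per object category, so e.g. adding puncta does not perturb nucleus
placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as _draw_disk

from .errors import ParameterError, PlacementError
from .stacks import ImageStack
from .puncta import DEFAULT_PERINUCLEAR_DMAX_UM

# fixed stream ids: category -> offset mixed with the user seed
_STREAMS = {
    "gaps_axon": 1, "gaps_glia": 2, "noise": 3, "nuclei": 4,
    "puncta_perinuclear": 5, "puncta_nonperinuclear": 6, "coloc": 7,
    "flight": 8, "climb": 9, "preparation": 10,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{name}: {msg}")


# --------------------------------------------------------------------------
# gap process
# --------------------------------------------------------------------------

def sample_gap_intervals(rng: np.random.Generator, length_um: float,
                         rate_per_um: float, mean_um: float,
                         sd_um: float) -> list[tuple[float, float]]:
    """Sample merged gap intervals from a marked Poisson process.

    Gap starts arrive at ``rate`` per µm on a window extended below zero by
    the maximum plausible gap length, so coverage is stationary along the
    whole branch (no artificial edge at the origin); lengths are N(mean, sd)
    truncated at zero.  Intervals are clipped to [0, L], sorted, and
    overlapping or touching intervals are merged, so the result is always
    sorted and disjoint with total length ≤ L.
    """
    window = mean_um + 6.0 * sd_um
    n = int(rng.poisson(rate_per_um * (length_um + window)))
    if n == 0:
        return []
    starts = rng.uniform(-window, length_um, n)
    lengths = rng.normal(mean_um, sd_um, n)
    while np.any(lengths <= 0):  # truncated normal via resampling
        bad = lengths <= 0
        lengths[bad] = rng.normal(mean_um, sd_um, int(bad.sum()))
    ends = np.minimum(starts + lengths, length_um)
    starts = np.maximum(starts, 0.0)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]
    order = np.argsort(starts)
    merged: list[tuple[float, float]] = []
    for s, e in zip(starts[order], ends[order]):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((float(s), float(e)))
    return merged


def _in_intervals(s: np.ndarray, intervals: Sequence[tuple[float, float]]) -> np.ndarray:
    """Boolean membership of arc positions in a sorted disjoint interval list."""
    out = np.zeros(np.shape(s), dtype=bool)
    if not intervals:
        return out
    starts = np.array([iv[0] for iv in intervals])
    ends = np.array([iv[1] for iv in intervals])
    idx = np.searchsorted(starts, s, side="right") - 1
    valid = idx >= 0
    out[valid] = s[valid] < ends[idx[valid]]
    return out


def total_gap_length(intervals: Sequence[tuple[float, float]]) -> float:
    return float(sum(e - s for s, e in intervals))


# --------------------------------------------------------------------------
# terminal axon branch with glial sheath
# --------------------------------------------------------------------------

@dataclass
class BranchSimParams:
    """Parameters of one simulated terminal axon branch.

    Lengths are in µm.  ``gap_rate_per_um`` is the expected number of gap
    events per µm of arc length; gap lengths are N(mean, sd) truncated at 0.
    ``snr`` is the peak-signal to noise-standard-deviation ratio of the
    rendered channels; ``snr=inf`` renders noise-free.  The z-step default of
    0.2 µm matches standard confocal acquisition of these preparations; the
    in-plane pixel size of 0.1 µm is an assumption recorded in the sidecar.
    """

    branch_length_um: float = 40.0
    tube_radius_um: float = 0.5
    curvature_amplitude_um: float = 2.0
    gap_rate_per_um: float = 0.0
    gap_length_um_mean: float = 1.5
    gap_length_um_sd: float = 0.5
    glia_offset_um: float = 1.2
    glia_coverage_fraction: float = 1.0
    axon_glia_gap_coupling: float = 0.0
    psf_sigma_um: float = 0.15
    snr: float = 20.0
    pixel_size_um: float = 0.1
    z_step_um: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        _require(self.branch_length_um > 0, "branch_length_um", "must be positive")
        _require(self.tube_radius_um > 0, "tube_radius_um", "must be positive")
        _require(self.curvature_amplitude_um >= 0, "curvature_amplitude_um",
                 "must be nonnegative")
        _require(self.gap_rate_per_um >= 0, "gap_rate_per_um", "must be nonnegative")
        _require(self.gap_length_um_mean > 0, "gap_length_um_mean", "must be positive")
        _require(self.gap_length_um_sd >= 0, "gap_length_um_sd", "must be nonnegative")
        _require(self.glia_offset_um >= 0, "glia_offset_um", "must be nonnegative")
        _require(0 <= self.glia_coverage_fraction <= 1, "glia_coverage_fraction",
                 "must lie in [0, 1]")
        _require(0 <= self.axon_glia_gap_coupling <= 1, "axon_glia_gap_coupling",
                 "must lie in [0, 1]")
        _require(self.psf_sigma_um >= 0, "psf_sigma_um", "must be nonnegative")
        _require(self.snr > 0, "snr", "must be positive")
        _require(self.pixel_size_um > 0, "pixel_size_um", "must be strictly positive")
        _require(self.z_step_um > 0, "z_step_um", "must be strictly positive")


@dataclass
class BranchGroundTruth:
    """Exact truth for one simulated branch.

    ``centerline_points_um`` is an ordered (N, 3) array of (x, y, z)
    coordinates in µm whose cumulative arc length spans [0, branch_length];
    gap intervals are sorted, disjoint (start, end) pairs on arc length.
    """

    centerline_points_um: np.ndarray
    gap_intervals_axon: list[tuple[float, float]]
    gap_intervals_glia: list[tuple[float, float]]
    channel_map: dict[str, str]
    branch_length_um: float
    glia_coverage_fraction: float = 1.0

    def to_dict(self) -> dict:
        return {
            "kind": "branch",
            "centerline_points_um": np.asarray(self.centerline_points_um).tolist(),
            "gap_intervals_axon": [list(iv) for iv in self.gap_intervals_axon],
            "gap_intervals_glia": [list(iv) for iv in self.gap_intervals_glia],
            "channel_map": dict(self.channel_map),
            "branch_length_um": self.branch_length_um,
            "glia_coverage_fraction": self.glia_coverage_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BranchGroundTruth":
        return cls(
            centerline_points_um=np.asarray(d["centerline_points_um"], dtype=float),
            gap_intervals_axon=[tuple(iv) for iv in d["gap_intervals_axon"]],
            gap_intervals_glia=[tuple(iv) for iv in d["gap_intervals_glia"]],
            channel_map=dict(d["channel_map"]),
            branch_length_um=float(d["branch_length_um"]),
            glia_coverage_fraction=float(d.get("glia_coverage_fraction", 1.0)),
        )


def _centerline(params: BranchSimParams, step_um: float) -> np.ndarray:
    """Arc-length-parameterized sinusoidal centerline, (N, 2) in µm (x, y)."""
    L = params.branch_length_um
    amp = params.curvature_amplitude_um
    period = max(L / 1.5, 1.0)
    # oversample in t, reparameterize by cumulative arc length, cut at L
    t = np.arange(0.0, 2.0 * L + step_um, step_um / 4.0)
    x = t
    y = amp * np.sin(2.0 * np.pi * t / period)
    seglen = np.hypot(np.diff(x), np.diff(y))
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    s_target = np.arange(0.0, L, step_um)
    s_target = np.append(s_target, L)  # land exactly on the branch end
    xs = np.interp(s_target, arc, x)
    ys = np.interp(s_target, arc, y)
    return np.column_stack([xs, ys])


def _render_tube(points_xy_um: np.ndarray, arc_um: np.ndarray,
                 gaps: Sequence[tuple[float, float]], shape_zyx: tuple,
                 origin_um: tuple[float, float], z_center_um: float,
                 radius_um: float, pixel_um: float, z_um: float) -> np.ndarray:
    """Rasterize a tube of given radius around a 2D polyline at fixed z.

    Each voxel is assigned the arc-length of its nearest centerline sample
    (via a Euclidean distance transform with physical sampling); voxels
    within ``radius_um`` of the centerline and outside all gap intervals
    get intensity 1.
    """
    nz, ny, nx = shape_zyx
    seeds = np.ones(shape_zyx, dtype=bool)
    iz = int(round(z_center_um / z_um))
    iy = np.clip(np.round((points_xy_um[:, 1] - origin_um[1]) / pixel_um).astype(int), 0, ny - 1)
    ix = np.clip(np.round((points_xy_um[:, 0] - origin_um[0]) / pixel_um).astype(int), 0, nx - 1)
    seeds[iz, iy, ix] = False
    arc_lookup = np.zeros(shape_zyx, dtype=np.float32)
    # later samples overwrite earlier at voxel collisions; sub-voxel detail
    arc_lookup[iz, iy, ix] = arc_um
    dist, inds = ndimage.distance_transform_edt(
        seeds, sampling=(z_um, pixel_um, pixel_um), return_indices=True)
    tube = dist <= radius_um
    vox_arc = arc_lookup[inds[0], inds[1], inds[2]]
    # gap intervals are half-open; keep the terminal cap inside the last one
    vox_arc = np.minimum(vox_arc, max(arc_um[-1] - 1e-9, 0.0))
    signal = tube.astype(np.float32)
    if gaps:
        signal[_in_intervals(vox_arc, gaps) & tube] = 0.0
    return signal


def _apply_noise(signal: np.ndarray, snr: float, psf_sigma_um: float,
                 pixel_um: float, z_um: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Gaussian PSF blur followed by mixed Poisson-Gaussian noise.

    Peak amplitude is set to snr² photons so shot noise at the peak has the
    requested SNR; a unit-variance Gaussian read-noise term is added.  With
    ``snr=inf`` the blurred signal is returned unchanged (noise-free render).
    """
    sig_vox = (psf_sigma_um / z_um, psf_sigma_um / pixel_um,
               psf_sigma_um / pixel_um)
    blurred = ndimage.gaussian_filter(signal.astype(np.float32), sigma=sig_vox)
    if not np.isfinite(snr):
        return blurred
    amplitude = snr**2
    background = max(2.0, 0.02 * amplitude)
    counts = background + amplitude * blurred
    noisy = rng.poisson(counts).astype(np.float32)
    noisy += rng.normal(0.0, 1.0, noisy.shape).astype(np.float32)
    return noisy


BRANCH_CHANNELS = ["HRP", "SYT", "GS2"]
BRANCH_CHANNEL_MAP = {"axon_membrane": "HRP", "synaptic_vesicle": "SYT",
                      "glia": "GS2"}


def _branch_geometry(params: BranchSimParams) -> tuple[np.ndarray, np.ndarray,
                                                       list, list]:
    """Centerline, cumulative arc length, and per-channel gap intervals."""
    pix = params.pixel_size_um
    axis = _centerline(params, pix / 2.0)
    arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(axis, axis=0).T))])

    rng_ax = _rng(params.seed, "gaps_axon")
    rng_gl = _rng(params.seed, "gaps_glia")
    gaps_axon = sample_gap_intervals(
        rng_ax, params.branch_length_um, params.gap_rate_per_um,
        params.gap_length_um_mean, params.gap_length_um_sd)
    gaps_glia = sample_gap_intervals(
        rng_gl, params.branch_length_um, params.gap_rate_per_um,
        params.gap_length_um_mean, params.gap_length_um_sd)
    if params.axon_glia_gap_coupling > 0 and gaps_axon:
        copy = rng_gl.uniform(size=len(gaps_axon)) < params.axon_glia_gap_coupling
        coupled = [iv for iv, c in zip(gaps_axon, copy) if c]
        merged = sorted(gaps_glia + coupled)
        out: list[tuple[float, float]] = []
        for s, e in merged:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        gaps_glia = out
    # glia sheath only covers the proximal coverage fraction of the branch
    if params.glia_coverage_fraction < 1.0:
        cov_end = params.glia_coverage_fraction * params.branch_length_um
        tail = (cov_end, params.branch_length_um)
        gaps_glia = [iv for iv in gaps_glia if iv[0] < cov_end]
        if gaps_glia and gaps_glia[-1][1] > cov_end:
            gaps_glia[-1] = (gaps_glia[-1][0], cov_end)
        if tail[1] > tail[0]:
            gaps_glia = gaps_glia + [tail]

    # clip to the realized arc length (chord sums fall a hair short of the
    # nominal length on curved branches)
    def _clip(ivs):
        L = float(arc[-1])
        return [(s, min(e, L)) for s, e in ivs if s < L]

    return axis, arc, _clip(gaps_axon), _clip(gaps_glia)


def generate_branch_ground_truth(params: BranchSimParams) -> BranchGroundTruth:
    """Simulate branch geometry and gaps without rendering an image.

    Draws from the same random streams as :func:`generate_branch_image`, so
    the intervals match a rendered branch with identical parameters.  Used
    for cohort-scale scoring where the image path is not needed.
    """
    params.validate()
    axis, arc, gaps_axon, gaps_glia = _branch_geometry(params)
    pts3 = np.column_stack([axis, np.zeros(len(axis))])
    return BranchGroundTruth(
        centerline_points_um=pts3, gap_intervals_axon=gaps_axon,
        gap_intervals_glia=gaps_glia, channel_map=dict(BRANCH_CHANNEL_MAP),
        branch_length_um=float(arc[-1]),
        glia_coverage_fraction=params.glia_coverage_fraction)


def generate_branch_image(params: BranchSimParams) -> tuple[ImageStack, BranchGroundTruth]:
    """Render one terminal axon branch with glial sheath and ground truth.

    Channels: axon membrane (HRP), synaptic vesicles (SYT, a punctate
    modulation of the axon tube), and the glial sheath (GS2) running
    parallel at ``glia_offset_um``.  Axon and glia intensity is zeroed
    inside that channel's gap intervals; the ground truth records the exact
    intervals and the centerline.  Identical params (including seed)
    reproduce the stack bit-for-bit.
    """
    params.validate()
    pix, zst = params.pixel_size_um, params.z_step_um
    axis, arc, gaps_axon, gaps_glia = _branch_geometry(params)

    # in-plane normal of the centerline, for the glial offset curve
    d = np.gradient(axis, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    normals = np.column_stack([-d[:, 1] / norm, d[:, 0] / norm])
    glia_axis = axis + params.glia_offset_um * normals

    margin = 3.0 * (params.tube_radius_um + params.psf_sigma_um) \
        + params.glia_offset_um + 1.0
    all_xy = np.vstack([axis, glia_axis])
    x0, y0 = all_xy[:, 0].min() - margin, all_xy[:, 1].min() - margin
    x1, y1 = all_xy[:, 0].max() + margin, all_xy[:, 1].max() + margin
    nx = int(np.ceil((x1 - x0) / pix))
    ny = int(np.ceil((y1 - y0) / pix))
    z_half = 2.0 * (params.tube_radius_um + params.psf_sigma_um)
    nz = max(3, int(np.ceil(2.0 * z_half / zst)) | 1)
    z_center = (nz // 2) * zst
    shape = (nz, ny, nx)

    axon = _render_tube(axis, arc, gaps_axon, shape, (x0, y0), z_center,
                        params.tube_radius_um, pix, zst)
    glia = _render_tube(glia_axis, arc, gaps_glia, shape, (x0, y0), z_center,
                        params.tube_radius_um, pix, zst)
    # synaptic vesicles: boutons every ~2 µm along the intact axon
    syt_gaps = gaps_axon
    syt = _render_tube(axis, arc, syt_gaps, shape, (x0, y0), z_center,
                       params.tube_radius_um, pix, zst)
    # bouton-like modulation along the branch (period ~2 µm in x)
    xs_um = x0 + np.arange(nx) * pix
    modulation = 0.4 + 0.6 * np.cos(np.pi * xs_um / 2.0) ** 2
    syt = syt * modulation[np.newaxis, np.newaxis, :].astype(np.float32)

    rng_noise = _rng(params.seed, "noise")
    channels = [
        _apply_noise(axon, params.snr, params.psf_sigma_um, pix, zst, rng_noise),
        _apply_noise(syt, params.snr, params.psf_sigma_um, pix, zst, rng_noise),
        _apply_noise(glia, params.snr, params.psf_sigma_um, pix, zst, rng_noise),
    ]
    stack = ImageStack(np.stack(channels), list(BRANCH_CHANNELS), pix, zst)

    pts3 = np.column_stack([axis - [x0, y0], np.full(len(axis), z_center)])
    truth = BranchGroundTruth(
        centerline_points_um=pts3,
        gap_intervals_axon=gaps_axon,
        gap_intervals_glia=gaps_glia,
        channel_map=dict(BRANCH_CHANNEL_MAP),
        branch_length_um=float(arc[-1]),
        glia_coverage_fraction=params.glia_coverage_fraction,
    )
    return stack, truth


# --------------------------------------------------------------------------
# simulated preparations (fields of candidate branches)
# --------------------------------------------------------------------------

@dataclass
class BranchSite:
    """One candidate branch within a simulated preparation."""

    branch_id: str
    position_um: tuple[float, float]  # location on the muscle surface
    params: BranchSimParams


def generate_preparation(base: BranchSimParams, n_candidates: int = 14,
                         field_size_um: tuple[float, float] = (200.0, 200.0),
                         seed: int = 0, prep_id: str = "prep") -> list[BranchSite]:
    """Lay out candidate branches on a simulated muscle surface.

    Emulates one neuromuscular preparation: ``n_candidates`` branches at
    random positions on the medial fiber surface, each with its own derived
    seed.  Downstream analysis selects the most centrally located branches
    (ten per preparation in the original design).
    """
    _require(n_candidates > 0, "n_candidates", "must be positive")
    rng = _rng(seed, "preparation")
    sites = []
    for i in range(n_candidates):
        pos = (float(rng.uniform(0, field_size_um[0])),
               float(rng.uniform(0, field_size_um[1])))
        p = BranchSimParams(**{**asdict(base),
                               "seed": int(rng.integers(0, 2**31 - 1))})
        sites.append(BranchSite(branch_id=f"{prep_id}-b{i:02d}",
                                position_um=pos, params=p))
    return sites


# --------------------------------------------------------------------------
# muscle fields: nuclei, ubiquitin puncta, P62
# --------------------------------------------------------------------------

@dataclass
class MuscleFieldSimParams:
    """Parameters of a simulated muscle-fiber field.

    Two classes of ubiquitin-positive puncta are placed relative to the
    nuclei: small puncta arranged in perinuclear rings (within
    ``perinuclear_ring_offset_um`` of a nucleus boundary) and larger
    dispersed puncta placed farther than the perinuclear distance threshold
    ``d_max_um`` from every nucleus boundary.  ``d_max_um`` is the same
    definition the classifier uses, so generated labels are recoverable
    exactly on clean renders.  A P62 punctum is co-placed at a ubiquitin
    punctum's position with the per-class colocalization probability.
    """

    field_size_um: tuple[float, float] = (80.0, 80.0)
    n_nuclei: int = 8
    nucleus_radius_um: float = 3.0
    n_perinuclear_puncta: int = 40
    perinuclear_ring_offset_um: float = 1.4
    n_nonperinuclear_puncta: int = 20
    puncta_radius_small_um: float = 0.4
    puncta_radius_large_um: float = 0.8
    p62_coloc_prob_perinuclear: float = 0.2
    p62_coloc_prob_nonperinuclear: float = 0.2
    d_max_um: float = DEFAULT_PERINUCLEAR_DMAX_UM
    min_spacing_um: float = 2.0
    psf_sigma_um: float = 0.15
    snr: float = 20.0
    pixel_size_um: float = 0.15
    z_step_um: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        _require(self.field_size_um[0] > 0 and self.field_size_um[1] > 0,
                 "field_size_um", "must be positive")
        _require(self.n_nuclei >= 0, "n_nuclei", "must be nonnegative")
        _require(self.nucleus_radius_um > 0, "nucleus_radius_um", "must be positive")
        _require(self.n_perinuclear_puncta >= 0, "n_perinuclear_puncta",
                 "must be nonnegative")
        _require(self.n_nonperinuclear_puncta >= 0, "n_nonperinuclear_puncta",
                 "must be nonnegative")
        _require(self.perinuclear_ring_offset_um >= 0, "perinuclear_ring_offset_um",
                 "must be nonnegative")
        _require(self.puncta_radius_small_um > 0, "puncta_radius_small_um",
                 "must be positive")
        _require(self.puncta_radius_large_um > 0, "puncta_radius_large_um",
                 "must be positive")
        for nm in ("p62_coloc_prob_perinuclear", "p62_coloc_prob_nonperinuclear"):
            _require(0 <= getattr(self, nm) <= 1, nm, "must lie in [0, 1]")
        _require(self.d_max_um > 0, "d_max_um", "must be positive")
        _require(self.perinuclear_ring_offset_um <= self.d_max_um,
                 "perinuclear_ring_offset_um", "must not exceed d_max_um")
        _require(self.snr > 0, "snr", "must be positive")
        _require(self.pixel_size_um > 0, "pixel_size_um", "must be strictly positive")
        _require(self.z_step_um > 0, "z_step_um", "must be strictly positive")
        if self.n_perinuclear_puncta > 0:
            _require(self.n_nuclei > 0, "n_nuclei",
                     "needed to place perinuclear puncta")


MUSCLE_CHANNELS = ["UBI", "P62", "DAPI"]

_MAX_ATTEMPTS = 4000


def _place_nuclei(params: MuscleFieldSimParams,
                  rng: np.random.Generator) -> np.ndarray:
    fx, fy = params.field_size_um
    r = params.nucleus_radius_um
    margin = r + params.d_max_um + 2.0
    min_sep = 2 * r + 2.5
    centers: list[tuple[float, float]] = []
    for _ in range(params.n_nuclei):
        for _attempt in range(_MAX_ATTEMPTS):
            c = (rng.uniform(margin, fx - margin), rng.uniform(margin, fy - margin))
            if all(np.hypot(c[0] - o[0], c[1] - o[1]) >= min_sep for o in centers):
                centers.append(c)
                break
        else:
            raise PlacementError(
                f"could not place {params.n_nuclei} nuclei of radius {r} µm "
                f"in a {fx}×{fy} µm field")
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _boundary_distance(p: np.ndarray, centers: np.ndarray, r: float) -> float:
    """Signed distance from a point to the nearest nucleus boundary (<0 inside)."""
    if len(centers) == 0:
        return np.inf
    return float(np.min(np.hypot(*(centers - p).T)) - r)


def generate_muscle_field(params: MuscleFieldSimParams
                          ) -> tuple[ImageStack, dict]:
    """Render a muscle field with nuclei, ubiquitin puncta and P62.

    Returns the stack (channels UBI, P62, DAPI) and a ground-truth dict with
    a ``puncta`` table (punctum_id, x_um, y_um, radius_um, class_label,
    p62_coloc, nucleus_id) and a ``nuclei`` table.  Placement uses bounded
    rejection sampling; impossible geometries raise :class:`PlacementError`.
    Deterministic under a fixed seed.
    """
    params.validate()
    fx, fy = params.field_size_um
    pix = params.pixel_size_um
    rng_nuc = _rng(params.seed, "nuclei")
    centers = _place_nuclei(params, rng_nuc)

    border = max(params.puncta_radius_large_um, params.puncta_radius_small_um) + 1.0
    placed: list[dict] = []

    def _try_place(point: np.ndarray, radius: float) -> bool:
        if not (border <= point[0] <= fx - border and border <= point[1] <= fy - border):
            return False
        for q in placed:
            if np.hypot(point[0] - q["x_um"], point[1] - q["y_um"]) < params.min_spacing_um:
                return False
        return True

    rng_peri = _rng(params.seed, "puncta_perinuclear")
    d_lo = min(0.3, params.perinuclear_ring_offset_um)
    d_hi = params.perinuclear_ring_offset_um
    for i in range(params.n_perinuclear_puncta):
        nuc = i % max(len(centers), 1)
        for _attempt in range(_MAX_ATTEMPTS):
            theta = rng_peri.uniform(0, 2 * np.pi)
            d = rng_peri.uniform(d_lo, d_hi)
            p = centers[nuc] + (params.nucleus_radius_um + d) * np.array(
                [np.cos(theta), np.sin(theta)])
            bd = _boundary_distance(p, centers, params.nucleus_radius_um)
            if bd < d_lo or bd > d_hi:  # pushed inside/afar by another nucleus
                continue
            if _try_place(p, params.puncta_radius_small_um):
                placed.append({"x_um": float(p[0]), "y_um": float(p[1]),
                               "radius_um": params.puncta_radius_small_um,
                               "class_label": "perinuclear", "nucleus_id": nuc})
                break
        else:
            raise PlacementError(
                f"could not place perinuclear punctum {i} after {_MAX_ATTEMPTS} "
                "attempts; relax counts, spacing or ring geometry")

    rng_non = _rng(params.seed, "puncta_nonperinuclear")
    clearance = params.d_max_um + 1.0 + params.puncta_radius_large_um
    for i in range(params.n_nonperinuclear_puncta):
        for _attempt in range(_MAX_ATTEMPTS):
            p = np.array([rng_non.uniform(border, fx - border),
                          rng_non.uniform(border, fy - border)])
            if _boundary_distance(p, centers, params.nucleus_radius_um) < clearance:
                continue
            if _try_place(p, params.puncta_radius_large_um):
                placed.append({"x_um": float(p[0]), "y_um": float(p[1]),
                               "radius_um": params.puncta_radius_large_um,
                               "class_label": "non_perinuclear", "nucleus_id": -1})
                break
        else:
            raise PlacementError(
                f"could not place non-perinuclear punctum {i} after "
                f"{_MAX_ATTEMPTS} attempts; field too crowded")

    rng_col = _rng(params.seed, "coloc")
    prob = {"perinuclear": params.p62_coloc_prob_perinuclear,
            "non_perinuclear": params.p62_coloc_prob_nonperinuclear}
    for q in placed:
        q["p62_coloc"] = bool(rng_col.uniform() < prob[q["class_label"]])

    ny, nx = int(np.ceil(fy / pix)), int(np.ceil(fx / pix))

    def _paint(points: list[tuple[float, float, float]]) -> np.ndarray:
        img = np.zeros((ny, nx), dtype=np.float32)
        for x, y, r in points:
            rr, cc = _draw_disk((y / pix, x / pix), max(r / pix, 1.0),
                                shape=(ny, nx))
            img[rr, cc] = 1.0
        return img

    ubi = _paint([(q["x_um"], q["y_um"], q["radius_um"]) for q in placed])
    p62 = _paint([(q["x_um"], q["y_um"], q["radius_um"])
                  for q in placed if q["p62_coloc"]])
    dapi = _paint([(c[0], c[1], params.nucleus_radius_um) for c in centers])

    # thin 3-slice stack: the focal plane plus dimmer flanking sections
    z_weights = np.array([0.6, 1.0, 0.6], dtype=np.float32)
    rng_noise = _rng(params.seed, "noise")
    channels = []
    for plane in (ubi, p62, dapi):
        vol = plane[np.newaxis] * z_weights[:, np.newaxis, np.newaxis]
        channels.append(_apply_noise(vol, params.snr, params.psf_sigma_um,
                                     pix, params.z_step_um, rng_noise))
    stack = ImageStack(np.stack(channels), list(MUSCLE_CHANNELS), pix,
                       params.z_step_um)

    puncta_df = pd.DataFrame(placed)
    if len(puncta_df):
        puncta_df.insert(0, "punctum_id", np.arange(len(puncta_df)))
    else:
        puncta_df = pd.DataFrame(columns=["punctum_id", "x_um", "y_um",
                                          "radius_um", "class_label",
                                          "nucleus_id", "p62_coloc"])
    nuclei_df = pd.DataFrame({
        "nucleus_id": np.arange(len(centers)),
        "x_um": centers[:, 0] if len(centers) else [],
        "y_um": centers[:, 1] if len(centers) else [],
        "radius_um": params.nucleus_radius_um,
    })
    truth = {"kind": "muscle_field", "puncta": puncta_df, "nuclei": nuclei_df,
             "d_max_um": params.d_max_um}
    return stack, truth


# --------------------------------------------------------------------------
# behavioral cohorts
# --------------------------------------------------------------------------

@dataclass
class FlightSimParams:
    """Flight-assay cohort: groups of six flies in an oiled cylinder.

    Each fly is flightless with probability ``p_flightless`` (lands at 0);
    fliers adhere at a height drawn from N(mean, sd), rounded to the closest
    integer and clipped to [0, max_height_cm].  The default ceiling of 17 cm
    comes from a 19 cm cylinder with the zero line 2 cm above the bottom.
    """

    n_tests: int = 10
    flies_per_test: int = 6
    p_flightless: float = 0.0
    flier_height_mean_cm: float = 10.0
    flier_height_sd_cm: float = 3.0
    max_height_cm: float = 17.0
    seed: int = 0
    condition: str = "sim"

    def validate(self) -> None:
        _require(self.n_tests > 0, "n_tests", "must be positive")
        _require(self.flies_per_test > 0, "flies_per_test", "must be positive")
        _require(0 <= self.p_flightless <= 1, "p_flightless", "must lie in [0, 1]")
        _require(self.max_height_cm > 0, "max_height_cm", "must be positive")
        _require(self.flier_height_sd_cm >= 0, "flier_height_sd_cm",
                 "must be nonnegative")


def generate_flight_cohort(params: FlightSimParams) -> pd.DataFrame:
    """Simulate a flight cohort as a tidy table.

    Columns: condition, test_id, fly_id, value (integer height in cm).
    """
    params.validate()
    rng = _rng(params.seed, "flight")
    rows = []
    for t in range(params.n_tests):
        flightless = rng.uniform(size=params.flies_per_test) < params.p_flightless
        heights = rng.normal(params.flier_height_mean_cm,
                             params.flier_height_sd_cm, params.flies_per_test)
        heights = np.clip(np.round(heights), 0, params.max_height_cm)
        heights[flightless] = 0
        for f, h in enumerate(heights):
            rows.append({"condition": params.condition, "test_id": t,
                         "fly_id": f, "value": int(h)})
    return pd.DataFrame(rows)


def generate_climb_cohort(n_tests: int, repeats_per_test: int = 3,
                          time_mean_s: float = 10.0, time_sd_s: float = 2.0,
                          seed: int = 0, condition: str = "sim") -> pd.DataFrame:
    """Simulate a climbing cohort (times for half the group to reach the mark).

    Times are N(mean, sd) truncated at zero.  Columns: condition, test_id,
    repeat_id, value (seconds).
    """
    _require(n_tests > 0, "n_tests", "must be positive")
    _require(repeats_per_test > 0, "repeats_per_test", "must be positive")
    _require(time_mean_s > 0, "time_mean_s", "must be positive")
    _require(time_sd_s >= 0, "time_sd_s", "must be nonnegative")
    rng = _rng(seed, "climb")
    rows = []
    for t in range(n_tests):
        times = rng.normal(time_mean_s, time_sd_s, repeats_per_test)
        while np.any(times <= 0):
            bad = times <= 0
            times[bad] = rng.normal(time_mean_s, time_sd_s, int(bad.sum()))
        for r, v in enumerate(times):
            rows.append({"condition": condition, "test_id": t,
                         "repeat_id": r, "value": float(v)})
    return pd.DataFrame(rows)
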