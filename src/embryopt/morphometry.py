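"""Per-embryo 3D morphometry: skeleton, landmarks and the 26-descriptor array.

Each segmented embryo is reduced to a named vector of shape and
intensity descriptors: voxel/physical volume, surface area, principal
axis lengths and ratios, solidity, extent, sphericity, skeleton length
and tortuosity, the distribution of skeleton-to-surface distances
(mean, variation = SD/mean, skewness, excess kurtosis), min-subtracted
intensity statistics, the anterior/posterior distance-map correlation
(AP index), the anterior–posterior chord, and centroid depth. The
descriptor array feeds the PCA morphospace downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse, stats
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import QhullError
from skimage.morphology import convex_hull_image

from .core import MultichannelVolume, Volume
from .segmentation import EmbryoMask

MISSING = float("nan")  # designated missing value for undefined statistics

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class Landmarks:
    """Anterior/posterior anchor points in voxel coordinates (z, y, x)."""

    anterior: np.ndarray
    posterior: np.ndarray
    source_channels: tuple[str, str] = ("anterior", "posterior")

    def __post_init__(self) -> None:
        self.anterior = np.asarray(self.anterior, dtype=float)
        self.posterior = np.asarray(self.posterior, dtype=float)


@dataclass
class Skeleton:
    """Pruned centerline of an embryo mask.

    ``path`` is the ordered voxel chain between the skeleton voxels
    nearest the anterior and posterior landmarks; successive points are
    26-neighbours. ``path_length`` is in µm.
    """

    path: np.ndarray              # (n, 3) voxel coordinates
    endpoints: np.ndarray         # (2, 3)
    path_length: float
    raw_skeleton: np.ndarray = field(repr=False, default=None)


@dataclass
class DescriptorVector:
    """The per-embryo morphological feature vector (26 named descriptors)."""

    embryo_id: str
    group_label: str
    descriptors: dict[str, float]

    def to_series(self) -> pd.Series:
        s = pd.Series(self.descriptors)
        s["embryo_id"] = self.embryo_id
        s["group_label"] = self.group_label
        return s


DEFAULT_DESCRIPTOR_NAMES: tuple[str, ...] = (
    "volume_voxels", "volume_um3", "surface_area_um2",
    "axis_length_L1_um", "axis_length_L2_um", "axis_length_L3_um",
    "axis_ratio_L2_L1", "axis_ratio_L3_L1", "axis_ratio_L3_L2",
    "solidity", "extent", "sphericity",
    "skeleton_length_um", "tortuosity",
    "skel_surf_dist_mean_um", "skel_surf_dist_variation",
    "skel_surf_dist_skewness", "skel_surf_dist_kurtosis",
    "intensity_mean", "intensity_variation",
    "intensity_skewness", "intensity_kurtosis",
    "ap_index", "ap_distance_um",
    "depth_mean_um", "depth_max_um",
)

# face-count surface areas overestimate smooth surfaces; 1.5 is the
# standard isotropic correction (exact in expectation for a sphere)
SURFACE_AREA_CORRECTION = 1.5


def _distribution_stats(values: np.ndarray) -> tuple[float, float, float, float]:
    """Mean, variation (SD/mean), sample skewness and excess kurtosis."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    variation = sd / mean if mean != 0 else MISSING
    if sd == 0.0:
        # constant sample: spread is zero, higher moments are undefined
        return mean, variation, MISSING, MISSING
    skw = float(stats.skew(values, bias=False))
    kur = float(stats.kurtosis(values, fisher=True, bias=False))
    return mean, variation, skw, kur


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

def detect_landmarks(anterior_channel: Volume, posterior_channel: Volume,
                     mask: EmbryoMask, search_dilation: int = 5) -> Landmarks:
    """Locate the A/P landmarks as brightest points of their marker channels.

    The search is restricted to a ``search_dilation``-voxel dilation of
    the embryo mask; ties resolve to the lowest linear index in (z, y, x)
    order.
    """
    region = ndimage.distance_transform_edt(~mask.mask) <= search_dilation

    def _argmax(channel: Volume, name: str) -> np.ndarray:
        data = np.where(region, channel.data, -np.inf)
        if not np.any(np.isfinite(data)) or np.nanmax(data[region]) <= 0:
            raise ValueError(f"landmark channel empty: no positive {name} signal "
                             "within the search region")
        return np.array(np.unravel_index(int(np.argmax(data)), data.shape), dtype=float)

    return Landmarks(anterior=_argmax(anterior_channel, "anterior"),
                     posterior=_argmax(posterior_channel, "posterior"),
                     source_channels=(anterior_channel.channel_label or "anterior",
                                      posterior_channel.channel_label or "posterior"))


# ---------------------------------------------------------------------------
# skeleton
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
                     for dx in (-1, 0, 1) if (dz, dy, dx) > (0, 0, 0)]


def _mask_graph(mask: np.ndarray, node_cost: np.ndarray | None = None
                ) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
    """26-connected adjacency of mask voxels, Euclidean step weights.

    ``node_cost`` (same shape as ``mask``) multiplies each step by the
    mean cost of its two endpoints. Returns (csr adjacency, index
    volume with -1 off-mask, (n, 3) voxel coordinates).
    """
    coords = np.argwhere(mask)
    n = len(coords)
    index = np.full(mask.shape, -1, dtype=np.int64)
    index[mask] = np.arange(n)
    rows, cols, weights = [], [], []
    shape = mask.shape
    for off in _NEIGHBOR_OFFSETS:
        src = tuple(slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape))
        dst = tuple(slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape))
        both = mask[src] & mask[dst]
        i = index[src][both]
        j = index[dst][both]
        w = np.full(len(i), float(np.linalg.norm(off)))
        if node_cost is not None:
            w = w * 0.5 * (node_cost[src][both] + node_cost[dst][both])
        rows.append(i)
        cols.append(j)
        weights.append(w)
    adj = sparse.coo_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsr()
    return adj, index, coords


def compute_skeleton(mask: EmbryoMask, landmarks: Landmarks,
                     smooth_window: int = 7,
                     anchor_depth_fraction: float = 0.5) -> Skeleton:
    """Extract the anterior-to-posterior centerline of an embryo mask.

    The centerline is the minimum-cost path through the mask between the
    near-medial voxels closest to the two landmarks, where each step is
    weighted by its Euclidean length divided by the squared distance to
    the surface — the path therefore runs along the medial axis (ridge
    of the distance transform) and side lobes are pruned automatically.
    Anchor candidates are restricted to voxels at least
    ``anchor_depth_fraction`` of the maximum depth, so the path of a
    quasi-spherical body collapses centrally instead of spanning the
    diameter. Path coordinates are smoothed over ``smooth_window`` voxels
    before measuring the length, removing voxel-staircase inflation.
    """
    m = mask.mask
    if m.sum() < 3:
        raise ValueError("mask too small to extract a centerline")
    edt = ndimage.distance_transform_edt(m)
    if edt.max() < 1.5:
        raise ValueError("mask thinner than 2 voxels everywhere")
    cost = np.zeros_like(edt)
    cost[m] = 1.0 / (edt[m] ** 2)
    adj, index, coords = _mask_graph(m, node_cost=cost)

    deep = edt[m] >= max(anchor_depth_fraction * edt.max(), 1.0)
    candidates = coords[deep]
    a_vox = candidates[int(np.argmin(np.linalg.norm(
        candidates - landmarks.anterior, axis=1)))]
    p_vox = candidates[int(np.argmin(np.linalg.norm(
        candidates - landmarks.posterior, axis=1)))]
    a_idx = int(index[tuple(a_vox)])
    p_idx = int(index[tuple(p_vox)])

    if a_idx == p_idx:
        path = coords[[a_idx]].astype(float)
    else:
        dist, pred = dijkstra(adj, directed=False, indices=a_idx,
                              return_predecessors=True)
        if not np.isfinite(dist[p_idx]):
            raise ValueError("mask is disconnected between the anterior and "
                             "posterior anchor voxels")
        chain = [p_idx]
        while chain[-1] != a_idx:
            chain.append(int(pred[chain[-1]]))
        path = coords[chain[::-1]].astype(float)

    raw = np.zeros(m.shape, dtype=bool)
    ip = path.astype(int)
    raw[ip[:, 0], ip[:, 1], ip[:, 2]] = True

    if len(path) > smooth_window:
        smoothed = np.column_stack([
            ndimage.uniform_filter1d(path[:, k], size=smooth_window, mode="nearest")
            for k in range(3)])
        smoothed[0], smoothed[-1] = path[0], path[-1]  # pin the anchors
    else:
        smoothed = path
    if len(smoothed) > 1:
        length = float(np.sum(np.linalg.norm(np.diff(smoothed, axis=0), axis=1))
                       ) * mask.voxel_size
    else:
        length = 0.0
    return Skeleton(path=path, endpoints=np.stack([smoothed[0], smoothed[-1]]),
                    path_length=length, raw_skeleton=raw)


def tortuosity(skeleton: Skeleton, voxel_size: float = 1.0) -> float:
    """Skeleton path length over the Euclidean endpoint chord (>= 1)."""
    chord = float(np.linalg.norm(skeleton.endpoints[1] - skeleton.endpoints[0])) * voxel_size
    if chord <= 0:
        raise ValueError("closed or degenerate path: coincident skeleton endpoints")
    return skeleton.path_length / chord


# ---------------------------------------------------------------------------
# shape descriptors
# ---------------------------------------------------------------------------

def principal_axis_lengths(mask: EmbryoMask) -> tuple[float, float, float]:
    """Full axis lengths (µm) of the intensity-equivalent ellipsoid.

    Eigenvalues lambda1 >= lambda2 >= lambda3 of the voxel-coordinate
    covariance give L_i = 4 sqrt(lambda_i) * voxel_size; only the ratios
    are scale-meaningful downstream.
    """
    coords = np.argwhere(mask.mask).astype(float)
    if len(coords) < 10:
        raise ValueError("degenerate mask: fewer than 10 voxels")
    cov = np.cov(coords.T)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    L = 4.0 * np.sqrt(eig) * mask.voxel_size
    return float(L[0]), float(L[1]), float(L[2])


def solidity(mask: EmbryoMask) -> float:
    """Mask voxel count over convex-hull voxel count, in (0, 1]."""
    if mask.voxel_count < 10:
        raise ValueError("degenerate mask: fewer than 10 voxels")
    try:
        # hull of voxel centres (no half-voxel offset): a convex digitized
        # body then scores exactly 1
        hull = convex_hull_image(mask.mask, offset_coordinates=False)
    except QhullError as exc:
        raise ValueError(f"degenerate (coplanar) mask: {exc}") from exc
    hull_count = int(hull.sum())
    if hull_count == 0:
        raise ValueError("degenerate mask: empty convex hull")
    return min(mask.voxel_count / hull_count, 1.0)


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Mask voxels 6-adjacent to background (or to the array border)."""
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return mask & ~interior


def surface_area(mask: EmbryoMask) -> float:
    """Exposed-voxel-face area (µm²) with the standard smoothing correction."""
    m = mask.mask
    faces = 0
    for ax in range(3):
        pad = np.pad(m, [(1, 1) if a == ax else (0, 0) for a in range(3)])
        diff = np.diff(pad.astype(np.int8), axis=ax)
        faces += int(np.abs(diff).sum())
    return faces * mask.voxel_size**2 / SURFACE_AREA_CORRECTION


def extent(mask: EmbryoMask) -> float:
    """Voxel count over bounding-box volume."""
    coords = np.argwhere(mask.mask)
    bbox = np.prod(coords.max(axis=0) - coords.min(axis=0) + 1)
    return mask.voxel_count / float(bbox)


def sphericity(mask: EmbryoMask) -> float:
    """pi^(1/3) (6V)^(2/3) / A: 1 for a ball, smaller for elongated bodies."""
    v = mask.voxel_count * mask.voxel_size**3
    a = surface_area(mask)
    return float(np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / a)


def skeleton_surface_stats(mask: EmbryoMask,
                           skeleton: Skeleton) -> tuple[float, float, float, float]:
    """Statistics of the skeleton-to-nearest-surface-voxel distances (µm).

    Returns (mean, variation = SD/mean, sample skewness, excess kurtosis)
    of the exact Euclidean distance from every path voxel to the nearest
    surface voxel of the mask. Path voxels closer to a path end (along
    the path) than their own surface distance are excluded: there the
    nearest surface is the body's end cap rather than its lateral wall,
    which would contaminate the local-radius distribution.
    """
    if len(skeleton.path) < 3:
        raise ValueError("skeleton path shorter than 3 voxels")
    surf = surface_voxels(mask.mask)
    dist = ndimage.distance_transform_edt(~surf)
    idx = skeleton.path.astype(int)
    d = dist[idx[:, 0], idx[:, 1], idx[:, 2]]
    steps = np.linalg.norm(np.diff(skeleton.path, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(steps)])
    from_end = np.minimum(arclen, arclen[-1] - arclen)
    keep = from_end >= d
    if keep.sum() >= 3:
        d = d[keep]
    return _distribution_stats(d * mask.voxel_size)


# ---------------------------------------------------------------------------
# distance maps and the AP index
# ---------------------------------------------------------------------------

def _snap_to_mask(point: np.ndarray, mask: np.ndarray, max_dist: float = 3.0) -> tuple:
    p = tuple(np.round(point).astype(int))
    p = tuple(np.clip(p, 0, np.asarray(mask.shape) - 1))
    if mask[p]:
        return p
    dist, idx = ndimage.distance_transform_edt(~mask, return_indices=True)
    if dist[p] > max_dist:
        raise ValueError(f"landmark {point} lies {dist[p]:.1f} voxels outside the mask "
                         f"(max {max_dist})")
    return tuple(int(idx[k][p]) for k in range(3))


def geodesic_distance_map(mask: np.ndarray, seed: np.ndarray | tuple,
                          voxel_size: float = 1.0) -> np.ndarray:
    """Within-mask shortest-path distance from ``seed`` to every mask voxel.

    Steps connect 26-neighbours and are weighted by their Euclidean
    length; off-mask voxels get NaN. Raises if any mask voxel is
    unreachable (disconnected mask).
    """
    adj, index, _coords = _mask_graph(mask)
    seed_vox = _snap_to_mask(np.asarray(seed, dtype=float), mask)
    d = dijkstra(adj, directed=False, indices=int(index[seed_vox]))
    if np.any(np.isinf(d)):
        raise ValueError("mask is disconnected: geodesic distance undefined for "
                         f"{int(np.isinf(d).sum())} voxels")
    out = np.full(mask.shape, np.nan)
    out[mask] = d * voxel_size
    return out


def euclidean_distance_map(mask: np.ndarray, seed: np.ndarray | tuple,
                           voxel_size: float = 1.0) -> np.ndarray:
    """Ambient Euclidean distance from ``seed``; off-mask voxels NaN."""
    seed_vox = np.asarray(_snap_to_mask(np.asarray(seed, dtype=float), mask), dtype=float)
    grids = np.indices(mask.shape, dtype=float)
    d = np.sqrt(sum((g - s) ** 2 for g, s in zip(grids, seed_vox))) * voxel_size
    d[~mask] = np.nan
    return d


def ap_index(mask: EmbryoMask, landmarks: Landmarks, mode: str = "geodesic") -> float:
    """Correlation of the distance maps seeded at the A and P landmarks.

    Pearson correlation over all mask voxels, in [-1, 1]: -1 for a
    straight body (the two distances sum to a constant), rising as the
    body folds onto itself.
    """
    mapper = {"geodesic": geodesic_distance_map, "euclidean": euclidean_distance_map}[mode]
    da = mapper(mask.mask, landmarks.anterior)
    dp = mapper(mask.mask, landmarks.posterior)
    a = da[mask.mask]
    p = dp[mask.mask]
    if a.std() == 0 or p.std() == 0:
        return 1.0 if np.allclose(a, p) else MISSING
    return float(np.corrcoef(a, p)[0, 1])


# ---------------------------------------------------------------------------
# intensity statistics
# ---------------------------------------------------------------------------

def intensity_stats(volume: Volume, mask: EmbryoMask) -> tuple[float, float, float, float]:
    """Min-subtracted in-mask intensity statistics.

    The in-mask minimum is subtracted first; returns (mean, SD/mean,
    sample skewness, excess kurtosis). A constant in-mask intensity
    yields mean 0 with the remaining statistics reported as NaN.
    """
    if volume.data.shape != mask.mask.shape:
        raise ValueError("volume and mask shapes differ")
    vals = volume.data[mask.mask].astype(float)
    vals = vals - vals.min()
    return _distribution_stats(vals)


# ---------------------------------------------------------------------------
# the descriptor array
# ---------------------------------------------------------------------------

def compute_descriptor_vector(volume: MultichannelVolume, mask: EmbryoMask,
                              landmarks: Landmarks, embryo_id: str = "",
                              group_label: str = "", nuclear_channel: int | str = 0,
                              ap_mode: str = "geodesic") -> DescriptorVector:
    """Assemble the full 26-descriptor feature vector for one embryo."""
    vs = mask.voxel_size
    d: dict[str, float] = {}

    def _stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"descriptor {name!r} failed: {exc}") from exc

    d["volume_voxels"] = float(mask.voxel_count)
    d["volume_um3"] = mask.voxel_count * vs**3
    d["surface_area_um2"] = _stage("surface_area_um2", lambda: surface_area(mask))
    L1, L2, L3 = _stage("axis_lengths", lambda: principal_axis_lengths(mask))
    d["axis_length_L1_um"], d["axis_length_L2_um"], d["axis_length_L3_um"] = L1, L2, L3
    d["axis_ratio_L2_L1"] = L2 / L1
    d["axis_ratio_L3_L1"] = L3 / L1
    d["axis_ratio_L3_L2"] = L3 / L2 if L2 > 0 else MISSING
    d["solidity"] = _stage("solidity", lambda: solidity(mask))
    d["extent"] = _stage("extent", lambda: extent(mask))
    d["sphericity"] = _stage("sphericity", lambda: sphericity(mask))

    skel = _stage("skeleton", lambda: compute_skeleton(mask, landmarks))
    d["skeleton_length_um"] = skel.path_length
    d["tortuosity"] = _stage("tortuosity", lambda: tortuosity(skel, voxel_size=vs))
    mean, var, skw, kur = _stage("skel_surf_dist",
                                 lambda: skeleton_surface_stats(mask, skel))
    d["skel_surf_dist_mean_um"] = mean
    d["skel_surf_dist_variation"] = var
    d["skel_surf_dist_skewness"] = skw
    d["skel_surf_dist_kurtosis"] = kur

    nuclear = volume.channel(nuclear_channel)
    mean, var, skw, kur = _stage("intensity", lambda: intensity_stats(nuclear, mask))
    d["intensity_mean"] = mean
    d["intensity_variation"] = var
    d["intensity_skewness"] = skw
    d["intensity_kurtosis"] = kur

    d["ap_index"] = _stage("ap_index", lambda: ap_index(mask, landmarks, mode=ap_mode))
    d["ap_distance_um"] = float(np.linalg.norm(landmarks.posterior - landmarks.anterior)) * vs

    depth = ndimage.distance_transform_edt(mask.mask)[mask.mask]
    d["depth_mean_um"] = float(depth.mean()) * vs
    d["depth_max_um"] = float(depth.max()) * vs

    assert set(d) == set(DEFAULT_DESCRIPTOR_NAMES) and len(d) == 26
    ordered = {k: d[k] for k in DEFAULT_DESCRIPTOR_NAMES}
    return DescriptorVector(embryo_id=embryo_id, group_label=group_label,
                            descriptors=ordered)


def descriptor_table(vectors: list[DescriptorVector]) -> pd.DataFrame:
    """Stack descriptor vectors into one row-per-embryo table."""
    rows = [v.to_series() for v in vectors]
    df = pd.DataFrame(rows)
    cols = ["embryo_id", "group_label", *DEFAULT_DESCRIPTOR_NAMES]
    return df[cols].reset_index(drop=True)
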