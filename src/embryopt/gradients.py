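"""Signaling-gradient quantitation from confocal nuclear stacks.

Nuclei are segmented per optical section by local-mean thresholding with
an erode/dilate refinement, labelled in 3D and filtered by size; an
optional per-section exclusion region removes extraembryonic (YSL)
nuclei. Per-nucleus centroids, voxel counts and per-channel mean
intensities are recorded, together with each nucleus' distance from the
embryonic margin along the profiling axis. Intensity-versus-distance
profiles are smoothed per embryo with lowess and aggregated across
embryos as mean and SEM on a common distance grid. A simple
signal-domain/embryo-area ratio quantifies domain size on maximum
intensity projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import MultichannelVolume, Volume


@dataclass
class MarginReference:
    """The margin plane used to measure per-nucleus distances.

    ``axis`` indexes the profiling direction in (z, y, x) order;
    ``position`` is the margin plane coordinate in voxels; ``direction``
    +1 if distance grows with the coordinate, -1 otherwise. Distances are
    clamped at zero.
    """

    axis: int = 1
    position: float = 0.0
    direction: int = 1


@dataclass
class GradientProfile:
    """Fitted per-embryo curves and their group aggregate."""

    distance_grid: np.ndarray           # µm, strictly increasing
    curves: np.ndarray                  # (n_embryos, n_grid)
    embryo_ids: list[str]
    mean: np.ndarray
    sem: np.ndarray


def segment_nuclei_stack(stack: Volume, mean_filter_radius: int = 8,
                         min_voxels: int = 30, offset: float | None = None,
                         exclusion_roi: np.ndarray | None = None) -> np.ndarray:
    """Label nuclei in a z-stack by per-section adaptive mean thresholding.

    A pixel is foreground when it exceeds the local mean within
    ``mean_filter_radius`` by ``offset`` (default: 1% of the stack
    maximum, which suppresses the faint halo where a nucleus' tail
    crosses its own windowed mean); each section is refined with one
    erosion and one dilation (3x3), voxels inside ``exclusion_roi`` (a
    2D boolean region applied to every section) are discarded, and 3D
    connected components smaller than ``min_voxels`` are removed.
    Returns a 3D label image (0 = background).
    """
    data = np.asarray(stack.data, dtype=np.float64)
    if data.size == 0 or data.max() == data.min():
        return np.zeros(data.shape, dtype=np.int32)
    if offset is None:
        offset = 0.01 * data.max()
    if exclusion_roi is not None:
        exclusion_roi = np.asarray(exclusion_roi, dtype=bool)
        if exclusion_roi.shape != data.shape[1:]:
            raise ValueError(f"exclusion_roi shape {exclusion_roi.shape} does not match "
                             f"section shape {data.shape[1:]}")
    size = 2 * mean_filter_radius + 1
    binary = np.zeros(data.shape, dtype=bool)
    se = np.ones((3, 3), dtype=bool)
    for z in range(data.shape[0]):
        local_mean = ndimage.uniform_filter(data[z], size=size, mode="reflect")
        b = data[z] > local_mean + offset
        b = ndimage.binary_erosion(b, structure=se)
        b = ndimage.binary_dilation(b, structure=se)
        binary[z] = b
    if exclusion_roi is not None:
        binary &= ~exclusion_roi[None, :, :]
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return labels.astype(np.int32)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_voxels)
    labels[np.isin(labels, small[small > 0])] = 0
    # relabel contiguously
    out, _ = ndimage.label(labels > 0, structure=np.ones((3, 3, 3), dtype=bool))
    return out.astype(np.int32)


def measure_nuclei(labels: np.ndarray, channels: MultichannelVolume | Volume,
                   margin: MarginReference | None = None) -> pd.DataFrame:
    """Per-nucleus centroid, size, margin distance and channel intensities.

    Returns one row per nucleus: ``nucleus_id``, centroid (z, y, x in
    voxels), ``voxel_count``, ``margin_distance_um`` and one
    ``mean_<label>`` column per channel.
    """
    if isinstance(channels, Volume):
        channels = MultichannelVolume(channels.data[None], voxel_size=channels.voxel_size,
                                      channel_labels=(channels.channel_label or "ch0",))
    if channels.data.shape[1:] != labels.shape:
        raise ValueError(f"channel shape {channels.data.shape[1:]} does not match "
                         f"label shape {labels.shape}")
    margin = margin or MarginReference()
    ids = np.arange(1, labels.max() + 1)
    if len(ids) == 0:
        cols = ["nucleus_id", "z", "y", "x", "voxel_count", "margin_distance_um"]
        cols += [f"mean_{lbl}" for lbl in channels.channel_labels]
        return pd.DataFrame(columns=cols)
    centroids = np.asarray(ndimage.center_of_mass(labels > 0, labels, ids))
    counts = ndimage.sum_labels(np.ones_like(labels), labels, ids).astype(int)
    dist = (centroids[:, margin.axis] - margin.position) * margin.direction
    dist = np.clip(dist * channels.voxel_size, 0.0, None)
    table = pd.DataFrame({
        "nucleus_id": ids,
        "z": centroids[:, 0], "y": centroids[:, 1], "x": centroids[:, 2],
        "voxel_count": counts,
        "margin_distance_um": dist,
    })
    for ci, lbl in enumerate(channels.channel_labels):
        table[f"mean_{lbl}"] = ndimage.mean(channels.data[ci], labels, ids)
    return table


def fit_gradient_profile(records: dict[str, pd.DataFrame], intensity_column: str,
                         smoothing_fraction: float = 0.3,
                         n_grid: int = 100,
                         distance_column: str = "margin_distance_um") -> GradientProfile:
    """Lowess-fit intensity vs margin distance per embryo and aggregate.

    ``records`` maps embryo id to its nucleus table. Each embryo needs at
    least 10 nuclei. Curves are evaluated on a common grid spanning the
    distance range shared by the data; the group aggregate is the
    pointwise mean and SEM across embryo curves.
    """
    if not records:
        raise ValueError("no embryos supplied")
    for eid, tab in records.items():
        if len(tab) < 10:
            raise ValueError(f"embryo {eid!r} has only {len(tab)} nuclei (need >= 10)")
    lo = min(tab[distance_column].min() for tab in records.values())
    hi = max(tab[distance_column].max() for tab in records.values())
    grid = np.linspace(lo, hi, n_grid)
    curves = []
    ids = []
    for eid, tab in records.items():
        x = tab[distance_column].to_numpy(dtype=float)
        y = tab[intensity_column].to_numpy(dtype=float)
        fitted = lowess(y, x, frac=smoothing_fraction, xvals=grid)
        curves.append(fitted)
        ids.append(eid)
    curves = np.asarray(curves)
    mean = curves.mean(axis=0)
    sem = (curves.std(axis=0, ddof=1) / np.sqrt(len(curves))
           if len(curves) > 1 else np.zeros_like(mean))
    return GradientProfile(distance_grid=grid, curves=curves, embryo_ids=ids,
                           mean=mean, sem=sem)


def domain_size_ratio(signal_area: float, embryo_area: float) -> float:
    """Signal-domain area over embryo area (both µm², same projection)."""
    if embryo_area <= 0 or signal_area < 0:
        raise ValueError("areas must be positive (embryo) and non-negative (signal)")
    if signal_area > embryo_area:
        raise ValueError(f"signal area {signal_area} exceeds embryo area {embryo_area}: "
                         "registration failure")
    return signal_area / embryo_area


def domain_areas_from_mip(signal_mip: np.ndarray, embryo_mip: np.ndarray,
                          pixel_size: float = 1.0) -> tuple[float, float]:
    """Otsu-threshold a signal MIP within the embryo region; return areas (µm²).

    The embryo region is the Otsu foreground of ``embryo_mip``; the
    signal region is the Otsu foreground of ``signal_mip`` restricted to
    the embryo region. A signal MIP with no dynamic range yields area 0.
    """
    embryo_region = embryo_mip > threshold_otsu(embryo_mip)
    sig = np.asarray(signal_mip, dtype=float)
    if np.ptp(sig[embryo_region]) == 0:
        signal_region = np.zeros_like(embryo_region) if sig[embryo_region].max() <= 0 \
            else embryo_region
    else:
        signal_region = (sig > threshold_otsu(sig[embryo_region])) & embryo_region
    a = pixel_size**2
    return float(signal_region.sum() * a), float(embryo_region.sum() * a)
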