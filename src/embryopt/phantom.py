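"""Synthetic embryo phantoms, OPT forward projection and confocal-like stacks.

Every downstream stage of the pipeline (axis correction, filtered
back-projection, segmentation, morphometry, morphospace, gradient
profiling) can be exercised against phantoms with exactly known ground
truth: a curved-tube "embryo body" with anterior/posterior marker spots,
severity-graded cohorts mimicking a dose–response experiment, and
nuclear z-stacks carrying a prescribed intensity gradient.

The tube body is built as a union of spheres along a Catmull-Rom
interpolated centerline, which guarantees an analytically known
centerline for skeleton and tortuosity tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .core import DEFAULT_VOXEL_SIZE_UM, MultichannelVolume, ProjectionSet, Volume

CHANNEL_LABELS = ("nuclear", "anterior", "posterior")


# ---------------------------------------------------------------------------
# specs and ground truth
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of one synthetic embryo phantom.

    If ``centerline_control_points`` is ``None``, a planar circular-arc
    centerline with arc/chord ratio ``target_tortuosity`` is constructed
    automatically, spanning ``axis_fraction`` of the volume x extent.
    All lengths are in µm.
    """

    centerline_control_points: Sequence[Sequence[float]] | None = None
    radius_profile: Callable[[np.ndarray], np.ndarray] | float = 42.0
    target_tortuosity: float = 1.10
    anterior_marker_sigma: float = 20.0
    posterior_marker_sigma: float = 20.0
    volume_shape: tuple[int, int, int] = (48, 72, 96)
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM
    intensity_level: float = 100.0
    noise_sigma: float = 0.0
    seed: int = 0
    axis_fraction: float = 0.72

    def __post_init__(self) -> None:
        if not self.target_tortuosity >= 1.0:
            raise ValueError("target_tortuosity must be >= 1")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        if len(self.volume_shape) != 3 or any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be 3 positive integers")

    def radius_at(self, s: np.ndarray) -> np.ndarray:
        """Tube radius (µm) at normalized arclength ``s`` in [0, 1]."""
        if callable(self.radius_profile):
            return np.asarray(self.radius_profile(np.asarray(s, dtype=float)), dtype=float)
        return np.full(np.shape(s), float(self.radius_profile))


@dataclass
class PhantomTruth:
    """Ground truth recorded while generating a phantom."""

    mask: np.ndarray                     # binary (z, y, x)
    centerline: np.ndarray               # (n, 3) voxel coordinates (z, y, x)
    anterior_point: np.ndarray           # (3,) voxel coordinates
    posterior_point: np.ndarray
    true_tortuosity: float
    true_volume: int                     # voxels
    radius_at_arclength: np.ndarray      # (n,) µm, sampled along the centerline

    def __post_init__(self) -> None:
        if self.true_tortuosity < 1.0 - 1e-9:
            raise ValueError("tortuosity ground truth must be >= 1")


@dataclass
class CohortSpec:
    """A severity-graded phantom cohort emulating a dose–response series.

    ``severity_map`` maps each dose label to shape parameters:
    ``tortuosity_mean``, ``tortuosity_sd``, ``thickness_amp`` (relative
    sinusoidal radius modulation), ``length_scale`` (multiplier on body
    length), ``notch_amp`` (relative mid-body radius pinch, reduces
    solidity). Severity must increase (weakly) with dose-level index.
    """

    dose_levels: Sequence[str]
    n_per_level: int
    severity_map: dict[str, dict[str, float]]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_level < 1:
            raise ValueError("n_per_level must be >= 1")
        missing = [d for d in self.dose_levels if d not in self.severity_map]
        if missing:
            raise ValueError(f"severity_map missing dose levels: {missing}")
        params = [self.severity_map[d] for d in self.dose_levels]
        for key, increasing in [("tortuosity_mean", True), ("thickness_amp", True),
                                ("notch_amp", True), ("length_scale", False)]:
            vals = [p.get(key, 1.0 if key == "length_scale" else 0.0) for p in params]
            diffs = np.diff(vals)
            ok = np.all(diffs >= -1e-12) if increasing else np.all(diffs <= 1e-12)
            if not ok:
                raise ValueError(f"severity parameter {key!r} must vary monotonically "
                                 f"with dose level; got {vals}")


def default_cohort_spec(n_per_level: int = 5, seed: int = 0) -> CohortSpec:
    """The default 4-level dose–response cohort (BMP-inhibitor style).

    Severity grows from unperturbed to heavily perturbed: the body
    becomes more tortuous, shorter, less uniformly thick and notched.
    """
    severity = {
        "0nM":   dict(tortuosity_mean=1.03, tortuosity_sd=0.01, thickness_amp=0.00,
                      length_scale=1.00, notch_amp=0.00),
        "100nM": dict(tortuosity_mean=1.18, tortuosity_sd=0.02, thickness_amp=0.10,
                      length_scale=0.92, notch_amp=0.15),
        "200nM": dict(tortuosity_mean=1.38, tortuosity_sd=0.03, thickness_amp=0.20,
                      length_scale=0.82, notch_amp=0.30),
        "400nM": dict(tortuosity_mean=1.62, tortuosity_sd=0.04, thickness_amp=0.30,
                      length_scale=0.70, notch_amp=0.45),
    }
    return CohortSpec(dose_levels=list(severity), n_per_level=n_per_level,
                      severity_map=severity, seed=seed)


# ---------------------------------------------------------------------------
# centerline construction
# ---------------------------------------------------------------------------

def _arc_angle_for_tortuosity(tau: float) -> float:
    """Central angle theta of a circular arc with arclength/chord = tau."""
    if tau <= 1.0 + 1e-12:
        return 0.0
    # tau = theta / (2 sin(theta/2)); monotone increasing on (0, 2*pi)
    f = lambda th: th / (2.0 * np.sin(th / 2.0)) - tau
    return float(optimize.brentq(f, 1e-6, 2.0 * np.pi - 1e-6))


def arc_control_points(chord_um: float, tortuosity: float, n_points: int = 7) -> np.ndarray:
    """Control points of a planar circular arc (z constant, bend in y).

    Returns an ``(n_points, 3)`` array of (z, y, x) offsets in µm, centred
    so the chord runs along x and the arc bulges toward +y, with the
    midpoint of the bounding box at the origin.
    """
    theta = _arc_angle_for_tortuosity(tortuosity)
    t = np.linspace(-0.5, 0.5, n_points)
    if theta < 1e-9:
        x = chord_um * t
        y = np.zeros_like(x)
    else:
        R = chord_um / (2.0 * np.sin(theta / 2.0))
        phi = theta * t
        x = R * np.sin(phi)
        y = R * (np.cos(phi) - np.cos(theta / 2.0))  # 0 at ends, sagitta at middle
        y -= y.max() / 2.0  # centre the bulge vertically
    z = np.zeros_like(x)
    return np.column_stack([z, y, x])


def catmull_rom(points: np.ndarray, samples_per_segment: int = 32) -> np.ndarray:
    """Uniform Catmull-Rom spline through ``points`` ((n, 3), n >= 2)."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("need an (n>=2, 3) control point array")
    # duplicate endpoints so the curve interpolates them
    ext = np.vstack([2 * pts[0] - pts[1], pts, 2 * pts[-1] - pts[-2]])
    out = []
    t = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)[:, None]
    for i in range(len(pts) - 1):
        p0, p1, p2, p3 = ext[i], ext[i + 1], ext[i + 2], ext[i + 3]
        a = 2 * p1
        b = p2 - p0
        c = 2 * p0 - 5 * p1 + 4 * p2 - p3
        d = -p0 + 3 * p1 - 3 * p2 + p3
        out.append(0.5 * (a + b * t + c * t**2 + d * t**3))
    out.append(pts[-1][None, :])
    return np.vstack(out)


def polyline_length(path: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def measure_tortuosity(path: np.ndarray) -> float:
    """Path length over endpoint chord of a polyline."""
    chord = float(np.linalg.norm(path[-1] - path[0]))
    if chord <= 0:
        raise ValueError("degenerate polyline: coincident endpoints")
    return polyline_length(path) / chord


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _rasterize_tube(centerline_vox: np.ndarray, radii_vox: np.ndarray,
                    shape: tuple[int, int, int]) -> np.ndarray:
    """Union of spheres along a densely sampled centerline."""
    mask = np.zeros(shape, dtype=bool)
    zz_cache: dict[int, tuple] = {}
    for c, r in zip(centerline_vox, radii_vox):
        ri = int(np.ceil(r))
        lo = np.maximum(np.floor(c - r).astype(int), 0)
        hi = np.minimum(np.ceil(c + r).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= d2 <= r * r
    return mask


def make_embryo_phantom(spec: PhantomSpec) -> tuple[MultichannelVolume, PhantomTruth]:
    """Generate a 3-channel embryo phantom and its ground truth.

    Channel 0 is the nuclear-like body intensity filling the tube;
    channels 1 and 2 are Gaussian marker spots centred on the anterior
    and posterior centerline endpoints (emulating head/tail expression
    landmarks). Identical spec + seed reproduce bit-identical output.
    """
    shape = tuple(int(s) for s in spec.volume_shape)
    vs = spec.voxel_size
    rng = np.random.default_rng(spec.seed)

    if spec.centerline_control_points is not None:
        ctrl_um = np.asarray(spec.centerline_control_points, dtype=float)
        ctrl_vox = ctrl_um / vs
    else:
        chord_um = spec.axis_fraction * shape[2] * vs
        ctrl_vox = arc_control_points(chord_um, spec.target_tortuosity) / vs
        ctrl_vox += np.asarray(shape, dtype=float) / 2.0 - 0.5

    path = catmull_rom(ctrl_vox)
    # resample to ~0.35 voxel spacing for a smooth union of spheres
    seglen = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arclen[-1]
    if total <= 0:
        raise ValueError("degenerate centerline: zero length")
    n_dense = max(int(np.ceil(total / 0.35)), 2)
    s_grid = np.linspace(0.0, total, n_dense)
    dense = np.column_stack([np.interp(s_grid, arclen, path[:, k]) for k in range(3)])
    s_norm = s_grid / total
    radii_um = spec.radius_at(s_norm)
    radii_vox = radii_um / vs

    lo = dense - radii_vox[:, None]
    hi = dense + radii_vox[:, None]
    if np.any(lo < 2.0) or np.any(hi > np.asarray(shape, dtype=float) - 3.0):
        bad = int(np.argmax(np.any((lo < 2.0) | (hi > np.asarray(shape) - 3.0), axis=1)))
        # report the nearest control point to the offending sample
        ctrl_idx = int(np.argmin(np.linalg.norm(ctrl_vox - dense[bad], axis=1)))
        raise ValueError(
            f"tube exits volume bounds (2-voxel margin) near control point "
            f"{ctrl_idx} at voxel {np.round(dense[bad], 1).tolist()}")

    mask = _rasterize_tube(dense, radii_vox, shape)

    body = spec.intensity_level * mask.astype(np.float64)

    def _marker(center_vox: np.ndarray, sigma_um: float) -> np.ndarray:
        sig_vox = max(sigma_um / vs, 0.5)
        grids = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center_vox))
        return spec.intensity_level * np.exp(-d2 / (2.0 * sig_vox**2))

    anterior = dense[0]
    posterior = dense[-1]
    channels = np.stack([
        body,
        _marker(anterior, spec.anterior_marker_sigma),
        _marker(posterior, spec.posterior_marker_sigma),
    ])
    if spec.noise_sigma > 0:
        channels = channels + rng.normal(0.0, spec.noise_sigma, size=channels.shape)

    truth = PhantomTruth(
        mask=mask,
        centerline=dense,
        anterior_point=anterior,
        posterior_point=posterior,
        true_tortuosity=measure_tortuosity(dense),
        true_volume=int(mask.sum()),
        radius_at_arclength=radii_um,
    )
    vol = MultichannelVolume(channels, voxel_size=vs, channel_labels=CHANNEL_LABELS)
    return vol, truth


def make_cohort(spec: CohortSpec) -> list[tuple[MultichannelVolume, PhantomTruth, str]]:
    """Generate a severity-graded phantom cohort, in dose-level order."""
    rng = np.random.default_rng(spec.seed)
    out = []
    base = PhantomSpec()
    for level in spec.dose_levels:
        p = spec.severity_map[level]
        for _ in range(spec.n_per_level):
            tau = max(1.0, rng.normal(p.get("tortuosity_mean", 1.0),
                                      p.get("tortuosity_sd", 0.0)))
            amp = p.get("thickness_amp", 0.0)
            notch = p.get("notch_amp", 0.0)
            base_r = float(base.radius_profile) if not callable(base.radius_profile) else 42.0

            def radius(s, _a=amp, _n=notch, _r=base_r):
                taper = 1.12 - 0.30 * s  # anterior (head) wider than posterior
                mod = 1.0 + _a * np.sin(2.0 * np.pi * 1.5 * s)
                pinch = 1.0 - _n * np.exp(-((s - 0.5) ** 2) / (2 * 0.06**2))
                return _r * np.clip(taper * mod * pinch, 0.15, None)

            phantom_spec = PhantomSpec(
                radius_profile=radius,
                target_tortuosity=tau,
                axis_fraction=base.axis_fraction * p.get("length_scale", 1.0),
                volume_shape=base.volume_shape,
                voxel_size=base.voxel_size,
                intensity_level=base.intensity_level,
                noise_sigma=2.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            vol, truth = make_embryo_phantom(phantom_spec)
            out.append((vol, truth, level))
    return out


# ---------------------------------------------------------------------------
# forward projection (parallel-beam OPT)
# ---------------------------------------------------------------------------

def forward_project(volume: Volume, n_angles: int = 400, axis_offset_px: float = 0.0,
                    noise_sigma: float = 0.0, seed: int = 0) -> ProjectionSet:
    """Parallel-beam line-integral projections at equally spaced angles over 360°.

    The detector plane is (z, x): rows follow the volume z axis, columns
    the axis perpendicular to the (vertical) rotation axis. A miscentred
    rotation axis is simulated by shifting detector columns by
    ``axis_offset_px`` (positive = axis right of the detector centre
    column). Gaussian noise of SD ``noise_sigma`` (detector counts) is
    added when nonzero. Noiseless, zero-offset projections conserve mass:
    each angle's projection sum equals the volume's total intensity.
    """
    if n_angles < 2:
        raise ValueError("n_angles must be >= 2")
    data = np.asarray(volume.data, dtype=np.float64)
    nz, ny, nx = data.shape
    # pad (y, x) so no mass leaves the grid under rotation
    diag = int(np.ceil(np.hypot(ny, nx))) + 4
    pad_y = (diag - ny) // 2, diag - ny - (diag - ny) // 2
    pad_x = (diag - nx) // 2, diag - nx - (diag - nx) // 2
    padded = np.pad(data, ((0, 0), pad_y, pad_x))

    angles = np.arange(n_angles) * (360.0 / n_angles)
    proj = np.empty((n_angles, nz, padded.shape[2]), dtype=np.float64)
    for i, ang in enumerate(angles):
        if ang == 0.0:
            rot = padded
        else:
            # rotate by -ang so the sinogram follows the standard Radon
            # convention expected by ramp-filtered back-projection
            rot = ndimage.rotate(padded, -ang, axes=(1, 2), reshape=False, order=1,
                                 mode="constant", cval=0.0, prefilter=False)
        proj[i] = rot.sum(axis=1)

    if axis_offset_px != 0.0:
        proj = ndimage.shift(proj, (0.0, 0.0, float(axis_offset_px)), order=1,
                             mode="nearest", prefilter=False)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        proj = proj + rng.normal(0.0, noise_sigma, size=proj.shape)

    return ProjectionSet(proj, angles, channel_label=volume.channel_label,
                         pixel_size=volume.voxel_size,
                         meta={"axis_offset_px": float(axis_offset_px),
                               "original_width": nx})


# ---------------------------------------------------------------------------
# confocal-like nuclear gradient stacks
# ---------------------------------------------------------------------------

def make_nuclear_gradient_stack(
    n_nuclei: int,
    decay: Callable[[np.ndarray], np.ndarray],
    noise_sigma: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int, int] = (40, 140, 140),
    voxel_size: float = 1.0,
    nucleus_sigma: float = 2.0,
) -> tuple[Volume, pd.DataFrame]:
    """Synthesize a nuclear z-stack carrying a margin-distance gradient.

    Gaussian-blob nuclei (SD ``nucleus_sigma`` voxels, nominal diameter
    4·SD) are placed with centre separation >= 2 nuclear diameters; the
    peak intensity of each nucleus equals ``decay(d)`` where ``d`` is the
    distance (µm) of its centre from the margin plane y = 0. Returns the
    stack and a truth table (centres, margin distances, intensities).
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    rng = np.random.default_rng(seed)
    stack = np.zeros(shape, dtype=np.float64)
    cols = ["z", "y", "x", "margin_distance_um", "intensity"]
    if n_nuclei == 0:
        if noise_sigma > 0:
            stack += rng.normal(0.0, noise_sigma, size=shape)
        return (Volume(stack, voxel_size=voxel_size, channel_label="nuclear"),
                pd.DataFrame(columns=cols))

    min_sep = 2.0 * 4.0 * nucleus_sigma  # two nominal diameters
    margin = 3.0 * nucleus_sigma
    if any(s - 1 - 2 * margin <= 0 for s in shape):
        raise ValueError(f"cannot place {n_nuclei} nuclei: stack {shape} is smaller "
                         f"than twice the {margin:.0f}-voxel placement margin")
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 10000 * n_nuclei
    while len(centers) < n_nuclei:
        if attempts >= max_attempts:
            raise ValueError(
                f"cannot place {n_nuclei} nuclei with separation >= {min_sep:.1f} voxels "
                f"in a {shape} stack (placed {len(centers)})")
        attempts += 1
        c = np.array([rng.uniform(margin, s - 1 - margin) for s in shape])
        if all(np.linalg.norm(c - prev) >= min_sep for prev in centers):
            centers.append(c)

    rows = []
    zi, yi, xi = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    for k, c in enumerate(centers):
        dist_um = max(c[1] * voxel_size, 0.0)
        inten = float(decay(np.asarray(dist_um)))
        r = int(np.ceil(4 * nucleus_sigma))
        lo = np.maximum(np.floor(c - r).astype(int), 0)
        hi = np.minimum(np.ceil(c + r).astype(int) + 1, shape)
        g = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        d2 = sum((gg - cc) ** 2 for gg, cc in zip(g, c))
        stack[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += inten * np.exp(-d2 / (2 * nucleus_sigma**2))
        rows.append([c[0], c[1], c[2], dist_um, inten])

    if noise_sigma > 0:
        stack += rng.normal(0.0, noise_sigma, size=shape)
    table = pd.DataFrame(rows, columns=cols)
    return Volume(stack, voxel_size=voxel_size, channel_label="nuclear"), table
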