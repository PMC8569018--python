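"""Core in-memory containers shared by all pipeline stages.

Axis-order contract: all 3D grids are indexed ``(z, y, x)``, 0-based.
Voxel sizes are isotropic and given in micrometres per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_VOXEL_SIZE_UM = 6.5  # rendering resolution of the OPT reconstructions


@dataclass
class Volume:
    """A 3D intensity grid with isotropic voxel size.

    Parameters
    ----------
    data:
        3D array, axis order ``(z, y, x)``. Negative values are allowed
        (filtered back-projection ringing is retained, not clipped).
    voxel_size:
        Isotropic voxel edge length in µm.
    channel_label:
        Free-text channel name (e.g. ``"nuclear"``, ``"anterior"``).
    """

    data: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D (z, y, x); got ndim={self.data.ndim}")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class MultichannelVolume:
    """A stack of co-registered single-channel volumes (channels first)."""

    data: np.ndarray  # (c, z, y, x)
    voxel_size: float = DEFAULT_VOXEL_SIZE_UM
    channel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("MultichannelVolume data must be 4D (c, z, y, x)")
        if not self.channel_labels:
            self.channel_labels = tuple(f"ch{i}" for i in range(self.data.shape[0]))
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    def channel(self, key: int | str) -> Volume:
        """Extract one channel as a :class:`Volume` (view, not copy)."""
        if isinstance(key, str):
            try:
                key = self.channel_labels.index(key)
            except ValueError:
                raise KeyError(f"no channel labelled {key!r}; have {self.channel_labels}") from None
        return Volume(self.data[key], voxel_size=self.voxel_size,
                      channel_label=self.channel_labels[key])


@dataclass
class ProjectionSet:
    """An angular series of 2D projection images (the sinogram stack).

    ``images`` has shape ``(n_angles, detector_rows, detector_cols)``;
    detector rows correspond to the volume z axis, columns to the axis
    perpendicular to the rotation axis. ``angles`` are in degrees, equally
    spaced over 360°.
    """

    images: np.ndarray
    angles: np.ndarray
    channel_label: str = ""
    pixel_size: float = DEFAULT_VOXEL_SIZE_UM
    applied_shift_px: float = 0.0  # bookkeeping for axis correction
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a 3D stack (n_angles, rows, cols)")
        if len(self.angles) != self.images.shape[0]:
            raise ValueError("one image per angle required")
        if len(self.angles) >= 2:
            d = np.diff(self.angles)
            if np.ptp(d) > 1e-6:
                raise ValueError("projection angles must be equally spaced (within 1e-6 deg)")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_angles(self) -> int:
        return self.images.shape[0]
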