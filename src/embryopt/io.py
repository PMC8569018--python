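"""Standard-format I/O: multi-page TIFF volumes/sinograms, CSV tables, JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import MultichannelVolume, ProjectionSet, Volume

FLOAT_FORMAT = "%.10g"  # fixed formatting keeps re-runs byte-identical


def write_volume(path, volume: Volume | MultichannelVolume) -> None:
    """Write a volume as multi-page TIFF with voxel size and labels in metadata."""
    meta = {"voxel_size_um": volume.voxel_size}
    if isinstance(volume, MultichannelVolume):
        meta["channel_labels"] = list(volume.channel_labels)
        meta["axes_order"] = "czyx"
    else:
        meta["channel_label"] = volume.channel_label
        meta["axes_order"] = "zyx"
    tifffile.imwrite(path, np.asarray(volume.data, dtype=np.float32),
                     metadata=meta)


def read_volume(path, multichannel: bool | None = None) -> Volume | MultichannelVolume:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    vs = float(meta.get("voxel_size_um", 1.0))
    if multichannel is None:
        multichannel = data.ndim == 4
    if multichannel:
        labels = tuple(meta.get("channel_labels", ()))
        return MultichannelVolume(data, voxel_size=vs, channel_labels=labels)
    return Volume(data, voxel_size=vs, channel_label=meta.get("channel_label", ""))


def write_projections(path, projections: ProjectionSet) -> None:
    meta = {
        "angles_deg": projections.angles.tolist(),
        "pixel_size_um": projections.pixel_size,
        "channel_label": projections.channel_label,
        "applied_shift_px": projections.applied_shift_px,
    }
    tifffile.imwrite(path, np.asarray(projections.images, dtype=np.float32),
                     metadata=meta)


def read_projections(path) -> ProjectionSet:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return ProjectionSet(data, np.asarray(meta["angles_deg"], dtype=float),
                         channel_label=meta.get("channel_label", ""),
                         pixel_size=float(meta.get("pixel_size_um", 1.0)),
                         applied_shift_px=float(meta.get("applied_shift_px", 0.0)))


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(path, obj: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
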