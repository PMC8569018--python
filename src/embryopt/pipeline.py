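"""End-to-end orchestration of the sinogram-to-morphospace workflow.

A :class:`RunConfig` (typically loaded from one JSON file with per-stage
sections) drives the whole chain: optional synthetic cohort generation,
optional forward projection + axis correction + filtered back-projection,
embryo segmentation, landmark detection, descriptor computation,
morphospace fitting and severity clustering. Artifacts are the
descriptor CSV, the morphospace model JSON, the scores/clusters CSV and
a run log recording every effective parameter.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as eio
from .core import MultichannelVolume, Volume
from .morphometry import (DescriptorVector, compute_descriptor_vector,
                          descriptor_table, detect_landmarks)
from .morphospace import cluster_embryos, fit_morphospace
from .phantom import (CohortSpec, default_cohort_spec, forward_project,
                      make_embryo_phantom, PhantomSpec)
from .recon import (AxisCorrectionParams, apply_axis_correction, center_crop,
                    estimate_axis_shift, reconstruct_fbp)
from .segmentation import SegmentationParams, segment_embryos

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    output_dir: str = "embryopt_out"
    input_volumes: list[str] = field(default_factory=list)   # multichannel TIFFs
    synthetic: bool = True
    cohort: CohortSpec | None = None
    simulate_projections: bool = False
    n_angles: int = 400
    axis_offset_px: float = 0.0
    projection_noise_sigma: float = 0.0
    axis_correction: AxisCorrectionParams = field(default_factory=AxisCorrectionParams)
    recon_voxel_size: float | None = None
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    channel_roles: dict[str, int] = field(
        default_factory=lambda: {"nuclear": 0, "anterior": 1, "posterior": 2})
    selected_features: list[str] | None = None
    cluster_method: str = "hierarchical"
    cluster_k: int = 4
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        raw = eio.read_json(path)
        kwargs = dict(raw)
        if "axis_correction" in kwargs:
            kwargs["axis_correction"] = AxisCorrectionParams(**kwargs["axis_correction"])
        if "segmentation" in kwargs:
            kwargs["segmentation"] = SegmentationParams(**kwargs["segmentation"])
        if "cohort" in kwargs and kwargs["cohort"] is not None:
            kwargs["cohort"] = CohortSpec(**kwargs["cohort"])
        return cls(**kwargs)

    def log_parameters(self) -> None:
        for f in dataclasses.fields(self):
            logger.info("config %s = %r", f.name, getattr(self, f.name))


def make_multi_embryo_acquisition(n_embryos: int = 5, seed: int = 0,
                                  base: PhantomSpec | None = None
                                  ) -> tuple[MultichannelVolume, list]:
    """One acquisition volume containing several embryos side by side.

    Phantoms with mildly varying tortuosity are generated in separate
    sub-volumes and concatenated along y, emulating a multi-embryo OPT
    acquisition.
    """
    rng = np.random.default_rng(seed)
    base = base or PhantomSpec(volume_shape=(40, 56, 96), radius_profile=36.0)
    blocks, truths = [], []
    for _ in range(n_embryos):
        spec = dataclasses.replace(
            base, target_tortuosity=float(1.02 + rng.uniform(0.0, 0.25)),
            seed=int(rng.integers(0, 2**31 - 1)), noise_sigma=2.0)
        vol, truth = make_embryo_phantom(spec)
        blocks.append(vol.data)
        truths.append(truth)
    data = np.concatenate(blocks, axis=2)  # side by side along y
    return MultichannelVolume(data, voxel_size=base.voxel_size,
                              channel_labels=("nuclear", "anterior", "posterior")), truths


def process_acquisition(volume: MultichannelVolume, config: RunConfig,
                        group_label: str = "", id_prefix: str = "e"
                        ) -> list[DescriptorVector]:
    """Reconstruct (optionally), segment and measure one acquisition."""
    roles = config.channel_roles
    if config.simulate_projections:
        channels = []
        shift_est = None
        for ci in range(volume.n_channels):
            ps = forward_project(volume.channel(ci), n_angles=config.n_angles,
                                 axis_offset_px=config.axis_offset_px,
                                 noise_sigma=config.projection_noise_sigma,
                                 seed=config.seed + ci)
            if shift_est is None:  # estimate once, on the nuclear channel
                nuc_ps = ps if ci == roles["nuclear"] else forward_project(
                    volume.channel(roles["nuclear"]), n_angles=config.n_angles,
                    axis_offset_px=config.axis_offset_px,
                    noise_sigma=config.projection_noise_sigma,
                    seed=config.seed + roles["nuclear"])
                shift_est = estimate_axis_shift(nuc_ps, config.axis_correction)
                logger.info("estimated axis shift: %.3f px", shift_est)
            corrected = apply_axis_correction(ps, shift_est)
            rec = reconstruct_fbp(corrected, voxel_size=config.recon_voxel_size)
            rec = center_crop(rec, volume.data.shape[1:])
            channels.append(rec.data)
        volume = MultichannelVolume(np.stack(channels), voxel_size=volume.voxel_size,
                                    channel_labels=volume.channel_labels)

    nuclear = volume.channel(roles["nuclear"])
    instances = segment_embryos(nuclear, config.segmentation)
    logger.info("segmented %d embryo instance(s)", len(instances))
    vectors = []
    for inst in instances:
        landmarks = detect_landmarks(volume.channel(roles["anterior"]),
                                     volume.channel(roles["posterior"]), inst)
        vec = compute_descriptor_vector(volume, inst, landmarks,
                                        embryo_id=f"{id_prefix}{inst.instance_id}",
                                        group_label=group_label,
                                        nuclear_channel=roles["nuclear"])
        vectors.append(vec)
    return vectors


def run_end_to_end(config: RunConfig) -> dict:
    """Run the full pipeline and write artifacts; returns the results.

    Artifacts in ``config.output_dir``: ``descriptors.csv``,
    ``morphospace_model.json``, ``scores_clusters.csv`` and ``run.log``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("embryopt")
    prev_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    root.addHandler(handler)
    try:
        config.log_parameters()
        vectors: list[DescriptorVector] = []
        if config.synthetic:
            from .phantom import make_cohort
            cohort_spec = config.cohort or default_cohort_spec(seed=config.seed)
            cohort = make_cohort(cohort_spec)
            for i, (vol, _truth, label) in enumerate(cohort):
                vecs = process_acquisition(vol, config, group_label=label,
                                           id_prefix=f"s{i:03d}_")
                vectors.extend(vecs)
        else:
            if not config.input_volumes:
                raise FileNotFoundError("no input volumes configured")
            for i, path in enumerate(config.input_volumes):
                if not Path(path).exists():
                    raise FileNotFoundError(f"input volume not found: {path}")
                vol = eio.read_volume(path, multichannel=True)
                vecs = process_acquisition(vol, config, group_label=Path(path).stem,
                                           id_prefix=f"s{i:03d}_")
                vectors.extend(vecs)

        table = descriptor_table(vectors)
        eio.write_table(out / "descriptors.csv", table)

        model = fit_morphospace(table, config.selected_features)
        model.to_json(out / "morphospace_model.json")
        assignment = cluster_embryos(model, method=config.cluster_method,
                                     k=min(config.cluster_k, len(model.embryo_ids)),
                                     seed=config.seed)
        scores = pd.DataFrame({
            "embryo_id": model.embryo_ids,
            "PC1": model.scores[:, 0],
            "PC2": model.scores[:, 1] if model.scores.shape[1] > 1 else 0.0,
            "cluster": assignment.labels,
        })
        eio.write_table(out / "scores_clusters.csv", scores)
        logger.info("variance explained (PC1, PC2): %.1f%%, %.1f%%",
                    model.variance_explained[0],
                    model.variance_explained[1] if len(model.variance_explained) > 1 else 0.0)
        return {"descriptors": table, "model": model, "clusters": assignment}
    finally:
        root.setLevel(prev_level)
        root.removeHandler(handler)
        handler.close()
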