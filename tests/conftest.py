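"""Shared fixtures: phantoms, cohorts and simple geometric masks.

Everything is generated programmatically at test time; heavy fixtures
(the severity cohort run through the full segmentation + morphometry
chain) are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from embryopt.morphometry import compute_descriptor_vector, descriptor_table, detect_landmarks
from embryopt.phantom import (PhantomSpec, default_cohort_spec, make_cohort,
                              make_embryo_phantom)
from embryopt.segmentation import EmbryoMask, segment_embryos

DOSE_CODE = {"0nM": 0, "100nM": 1, "200nM": 2, "400nM": 3}


@pytest.fixture(scope="session")
def default_phantom():
    """Noiseless default phantom with ground truth."""
    return make_embryo_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default phantom with detector-scale Gaussian noise."""
    return make_embryo_phantom(PhantomSpec(noise_sigma=2.0, seed=1))


@pytest.fixture(scope="session")
def small_phantom():
    """Compact phantom for projection-heavy tests."""
    spec = PhantomSpec(volume_shape=(24, 48, 64), radius_profile=30.0,
                       target_tortuosity=1.2, seed=0)
    return make_embryo_phantom(spec)


@pytest.fixture(scope="session")
def cohort_descriptors():
    """Severity cohort (4 levels x 5) run through segmentation + morphometry.

    Returns (descriptor table, dose codes, truths).
    """
    cohort = make_cohort(default_cohort_spec(n_per_level=5, seed=11))
    vectors, codes, truths = [], [], []
    for i, (vol, truth, label) in enumerate(cohort):
        instances = segment_embryos(vol.channel("nuclear"))
        assert instances, f"phantom {i} ({label}) not segmented"
        mask = instances[0]
        lm = detect_landmarks(vol.channel("anterior"), vol.channel("posterior"), mask)
        vectors.append(compute_descriptor_vector(vol, mask, lm,
                                                 embryo_id=f"e{i:02d}",
                                                 group_label=label))
        codes.append(DOSE_CODE[label])
        truths.append(truth)
    return descriptor_table(vectors), np.asarray(codes), truths


def make_ball(radius: int, pad: int = 4, voxel_size: float = 1.0) -> EmbryoMask:
    n = 2 * (radius + pad) + 1
    c = n // 2
    zz, yy, xx = np.ogrid[0:n, 0:n, 0:n]
    mask = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= radius**2
    return EmbryoMask(mask, 1, int(mask.sum()), voxel_size)


def make_ellipsoid(a: int, b: int, c: int, pad: int = 3,
                   voxel_size: float = 1.0, order=(0, 1, 2)) -> EmbryoMask:
    """Solid ellipsoid with semiaxes (a, b, c) along the permuted axes."""
    semis = np.array([a, b, c], dtype=float)[list(order)]
    shape = (2 * (semis + pad)).astype(int) + 1
    centers = shape // 2
    zz, yy, xx = np.ogrid[0:shape[0], 0:shape[1], 0:shape[2]]
    mask = (((zz - centers[0]) / semis[0]) ** 2 + ((yy - centers[1]) / semis[1]) ** 2
            + ((xx - centers[2]) / semis[2]) ** 2) <= 1.0
    return EmbryoMask(mask, 1, int(mask.sum()), voxel_size)


def make_cylinder(radius: int, length: int, pad: int = 4,
                  voxel_size: float = 1.0) -> EmbryoMask:
    """Solid cylinder along x."""
    n = 2 * (radius + pad) + 1
    c = n // 2
    zz, yy = np.ogrid[0:n, 0:n]
    disk = ((zz - c) ** 2 + (yy - c) ** 2) <= radius**2
    mask = np.zeros((n, n, length + 2 * pad), dtype=bool)
    mask[:, :, pad:pad + length] = disk[:, :, None]
    return EmbryoMask(mask, 1, int(mask.sum()), voxel_size)
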