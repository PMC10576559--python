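"""Shared fixtures: small deterministic phantoms and mask builders."""

from __future__ import annotations

import numpy as np
import pytest

from gliomets.imgproc import brain_mask_of, znorm_image
from gliomets.phantom import PhantomSpec, generate_case
from gliomets.volume import SegMask


def make_ball_mask(radius_mm=10.0, shape=(32, 32, 32), spacing=(1.0, 1.0, 1.0), label=2):
    """Digital ball labeled ``label``, centered in the grid."""
    coords = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)],
        indexing="ij",
    )
    ball = sum(c**2 for c in coords) <= radius_mm**2
    labels = np.zeros(shape, dtype=np.int16)
    labels[ball] = label
    return SegMask(labels=labels, spacing=spacing)


def make_cube_mask(corner, size, shape=(24, 24, 24), label=1):
    labels = np.zeros(shape, dtype=np.int16)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, (size,) * 3))
    labels[sl] = label
    return SegMask(labels=labels, spacing=(1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def glioma_case():
    return generate_case(PhantomSpec(tumor_type="glioma", seed=11))


@pytest.fixture(scope="session")
def mets_case():
    return generate_case(
        PhantomSpec(
            tumor_type="mets", lesion_count=5, lesion_radius_mm=(3.0, 7.0), seed=12
        )
    )


@pytest.fixture(scope="session")
def glioma_case_normalized(glioma_case):
    t1 = znorm_image(glioma_case.t1ce, brain_mask_of(glioma_case.t1ce))
    fl = znorm_image(glioma_case.t2flair, brain_mask_of(glioma_case.t2flair))
    return glioma_case, t1, fl
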