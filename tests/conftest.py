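"""Shared fixtures: phantom specs and voxelized analytic solids."""

import numpy as np
import pytest

from plastoquant.segmentation import BinaryMask
from plastoquant.stack_io import RunConfig
from plastoquant.synthetic_networks import PhantomSpec

#: render settings for clean (noiseless, blur at/below one voxel) fixtures
CLEAN_RENDER = dict(domain_um=(4.0, 6.0, 6.0),
                    blur_sigma_um=(0.12, 0.05, 0.05), snr=None)

#: the degraded-imaging study condition: 30 well-separated junctions,
#: anisotropic PSF blur (70 nm lateral, 300 nm axial) and SNR 10
DEGRADED = dict(n_junctions=30, domain_um=(4.2, 6.0, 6.0), shell_margin_um=1.0,
                blur_sigma_um=(0.3, 0.07, 0.07), snr=10.0)

#: compact ground-truth-only phantom for statistical simulations; enough
#: 4-way junctions that per-network angle means are reasonably normal
SMALL_STATS = dict(n_junctions=14, domain_um=(3.0, 4.4, 4.4),
                   shell_margin_um=0.8, n_open=2,
                   degree_probs={3: 0.7, 4: 0.3})


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def clean_spec():
    return PhantomSpec(seed=0, **CLEAN_RENDER)


def ellipsoid_mask(semi_axes_um, spacing=(0.1, 0.1, 0.1)) -> BinaryMask:
    """Voxelized solid ellipsoid: voxel kept iff its centre is inside."""
    semi = np.asarray(semi_axes_um, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    shape = np.ceil((2 * semi + 0.6) / sp).astype(int)
    zz, yy, xx = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(shape, sp)],
                             indexing="ij")
    c = shape * sp / 2
    inside = (((zz - c[0]) / semi[0]) ** 2 + ((yy - c[1]) / semi[1]) ** 2
              + ((xx - c[2]) / semi[2]) ** 2) <= 1.0
    return BinaryMask(inside, tuple(sp))
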