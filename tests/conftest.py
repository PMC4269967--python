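import numpy as np
import pytest
import scipy.ndimage as ndi

from papnuclei.segmentation import NucleusRegion
from papnuclei.synthetic_data import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """Noiseless 640x480 scene with 6 single nuclei and 2 overlapped pairs."""
    spec = SceneSpec(width=640, height=480, n_single=6, n_overlap=2,
                     noise_sigma=0.0, rng_seed=7)
    rgb, truth = generate_scene(spec)
    return spec, rgb, truth


@pytest.fixture(scope="session")
def sweep_result():
    """Full-scale end-to-end sweep shared by the acceptance tests."""
    from papnuclei.benchmark import run_synthetic_sweep

    return run_synthetic_sweep(n_scenes=10, seed=1)


def region_from_mask(mask: np.ndarray, label: int = 1) -> NucleusRegion:
    """Wrap a boolean mask as a NucleusRegion for feature tests."""
    rows, cols = np.nonzero(mask)
    boundary = mask & ~ndi.binary_erosion(
        mask, ndi.generate_binary_structure(2, 1))
    return NucleusRegion(
        label=label,
        boundary_pixels=np.argwhere(boundary),
        filled_mask=mask,
        bounding_box=(int(rows.min()), int(cols.min()),
                      int(rows.max()) + 1, int(cols.max()) + 1),
    )
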