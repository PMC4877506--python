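import numpy as np
import pytest

from stemtract import phantom
from stemtract.dissection import StemROI
from stemtract.tract_io import modal_dilate


@pytest.fixture(scope="session")
def spec():
    return phantom.PhantomSpec()


@pytest.fixture(scope="session")
def atlas(spec):
    return phantom.build_phantom_atlas(spec)


@pytest.fixture(scope="session")
def dilated(atlas):
    return modal_dilate(atlas, 1)


@pytest.fixture(scope="session")
def stem_roi_factory(spec):
    def make(tract, hemisphere, operator=""):
        vox = spec.stem_mask_voxels(tract, hemisphere)
        mask = np.zeros(spec.grid_shape, dtype=bool)
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        orientation = "coronal" if tract == "IFOF" else "axial"
        return StemROI(mask, spec.affine, orientation, tract_tag=tract,
                       hemisphere=hemisphere, operator=operator)
    return make


@pytest.fixture(scope="session")
def small_subject(atlas, spec):
    """One default-cohort subject shared across read-only tests."""
    cohort = phantom.CohortSpec(n_subjects=1, seed=7)
    tractogram, truth = phantom.simulate_subject(atlas, cohort, 0, spec)
    return cohort, tractogram, truth
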