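import numpy as np
import pytest

from fibsemquant import cell_segmentation as cellseg
from fibsemquant import synthetic_data as sd
from fibsemquant.pipeline import detect_stack
from fibsemquant.stack_io import VoxelGeometry


@pytest.fixture(scope="session")
def geom():
    return VoxelGeometry(
        pixel_size_x=6.3, pixel_size_y=6.3, slice_thickness=40.0, view_angle=0.0
    )


@pytest.fixture(scope="session")
def singles_phantom():
    """Five isolated spheres plus three agglomerates, rendered once."""
    agg = [(1, "in_plane")] * 5 + [(2, "stacked"), (2, "in_plane"), (3, "random")]
    phantom = sd.generate_phantom(agg, shape=(40, 200, 256), noise_sd=0.05, seed=3)
    stack, truth = sd.render_stack(phantom)
    return phantom, stack, truth


@pytest.fixture(scope="session")
def detection_setup(singles_phantom):
    """Segmentation + detection run once on the singles phantom."""
    phantom, stack, truth = singles_phantom
    seg = cellseg.segment_cell_stack(stack)
    aiu, rough, refined = detect_stack(stack, seg)
    return {
        "phantom": phantom,
        "stack": stack,
        "truth": truth,
        "seg": seg,
        "aiu": aiu,
        "rough": rough,
        "clusters": refined,
    }


@pytest.fixture(scope="session")
def quiet_cell_slice():
    """A particle-free cell slice with its trench, for low-level tests."""
    phantom = sd.generate_phantom([], shape=(8, 160, 192), noise_sd=0.05, seed=1)
    stack, _ = sd.render_stack(phantom)
    img = stack.data[4]
    trench = cellseg.detect_trench(img)
    return phantom, img, trench

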