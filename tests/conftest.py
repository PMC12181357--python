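import numpy as np
import pytest

from ezreflect import phantom, quantify


@pytest.fixture(scope="session")
def flat_params():
    """Noise-free, flat, pathology-free phantom geometry."""
    return phantom.PhantomParams(
        n_bscans=11, ascans_per_bscan=90, rows_per_ascan=160
    )


@pytest.fixture(scope="session")
def flat_phantom(flat_params):
    return phantom.generate_volume(flat_params, seed=7)


@pytest.fixture(scope="session")
def pathology_params():
    """Noise-free phantom with curvature, one druse and one atrophy disc."""
    return phantom.PhantomParams(
        n_bscans=15,
        ascans_per_bscan=108,
        rows_per_ascan=160,
        curvature_amplitude=8.0,
        drusen_spec=((30.0, 4.0, 12.0, 22.0),),
        atrophy_spec=((80.0, 11.0, 9.0),),
    )


@pytest.fixture(scope="session")
def pathology_phantom(pathology_params):
    return phantom.generate_volume(pathology_params, seed=11)


def uniform_map(value=5.0, n_bscans=161, n_rois=48, spacing_um=90.0):
    """A synthetic uniform REZRMap with symmetric degree-space geometry."""
    values = np.full((n_bscans, n_rois), float(value))
    excl = {
        k: np.zeros((n_bscans, n_rois), dtype=bool)
        for k in ("drusen", "atrophy", "no_segmentation", "edge")
    }
    x_um = (np.arange(n_rois) - (n_rois - 1) / 2.0) * spacing_um
    y_um = (np.arange(n_bscans) - (n_bscans - 1) / 2.0) * 30.0
    return quantify.REZRMap(values=values, exclusions=excl, x_um=x_um, y_um=y_um)
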