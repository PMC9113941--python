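import warnings

import numpy as np
import pytest

from nucarray.synthetic import (
    SyntheticArraySpec,
    build_array,
    build_core,
    preset_spec,
    reference_mononucleosome,
)


@pytest.fixture(scope="session")
def core_geometry():
    return build_core(SyntheticArraySpec())


@pytest.fixture(scope="session")
def reference_array():
    return reference_mononucleosome()


@pytest.fixture(scope="session")
def reference_track(reference_array):
    return reference_array.track("nuc1")


@pytest.fixture(scope="session")
def preset_arrays():
    """The four packaged NRL presets, built once per session."""
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # presets must build cleanly
        for nrl in (177, 187, 197, 207):
            out[nrl] = build_array(preset_spec(nrl))
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_rotation(rng):
    """Uniform proper rotation matrix from a seeded generator."""
    from scipy.spatial.transform import Rotation

    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
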