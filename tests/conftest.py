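import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for epg_reference

from t2pools import (
    CompartmentBoundaries,
    FitConfig,
    PhantomSpec,
    SequenceParams,
    T2Grid,
    generate_phantom,
)
from t2pools.compartment_maps import assemble_maps
from t2pools.spectrum_fit import fit_volume
from t2pools.synthetic_data import LesionSpec


@pytest.fixture(scope="session")
def params() -> SequenceParams:
    return SequenceParams()


@pytest.fixture(scope="session")
def grid() -> T2Grid:
    return T2Grid.logspaced()


@pytest.fixture(scope="session")
def small_phantom_spec() -> PhantomSpec:
    """A quick-to-fit phantom with WM, CSF and both lesion classes."""
    return PhantomSpec(
        shape=(14, 14, 4),
        csf_radius=2.2,
        lesions=(
            LesionSpec((4.0, 4.0, 1.5), 1.4, t1_hypo=False),
            LesionSpec((10.0, 10.0, 2.0), 1.6, t1_hypo=True),
        ),
        snr=200.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_spec):
    return generate_phantom(small_phantom_spec)


@pytest.fixture(scope="session")
def small_phantom_fit(small_phantom):
    ph = small_phantom
    mask = ph.tissue_labels > 0
    return fit_volume(ph.echoes, mask, ph.spec.params, T2Grid.logspaced(), FitConfig())


@pytest.fixture(scope="session")
def small_phantom_maps(small_phantom_fit):
    return assemble_maps(small_phantom_fit, CompartmentBoundaries())
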