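import numpy as np
import pytest

from t2biexp import (BiexpParams, EchoTimes, PhantomSpec, ROIPlacement,
                     make_phantom, reference_tissue)


@pytest.fixture(scope="session")
def tes():
    return EchoTimes.default()


@pytest.fixture(scope="session")
def retrodiscal_nd():
    """No-displacement retrodiscal reference parameters (exact means)."""
    return BiexpParams(amp_short=0.666, amp_long=0.334,
                       t2_short=17.6, t2_long=105.3)


@pytest.fixture(scope="session")
def noiseless_phantom(tes):
    """Tiny zero-variance, noise-free retrodiscal phantom with truth maps."""
    tissue = reference_tissue("retrodiscal_tissue", "no_displacement").zero_sd()
    roi = ROIPlacement(label=1, x=(2, 6), y=(2, 6), z=(0, 1))
    spec = PhantomSpec(rois=((tissue, roi),), shape=(8, 8, 1),
                       echo_times=tes, seed=3)
    vol, truth = make_phantom(spec)
    return vol, truth, roi
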