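import logging

import pytest

import fiberlab
from fiberlab import simulate as sim


@pytest.fixture(autouse=True)
def _quiet_logs():
    """Silence the package's clamp/interpolation warnings during tests."""
    logging.disable(logging.WARNING)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture(scope="session")
def waxd_image():
    """One default-truth synthetic diffraction image (Poisson, seed 0)."""
    return sim.gen_waxd_image()


@pytest.fixture(scope="session")
def waxd_analysis(waxd_image):
    """Full WAXD pipeline result on the default synthetic image (shared:
    the image analysis is the most expensive step in the suite)."""
    logging.disable(logging.WARNING)
    try:
        return fiberlab.analyze_image(waxd_image)
    finally:
        logging.disable(logging.NOTSET)
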