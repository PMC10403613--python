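import numpy as np
import pytest

from vsdpop.core import AcquisitionSpec, DffMovie, StimulusSpec


@pytest.fixture
def acq():
    return AcquisitionSpec()


@pytest.fixture
def small_acq():
    """Small frame for brute-force oracles."""
    return AcquisitionSpec(height_px=20, width_px=20, n_frames=15, onset_frame=3)


def make_movie(data, acq=None, **kwargs):
    """DffMovie from a raw (frames, rows, cols) array."""
    if acq is None:
        f, h, w = data.shape
        acq = AcquisitionSpec(height_px=h, width_px=w, n_frames=f,
                              onset_frame=kwargs.pop("onset_frame", 2))
    return DffMovie(data=np.asarray(data, dtype=float), acq=acq, **kwargs)


def opto_stim(site=(50, 50), pulse_ms=10.0):
    return StimulusSpec(modality="opto", pulse_ms=pulse_ms, site_px=site,
                        power_mw=15.0)
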