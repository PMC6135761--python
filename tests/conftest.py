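import numpy as np
import pytest

from fscvkit import (
    CalibrationSet,
    PCRCalibration,
    TemplateSpec,
    build_waveform,
    make_calibration_standards,
)


@pytest.fixture(scope="session")
def waveform():
    """Default acquisition waveform: -0.4 -> 1.3 V, 400 V/s, 10 Hz, 214 samples."""
    return build_waveform()


@pytest.fixture(scope="session")
def template_spec():
    return TemplateSpec()


@pytest.fixture(scope="session")
def noiseless_calibration(waveform, template_spec):
    """PCR calibration fitted on noiseless DA + pH + drift standards."""
    cvs, labels = make_calibration_standards(
        template_spec, waveform, current_noise_rms=0.0
    )
    return PCRCalibration(CalibrationSet(cvs, labels, waveform)).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
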