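import numpy as np
import pytest

from cbctdose import (
    CalibrationPoint,
    ScatterModelParams,
    build_calibration,
    make_protocol,
)


@pytest.fixture
def head_protocol():
    return make_protocol("full_fan")


@pytest.fixture
def body_protocol():
    return make_protocol("half_fan")


@pytest.fixture
def basic_params():
    """Noiseless sharp-edge scatter model used by the closed-form oracles."""
    return ScatterModelParams(
        equilibrium_dose_h=1.0, scatter_fraction_eta=0.4, scatter_range_d=50.0
    )


def make_log_calibration(pv_unexposed=40000.0, k=0.08, e_max=16.07, n=17):
    """Calibration points from an exposure-linear NOD response.

    PV(E) = PV0 * 10**(-k*E): net optical density grows linearly with
    exposure, the qualitative behaviour of radiochromic film.  The
    default ladder spacing (~1 R) keeps the piecewise-cubic
    interpolation error well below the 1% dosimetric budget.
    """
    exposures = np.linspace(0.0, e_max, n)
    pvs = pv_unexposed * 10.0 ** (-k * exposures)
    return [CalibrationPoint(pv, e) for pv, e in zip(pvs, exposures)]


@pytest.fixture
def log_calibration_curve():
    return build_calibration(make_log_calibration())
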