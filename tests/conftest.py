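import numpy as np
import pytest

from delaykin import ConductivitySeries, ProtocolSpec, REFERENCE_ESTIMATE


@pytest.fixture(scope="session")
def reference_pi():
    """Six-parameter estimate of the AChE + AChCl conductometric study."""
    return REFERENCE_ESTIMATE


@pytest.fixture(scope="session")
def protocol():
    return ProtocolSpec()


@pytest.fixture()
def flat_series():
    """Two-point series with no substrate (nS0 = 0): predicted kappa is 0,
    so residuals equal the recorded conductance directly."""

    def make(kappa, series_id="flat", addition_time=0.0):
        kappa = np.asarray(kappa, dtype=float)
        times = addition_time + np.arange(1, len(kappa) + 1.0)
        return ConductivitySeries(
            series_id=series_id,
            times=times,
            kappa=kappa,
            addition_time=times[0],
            nS0=0.0,
            nE0=0.05,
        )

    return make
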