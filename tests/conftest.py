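import numpy as np
import pytest

import vepforward as vf


@pytest.fixture(scope="session")
def layout():
    return vf.standard_128_layout()


@pytest.fixture(scope="session")
def wedges():
    return vf.build_wedge_set()


@pytest.fixture(scope="session")
def predicted(layout, wedges):
    """Parametric predicted topography sets for V1/V2/V3, unit RMS."""
    preds = vf.predicted_topographies(layout=layout, wedges=wedges)
    return {
        a: t.scaled(1.0 / np.sqrt(np.mean(t.values**2)))
        for a, t in preds.items()
    }


@pytest.fixture(scope="session")
def pulse_streams():
    return vf.pulse_streams_from_msequence(vf.generate_msequence(12))


def upper_mask(wedges):
    return np.array([w.upper_field for w in wedges])
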