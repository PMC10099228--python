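from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from b1sandwich import get_preset, prep_lookup
from b1sandwich.epg import TissueParams
from b1sandwich.pulses import make_hs8, make_sinc, simulate_pulse_response, build_lookup

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tissue_t2s():
    return TissueParams(t1=2.0, t2=0.05)


@pytest.fixture(scope="session")
def hs8_pulse():
    """5 ms, TBP-15, 1% truncation HS8 calibrated to 130 degrees."""
    return make_hs8(5e-3, 15, 130.0)


@pytest.fixture(scope="session")
def sinc_pulse():
    """Matched-bandwidth (+-3 kHz), matched-duration, matched-flip sinc."""
    return make_sinc(5e-3, 6000.0, 130.0)


@pytest.fixture(scope="session")
def hs8_lookup(hs8_pulse):
    scales = np.linspace(0.0, 2.5, 501)
    return build_lookup(simulate_pulse_response(hs8_pulse, scales, [0.0]))


@pytest.fixture(scope="session")
def rect_lookup():
    return prep_lookup(get_preset("2d-sattfl"))


def ideal_sattfl(n_lines: int = 1):
    """Fully-relaxed single-line satTFL: the arccos model is exact here."""
    return replace(
        get_preset("2d-sattfl"),
        n_lines_per_shot=n_lines,
        n_segments=36 // n_lines,
        td_s=15.0,
        tr_s=40.0,
        tr_fill_s=None,
    )
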