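import numpy as np
import pytest

from lqiso.reference import LITERATURE_FITS


@pytest.fixture(scope="session")
def fits():
    """Published cell-line fits keyed by label."""
    return LITERATURE_FITS


@pytest.fixture(scope="session")
def all_parameter_sets(fits):
    """Every published parameter set (LQ and finite-gamma ELQ), labelled."""
    out = {}
    for name, f in fits.items():
        out[f"{name}_LQ"] = f.lq
        if not f.elq.gamma_unbounded:
            out[f"{name}_ELQ"] = f.elq
    return out


@pytest.fixture(autouse=True)
def _quiet_clip_warnings():
    """Proportional noise near S=1 routinely clips a few draws; keep test
    output clean without hiding other warnings."""
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="noise_cv=.*clipped", category=RuntimeWarning)
        yield
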