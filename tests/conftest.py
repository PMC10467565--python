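import numpy as np
import pytest

import gluchange as g


def rates_from_eyring(spec, eyring_table, T):
    """Ground-truth group rates at temperature T from (kappa, dG) pairs."""
    return np.array(
        [
            g.eyring_rate(g.EyringParams(*eyring_table[grp]), T).k_ex
            for grp in spec.rate_group_names
        ]
    )


@pytest.fixture(scope="session")
def restricted_spec():
    return g.build_model("restricted")


@pytest.fixture(scope="session")
def acq():
    return g.AcquisitionConfig()


@pytest.fixture(scope="session")
def params_270K(restricted_spec):
    """Published restricted-model parameters evaluated at 270 K (pH 6.21)."""
    spec = restricted_spec
    return g.ModelParameters(
        deltas=[g.RESTRICTED_DELTAS_PH621[lbl] for lbl in spec.non_water_labels],
        rates=rates_from_eyring(spec, g.EYRING_PH621, 270.0),
    )


@pytest.fixture(scope="session")
def water_only_spec():
    """Single-pool model: just the water protons, no exchange partner."""
    return g.ExchangeModelSpec(
        variant="two_site",
        pools=[g.ProtonPool("water", 0.0, 1.0, "water")],
        rate_groups=[],
        rate_group_names=[],
    )


@pytest.fixture(scope="session")
def symmetric_two_site():
    """Equal-population two-pool system; the non-water pool carries the offset."""

    def make(delta_ppm, k_ex):
        spec = g.two_site_model(0.5)
        params = g.ModelParameters(deltas=[delta_ppm], rates=[k_ex])
        return spec, params

    return make
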