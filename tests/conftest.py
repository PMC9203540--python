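import numpy as np
import pytest

import coxtcm as cx

# the constant-infusion scenario: potency inferred from the threshold
# concentration lambda0/eta = 4032.3 of the equilibrium analysis
FIG_ETA = 0.25 / 4032.3


@pytest.fixture(scope="session")
def mouse150():
    """Domain objects for the PK-driven xenograft parameterization."""
    return {
        "growth": cx.GrowthParams("simeoni", lambda0=0.25, lambda1=0.4603, phi=20),
        "mortality": cx.MortalityParams(eta=0.7816),
        "tcm": cx.TCMParams(n=4, k1=0.2859, p=0.44268),
        "pk": cx.PKParams(k01=1.6, k21=0.2353, k12=0.1699, V=1028),
        "schedule": cx.daily_bolus_schedule(start=13.0, n_doses=10, amount=4.5e7, horizon=40.0),
        "w0": 0.0121,
    }


@pytest.fixture(scope="session")
def infusion_scenario(mouse150):
    """Simeoni growth with the threshold-scale potency (constant infusion)."""
    return {
        "growth": mouse150["growth"],
        "mortality": cx.MortalityParams(eta=FIG_ETA),
        "threshold": 4032.3,
    }


@pytest.fixture(scope="session")
def spheroid_truth():
    """Logistic-growth constant-concentration parameterization."""
    return {
        "growth": cx.GrowthParams("logistic", lambda0=0.12, umax=0.0066),
        "mortality": cx.MortalityParams(eta=0.0035),
        "tcm": cx.TCMParams(n=5, k1=0.1682, p=0.9),
        "w0": 0.002,
    }
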