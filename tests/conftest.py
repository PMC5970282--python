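import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def clinical_table(rng):
    """Small mixed-kind table consistent with `clinical_metafile`."""
    n = 240
    return pd.DataFrame(
        {
            "serum": rng.lognormal(0.5, 0.8, n),
            "events": rng.poisson(3.0, n),
            "mmse": rng.binomial(30, 0.8, n),
            "ecog_frac": rng.beta(2, 5, n),
            "severity": rng.choice(["none", "mild", "moderate", "severe"], n,
                                   p=[0.4, 0.3, 0.2, 0.1]),
        }
    )


@pytest.fixture
def clinical_metafile(tmp_path):
    path = tmp_path / "meta.csv"
    path.write_text(
        "variable,type,lower,upper,denominator,components,reverse,order\n"
        "serum,amount,,,,,,\n"
        "events,count,,,,,,\n"
        "mmse,bounded_count,0,30,,,,\n"
        "ecog_frac,fraction,,,,,,\n"
        "severity,ordinal,,,,,,none|mild|moderate|severe\n"
    )
    return path
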