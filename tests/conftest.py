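import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gsemkit import build_model, free_parameter_names
from gsemkit.simulate import standardized_truth

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_FACTORS = ["COMMON", "U_USE", "U_AUD", "LS"]
_PSI_TRUTH = {("LS", "COMMON"): -0.17, ("LS", "U_USE"): 0.22, ("LS", "U_AUD"): 0.0}


def theta_for_bifactor(spec):
    """Map the standardized generative truth onto a bifactor spec's theta order."""
    names, Lam, Psi, Theta = standardized_truth()
    lam = {
        ("lambda", it, f): Lam[i, k]
        for i, it in enumerate(names)
        for k, f in enumerate(_FACTORS)
        if Lam[i, k] != 0
    }
    out = []
    for n in free_parameter_names(spec):
        if n[0] == "lambda":
            out.append(lam.get(n, 0.0))
        elif n[0] == "psi":
            out.append(_PSI_TRUTH[(n[1], n[2])])
        else:
            out.append(Theta[names.index(n[1])])
    return np.array(out)


@pytest.fixture(scope="session")
def bifactor_spec():
    return build_model("D")


@pytest.fixture(scope="session")
def bifactor_theta(bifactor_spec):
    return theta_for_bifactor(bifactor_spec)
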