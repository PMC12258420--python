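import numpy as np
import pytest
from scipy import integrate, stats

from mvatost import EquivalenceSpec


@pytest.fixture
def spec():
    """Regulatory defaults: margin log(1.25), nominal level 0.05."""
    return EquivalenceSpec()


def univariate_tost_power_quadrature(gamma, theta, sigma, nu, c):
    """Independent oracle for the univariate TOST declaration probability.

    Integrates P(|theta_hat| <= c - t_{gamma,nu} * sigma_hat) over the
    chi-type law of sigma_hat (sigma_hat = sigma * sqrt(X / nu), X ~ chi2_nu)
    by adaptive quadrature -- no Wishart sampling, no shared code with the
    power kernel under test.
    """
    tq = stats.t.isf(gamma, nu)

    def integrand(x):
        s = sigma * np.sqrt(x / nu)
        u = c - tq * s
        if u <= 0:
            return 0.0
        p = stats.norm.cdf((u - theta) / sigma) - stats.norm.cdf((-u - theta) / sigma)
        return max(p, 0.0) * stats.chi2.pdf(x, nu)

    val, _ = integrate.quad(integrand, 0.0, stats.chi2.ppf(1 - 1e-12, nu), limit=200)
    return val
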