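"""Independent straight-line transcription of the binary HGF update
equations, kept deliberately separate from the package implementation.

Each trial is stepped with explicit scalar arithmetic following the
prediction / update structure of the model: variance inflation
exp(kappa*mu3 + omega2) on level 2, Bernoulli information in the level-2
posterior precision, and the volatility prediction error driving level 3.
Used only as a test oracle.
"""

import math


def step_hgf(u_k, mu2, sa2, mu3, sa3, kappa, omega2, omega3):
    # predictions
    muhat2 = mu2
    muhat1 = 1.0 / (1.0 + math.exp(-muhat2))
    muhat3 = mu3

    # level 2
    v2 = math.exp(kappa * mu3 + omega2)
    sahat2 = sa2 + v2
    pihat2 = 1.0 / sahat2
    da1 = u_k - muhat1
    pi2 = pihat2 + muhat1 * (1.0 - muhat1)
    sa2_new = 1.0 / pi2
    eps2 = sa2_new * da1
    mu2_new = muhat2 + eps2

    # level 3
    w2 = v2 * pihat2
    da2 = (sa2_new + eps2 * eps2) * pihat2 - 1.0
    pihat3 = 1.0 / (sa3 + math.exp(omega3))
    pi3 = pihat3 + 0.5 * kappa * kappa * w2 * (w2 + (2.0 * w2 - 1.0) * da2)
    sa3_new = 1.0 / pi3
    eps3 = 0.5 * sa3_new * kappa * w2 * da2
    mu3_new = muhat3 + eps3

    return {
        "mu1hat": muhat1,
        "da1": da1,
        "mu2": mu2_new,
        "sigma2": sa2_new,
        "mu2hat": muhat2,
        "eps2": eps2,
        "da2": da2,
        "mu3": mu3_new,
        "sigma3": sa3_new,
        "eps3": eps3,
        "env_uncertainty": v2,
    }


def run_hgf(u, kappa=1.0, omega2=-3.0, omega3=-6.0,
            mu2_0=0.0, sigma2_0=1.0, mu3_0=1.0, sigma3_0=1.0):
    mu2, sa2, mu3, sa3 = mu2_0, sigma2_0, mu3_0, sigma3_0
    rows = []
    for u_k in u:
        row = step_hgf(u_k, mu2, sa2, mu3, sa3, kappa, omega2, omega3)
        rows.append(row)
        mu2, sa2, mu3, sa3 = row["mu2"], row["sigma2"], row["mu3"], row["sigma3"]
    return rows
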