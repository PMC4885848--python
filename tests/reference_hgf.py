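"""Deliberately slow, equation-by-equation scalar binary-HGF reference.

Independent oracle for the package's filter: every update is written out
one equation per line, directly transcribing the three-level binary filter
without perceptual uncertainty.  Used only by tests.
"""

import math


def sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


def reference_filter(inputs, mu2_0=0.0, mu3_0=0.0, sigma2_0=0.1, sigma3_0=1.0,
                     rho2=0.0, kappa2=1.0, omega2=-2.28, omega3=-6.14):
    """Return a list of dicts with mu1hat, mu2, sigma2, mu3, sigma3 per trial."""
    mu2 = mu2_0
    sigma2 = sigma2_0
    mu3 = mu3_0
    sigma3 = sigma3_0
    out = []
    for u in inputs:
        # prediction step
        mu2hat = mu2 + rho2
        mu1hat = sigmoid(mu2hat)
        phasic2 = math.exp(kappa2 * mu3 + omega2)
        phasic3 = math.exp(omega3)

        if u is None:
            # no contingency information: variances inflate, means drift only
            mu2 = mu2hat
            sigma2 = sigma2 + phasic2
            sigma3 = sigma3 + phasic3
            out.append({"mu1hat": mu1hat, "mu2": mu2, "sigma2": sigma2,
                        "mu3": mu3, "sigma3": sigma3})
            continue

        # level-2 update
        pihat2 = 1.0 / (sigma2 + phasic2)
        delta1 = u - mu1hat
        pi2 = pihat2 + mu1hat * (1.0 - mu1hat)
        mu2_new = mu2hat + delta1 / pi2
        sigma2_new = 1.0 / pi2

        # level-3 update (volatility weighting)
        delta2 = (sigma2_new + (mu2_new - mu2hat) ** 2) * pihat2 - 1.0
        pihat3 = 1.0 / (sigma3 + phasic3)
        w2 = phasic2 * pihat2
        pi3 = pihat3 + 0.5 * kappa2 * kappa2 * w2 * (w2 + (2.0 * w2 - 1.0) * delta2)
        mu3_new = mu3 + 0.5 * kappa2 * w2 * delta2 / pi3
        sigma3_new = 1.0 / pi3

        mu2 = mu2_new
        sigma2 = sigma2_new
        mu3 = mu3_new
        sigma3 = sigma3_new
        out.append({"mu1hat": mu1hat, "mu2": mu2, "sigma2": sigma2,
                    "mu3": mu3, "sigma3": sigma3})
    return out


def reference_surprise(inputs, **kwargs):
    states = reference_filter(inputs, **kwargs)
    total = 0.0
    for state, u in zip(states, inputs):
        if u is None:
            continue
        p = state["mu1hat"] if u == 1 else 1.0 - state["mu1hat"]
        total = total - math.log(p)
    return total
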