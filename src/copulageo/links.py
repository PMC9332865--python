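"""Binary-margin link functions (logit, probit, cloglog) with derivatives.

Each margin of the joint model maps a linear predictor eta to an event
probability p = g^{-1}(eta). Probabilities are clipped to
[1e-10, 1 - 1e-10] so that log cell probabilities stay finite even for
extreme predictors; the derivatives are the exact analytic ones of the
unclipped inverse link.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats

__all__ = ["LINKS", "inverse_link", "link", "inverse_link_derivatives"]

P_CLIP = 1e-10
LINKS = ("logit", "probit", "cloglog")


def _check(link_name: str, eta=None):
    if link_name not in LINKS:
        raise ValueError(f"unknown link {link_name!r}; expected one of {LINKS}")
    if eta is not None:
        eta = np.asarray(eta, dtype=float)
        if not np.all(np.isfinite(eta)):
            raise ValueError("eta must be finite")
        return eta
    return None


def inverse_link(link_name: str, eta):
    """p = g^{-1}(eta), strictly increasing, clipped into (0, 1)."""
    eta = _check(link_name, eta)
    if link_name == "logit":
        p = special.expit(eta)
    elif link_name == "probit":
        p = special.ndtr(eta)
    else:  # cloglog: p = 1 - exp(-exp(eta))
        p = -np.expm1(-np.exp(np.minimum(eta, 30.0)))
    p = np.clip(p, P_CLIP, 1.0 - P_CLIP)
    return p if np.ndim(p) else float(p)


def link(link_name: str, p):
    """Forward link g(p) on (0, 1)."""
    _check(link_name)
    p = np.clip(np.asarray(p, dtype=float), P_CLIP, 1.0 - P_CLIP)
    if link_name == "logit":
        out = special.logit(p)
    elif link_name == "probit":
        out = stats.norm.ppf(p)
    else:
        out = np.log(-np.log1p(-p))
    return out if np.ndim(out) else float(out)


def inverse_link_derivatives(link_name: str, eta):
    """(dp/deta, d2p/deta2), analytic; the first is strictly positive."""
    eta = _check(link_name, eta)
    if link_name == "logit":
        p = special.expit(eta)
        d1 = p * (1.0 - p)
        d2 = d1 * (1.0 - 2.0 * p)
    elif link_name == "probit":
        d1 = stats.norm.pdf(eta)
        d2 = -eta * d1
    else:
        e = np.exp(np.minimum(eta, 30.0))
        d1 = e * np.exp(-e)
        d2 = d1 * (1.0 - e)
    d1 = np.maximum(d1, 1e-300)
    if np.ndim(eta):
        return d1, d2
    return float(d1), float(d2)
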