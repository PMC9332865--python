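"""Archimedean copula families: generators, CDFs, partial derivatives, Kendall's tau.

A bivariate Archimedean copula is built from a generator ``lam`` (a convex,
decreasing function on (0, 1] with ``lam(1) = 0``) via

    C(u, v) = lam_pseudo_inverse(lam(u) + lam(v)).

Three one-parameter families are supported — Clayton (lower tail dependence),
Gumbel (upper tail dependence) and Frank (no tail dependence) — plus the
independence copula ``C(u, v) = u v`` as a parameter-free reference family.
All families here are strict (``lam(0) = +inf``), so the pseudo-inverse agrees
with the ordinary inverse on the whole half-line; the truncation branch is kept
for generality.

Numerical notes
---------------
* Frank quantities are evaluated with ``expm1``/``log1p`` and switch to a
  second-order series in theta for ``|theta| < 1e-5``, where the direct ratio
  degenerates to 0/0.
* Clayton is restricted to theta > 0 (positive dependence); negative-dependence
  Clayton has no Gumbel analogue and would make family comparison ill-posed.
  Independence is exposed as its own family rather than as a boundary.
* Identities (symmetry, associativity, generator-vs-closed-form agreement) hold
  to 1e-9 absolute over the supported parameter ranges.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Union

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "CopulaFamily",
    "CopulaParam",
    "TauTest",
    "get_family",
    "check_theta",
    "generator",
    "generator_pseudo_inverse",
    "copula_cdf",
    "copula_cdf_via_generator",
    "copula_cdf_partial_u",
    "copula_cdf_partial_v",
    "copula_cdf_partial_theta",
    "kendall_tau_from_theta",
    "theta_from_kendall_tau",
    "empirical_kendall_tau_2x2",
]

_FRANK_SERIES_SWITCH = 1e-5  # |theta| below which Frank uses its theta-series


@dataclasses.dataclass(frozen=True)
class CopulaFamily:
    """An Archimedean copula family with its parameter domain.

    ``parameter_domain`` is ``(lo, hi, lo_open, hi_open)``; the independence
    family has an empty domain (``None``).
    """

    name: str
    parameter_domain: tuple | None
    tail_dependence: str  # one of {"lower", "upper", "none"}

    def theta_valid(self, theta: float) -> bool:
        if self.parameter_domain is None:
            return theta is None
        if theta is None or not np.isfinite(theta):
            return False
        lo, hi, lo_open, hi_open = self.parameter_domain
        if self.name == "frank" and theta == 0.0:
            return False
        ok_lo = theta > lo if lo_open else theta >= lo
        ok_hi = theta < hi if hi_open else theta <= hi
        return bool(ok_lo and ok_hi)


CLAYTON = CopulaFamily("clayton", (0.0, math.inf, True, True), "lower")
GUMBEL = CopulaFamily("gumbel", (1.0, math.inf, False, True), "upper")
FRANK = CopulaFamily("frank", (-math.inf, math.inf, True, True), "none")
INDEPENDENCE = CopulaFamily("independence", None, "none")

_FAMILIES = {f.name: f for f in (CLAYTON, GUMBEL, FRANK, INDEPENDENCE)}

FamilyLike = Union[str, CopulaFamily]


def get_family(family: FamilyLike) -> CopulaFamily:
    if isinstance(family, CopulaFamily):
        return family
    try:
        return _FAMILIES[family.lower()]
    except KeyError:
        raise ValueError(
            f"unknown copula family {family!r}; expected one of {sorted(_FAMILIES)}"
        ) from None


def check_theta(family: FamilyLike, theta) -> CopulaFamily:
    fam = get_family(family)
    if not fam.theta_valid(theta):
        raise ValueError(f"theta={theta!r} outside the {fam.name} parameter domain")
    return fam


@dataclasses.dataclass(frozen=True)
class CopulaParam:
    """Copula dependence parameter on the natural and unconstrained scales.

    The unconstrained scale is what the optimizer works on:
    gumbel ``theta = 1 + exp(eta)``, clayton ``theta = exp(eta)``,
    frank ``theta = eta``. The map is a smooth bijection onto the domain and
    round-trips to better than 1e-12.
    """

    family: CopulaFamily
    theta: float | None

    def __post_init__(self):
        check_theta(self.family, self.theta)

    @property
    def theta_unconstrained(self) -> float | None:
        return theta_to_unconstrained(self.family, self.theta)

    @classmethod
    def from_unconstrained(cls, family: FamilyLike, eta: float | None) -> "CopulaParam":
        fam = get_family(family)
        return cls(fam, theta_from_unconstrained(fam, eta))


def theta_to_unconstrained(family: FamilyLike, theta) -> float | None:
    fam = check_theta(family, theta)
    if fam.name == "independence":
        return None
    if fam.name == "gumbel":
        return math.log(theta - 1.0)
    if fam.name == "clayton":
        return math.log(theta)
    return float(theta)  # frank


def theta_from_unconstrained(family: FamilyLike, eta) -> float | None:
    fam = get_family(family)
    if fam.name == "independence":
        return None
    eta = float(eta)
    if fam.name == "gumbel":
        return 1.0 + math.exp(eta)
    if fam.name == "clayton":
        return math.exp(eta)
    return eta  # frank


def dtheta_deta(family: FamilyLike, theta: float) -> float:
    """Jacobian d theta / d eta of the unconstrained transform at ``theta``."""
    fam = get_family(family)
    if fam.name == "gumbel":
        return theta - 1.0
    if fam.name == "clayton":
        return theta
    if fam.name == "frank":
        return 1.0
    raise ValueError("independence family has no dependence parameter")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generator(family: FamilyLike, theta, t):
    """Generator lam(t) of the family, elementwise on ``t`` in (0, 1]."""
    fam = check_theta(family, theta)
    t = np.asarray(t, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t <= 0.0) or np.any(t > 1.0):
        raise ValueError("generator argument t must lie in (0, 1]")
    if fam.name == "clayton":
        out = (np.power(t, -theta) - 1.0) / theta
    elif fam.name == "gumbel":
        out = np.power(-np.log(t), theta)
    elif fam.name == "frank":
        # -log( (e^{-theta t} - 1) / (e^{-theta} - 1) ); expm1 keeps this
        # stable for small |theta|.
        out = -np.log(np.expm1(-theta * t) / np.expm1(-theta))
    else:  # independence
        out = -np.log(t)
    return out if out.ndim else float(out)


def generator_pseudo_inverse(family: FamilyLike, theta, s):
    """Pseudo-inverse of the generator: ordinary inverse on [0, lam(0)), 0 beyond."""
    fam = check_theta(family, theta)
    s = np.asarray(s, dtype=float)
    if np.any(~np.isfinite(s)) or np.any(s < 0.0):
        raise ValueError("generator pseudo-inverse argument s must be >= 0")
    if fam.name == "clayton":
        out = np.power(1.0 + theta * s, -1.0 / theta)
    elif fam.name == "gumbel":
        out = np.exp(-np.power(s, 1.0 / theta))
    elif fam.name == "frank":
        out = -np.log1p(np.exp(-s) * np.expm1(-theta)) / theta
    else:
        out = np.exp(-s)
    # all supported families are strict (lam(0) = inf); clip guards round-off
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# CDFs
# ---------------------------------------------------------------------------

def _check_uv(u, v):
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(u < 0) or np.any(u > 1) or np.any(v < 0) or np.any(v > 1):
        raise ValueError("copula arguments must lie in [0, 1]")
    return np.broadcast_arrays(u, v)


def copula_cdf(family: FamilyLike, theta, u, v):
    """Closed-form family CDF C(u, v; theta)."""
    fam = check_theta(family, theta)
    u, v = _check_uv(u, v)
    if fam.name == "independence":
        out = u * v
        return out if out.ndim else float(out)

    interior = (u > 0) & (v > 0) & (u < 1) & (v < 1)
    ui = np.where(interior, u, 0.5)
    vi = np.where(interior, v, 0.5)
    with np.errstate(all="ignore"):
        if fam.name == "clayton":
            s = np.power(ui, -theta) + np.power(vi, -theta) - 1.0
            core = np.power(s, -1.0 / theta)
        elif fam.name == "gumbel":
            a = np.power(-np.log(ui), theta) + np.power(-np.log(vi), theta)
            core = np.exp(-np.power(a, 1.0 / theta))
        else:  # frank
            if abs(theta) < _FRANK_SERIES_SWITCH:
                core = ui * vi * (1.0 + 0.5 * theta * (1.0 - ui) * (1.0 - vi))
            else:
                x = np.expm1(-theta * ui) * np.expm1(-theta * vi) / np.expm1(-theta)
                core = -np.log1p(x) / theta
    out = np.where(interior, core, 0.0)
    # boundaries: C(u, 0)=0, C(u, 1)=u and symmetric counterparts
    out = np.where((u == 0) | (v == 0), 0.0, out)
    out = np.where(v == 1, np.where(u == 1, 1.0, u), out)
    out = np.where((u == 1) & (v < 1), v, out)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def copula_cdf_via_generator(family: FamilyLike, theta, u, v):
    """C(u, v) by the generic generator construction; agreement with
    :func:`copula_cdf` to 1e-9 is a core correctness oracle."""
    fam = check_theta(family, theta)
    u, v = _check_uv(u, v)
    if fam.name == "independence":
        out = u * v
        return out if out.ndim else float(out)
    zero = (u == 0) | (v == 0)
    uc = np.clip(u, 1e-300, 1.0)
    vc = np.clip(v, 1e-300, 1.0)
    s = np.asarray(generator(fam, theta, uc) + generator(fam, theta, vc))
    out = np.asarray(generator_pseudo_inverse(fam, theta, np.minimum(s, 1e300)))
    out = np.where(zero, 0.0, out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# partial derivatives (used by the likelihood)
# ---------------------------------------------------------------------------

def copula_cdf_partial_u(family: FamilyLike, theta, u, v):
    """dC/du at interior points; boundary values by continuous extension."""
    fam = check_theta(family, theta)
    u, v = _check_uv(u, v)
    if fam.name == "independence":
        out = v.astype(float)
        return out if out.ndim else float(out)
    eps = 1e-12
    ui = np.clip(u, eps, 1.0 - eps)
    vi = np.clip(v, eps, 1.0 - eps)
    with np.errstate(all="ignore"):
        if fam.name == "clayton":
            s = np.power(ui, -theta) + np.power(vi, -theta) - 1.0
            out = np.exp((-theta - 1.0) * np.log(ui) + (-1.0 / theta - 1.0) * np.log(s))
        elif fam.name == "gumbel":
            x = -np.log(ui)
            y = -np.log(vi)
            a = np.power(x, theta) + np.power(y, theta)
            c = np.exp(-np.power(a, 1.0 / theta))
            out = c * np.power(a, 1.0 / theta - 1.0) * np.power(x, theta - 1.0) / ui
        else:  # frank
            if abs(theta) < _FRANK_SERIES_SWITCH:
                out = vi * (1.0 + 0.5 * theta * (1.0 - vi) * (1.0 - 2.0 * ui))
            else:
                num = np.exp(-theta * ui) * np.expm1(-theta * vi)
                den = np.expm1(-theta) + np.expm1(-theta * ui) * np.expm1(-theta * vi)
                out = num / den
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def copula_cdf_partial_v(family: FamilyLike, theta, u, v):
    return copula_cdf_partial_u(family, theta, v, u)


def copula_cdf_partial_theta(family: FamilyLike, theta, u, v):
    """dC/dtheta. Analytic for Clayton/Gumbel; central differences for Frank,
    whose closed-form theta-derivative is error-prone."""
    fam = check_theta(family, theta)
    u, v = _check_uv(u, v)
    if fam.name == "independence":
        raise ValueError("independence copula has no dependence parameter")
    eps = 1e-12
    ui = np.clip(u, eps, 1.0 - eps)
    vi = np.clip(v, eps, 1.0 - eps)
    with np.errstate(all="ignore"):
        if fam.name == "clayton":
            lu = np.log(ui)
            lv = np.log(vi)
            s = np.exp(-theta * lu) + np.exp(-theta * lv) - 1.0
            c = np.power(s, -1.0 / theta)
            out = c * (
                np.log(s) / theta**2
                + (np.exp(-theta * lu) * lu + np.exp(-theta * lv) * lv) / (theta * s)
            )
        elif fam.name == "gumbel":
            x = -np.log(ui)
            y = -np.log(vi)
            xt = np.power(x, theta)
            yt = np.power(y, theta)
            a = xt + yt
            b = np.power(a, 1.0 / theta)
            c = np.exp(-b)
            dlnb = -np.log(a) / theta**2 + (xt * np.log(x) + yt * np.log(y)) / (theta * a)
            out = -c * b * dlnb
        else:  # frank, central differences
            if abs(theta) < _FRANK_SERIES_SWITCH:
                out = 0.5 * ui * vi * (1.0 - ui) * (1.0 - vi)
            else:
                h = 1e-6 * max(1.0, abs(theta))
                out = (
                    np.asarray(copula_cdf(fam, theta + h, ui, vi))
                    - np.asarray(copula_cdf(fam, theta - h, ui, vi))
                ) / (2.0 * h)
    out = np.where(np.isfinite(out), out, 0.0)
    return out if np.ndim(out) else float(out)


# ---------------------------------------------------------------------------
# Kendall's tau
# ---------------------------------------------------------------------------

def _debye1(theta: float) -> float:
    """First Debye function D1(theta) = (1/theta) * int_0^theta t/(e^t - 1) dt."""
    val, _ = integrate.quad(lambda t: t / math.expm1(t) if t != 0 else 1.0, 0.0, theta)
    return val / theta


def kendall_tau_from_theta(family: FamilyLike, theta=None) -> float:
    """Population Kendall's tau implied by the copula parameter.

    Gumbel: 1 - 1/theta; Clayton: theta/(theta+2);
    Frank: 1 + 4 (D1(theta) - 1)/theta (odd in theta); independence: 0.
    """
    fam = check_theta(family, theta)
    if fam.name == "independence":
        return 0.0
    if fam.name == "gumbel":
        return 1.0 - 1.0 / theta
    if fam.name == "clayton":
        return theta / (theta + 2.0)
    if abs(theta) < _FRANK_SERIES_SWITCH:
        return theta / 9.0
    return 1.0 + 4.0 * (_debye1(theta) - 1.0) / theta


def theta_from_kendall_tau(family: FamilyLike, tau: float) -> float:
    """Inverse of :func:`kendall_tau_from_theta`; raises if tau is unattainable."""
    fam = get_family(family)
    tau = float(tau)
    if not -1.0 < tau < 1.0:
        raise ValueError("tau must lie strictly inside (-1, 1)")
    if fam.name == "independence":
        if tau != 0.0:
            raise ValueError("independence copula attains only tau = 0")
        return 0.0
    if fam.name == "gumbel":
        if tau < 0.0:
            raise ValueError("gumbel attains only tau in [0, 1)")
        return 1.0 / (1.0 - tau)
    if fam.name == "clayton":
        if tau <= 0.0:
            raise ValueError("clayton (theta > 0) attains only tau in (0, 1)")
        return 2.0 * tau / (1.0 - tau)
    # frank: monotone in theta; bracket then root-find
    if tau == 0.0:
        raise ValueError("frank attains tau = 0 only in the theta -> 0 limit")
    hi = 1.0
    while kendall_tau_from_theta(fam, hi) < abs(tau):
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"tau={tau} not attainable by frank within theta <= 1e6")
    theta = optimize.brentq(
        lambda th: kendall_tau_from_theta(fam, th) - abs(tau), 1e-8, hi, xtol=1e-12
    )
    return theta if tau > 0 else -theta


@dataclasses.dataclass(frozen=True)
class TauTest:
    tau_b: float
    z: float
    p_value: float
    n: int


def empirical_kendall_tau_2x2(counts) -> TauTest:
    """Kendall's tau-b for a 2x2 contingency table with an asymptotic z test.

    For a 2x2 table tau-b reduces to the phi coefficient
    ``(n11 n22 - n12 n21) / sqrt(r1 r2 c1 c2)`` and ``n * tau_b**2`` is the
    Pearson chi-square statistic, so the test is the usual one-degree
    chi-square test of association expressed as a signed z.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(c < 0) or np.any(c != np.floor(c)):
        raise ValueError("counts must be nonnegative integers")
    n = c.sum()
    if n <= 0:
        raise ValueError("table is empty")
    r = c.sum(axis=1)
    col = c.sum(axis=0)
    if np.any(r == 0) or np.any(col == 0):
        raise ValueError("tau-b undefined: a table margin is zero")
    tau = (c[0, 0] * c[1, 1] - c[0, 1] * c[1, 0]) / math.sqrt(r[0] * r[1] * col[0] * col[1])
    z = tau * math.sqrt(n)
    p = 2.0 * stats.norm.sf(abs(z))
    return TauTest(tau_b=float(tau), z=float(z), p_value=float(p), n=int(n))
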