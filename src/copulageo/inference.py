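"""AIC-based copula/link selection and Wald inference.

Model comparison uses AIC = -2 log L + 2 V with V the effective degrees of
freedom of the fit (the raw parameter count for unpenalized models). Fixed
effects get per-coefficient z tests; the penalized blocks (age smooth,
structured and unstructured spatial effects) get block chi-square tests
``beta_b' V_b^- beta_b`` on the block's effective degrees of freedom, rounded
to the nearest half and referred to the (possibly fractional-df) chi-square
distribution via the gamma CDF.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from . import copulas
from .design import ModelSpec, RegionGraph
from .fitting import FitOptions, FitResult, fit_model

__all__ = [
    "aic",
    "SelectionTable",
    "select_copula",
    "select_links",
    "WaldResult",
    "wald_fixed",
    "wald_block",
    "model_kendall_tau",
    "DEFAULT_LINK_PAIRS",
]

DEFAULT_COPULA_CANDIDATES = ("clayton", "gumbel", "frank")
DEFAULT_LINK_PAIRS = (
    ("logit", "logit"),
    ("logit", "cloglog"),
    ("logit", "probit"),
    ("cloglog", "probit"),
)


def aic(loglik: float, v: float) -> float:
    """Akaike information criterion -2 logL + 2 V; lower is better."""
    if v < 0:
        raise ValueError("effective parameter count v must be nonnegative")
    return -2.0 * loglik + 2.0 * v


@dataclasses.dataclass
class SelectionTable:
    """AIC comparison of candidate models; the first minimal-AIC candidate
    (in candidate order) is the winner."""

    rows: pd.DataFrame  # columns: candidate, edf, aic (candidate order preserved)
    best: str
    fits: dict

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def _select(data, spec_for, candidates, labels, graph, options) -> SelectionTable:
    rows = []
    fits = {}
    for cand, label in zip(candidates, labels):
        try:
            fit = fit_model(spec_for(cand), data, graph=graph, options=options)
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"candidate {label} failed to fit: {exc}")
            continue
        if not fit.converged:
            warnings.warn(f"candidate {label} did not converge; excluded")
            continue
        fits[label] = fit
        rows.append({"candidate": label, "edf": fit.edf, "aic": fit.aic})
    if not rows:
        raise RuntimeError("every candidate failed to converge")
    table = pd.DataFrame(rows)
    best = table.loc[table["aic"].idxmin(), "candidate"]  # idxmin: first minimum
    return SelectionTable(rows=table, best=str(best), fits=fits)


def select_copula(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    candidates=DEFAULT_COPULA_CANDIDATES,
    graph: RegionGraph | None = None,
    options: FitOptions | None = None,
) -> SelectionTable:
    """Fit one model per copula family (at the spec's links) and rank by AIC."""
    spec = spec or ModelSpec.fixed_effects_only()

    def spec_for(fam):
        d = spec.to_dict()
        d["family"] = fam
        return ModelSpec.from_dict(d)

    return _select(data, spec_for, candidates, list(candidates), graph, options)


def select_links(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    candidates=DEFAULT_LINK_PAIRS,
    graph: RegionGraph | None = None,
    options: FitOptions | None = None,
) -> SelectionTable:
    """Fit one model per (link1, link2) pair at the spec's family; rank by AIC."""
    spec = spec or ModelSpec.fixed_effects_only()

    def spec_for(pair):
        d = spec.to_dict()
        d["links"] = list(pair)
        return ModelSpec.from_dict(d)

    labels = [f"c({a!r}, {b!r})" for a, b in candidates]
    return _select(data, spec_for, list(candidates), labels, graph, options)


@dataclasses.dataclass
class WaldResult:
    term: str
    estimate: np.ndarray | float
    se: np.ndarray | float | None
    statistic: float
    df: float
    p_value: float
    kind: str  # "z" or "chi2"

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def wald_fixed(fit: FitResult, term: str | None = None, margin: int | None = None):
    """Per-coefficient Wald z tests for the fixed effects.

    With ``term`` given, returns the single :class:`WaldResult` (term names
    are ``"factor[level]"`` or ``"intercept"``); otherwise a tidy DataFrame
    with one row per coefficient per margin.
    """
    se_all = np.sqrt(np.maximum(np.diag(fit.covariance), 0.0))
    rows = []
    for blk in fit.blocks:
        if blk["name"] != "fixed":
            continue
        if margin is not None and blk["margin"] != margin:
            continue
        for name, i in zip(blk["names"], range(blk["gsl"].start, blk["gsl"].stop)):
            est = float(fit.params[i])
            se = float(se_all[i])
            z = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
            p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else 0.0
            if est == 0.0:
                z, p = 0.0, 1.0
            rows.append(
                {
                    "margin": blk["margin"],
                    "term": name,
                    "estimate": est,
                    "se": se,
                    "statistic": z,
                    "df": 1.0,
                    "p_value": p,
                }
            )
    table = pd.DataFrame(rows)
    if term is None:
        return table
    match = table[table["term"] == term]
    if margin is None and len(match) > 1:
        raise ValueError(f"term {term!r} appears in both margins; pass margin=")
    if match.empty:
        raise KeyError(f"unknown fixed-effect term {term!r}")
    r = match.iloc[0]
    return WaldResult(
        term=term,
        estimate=float(r["estimate"]),
        se=float(r["se"]),
        statistic=float(r["statistic"]),
        df=1.0,
        p_value=float(r["p_value"]),
        kind="z",
    )


def _chi2_sf_fractional(stat: float, df: float) -> float:
    """Upper tail of chi-square with (possibly fractional) df via Gamma(df/2, 2)."""
    if df <= 0:
        return 1.0
    return float(stats.gamma.sf(stat, a=df / 2.0, scale=2.0))


def wald_block(fit: FitResult, block: str, margin: int = 1) -> WaldResult:
    """Block Wald chi-square test for a penalized term of one margin.

    ``block`` is one of ``smooth_age``, ``structured``, ``unstructured``.
    The statistic is ``beta_b' Cov_b^- beta_b`` with a generalized inverse;
    df is the block's effective degrees of freedom rounded to the nearest 0.5.
    """
    sl = fit.block_slice(margin, block)
    beta = fit.params[sl]
    cov_b = fit.covariance[sl, sl]
    cov_inv = np.linalg.pinv(cov_b, rcond=1e-10, hermitian=True)
    stat = float(beta @ cov_inv @ beta)
    edf = fit.edf_by_block[f"{block}_{margin}"]
    df = max(round(edf * 2.0) / 2.0, 0.5)
    p = 1.0 if np.isclose(stat, 0.0) else _chi2_sf_fractional(stat, df)
    return WaldResult(
        term=f"{block} (margin {margin})",
        estimate=beta.copy(),
        se=None,
        statistic=stat,
        df=df,
        p_value=p,
        kind="chi2",
    )


def block_test_table(fit: FitResult) -> pd.DataFrame:
    """Chi-square tests for all penalized blocks of both margins."""
    rows = []
    for blk in fit.blocks:
        if blk["S"] is None:
            continue
        res = wald_block(fit, blk["name"], blk["margin"])
        rows.append(
            {
                "margin": blk["margin"],
                "term": blk["name"],
                "chi_square": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def model_kendall_tau(fit: FitResult, level: float = 0.95):
    """Model-implied Kendall's tau with a delta-method confidence interval.

    The CI propagates the variance of the unconstrained dependence parameter
    through theta(eta) and tau(theta). For an independence-family fit, tau is
    exactly 0 with a degenerate interval.
    """
    fam = fit.theta_hat.family
    if fam.name == "independence":
        return 0.0, (0.0, 0.0)
    theta = fit.theta_hat.theta
    tau = copulas.kendall_tau_from_theta(fam, theta)
    var_eta = float(fit.covariance[-1, -1])
    h = 1e-6 * max(1.0, abs(theta))
    lo_th = max(theta - h, {"gumbel": 1.0 + 1e-12, "clayton": 1e-12}.get(fam.name, theta - h))
    dtau_dth = (
        copulas.kendall_tau_from_theta(fam, theta + h)
        - copulas.kendall_tau_from_theta(fam, lo_th)
    ) / (theta + h - lo_th)
    dth_deta = copulas.dtheta_deta(fam, theta)
    se_tau = abs(dtau_dth * dth_deta) * np.sqrt(max(var_eta, 0.0))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    ci = (max(tau - zq * se_tau, -1.0), min(tau + zq * se_tau, 1.0))
    return float(tau), ci
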