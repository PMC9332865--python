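"""Synthetic DHS-like data with known copula dependence and spatial structure.

The generator inverts the model: it draws categorical covariates with
frequencies resembling the pooled three-country sample, a uniform age in
months on [0, 59], and region labels on a lattice; forms each margin's linear
predictor from chosen fixed-effect coefficients, a smooth age curve, and
structured (intrinsic-autoregressive) plus unstructured (i.i.d.) region
effects; maps the predictors through the links; computes the four joint-cell
probabilities through the copula; and draws one multinomial cell per child.
The latent truth (region effects and per-record probabilities) is stored
alongside the records so recovery can be tested end to end.

This module also packages the study's printed 2x2 anaemia-by-malnutrition
contingency table as a fixture for the descriptive analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Callable

import numpy as np
import pandas as pd

from . import copulas
from .design import FACTOR_LEVELS, RegionGraph, age_band_from_months, grid_graph
from .fitting import cell_probabilities
from .links import inverse_link

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_spatial_effects",
    "simulate_dataset",
    "table1_fixture",
    "table1_summary",
    "TABLE2_RESIDENCE_BOTH",
    "default_sine_smooth",
]

# Covariate category frequencies approximating the pooled-sample margins;
# order matches FACTOR_LEVELS (reference level first).
_DEFAULT_COVARIATE_PROBS = {
    "residence": (0.40, 0.60),
    "sex": (0.50, 0.50),
    "mother_education": (0.12, 0.55, 0.33),
    "birth_interval": (0.26, 0.40, 0.34),
    "wealth": (0.45, 0.25, 0.30),
    "birth_order": (0.32, 0.31, 0.37),
}

# Moderate fixed-effect coefficients (treatment coding, non-reference levels),
# chosen to produce realistic prevalences without separation.
_DEFAULT_BETA1 = {  # anaemia margin
    "intercept": 0.4,
    "residence[rural]": 0.15,
    "sex[female]": 0.15,
    "mother_education[primary]": 0.60,
    "mother_education[secondary]": 0.30,
    "birth_interval[24-47]": -0.20,
    "birth_interval[>47]": -0.25,
    "wealth[middle]": -0.30,
    "wealth[not poor]": -0.60,
    "birth_order[4-5]": 0.10,
    "birth_order[>5]": 0.20,
}
_DEFAULT_BETA2 = {  # malnutrition margin
    "intercept": 0.3,
    "residence[rural]": 0.10,
    "sex[female]": -0.10,
    "mother_education[primary]": 0.50,
    "mother_education[secondary]": 0.25,
    "birth_interval[24-47]": -0.15,
    "birth_interval[>47]": -0.10,
    "wealth[middle]": -0.25,
    "wealth[not poor]": -0.50,
    "birth_order[4-5]": -0.15,
    "birth_order[>5]": -0.25,
}


def default_sine_smooth(amplitude: float = 0.5) -> Callable:
    """A single-arch sine in age: rises to a peak near 30 months then falls,
    mirroring the empirical age profile of anaemia risk."""

    def f(age):
        return amplitude * np.sin(np.pi * np.asarray(age, dtype=float) / 59.0)

    return f


@dataclasses.dataclass
class SyntheticConfig:
    """Ground-truth configuration for one synthetic dataset."""

    n: int = 5000
    grid: tuple = (4, 4)
    family: str = "gumbel"
    theta: float | None = 2.0
    links: tuple = ("logit", "probit")
    beta1: dict = dataclasses.field(default_factory=lambda: dict(_DEFAULT_BETA1))
    beta2: dict = dataclasses.field(default_factory=lambda: dict(_DEFAULT_BETA2))
    smooth1: Callable | None = dataclasses.field(default_factory=default_sine_smooth)
    smooth2: Callable | None = dataclasses.field(default_factory=default_sine_smooth)
    var_structured: float = 0.15
    var_unstructured: float = 0.05
    covariate_probs: dict = dataclasses.field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_COVARIATE_PROBS.items()}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.grid[0] < 1 or self.grid[1] < 1:
            raise ValueError("grid dimensions must be positive")
        copulas.check_theta(self.family, self.theta)
        for fac, probs in self.covariate_probs.items():
            if fac not in FACTOR_LEVELS:
                raise ValueError(f"unknown factor {fac!r}")
            if len(probs) != len(FACTOR_LEVELS[fac]):
                raise ValueError(f"wrong number of category probabilities for {fac!r}")
            if abs(sum(probs) - 1.0) > 1e-8:
                raise ValueError(f"category probabilities for {fac!r} must sum to 1")
        if self.var_structured < 0 or self.var_unstructured < 0:
            raise ValueError("spatial variances must be nonnegative")


@dataclasses.dataclass
class SyntheticDataset:
    records: pd.DataFrame
    truth: pd.DataFrame  # per-record p1, p2, p11, p10, p01, p00, eta1, eta2
    structured: pd.Series  # per-region
    unstructured: pd.Series
    graph: RegionGraph
    config: SyntheticConfig

    def write(self, outdir) -> dict:
        """Write observations.csv, adjacency.gal, truth.csv; returns paths."""
        import os

        os.makedirs(outdir, exist_ok=True)
        obs = os.path.join(outdir, "observations.csv")
        gal = os.path.join(outdir, "adjacency.gal")
        tru = os.path.join(outdir, "truth.csv")
        self.records.to_csv(obs, index=False)
        write_gal(self.graph, gal)
        self.truth.to_csv(tru, index=False)
        return {"observations": obs, "adjacency": gal, "truth": tru}


def write_gal(graph: RegionGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{graph.n_regions}\n")
        for rid in graph.region_ids:
            nbrs = sorted(graph.neighbors.get(rid, ()), key=graph.region_ids.index)
            fh.write(f"{rid} {len(nbrs)}\n")
            if nbrs:
                fh.write(" ".join(map(str, nbrs)) + "\n")


def simulate_spatial_effects(graph: RegionGraph, variances, seed=None, rng=None):
    """Draw (structured, unstructured) region effects.

    The structured effect is a zero-mean Gaussian with precision proportional
    to the graph Laplacian (made proper with a 1e-6 ridge), centered to sum
    to zero within each connected component; the unstructured effect is
    i.i.d. Gaussian. ``variances`` is (var_structured, var_unstructured).
    Deterministic given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    var_s, var_u = variances
    r = graph.n_regions
    q = graph.laplacian() + 1e-6 * np.eye(r)
    # scale the precision deterministically so the average marginal variance
    # of the (properized) Gaussian equals var_s
    avg_var = float(np.trace(np.linalg.inv(q)) / r)
    chol = np.linalg.cholesky(q)
    z = rng.standard_normal(r)
    x = np.linalg.solve(chol.T, z)  # x ~ N(0, Q^{-1})
    x = x * np.sqrt(var_s / avg_var) if var_s > 0 else np.zeros(r)
    # center per connected component so the effect is identified
    pos = {rid: i for i, rid in enumerate(graph.region_ids)}
    for comp in graph.components():
        idx = [pos[c] for c in comp]
        x[idx] -= x[idx].mean()
    u = rng.standard_normal(r) * np.sqrt(var_u)
    u -= u.mean()  # centered so the intercept stays identified
    ids = list(graph.region_ids)
    return pd.Series(x, index=ids, name="structured"), pd.Series(
        u, index=ids, name="unstructured"
    )


def _draw_covariates(cfg: SyntheticConfig, rng) -> pd.DataFrame:
    n = cfg.n
    df = {}
    for fac, probs in cfg.covariate_probs.items():
        levels = FACTOR_LEVELS[fac]
        df[fac] = rng.choice(levels, size=n, p=np.asarray(probs))
    df["age_months"] = rng.integers(0, 60, size=n)
    return pd.DataFrame(df)


def _fixed_eta(df: pd.DataFrame, beta: dict) -> np.ndarray:
    eta = np.full(len(df), beta.get("intercept", 0.0))
    for key, val in beta.items():
        if key == "intercept":
            continue
        fac, lev = key[:-1].split("[")
        eta += val * (df[fac].astype(str) == lev).to_numpy(dtype=float)
    return eta


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset (reproducible per seed) with its latent truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    graph = grid_graph(*cfg.grid)
    df = _draw_covariates(cfg, rng)
    df["age_band"] = age_band_from_months(df["age_months"])
    df["region_id"] = rng.choice(graph.region_ids, size=cfg.n)

    struct, unstruct = simulate_spatial_effects(
        graph, (cfg.var_structured, cfg.var_unstructured), rng=rng
    )
    spat = struct.add(unstruct).reindex(df["region_id"]).to_numpy()

    ages = df["age_months"].to_numpy(dtype=float)
    age_grid = np.arange(60, dtype=float)

    def centered_smooth(f):
        if f is None:
            return np.zeros_like(ages)
        return f(ages) - np.mean(f(age_grid))  # centered over the uniform age range

    eta1 = _fixed_eta(df, cfg.beta1) + centered_smooth(cfg.smooth1) + spat
    eta2 = _fixed_eta(df, cfg.beta2) + centered_smooth(cfg.smooth2) + spat

    p1 = np.asarray(inverse_link(cfg.links[0], eta1))
    p2 = np.asarray(inverse_link(cfg.links[1], eta2))
    p11, p10, p01, p00 = cell_probabilities(p1, p2, cfg.family, cfg.theta)

    cells = np.stack([p11, p10, p01, p00], axis=1)
    u = rng.random(cfg.n)
    cum = np.cumsum(cells, axis=1)
    cell_idx = (u[:, None] > cum).sum(axis=1)  # 0:11, 1:10, 2:01, 3:00
    df["anaemia"] = np.isin(cell_idx, (0, 1)).astype(int)
    df["malnourished"] = np.isin(cell_idx, (0, 2)).astype(int)

    truth = pd.DataFrame(
        {
            "eta1": eta1,
            "eta2": eta2,
            "p1": p1,
            "p2": p2,
            "p11": p11,
            "p10": p10,
            "p01": p01,
            "p00": p00,
            "region_id": df["region_id"],
        }
    )
    cols = [
        "anaemia",
        "malnourished",
        "residence",
        "sex",
        "age_months",
        "age_band",
        "mother_education",
        "birth_interval",
        "wealth",
        "birth_order",
        "region_id",
    ]
    return SyntheticDataset(
        records=df[cols].copy(),
        truth=truth,
        structured=struct,
        unstructured=unstruct,
        graph=graph,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# printed contingency fixtures
# ---------------------------------------------------------------------------

def table1_fixture():
    """The study's printed 2x2 anaemia-by-malnutrition table (counts).

    Rows: (anaemic, not anaemic); columns: (malnourished, nourished); grand
    total 11557. Note a documented inconsistency in the source: the prose
    states an anaemia prevalence of 68% while the "Anaemic" row totals 32.1%
    (68% is the "Not anaemic" row share). The counts are stored verbatim.
    """
    counts = np.array([[2916, 793], [6677, 1171]], dtype=int)
    row_labels = ("anaemic", "not anaemic")
    col_labels = ("malnourished", "nourished")
    return counts, row_labels, col_labels


# Rural/urban counts among children with both conditions, from the printed
# outcome-by-covariate table.
TABLE2_RESIDENCE_BOTH = {"rural": 2514, "urban": 402}


def table1_summary() -> dict:
    """Descriptive analysis of the packaged 2x2 table: cell and marginal
    percentages plus the Kendall tau-b association test."""
    counts, rows, cols = table1_fixture()
    n = counts.sum()
    test = copulas.empirical_kendall_tau_2x2(counts)
    pct = 100.0 * counts / n
    return {
        "counts": counts,
        "n": int(n),
        "cell_pct": pct,
        "row_pct": 100.0 * counts.sum(axis=1) / n,
        "col_pct": 100.0 * counts.sum(axis=0) / n,
        "tau_b": test.tau_b,
        "z": test.z,
        "p_value": test.p_value,
        "row_labels": rows,
        "col_labels": cols,
    }
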