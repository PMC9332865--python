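"""Outcome classification, covariate coding, spline and spatial design matrices.

The joint model's linear predictor for each margin is assembled from four
blocks:

* fixed effects — treatment-coded categorical factors (intercept included),
* a penalized cubic B-spline in the child's age in months (P-spline with a
  second-order difference penalty, centered to be orthogonal to the intercept),
* a structured spatial effect — one coefficient per region with an intrinsic
  autoregressive (graph-Laplacian) penalty over the region adjacency graph,
* an unstructured spatial effect — one coefficient per region with a ridge
  (identity) penalty, capturing non-spatial regional heterogeneity.

Outcome indicators follow the anthropometric/haematological thresholds used
in the study population: a child is malnourished when the weight-for-age
z-score (WAZ) is below -3.0 and anaemic when haemoglobin is below 9.9 g/dL;
values exactly at a threshold are classified healthy.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, linalg

__all__ = [
    "FACTOR_LEVELS",
    "SEVEN_FACTORS",
    "ANAEMIA_HB_THRESHOLD",
    "MALNUTRITION_WAZ_THRESHOLD",
    "classify_outcomes",
    "age_band_from_months",
    "encode_covariates",
    "build_spline_basis",
    "SplineBasis",
    "build_spatial_design",
    "SpatialDesign",
    "RegionGraph",
    "read_adjacency",
    "grid_graph",
    "ModelSpec",
    "DesignBuilder",
]

ANAEMIA_HB_THRESHOLD = 9.9  # g/dL
MALNUTRITION_WAZ_THRESHOLD = -3.0  # weight-for-age z-score

# Category level sets; the first level of each factor is the reference.
FACTOR_LEVELS: dict[str, tuple[str, ...]] = {
    "residence": ("urban", "rural"),
    "age_band": ("<12", "12-23", "24-35", "36-47", "48-59"),
    "sex": ("male", "female"),
    "mother_education": ("higher", "primary", "secondary"),
    "birth_interval": ("<24", "24-47", ">47"),
    "wealth": ("poor", "middle", "not poor"),
    "birth_order": ("2-3", "4-5", ">5"),
}

SEVEN_FACTORS: tuple[str, ...] = (
    "residence",
    "age_band",
    "sex",
    "mother_education",
    "birth_interval",
    "wealth",
    "birth_order",
)


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def classify_outcomes(haemoglobin, waz):
    """Binary (anaemia, malnourished) indicators from raw measurements.

    Missing (NaN) measurements yield NaN indicators; downstream analysis is
    complete-case. Values exactly at a threshold are on the healthy side.
    """
    hb = np.asarray(haemoglobin, dtype=float)
    wz = np.asarray(waz, dtype=float)
    anaemia = np.where(np.isnan(hb), np.nan, (hb < ANAEMIA_HB_THRESHOLD).astype(float))
    maln = np.where(np.isnan(wz), np.nan, (wz < MALNUTRITION_WAZ_THRESHOLD).astype(float))
    if np.ndim(anaemia) == 0:
        return float(anaemia), float(maln)
    return anaemia, maln


def age_band_from_months(age_months):
    """Map age in months (0-59) onto the five age bands."""
    age = np.asarray(age_months)
    if np.any((age < 0) | (age > 59)):
        raise ValueError("age_months must lie in [0, 59]")
    bins = [-1, 11, 23, 35, 47, 59]
    labels = FACTOR_LEVELS["age_band"]
    idx = np.digitize(age, bins[1:], right=True)
    out = np.asarray(labels)[idx]
    return out if out.ndim else str(out)


# ---------------------------------------------------------------------------
# fixed effects
# ---------------------------------------------------------------------------

def encode_covariates(records: pd.DataFrame, factors: Sequence[str]):
    """Treatment-coded design matrix (with intercept) for the given factors.

    Returns ``(X, names)``; ``names[0]`` is ``"intercept"`` and the remaining
    columns are ``"factor[level]"`` for each non-reference level, in the
    declared level order.
    """
    n = len(records)
    cols = [np.ones(n)]
    names = ["intercept"]
    for fac in factors:
        levels = FACTOR_LEVELS.get(fac)
        if levels is None:
            raise ValueError(f"unknown factor {fac!r}")
        if fac not in records.columns:
            raise ValueError(f"records lack required column {fac!r}")
        vals = records[fac].astype(str)
        bad = ~vals.isin(levels)
        if bad.any():
            rows = list(records.index[bad][:10])
            raise ValueError(
                f"factor {fac!r} has unknown levels {sorted(vals[bad].unique())} "
                f"in rows {rows}"
            )
        for lev in levels[1:]:
            cols.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{fac}[{lev}]")
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# age smooth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplineBasis:
    """Cubic B-spline basis for the age smooth and its difference penalty.

    ``basis`` rows form a partition of unity; ``penalty`` is the
    ``D_order' D_order`` difference penalty of rank ``k - order``. The
    centering ``transform`` Z (k x (k-1)) removes the component confounded
    with the intercept: the centered basis is ``basis @ transform`` with
    penalty ``transform' penalty transform``.
    """

    knots: np.ndarray
    degree: int
    basis: np.ndarray
    penalty: np.ndarray
    constraint: np.ndarray  # 1 x k column means on the training ages
    transform: np.ndarray  # k x (k-1) null-space basis of the constraint

    @property
    def k(self) -> int:
        return self.basis.shape[1]

    def evaluate(self, ages) -> np.ndarray:
        """Raw (uncentered) basis at new ages."""
        x = np.asarray(ages, dtype=float)
        if np.any((x < self.knots[0]) | (x > self.knots[-1])):
            raise ValueError("ages outside the spline's training range")
        return interpolate.BSpline.design_matrix(
            x, self.knots, self.degree, extrapolate=False
        ).toarray()

    def centered(self, ages=None) -> np.ndarray:
        b = self.basis if ages is None else self.evaluate(ages)
        return b @ self.transform

    @property
    def centered_penalty(self) -> np.ndarray:
        return self.transform.T @ self.penalty @ self.transform


def build_spline_basis(
    age_months, k: int = 10, degree: int = 3, penalty_order: int = 2
) -> SplineBasis:
    """P-spline basis for ages on [0, 59]: equally spaced clamped knots,
    ``k`` basis functions, difference penalty of the given order."""
    x = np.asarray(age_months, dtype=float)
    if np.any((x < 0) | (x > 59)):
        raise ValueError("age_months must lie in [0, 59]")
    if len(np.unique(x)) < k:
        raise ValueError(
            f"only {len(np.unique(x))} distinct ages for a basis of dimension {k}; "
            "use a smaller basis (lower k)"
        )
    lo, hi = 0.0, 59.0
    inner = np.linspace(lo, hi, k - degree + 1)
    knots = np.concatenate([[lo] * degree, inner, [hi] * degree])
    basis = interpolate.BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    d = np.diff(np.eye(k), n=penalty_order, axis=0)
    penalty = d.T @ d
    constraint = basis.mean(axis=0, keepdims=True)
    transform = linalg.null_space(constraint)
    return SplineBasis(
        knots=knots,
        degree=degree,
        basis=basis,
        penalty=penalty,
        constraint=constraint,
        transform=transform,
    )


# ---------------------------------------------------------------------------
# region graph & spatial design
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegionGraph:
    """Symmetric region adjacency with an ordered id list."""

    region_ids: list
    neighbors: dict

    def __post_init__(self):
        ids = set(self.region_ids)
        if len(ids) != len(self.region_ids):
            raise ValueError("duplicate region ids")
        for rid, nbrs in self.neighbors.items():
            if rid not in ids:
                raise ValueError(f"neighbor list references unknown region {rid!r}")
            if rid in nbrs:
                raise ValueError(f"self-loop at region {rid!r}")
            for nb in nbrs:
                if nb not in ids:
                    raise ValueError(f"unknown neighbor {nb!r} of region {rid!r}")
                if rid not in self.neighbors.get(nb, set()):
                    raise ValueError("adjacency is not symmetric")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        for rid, nbrs in self.neighbors.items():
            g.add_edges_from((rid, nb) for nb in nbrs)
        return g

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.to_networkx())

    def components(self) -> list[list]:
        order = {r: i for i, r in enumerate(self.region_ids)}
        comps = nx.connected_components(self.to_networkx())
        return [sorted(c, key=order.get) for c in sorted(comps, key=lambda c: min(order[r] for r in c))]

    def adjacency_matrix(self) -> np.ndarray:
        idx = {r: i for i, r in enumerate(self.region_ids)}
        a = np.zeros((self.n_regions, self.n_regions))
        for rid, nbrs in self.neighbors.items():
            for nb in nbrs:
                a[idx[rid], idx[nb]] = 1.0
        return a

    def laplacian(self) -> np.ndarray:
        a = self.adjacency_matrix()
        return np.diag(a.sum(axis=1)) - a


def read_adjacency(path) -> RegionGraph:
    """Read a GAL-style neighbor-list file.

    Format: a header line whose last-but-one or only numeric token is the
    region count, then alternating ``id n_neighbors`` / neighbor-id lines.
    Asymmetric listings are symmetrized with a warning; duplicates are
    dropped.
    """
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh]
    lines = [(i + 1, ln) for i, ln in enumerate(lines) if ln and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty GAL file")
    lineno, header = lines[0]
    toks = header.split()
    try:
        n_declared = int(toks[1]) if len(toks) > 1 and toks[0] == "0" else int(toks[0])
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed GAL header {header!r}") from None
    region_ids: list = []
    raw: dict = {}
    i = 1
    while i < len(lines):
        lineno, ln = lines[i]
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id n_neighbors', got {ln!r}")
        rid = parts[0]
        try:
            deg = int(parts[1])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: bad neighbor count in {ln!r}") from None
        nbrs: list = []
        if deg > 0:
            i += 1
            if i >= len(lines):
                raise ValueError(f"{path}:{lineno}: missing neighbor line for {rid!r}")
            nlineno, nline = lines[i]
            nbrs = nline.split()
            if len(nbrs) != deg:
                raise ValueError(
                    f"{path}:{nlineno}: region {rid!r} declares {deg} neighbors "
                    f"but lists {len(nbrs)}"
                )
        if rid not in raw:
            region_ids.append(rid)
        raw.setdefault(rid, set()).update(nbrs)
        i += 1
    if n_declared != len(region_ids):
        warnings.warn(
            f"{path}: header declares {n_declared} regions, file lists {len(region_ids)}"
        )
    # register neighbors that never get their own entry
    for rid in list(raw):
        for nb in raw[rid]:
            if nb not in raw:
                region_ids.append(nb)
                raw[nb] = set()
    asym = any(rid not in raw.get(nb, set()) for rid in raw for nb in raw[rid])
    if asym:
        warnings.warn(f"{path}: asymmetric adjacency symmetrized")
        for rid in list(raw):
            for nb in raw[rid]:
                raw[nb].add(rid)
    for rid in raw:
        raw[rid].discard(rid)
    return RegionGraph(region_ids=region_ids, neighbors={r: set(raw[r]) for r in raw})


def grid_graph(rows: int, cols: int) -> RegionGraph:
    """Rook-adjacency lattice of regions labelled ``R<row><col>``."""
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be positive")
    ids = [f"R{i}{j}" for i in range(rows) for j in range(cols)]
    nbrs = {rid: set() for rid in ids}
    for i in range(rows):
        for j in range(cols):
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if 0 <= ii < rows and 0 <= jj < cols:
                    nbrs[f"R{i}{j}"].add(f"R{ii}{jj}")
    return RegionGraph(region_ids=ids, neighbors=nbrs)


@dataclasses.dataclass
class SpatialDesign:
    """Region incidence matrices and penalties for the spatial blocks.

    ``transform`` absorbs the per-component sum-to-zero constraint of the
    intrinsic autoregressive prior: the constrained structured design is
    ``Z_struct @ transform`` with penalty ``transform' K_struct transform``
    (full rank when every component has more than one region).
    """

    region_ids: list
    Z_struct: np.ndarray
    K_struct: np.ndarray
    Z_unstruct: np.ndarray
    transform: np.ndarray
    structured_enabled: bool


def build_spatial_design(records: pd.DataFrame, graph: RegionGraph) -> SpatialDesign:
    ids = graph.region_ids
    idx = {r: i for i, r in enumerate(ids)}
    missing = sorted(set(records["region_id"].astype(str)) - set(map(str, ids)))
    if missing:
        raise ValueError(f"records reference regions absent from the graph: {missing}")
    n = len(records)
    z = np.zeros((n, len(ids)))
    rows = records["region_id"].astype(str).map({str(r): idx[r] for r in ids}).to_numpy()
    z[np.arange(n), rows] = 1.0
    k = graph.laplacian()
    comps = graph.components()
    singletons = [c[0] for c in comps if len(c) == 1]
    structured = True
    if len(ids) == 1 or len(singletons) == len(ids):
        warnings.warn("structured spatial effect disabled: no adjacency structure")
        structured = False
    elif singletons:
        warnings.warn(
            f"regions {singletons} are disconnected singletons; they contribute "
            "only to the unstructured effect"
        )
    # per-component sum-to-zero constraint matrix
    cons = np.zeros((len(comps), len(ids)))
    for ci, comp in enumerate(comps):
        for r in comp:
            cons[ci, idx[r]] = 1.0
    transform = linalg.null_space(cons) if structured else np.zeros((len(ids), 0))
    return SpatialDesign(
        region_ids=list(ids),
        Z_struct=z,
        K_struct=k,
        Z_unstruct=z.copy(),
        transform=transform,
        structured_enabled=structured,
    )


# ---------------------------------------------------------------------------
# model specification & design assembly
# ---------------------------------------------------------------------------

_DEFAULT_FIXED = SEVEN_FACTORS
_DEFAULT_GEO = tuple(f for f in SEVEN_FACTORS if f != "age_band")


@dataclasses.dataclass
class ModelSpec:
    """What enters each margin's linear predictor, plus copula family and links.

    Age may enter either as the categorical age bands (a fixed-effect factor)
    or as the continuous penalized smooth — never both in one margin, for
    identifiability.
    """

    factors1: tuple = _DEFAULT_GEO
    factors2: tuple = _DEFAULT_GEO
    smooth_age: bool = True
    spatial_structured: bool = True
    spatial_unstructured: bool = True
    family: str = "gumbel"
    links: tuple = ("logit", "probit")
    spline_k: int = 10
    spline_degree: int = 3
    penalty_order: int = 2

    def __post_init__(self):
        self.factors1 = tuple(self.factors1)
        self.factors2 = tuple(self.factors2)
        self.links = tuple(self.links)
        if not self.factors1 or not self.factors2:
            raise ValueError("factor lists must be non-empty")
        for fac in (*self.factors1, *self.factors2):
            if fac not in FACTOR_LEVELS:
                raise ValueError(f"unknown factor {fac!r}")
        if self.smooth_age and (
            "age_band" in self.factors1 or "age_band" in self.factors2
        ):
            raise ValueError(
                "age cannot enter both as age_band fixed effect and as the smooth"
            )
        if len(self.links) != 2:
            raise ValueError("links must be a pair, one per margin")

    @classmethod
    def fixed_effects_only(cls, family="gumbel", links=("logit", "probit")) -> "ModelSpec":
        """The seven-factor fixed-effects model (31 free parameters with a
        one-parameter copula); used for copula and link selection."""
        return cls(
            factors1=_DEFAULT_FIXED,
            factors2=_DEFAULT_FIXED,
            smooth_age=False,
            spatial_structured=False,
            spatial_unstructured=False,
            family=family,
            links=links,
        )

    @classmethod
    def geoadditive(cls, family="gumbel", links=("logit", "probit"), **kw) -> "ModelSpec":
        """Six fixed factors + age smooth + structured/unstructured spatial."""
        return cls(family=family, links=links, **kw)

    def to_dict(self) -> dict:
        return {
            "factors1": list(self.factors1),
            "factors2": list(self.factors2),
            "smooth_age": self.smooth_age,
            "spatial_structured": self.spatial_structured,
            "spatial_unstructured": self.spatial_unstructured,
            "family": self.family,
            "links": list(self.links),
            "spline_k": self.spline_k,
            "spline_degree": self.spline_degree,
            "penalty_order": self.penalty_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclasses.dataclass
class Block:
    """A contiguous coefficient block within one margin's design."""

    name: str  # fixed | smooth_age | structured | unstructured
    sl: slice
    penalty: np.ndarray | None  # None for unpenalized blocks
    names: list


@dataclasses.dataclass
class MarginDesign:
    M: np.ndarray  # n x p assembled design for the margin
    blocks: list

    @property
    def p(self) -> int:
        return self.M.shape[1]

    @property
    def coef_names(self) -> list:
        out = []
        for b in self.blocks:
            out.extend(b.names)
        return out


class DesignBuilder:
    """Fits design metadata on training records, then builds matrices for any
    schema-compatible records (training or new)."""

    def __init__(self, spec: ModelSpec, graph: RegionGraph | None = None):
        self.spec = spec
        self.graph = graph
        self.spline: SplineBasis | None = None
        self.spatial: SpatialDesign | None = None
        self._fitted = False

    def fit(self, records: pd.DataFrame) -> "DesignBuilder":
        records = prepare_records(records)
        if self.spec.smooth_age:
            self.spline = build_spline_basis(
                records["age_months"],
                k=self.spec.spline_k,
                degree=self.spec.spline_degree,
                penalty_order=self.spec.penalty_order,
            )
        if self.spec.spatial_structured or self.spec.spatial_unstructured:
            if self.graph is None:
                raise ValueError("spatial terms requested but no region graph given")
            self.spatial = build_spatial_design(records, self.graph)
        self._fitted = True
        return self

    def _region_incidence(self, records: pd.DataFrame, allow_unseen: bool) -> np.ndarray:
        ids = self.spatial.region_ids
        idx = {str(r): i for i, r in enumerate(ids)}
        regs = records["region_id"].astype(str)
        unseen = sorted(set(regs) - set(idx))
        if unseen:
            raise ValueError(f"unseen regions in prediction data: {unseen}")
        z = np.zeros((len(records), len(ids)))
        z[np.arange(len(records)), regs.map(idx).to_numpy()] = 1.0
        return z

    def matrices(self, records: pd.DataFrame, allow_unseen_region: bool = False):
        if not self._fitted:
            raise RuntimeError("DesignBuilder.fit must be called first")
        records = prepare_records(records)
        out = []
        for m, factors in enumerate((self.spec.factors1, self.spec.factors2)):
            x, names = encode_covariates(records, factors)
            cols = [x]
            blocks = [Block("fixed", slice(0, x.shape[1]), None, names)]
            pos = x.shape[1]
            if self.spec.smooth_age:
                b = self.spline.centered(records["age_months"].to_numpy())
                cols.append(b)
                blocks.append(
                    Block(
                        "smooth_age",
                        slice(pos, pos + b.shape[1]),
                        self.spline.centered_penalty,
                        [f"s(age).{j}" for j in range(b.shape[1])],
                    )
                )
                pos += b.shape[1]
            if self.spec.spatial_structured and self.spatial.structured_enabled:
                z = self._region_incidence(records, allow_unseen_region)
                zs = z @ self.spatial.transform
                ks = self.spatial.transform.T @ self.spatial.K_struct @ self.spatial.transform
                cols.append(zs)
                blocks.append(
                    Block(
                        "structured",
                        slice(pos, pos + zs.shape[1]),
                        ks,
                        [f"struct.{j}" for j in range(zs.shape[1])],
                    )
                )
                pos += zs.shape[1]
            if self.spec.spatial_unstructured:
                z = self._region_incidence(records, allow_unseen_region)
                cols.append(z)
                blocks.append(
                    Block(
                        "unstructured",
                        slice(pos, pos + z.shape[1]),
                        np.eye(z.shape[1]),
                        [f"unstruct.{r}" for r in self.spatial.region_ids],
                    )
                )
                pos += z.shape[1]
            out.append(MarginDesign(M=np.column_stack(cols), blocks=blocks))
        return out

    # -- serialization (for saved models) -----------------------------------
    def to_dict(self) -> dict:
        d = {"spec": self.spec.to_dict()}
        if self.spline is not None:
            d["spline"] = {
                "knots": self.spline.knots.tolist(),
                "degree": self.spline.degree,
                "penalty": self.spline.penalty.tolist(),
                "constraint": self.spline.constraint.tolist(),
                "transform": self.spline.transform.tolist(),
            }
        if self.spatial is not None:
            d["spatial"] = {
                "region_ids": list(map(str, self.spatial.region_ids)),
                "K_struct": self.spatial.K_struct.tolist(),
                "transform": self.spatial.transform.tolist(),
                "structured_enabled": self.spatial.structured_enabled,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignBuilder":
        builder = cls(ModelSpec.from_dict(d["spec"]))
        if "spline" in d:
            sp = d["spline"]
            builder.spline = SplineBasis(
                knots=np.asarray(sp["knots"]),
                degree=sp["degree"],
                basis=np.zeros((0, len(sp["penalty"]))),
                penalty=np.asarray(sp["penalty"]),
                constraint=np.asarray(sp["constraint"]),
                transform=np.asarray(sp["transform"]),
            )
        if "spatial" in d:
            sp = d["spatial"]
            ids = sp["region_ids"]
            builder.spatial = SpatialDesign(
                region_ids=ids,
                Z_struct=np.zeros((0, len(ids))),
                K_struct=np.asarray(sp["K_struct"]),
                Z_unstruct=np.zeros((0, len(ids))),
                transform=np.asarray(sp["transform"]),
                structured_enabled=sp["structured_enabled"],
            )
        builder._fitted = True
        return builder


def prepare_records(records: pd.DataFrame) -> pd.DataFrame:
    """Normalize a raw observation table: derive indicators from raw
    measurements when needed, derive age_band, and drop incomplete rows."""
    df = records.copy()
    if "anaemia" not in df.columns or "malnourished" not in df.columns:
        if "haemoglobin" not in df.columns or "waz" not in df.columns:
            raise ValueError(
                "records need either (anaemia, malnourished) indicators or "
                "(haemoglobin, waz) raw measurements"
            )
        an, ma = classify_outcomes(df["haemoglobin"], df["waz"])
        df["anaemia"] = an
        df["malnourished"] = ma
    if "age_band" not in df.columns and "age_months" in df.columns:
        df["age_band"] = age_band_from_months(df["age_months"])
    needed = [c for c in ("anaemia", "malnourished") if c in df.columns]
    before = len(df)
    df = df.dropna(subset=needed)
    if len(df) < before:
        warnings.warn(f"dropped {before - len(df)} incomplete rows (complete-case)")
    return df
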