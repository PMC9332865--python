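"""Joint outcome-probability prediction and per-region export.

From a fitted model, each child's four joint-cell probabilities
(p11 = both conditions, p10 = anaemic only, p01 = malnourished only,
p00 = neither) are computed from the full linear predictors (fixed + smooth +
spatial) and the fitted copula, then averaged within region (unweighted) to
give the region tables behind joint-probability maps. Exports are plain CSV
and, when region polygons are supplied, a GeoJSON FeatureCollection with the
four probabilities joined on ``region_id``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd

from .design import prepare_records
from .fitting import FitResult, cell_probabilities

__all__ = ["JointProbSurface", "predict_joint", "region_average", "export_region_table"]

_CELLS = ("p11", "p10", "p01", "p00")


@dataclasses.dataclass
class JointProbSurface:
    """Per-observation joint-cell probabilities keyed by region."""

    observations: pd.DataFrame  # region_id, p1, p2, p11, p10, p01, p00

    def __post_init__(self):
        q = self.observations[list(_CELLS)].to_numpy()
        if np.any(q < -1e-12) or np.any(q > 1 + 1e-12):
            raise ValueError("cell probabilities outside [0, 1]")
        if np.max(np.abs(q.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("cell probabilities must sum to 1 per observation")


def predict_joint(fit: FitResult, newdata: pd.DataFrame) -> JointProbSurface:
    """Predict the four joint-cell probabilities for each record.

    ``newdata`` must use the training schema; regions must be known to the
    fit when spatial terms are in the model.
    """
    df = prepare_records(newdata)
    margins = fit.builder.matrices(df)
    beta1 = fit.params[: margins[0].p]
    beta2 = fit.params[margins[0].p : margins[0].p + margins[1].p]
    from . import links as links_mod

    p1 = np.asarray(links_mod.inverse_link(fit.spec.links[0], margins[0].M @ beta1))
    p2 = np.asarray(links_mod.inverse_link(fit.spec.links[1], margins[1].M @ beta2))
    p11, p10, p01, p00 = cell_probabilities(
        p1, p2, fit.spec.family, fit.theta_hat.theta
    )
    obs = pd.DataFrame(
        {
            "region_id": df["region_id"].astype(str).to_numpy(),
            "p1": p1,
            "p2": p2,
            "p11": p11,
            "p10": p10,
            "p01": p01,
            "p00": p00,
        }
    )
    return JointProbSurface(observations=obs)


def region_average(surface: JointProbSurface) -> pd.DataFrame:
    """Unweighted within-region means of the four cell probabilities.

    Returns columns (region_id, p11, p10, p01, p00, n); the four means sum
    to 1 per region.
    """
    if surface.observations.empty:
        raise ValueError("empty surface")
    g = surface.observations.groupby("region_id", sort=True)
    out = g[list(_CELLS)].mean()
    out["n"] = g.size()
    return out.reset_index()


def export_region_table(
    table: pd.DataFrame,
    csv_path,
    geojson_path=None,
    polygons_path=None,
) -> list:
    """Write the region table as CSV and, given polygons, as GeoJSON.

    Polygons come as a GeoJSON FeatureCollection whose features carry a
    ``region_id`` property; the probability columns are left-joined onto the
    features, and unmatched regions (either direction) are reported with a
    warning. Duplicate region ids in the polygons are an error.
    """
    cols = ["region_id", *list(_CELLS), "n"]
    table = table[cols]
    table.to_csv(csv_path, index=False, float_format="%.6g")
    written = [str(csv_path)]
    if polygons_path is None:
        return written
    if geojson_path is None:
        raise ValueError("geojson_path required when polygons are supplied")
    with open(polygons_path, "r", encoding="utf-8") as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    ids = [str(f.get("properties", {}).get("region_id")) for f in feats]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate region_id in polygons: {sorted(dupes)}")
    lookup = {str(r["region_id"]): r for r in table.to_dict("records")}
    matched = set()
    for feat, rid in zip(feats, ids):
        row = lookup.get(rid)
        if row is None:
            continue
        matched.add(rid)
        props = feat.setdefault("properties", {})
        for c in (*_CELLS, "n"):
            props[c] = row[c]
    missing_in_polys = sorted(set(lookup) - matched)
    if missing_in_polys:
        warnings.warn(f"regions without polygons: {missing_in_polys}")
    extra_polys = sorted(set(ids) - set(lookup))
    if extra_polys:
        warnings.warn(f"polygons without probability rows: {extra_polys}")
    with open(geojson_path, "w", encoding="utf-8") as fh:
        json.dump(gj, fh)
    written.append(str(geojson_path))
    return written
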