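"""Distance-to-tumour spatial statistics for classified CAFs.

For every classified CAF the Euclidean distance (um) to the nearest
tumour-region boundary is computed (0 for points inside or on a
region), and the per-subset distance distributions are summarised and
compared pairwise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely
from statsmodels.stats.multitest import multipletests

from .flow import compare_groups

__all__ = [
    "distance_to_nearest_tumour",
    "distance_records",
    "subset_distance_comparison",
]

log = logging.getLogger(__name__)


def distance_to_nearest_tumour(points, regions) -> np.ndarray:
    """Distance (um) from each point to the nearest tumour region.

    ``points`` is an (n, 2) array of x/y coordinates; ``regions`` a
    non-empty list of simple polygons in the same frame.  The distance
    is to the region interior, so points inside or on a region score 0.
    """
    if regions is None or len(regions) == 0:
        raise ValueError("need at least one tumour region")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    geoms = shapely.points(pts[:, 0], pts[:, 1])
    union = shapely.union_all(list(regions))
    return shapely.distance(geoms, union)


def distance_records(core, labels: pd.Series | None = None) -> pd.DataFrame:
    """Per-CAF distance records for one tissue core.

    ``core`` is a :class:`~cafsubsets.simulate.TissueCore`-like object
    (``cells`` DataFrame with x/y, ``regions`` polygons); ``labels`` maps
    cell index to subset (default: a ``subset`` column on the cells).
    Tumour-compartment cells are not CAFs and are dropped.
    """
    cells = core.cells
    if labels is None:
        if "subset" not in cells.columns:
            raise ValueError("no labels given and no 'subset' column present")
        labels = cells["subset"]
    stroma = cells[cells["compartment"] == "stroma"]
    d = distance_to_nearest_tumour(stroma[["x", "y"]].to_numpy(), core.regions)
    return pd.DataFrame({
        "cell_id": stroma["cell_id"].to_numpy(),
        "subset": labels.loc[stroma.index].to_numpy(),
        "distance": d,
    })


def subset_distance_comparison(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise and compare distance distributions across subsets.

    Returns ``(summary, pairwise)``: per-subset n/median/mean/SD, and
    pairwise Welch t-tests with Benjamini-Hochberg correction across
    the subset pairs.  Subsets with no cells are omitted with a warning;
    at least two populated subsets are required.
    """
    groups = {
        s: g["distance"].to_numpy()
        for s, g in records.groupby("subset")
    }
    empty = [s for s, v in groups.items() if v.size == 0]
    for s in empty:
        log.warning("subset %s has no cells; omitted", s)
        del groups[s]
    if len(groups) < 2:
        raise ValueError("need at least two subsets with cells to compare")

    summary = pd.DataFrame([
        {
            "subset": s,
            "n": v.size,
            "median": float(np.median(v)),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
        }
        for s, v in groups.items()
    ]).set_index("subset")

    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, p = compare_groups(groups[a], groups[b])
            rows.append({"subset_a": a, "subset_b": b, "t": t, "p": p})
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return summary, pairwise
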