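"""Self-organizing-map metaclustering of pooled fibroblast events.

The pooled, gated and downsampled cohort is clustered in two stages, in
the style of cytometry SOM pipelines: (1) a batch-trained SOM summarises
events into a small grid of codebook nodes in z-scaled log-intensity
space; (2) the occupied nodes are metaclustered by Ward hierarchical
clustering, with the cluster count chosen automatically as the k in
[2, k_max] maximising the event-weighted mean silhouette of the nodes —
no user-supplied cluster number.  Metaclusters are then labelled as
CAF-S1..S5 by discretising their per-marker geometric MFIs onto the
ordinal scale and matching against the reference subset profiles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_samples

from .flow import compare_groups, geometric_mfi
from .profiles import PHENO_MARKERS, IntensityModel, LEVEL_RANK, MarkerProfile, SchemaError

__all__ = [
    "SOMResult",
    "MetaclusterResult",
    "SubsetAssignment",
    "train_som",
    "metacluster",
    "assign_subsets",
    "subset_composition",
    "compare_composition",
]

log = logging.getLogger(__name__)


@dataclass
class SOMResult:
    """Trained SOM: codebook in scaled space plus event assignments."""

    codebook: np.ndarray          # (n_nodes, n_markers), z-scaled log space
    node_assignment: np.ndarray   # (n_events,) winning node per event
    grid_shape: tuple[int, int]
    markers: tuple[str, ...]
    scale_mean: np.ndarray        # per-marker mean of log intensities
    scale_sd: np.ndarray          # per-marker sd of log intensities


@dataclass
class MetaclusterResult:
    """Metaclustering of SOM nodes with automatically selected k."""

    k: int
    node_to_cluster: np.ndarray   # (n_nodes,) cluster id, -1 for empty nodes
    event_labels: np.ndarray      # (n_events,) cluster id
    quality_curve: dict[int, float]


@dataclass
class SubsetAssignment:
    """Ordinal-profile labelling of metaclusters."""

    cluster_to_subset: dict[int, str]
    cluster_mfi: pd.DataFrame        # clusters x markers, geometric MFI
    normalised: pd.DataFrame         # min-max normalised within each marker
    cluster_levels: pd.DataFrame     # clusters x markers, ordinal level names


def _scaled_log(events: pd.DataFrame, markers, mean=None, sd=None):
    X = np.log(events.loc[:, list(markers)].to_numpy(dtype=float))
    if mean is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def train_som(
    pooled: pd.DataFrame,
    markers: tuple[str, ...] = PHENO_MARKERS,
    grid_shape: tuple[int, int] = (10, 10),
    epochs: int = 20,
    seed: int = 0,
) -> SOMResult:
    """Batch-train a SOM on z-scaled log intensities.

    Codebook vectors are initialised from a random subset of events and
    refined with a Gaussian neighbourhood whose radius shrinks linearly
    from half the grid diagonal to 0.5 over ``epochs`` rounds.  Events
    are finally assigned to their nearest codebook node.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    missing = [m for m in markers if m not in pooled.columns]
    if missing:
        raise SchemaError(f"pooled table missing markers: {missing}")
    rows, cols = grid_shape
    n_nodes = rows * cols
    n_events = len(pooled)
    if n_events < n_nodes:
        raise ValueError(
            f"{n_events} events < {n_nodes} grid nodes; shrink the grid")

    X, mean, sd = _scaled_log(pooled, markers)
    rng = np.random.default_rng(seed)
    codebook = X[rng.choice(n_events, n_nodes, replace=False)].copy()

    gy, gx = np.divmod(np.arange(n_nodes), cols)
    grid = np.column_stack([gy, gx]).astype(float)
    grid_d2 = cdist(grid, grid, "sqeuclidean")

    sigma0 = max(rows, cols) / 2.0
    for e in range(epochs):
        sigma = sigma0 + (0.5 - sigma0) * e / max(epochs - 1, 1)
        bmu = cdist(X, codebook).argmin(axis=1)
        h = np.exp(-grid_d2 / (2.0 * sigma * sigma))  # (nodes, nodes)
        counts = np.bincount(bmu, minlength=n_nodes).astype(float)
        sums = np.zeros_like(codebook)
        np.add.at(sums, bmu, X)
        num = h @ sums
        den = (h @ counts)[:, None]
        upd = den[:, 0] > 1e-12
        codebook[upd] = num[upd] / den[upd]

    bmu = cdist(X, codebook).argmin(axis=1)
    return SOMResult(codebook, bmu, grid_shape, tuple(markers), mean, sd)


def metacluster(som: SOMResult, k_max: int = 15) -> MetaclusterResult:
    """Ward-metacluster occupied SOM nodes; choose k by silhouette.

    For each k in [2, k_max] the occupied codebook nodes are cut into k
    Ward clusters and scored by the mean node silhouette weighted by the
    number of events each node won; the maximising k wins (ties to the
    smaller k).  A degenerate codebook (all occupied nodes identical)
    yields k = 1 with a warning.
    """
    n_nodes = som.codebook.shape[0]
    if k_max < 2 or k_max > n_nodes:
        raise ValueError("need 2 <= k_max <= node count")
    counts = np.bincount(som.node_assignment, minlength=n_nodes)
    occupied = np.flatnonzero(counts > 0)
    nodes = som.codebook[occupied]
    weights = counts[occupied].astype(float)

    if len(occupied) < 2 or np.allclose(nodes, nodes[0]):
        warnings.warn("degenerate codebook: all occupied nodes identical; k=1")
        node_to_cluster = np.full(n_nodes, -1)
        node_to_cluster[occupied] = 0
        return MetaclusterResult(
            1, node_to_cluster, node_to_cluster[som.node_assignment], {})

    quality: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in range(2, min(k_max, len(occupied) - 1) + 1):
        lab = AgglomerativeClustering(n_clusters=k, linkage="ward").fit_predict(nodes)
        sil = silhouette_samples(nodes, lab)
        quality[k] = float(np.average(sil, weights=weights))
        labels_by_k[k] = lab
    best_k = max(quality, key=lambda k: (quality[k], -k))
    lab = labels_by_k[best_k]

    node_to_cluster = np.full(n_nodes, -1)
    node_to_cluster[occupied] = lab
    # empty nodes inherit the cluster of the nearest occupied node
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        nearest = cdist(som.codebook[empty], nodes).argmin(axis=1)
        node_to_cluster[empty] = lab[nearest]
    return MetaclusterResult(
        best_k, node_to_cluster, node_to_cluster[som.node_assignment], quality)


def assign_subsets(
    meta: MetaclusterResult,
    pooled: pd.DataFrame,
    profiles: list[MarkerProfile],
    model: IntensityModel | None = None,
) -> SubsetAssignment:
    """Label metaclusters as CAF subsets by ordinal-profile matching.

    Each cluster's per-marker geometric MFI is discretised to the
    nearest ordinal level of the fluorescence model; the cluster is
    assigned to the reference profile with minimal L1 distance on the
    integer rank scale (Neg=0 .. High=5).  A cluster equidistant from
    two profiles stays ``unassigned``.
    """
    model = model or IntensityModel()
    if len(meta.event_labels) != len(pooled):
        raise SchemaError("metacluster labels and pooled table length differ")
    clusters = sorted(set(meta.event_labels))
    mfi = pd.DataFrame(index=clusters, columns=list(PHENO_MARKERS), dtype=float)
    for c in clusters:
        sub = pooled.loc[np.asarray(meta.event_labels) == c]
        for m in PHENO_MARKERS:
            mfi.loc[c, m] = geometric_mfi(sub[m])

    levels = mfi.map(model.nearest_level)
    rank = levels.map(lambda lv: LEVEL_RANK[lv])

    cluster_to_subset: dict[int, str] = {}
    for c in clusters:
        costs = {
            p.subset_name: int(np.abs(rank.loc[c].to_numpy() - p.ranks()).sum())
            for p in profiles
        }
        best = min(costs.values())
        winners = [s for s, v in costs.items() if v == best]
        cluster_to_subset[c] = winners[0] if len(winners) == 1 else "unassigned"

    span = mfi.max() - mfi.min()
    normalised = (mfi - mfi.min()) / span.where(span > 0, 1.0)
    return SubsetAssignment(cluster_to_subset, mfi, normalised, levels)


def subset_composition(
    labels,
    sample_ids,
    tissue=None,
) -> pd.DataFrame:
    """Per-sample subset composition (percent of assigned events).

    ``labels`` are subset names per event (``unassigned`` allowed and
    reported separately as ``pct_unassigned``).  Returns one row per
    sample with subset percentages summing to 100 over assigned events,
    plus the sample's tissue label when given.
    """
    df = pd.DataFrame({"label": np.asarray(labels), "sample_id": np.asarray(sample_ids)})
    if tissue is not None:
        df["tissue"] = np.asarray(tissue)
    rows = []
    for sid, g in df.groupby("sample_id", sort=True):
        assigned = g[g["label"] != "unassigned"]
        if len(assigned) == 0:
            log.warning("sample %s has no assigned events; excluded", sid)
            continue
        pct = assigned["label"].value_counts(normalize=True) * 100.0
        row = {"sample_id": sid, "pct_unassigned": 100.0 * (1 - len(assigned) / len(g))}
        if tissue is not None:
            row["tissue"] = g["tissue"].iloc[0]
        row.update(pct.to_dict())
        rows.append(row)
    out = pd.DataFrame(rows).fillna(0.0)
    return out


def compare_composition(composition: pd.DataFrame, subsets=None) -> pd.DataFrame:
    """Tumour-vs-NCL Welch comparison of per-sample subset percentages."""
    if "tissue" not in composition.columns:
        raise SchemaError("composition table needs a 'tissue' column")
    subsets = subsets or [c for c in composition.columns
                          if c.startswith("CAF-S")]
    tum = composition[composition["tissue"] == "tumour"]
    ncl = composition[composition["tissue"] == "NCL"]
    rows = []
    for s in subsets:
        t, p = compare_groups(tum.get(s, pd.Series(dtype=float)),
                              ncl.get(s, pd.Series(dtype=float)))
        rows.append({"subset": s, "mean_tumour": float(tum[s].mean()),
                     "mean_ncl": float(ncl[s].mean()), "t": t, "p": p})
    return pd.DataFrame(rows).set_index("subset")
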