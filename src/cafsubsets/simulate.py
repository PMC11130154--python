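"""Synthetic data generators with planted ground truth.

Every downstream stage of the pipeline (gating, SOM metaclustering,
multiplex-IF classification, spatial statistics, differential expression,
survival stratification) consumes tables these generators can produce, so
the whole analysis is testable without patient material.  Each generator
takes an integer seed and is bit-deterministic given identical arguments.

What is emulated, per modality:

* **Flow**: events x markers fluorescence tables.  Fibroblasts are drawn
  from the log-normal of each subset's ordinal level per marker; lineage
  contaminants (EpCAM+/CD45+/CD31+) and dead cells stain bright on their
  respective channel and are removed by the gating stage.
* **Multiplex-IF cores**: stromal cells placed outside tumour-region
  polygons with subset-specific exponential distance kernels, so the
  near-to-far subset ordering is planted; per-marker bimodal (ON/OFF)
  intensities.
* **scRNA**: negative-binomial counts for two marker-filterable groups
  (CAF-S1 = aSMA/ACTA2-expressing, CAF-S5 = ACTA2-silent) with planted
  signed log2 fold-changes on named genes.
* **Survival cohorts**: exponential event times whose hazard is
  multiplied by a planted ratio in the high-covariate group, with
  independent exponential censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon, box

from .profiles import (
    LINEAGE_MARKERS,
    PHENO_MARKERS,
    VIABILITY_MARKER,
    IntensityModel,
    MarkerProfile,
    SchemaError,
    default_profiles,
)

__all__ = [
    "SyntheticTruth",
    "TissueCore",
    "generate_flow_sample",
    "generate_flow_cohort",
    "generate_mif_core",
    "generate_scrna_counts",
    "generate_survival_cohort",
    "DEFAULT_TUMOUR_MIX",
    "DEFAULT_NCL_MIX",
    "DEFAULT_PLANTED_LFC",
    "MIF_MARKERS",
]


class InvalidMixtureError(ValueError):
    """Mixture plus contamination fractions exceed 1."""


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    cell_labels: pd.Series | None = None
    sample_proportions: pd.DataFrame | None = None
    distance_order: list[str] | None = None
    planted_lfc: dict[str, float] = field(default_factory=dict)
    hazard_ratio: float | None = None


@dataclass
class TissueCore:
    """One multiplex-IF tissue core: cell records plus tumour geometry.

    ``cells`` columns: cell_id, core_id, x, y (um), compartment
    ('tumour'/'stroma') and one mean-intensity column per marker.
    """

    core_id: str
    cells: pd.DataFrame
    regions: list[Polygon]


#: Default subset composition of tumour tissue (CAF-S1/S4/S5 enriched).
DEFAULT_TUMOUR_MIX: dict[str, float] = {
    "CAF-S1": 0.26, "CAF-S2": 0.12, "CAF-S3": 0.06,
    "CAF-S4": 0.30, "CAF-S5": 0.26,
}

#: Default composition of non-cancerous lung (CAF-S2/S3 enriched).
DEFAULT_NCL_MIX: dict[str, float] = {
    "CAF-S1": 0.08, "CAF-S2": 0.30, "CAF-S3": 0.40,
    "CAF-S4": 0.12, "CAF-S5": 0.10,
}

_CONTAMINANT_CHANNEL = {
    "EpCAM+": "EpCAM",
    "CD45+": "CD45",
    "CD31+": "CD31",
    "dead": VIABILITY_MARKER,
}


def _flow_columns() -> list[str]:
    return [VIABILITY_MARKER, *LINEAGE_MARKERS, *PHENO_MARKERS]


def generate_flow_sample(
    profiles: list[MarkerProfile] | None = None,
    mixture: dict[str, float] | None = None,
    n_events: int = 1000,
    contamination: dict[str, float] | None = None,
    model: IntensityModel | None = None,
    seed: int = 0,
    sample_id: str = "sample-01",
    tissue: str = "tumour",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate one flow-cytometry event table.

    Parameters
    ----------
    profiles
        Subset profiles to draw from (default: the five published ones).
    mixture
        Subset name -> fraction of events.  Together with
        ``contamination`` the fractions must sum to at most 1; if the sum
        is below 1 the fractions are renormalised.
    n_events
        Total events in the table.
    contamination
        Fractions for the lineage contaminant classes
        ``EpCAM+``, ``CD45+``, ``CD31+`` and ``dead``.
    model
        Fluorescence model (default :class:`IntensityModel`).

    Returns
    -------
    (events, truth)
        ``events`` has ``sample_id``/``tissue`` metadata columns and one
        intensity column per channel; ``truth.cell_labels`` records the
        planted class of every event.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    profiles = profiles if profiles is not None else default_profiles()
    model = model if model is not None else IntensityModel()
    mixture = dict(mixture) if mixture else {}
    contamination = dict(contamination) if contamination else {}

    by_name = {p.subset_name: p for p in profiles}
    for name in mixture:
        if name not in by_name:
            raise SchemaError(f"mixture names unknown subset {name!r}")
    for name in contamination:
        if name not in _CONTAMINANT_CHANNEL:
            raise SchemaError(f"unknown contaminant class {name!r}")

    classes = list(mixture) + list(contamination)
    fracs = np.array([mixture[c] for c in mixture]
                     + [contamination[c] for c in contamination], dtype=float)
    if fracs.size == 0 or np.any(fracs < 0):
        raise InvalidMixtureError("need non-negative fractions for >= 1 class")
    total = fracs.sum()
    if total > 1 + 1e-9:
        raise InvalidMixtureError(f"fractions sum to {total:.4f} > 1")
    fracs = fracs / total

    rng = np.random.default_rng(seed)
    labels = rng.choice(classes, size=n_events, p=fracs)

    cols = _flow_columns()
    data = np.empty((n_events, len(cols)))
    col_idx = {c: i for i, c in enumerate(cols)}
    for cls in classes:
        mask = labels == cls
        k = int(mask.sum())
        if k == 0:
            continue
        if cls in by_name:  # fibroblast subset
            for ch in (VIABILITY_MARKER, *LINEAGE_MARKERS):
                data[mask, col_idx[ch]] = model.sample("Neg", k, rng)
            for m in PHENO_MARKERS:
                data[mask, col_idx[m]] = model.sample(
                    by_name[cls].levels[m], k, rng)
        else:  # contaminant: bright on its channel, negative elsewhere
            bright = _CONTAMINANT_CHANNEL[cls]
            for ch in cols:
                level = "High" if ch == bright else "Neg"
                data[mask, col_idx[ch]] = model.sample(level, k, rng)

    events = pd.DataFrame(data, columns=cols)
    events.insert(0, "sample_id", sample_id)
    events.insert(1, "tissue", tissue)

    props = pd.Series(labels).value_counts(normalize=True)
    truth = SyntheticTruth(
        cell_labels=pd.Series(labels, name="true_label"),
        sample_proportions=props.rename(sample_id).to_frame().T,
    )
    return events, truth


def generate_flow_cohort(
    n_samples: int = 14,
    n_events: int = 800,
    tissue: str = "tumour",
    base_mixture: dict[str, float] | None = None,
    contamination: dict[str, float] | None = None,
    dirichlet_kappa: float = 80.0,
    model: IntensityModel | None = None,
    seed: int = 0,
) -> tuple[list[pd.DataFrame], list[SyntheticTruth]]:
    """Generate a cohort of flow samples with mild inter-sample variation.

    Per-sample subset fractions are drawn from a Dirichlet centred on
    ``base_mixture`` with concentration ``dirichlet_kappa`` (larger =
    less heterogeneity between patients).
    """
    if base_mixture is None:
        base_mixture = DEFAULT_TUMOUR_MIX if tissue == "tumour" else DEFAULT_NCL_MIX
    if contamination is None:
        contamination = {"EpCAM+": 0.05, "CD45+": 0.05, "CD31+": 0.03, "dead": 0.02}
    contam_total = sum(contamination.values())
    subset_total = 1.0 - contam_total
    names = list(base_mixture)
    alpha = np.array([base_mixture[n] for n in names]) * dirichlet_kappa

    rng = np.random.default_rng(seed)
    samples, truths = [], []
    for i in range(n_samples):
        p = rng.dirichlet(alpha)
        mix = {n: float(v) * subset_total for n, v in zip(names, p)}
        ev, tr = generate_flow_sample(
            mixture=mix,
            n_events=n_events,
            contamination=contamination,
            model=model,
            seed=int(rng.integers(2**31)),
            sample_id=f"{tissue}-{i + 1:02d}",
            tissue=tissue,
        )
        samples.append(ev)
        truths.append(tr)
    return samples, truths


# ---------------------------------------------------------------------------
# Multiplex immunofluorescence cores
# ---------------------------------------------------------------------------

#: Markers measured on the multiplex-IF panel.
MIF_MARKERS: tuple[str, ...] = ("PanCK", "FAP", "aSMA", "PDPN", "FSP1", "CD90")

# ON/OFF marker pattern per subset (the CD90-bearing flow-derived
# definitions; the CD90-free ruleset classifies these identically).
_MIF_PATTERNS: dict[str, dict[str, bool]] = {
    "CAF-S1": {"FAP": True, "aSMA": True, "FSP1": False, "CD90": True, "PDPN": True},
    "CAF-S4": {"FAP": False, "aSMA": True, "FSP1": False, "CD90": True, "PDPN": False},
    "CAF-S5": {"FAP": True, "aSMA": False, "FSP1": False, "CD90": False, "PDPN": True},
}

_MIF_PATTERN_MARKERS = ("FAP", "aSMA", "PDPN", "FSP1", "CD90")


def _other_patterns() -> list[dict[str, bool]]:
    """Marker call patterns that no subset rule (either version) accepts.

    'Other' stromal cells draw uniformly from these, so every channel of
    a core carries both stained and unstained populations (a global
    staining threshold is only identifiable on a bimodal channel) while
    never colliding with a subset definition.
    """
    import itertools

    from .mif import classify_subset, methods_ruleset, results_ruleset

    rulesets = (results_ruleset(), methods_ruleset())
    out = []
    for bits in itertools.product([True, False], repeat=len(_MIF_PATTERN_MARKERS)):
        calls = dict(zip(_MIF_PATTERN_MARKERS, bits))
        if all(classify_subset(calls, rs) == "other" for rs in rulesets):
            out.append(calls)
    return out

# Bimodal intensity model for IF channels (natural-log scale).
_MIF_OFF = (math.log(4.0), 0.6)
_MIF_ON = (math.log(400.0), 0.5)

_DEFAULT_MIF_MIX = {"CAF-S4": 0.45, "CAF-S1": 0.30, "CAF-S5": 0.15, "other": 0.10}
_DEFAULT_DISTANCE_ORDER = ["CAF-S4", "CAF-S1", "CAF-S5"]


class NoStromaError(ValueError):
    """Tumour regions cover the whole frame: nowhere to place stroma."""


def _default_regions() -> list[Polygon]:
    # Two tumour nests in a 1000 x 1000 um core.
    return [
        Point(330.0, 350.0).buffer(190.0, quad_segs=32),
        Point(720.0, 680.0).buffer(140.0, quad_segs=32),
    ]


def _mif_intensity(on: bool, size: int, rng: np.random.Generator) -> np.ndarray:
    mu, sd = _MIF_ON if on else _MIF_OFF
    return np.exp(rng.normal(mu, sd, size))


def generate_mif_core(
    region_spec: list[Polygon] | None = None,
    n_cells: int = 2000,
    subset_mix: dict[str, float] | None = None,
    distance_order: list[str] | None = None,
    seed: int = 0,
    core_id: str = "core-01",
    frame: tuple[float, float] = (1000.0, 1000.0),
    n_tumour_cells: int = 400,
    base_scale: float = 35.0,
    scale_ratio: float = 2.4,
) -> tuple[TissueCore, SyntheticTruth]:
    """Generate one segmented multiplex-IF core with planted spatial order.

    Stromal cells are placed outside the tumour regions; a cell of the
    ``i``-th subset in ``distance_order`` is accepted at distance ``d``
    from the nearest tumour boundary with probability
    ``exp(-d / (base_scale * scale_ratio**i))``, so median distance
    increases along the list.  Subsets absent from ``distance_order``
    are placed uniformly over the stroma.

    Returns the :class:`TissueCore` and a truth record with per-cell
    subset labels and the planted ordering.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    regions = region_spec if region_spec is not None else _default_regions()
    if not regions:
        raise ValueError("need at least one tumour region")
    subset_mix = dict(subset_mix) if subset_mix else dict(_DEFAULT_MIF_MIX)
    order = list(distance_order) if distance_order is not None \
        else [s for s in _DEFAULT_DISTANCE_ORDER if s in subset_mix]
    for name in subset_mix:
        if name not in _MIF_PATTERNS and name != "other":
            raise SchemaError(f"unknown subset {name!r} in subset_mix")

    union = shapely.union_all(regions)
    w, h = frame
    stroma_area = box(0, 0, w, h).difference(union)
    if stroma_area.is_empty or stroma_area.area < 1e-9:
        raise NoStromaError("tumour regions cover the entire frame")

    rng = np.random.default_rng(seed)
    names = list(subset_mix)
    fracs = np.array([subset_mix[n] for n in names], dtype=float)
    fracs = fracs / fracs.sum()
    labels = rng.choice(names, size=n_cells, p=fracs)

    scales = {s: base_scale * scale_ratio**i for i, s in enumerate(order)}

    xs = np.empty(n_cells)
    ys = np.empty(n_cells)
    dists = np.empty(n_cells)
    pending = np.arange(n_cells)
    while pending.size:
        m = pending.size
        px = rng.uniform(0, w, 4 * m)
        py = rng.uniform(0, h, 4 * m)
        pts = shapely.points(px, py)
        outside = ~shapely.contains(union, pts)
        d = shapely.distance(pts, union)
        u = rng.uniform(size=4 * m)
        filled = 0
        # consume accepted proposals in order, cell by cell
        accept_scale = np.array([scales.get(labels[i], np.inf) for i in pending])
        for j in range(4 * m):
            if filled >= m:
                break
            sc = accept_scale[filled]
            ok = outside[j] and (not np.isfinite(sc) or u[j] < math.exp(-d[j] / sc))
            if ok:
                i = pending[filled]
                xs[i], ys[i], dists[i] = px[j], py[j], d[j]
                filled += 1
        pending = pending[filled:]

    records = {
        "cell_id": [f"{core_id}-s{i}" for i in range(n_cells)],
        "core_id": core_id,
        "x": xs,
        "y": ys,
        "compartment": "stroma",
    }
    other_pats = _other_patterns()
    pattern_idx = rng.integers(len(other_pats), size=n_cells)
    on_flags = {mk: np.zeros(n_cells, dtype=bool) for mk in MIF_MARKERS}
    for name in names:
        mask = labels == name
        if not mask.any():
            continue
        for mk in MIF_MARKERS:
            if mk == "PanCK":
                continue
            if name == "other":
                on_flags[mk][mask] = np.array(
                    [other_pats[i][mk] for i in pattern_idx[mask]])
            else:
                on_flags[mk][mask] = _MIF_PATTERNS[name][mk]
    for mk in MIF_MARKERS:
        col = _mif_intensity(False, n_cells, rng)
        on = on_flags[mk]
        if on.any():
            col[on] = _mif_intensity(True, int(on.sum()), rng)
        records[mk] = col
    cells = pd.DataFrame(records)

    if n_tumour_cells > 0:
        minx, miny, maxx, maxy = union.bounds
        txs, tys = [], []
        while len(txs) < n_tumour_cells:
            cand_x = rng.uniform(minx, maxx, 4 * n_tumour_cells)
            cand_y = rng.uniform(miny, maxy, 4 * n_tumour_cells)
            inside = shapely.contains(union, shapely.points(cand_x, cand_y))
            txs.extend(cand_x[inside])
            tys.extend(cand_y[inside])
        txs = np.array(txs[:n_tumour_cells])
        tys = np.array(tys[:n_tumour_cells])
        trec = {
            "cell_id": [f"{core_id}-t{i}" for i in range(n_tumour_cells)],
            "core_id": core_id,
            "x": txs,
            "y": tys,
            "compartment": "tumour",
        }
        for mk in MIF_MARKERS:
            trec[mk] = _mif_intensity(mk == "PanCK", n_tumour_cells, rng)
        cells = pd.concat([cells, pd.DataFrame(trec)], ignore_index=True)

    truth = SyntheticTruth(
        cell_labels=pd.Series(
            list(labels) + ["tumour"] * max(n_tumour_cells, 0),
            index=cells["cell_id"], name="true_label"),
        distance_order=order,
    )
    truth.cell_distances = pd.Series(  # type: ignore[attr-defined]
        np.concatenate([dists, np.zeros(max(n_tumour_cells, 0))]),
        index=cells["cell_id"], name="true_distance")
    core = TissueCore(core_id=core_id, cells=cells, regions=list(regions))
    return core, truth


# ---------------------------------------------------------------------------
# scRNA counts
# ---------------------------------------------------------------------------

#: Inclusion/exclusion marker genes used by the CAF-S1/S5 filter.
SCRNA_MARKER_GENES = ("ITGB1", "PDGFRB", "PDPN", "FAP", "S100A4", "ACTA2")

#: Default planted effects (log2 CAF-S5 vs CAF-S1): contractile genes
#: down in CAF-S5, complement/inflammatory genes up.
DEFAULT_PLANTED_LFC: dict[str, float] = {
    "TAGLN": -2.0, "TPM2": -2.0, "SPARC": -2.0, "MYL9": -2.0,
    "C3": 2.0, "SEPP1": 2.0, "C7": 2.0, "CLU": 2.0,
}


def generate_scrna_counts(
    n_cells_per_group: int | tuple[int, int] = 150,
    n_genes: int = 200,
    planted_lfc: dict[str, float] | None = None,
    seed: int = 0,
    nb_dispersion: float = 2.0,
    base_mean_log_mu: float = 1.0,
    base_mean_log_sd: float = 1.0,
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate a CAF-S1 / CAF-S5 single-cell count matrix.

    Counts are negative-binomial with gene-specific base means (drawn
    log-normally) and common dispersion ``nb_dispersion`` (NB size
    parameter; smaller = more overdispersed).  Marker genes are set so
    every cell passes the CAF-S1/S5 inclusion filter: ITGB1, PDGFRB,
    PDPN and FAP are > 0 everywhere, S100A4 (FSP1) is 0 everywhere, and
    ACTA2 (aSMA) is > 0 in CAF-S1 cells and exactly 0 in CAF-S5 cells.
    Genes named in ``planted_lfc`` have their CAF-S5 mean multiplied by
    ``2**lfc``.

    Returns an :class:`anndata.AnnData` (cells x genes, raw counts, true
    group in ``obs['true_subset']``) and the truth record.
    """
    if isinstance(n_cells_per_group, int):
        n1 = n5 = n_cells_per_group
    else:
        n1, n5 = n_cells_per_group
    if n1 < 1 or n5 < 1:
        raise ValueError("both groups must be non-empty")
    planted = dict(DEFAULT_PLANTED_LFC) if planted_lfc is None else dict(planted_lfc)

    # fixed gene universe: marker genes, the named effect genes, fillers
    genes = list(SCRNA_MARKER_GENES) + list(DEFAULT_PLANTED_LFC)
    n_fill = n_genes - len(genes)
    if n_fill < 0:
        raise SchemaError("n_genes smaller than marker + named gene count")
    genes += [f"GENE{i:04d}" for i in range(n_fill)]
    gene_idx = {g: i for i, g in enumerate(genes)}
    for g in planted:
        if g not in gene_idx:
            raise SchemaError(f"planted gene {g!r} not among the {n_genes} genes")
        if g in SCRNA_MARKER_GENES:
            raise SchemaError(f"cannot plant an effect on marker gene {g!r}")

    rng = np.random.default_rng(seed)
    n_cells = n1 + n5
    group = np.array(["CAF-S1"] * n1 + ["CAF-S5"] * n5)

    base = np.exp(rng.normal(base_mean_log_mu, base_mean_log_sd, len(genes)))
    mean = np.tile(base, (n_cells, 1))
    for g, lfc in planted.items():
        mean[n1:, gene_idx[g]] *= 2.0**lfc

    r = nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean)).astype(np.int64)

    # marker-gene structure guaranteeing filter survival
    for g in ("ITGB1", "PDGFRB", "PDPN", "FAP"):
        j = gene_idx[g]
        mu = 4.0
        counts[:, j] = 1 + rng.negative_binomial(r, r / (r + mu), n_cells)
    counts[:, gene_idx["S100A4"]] = 0
    j = gene_idx["ACTA2"]
    counts[:n1, j] = 1 + rng.negative_binomial(r, r / (r + 6.0), n1)
    counts[n1:, j] = 0

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"true_subset": group},
            index=[f"cell{i:05d}" for i in range(n_cells)]),
        var=pd.DataFrame(index=genes),
    )
    truth = SyntheticTruth(
        cell_labels=pd.Series(group, index=adata.obs_names, name="true_subset"),
        planted_lfc=planted,
    )
    return adata, truth


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

def generate_survival_cohort(
    n_patients: int = 163,
    covariate: str = "subset_abundance",
    hazard_ratio: float = 2.0,
    censoring_rate: float = 0.2,
    seed: int = 0,
    baseline_median_days: float = 1200.0,
) -> pd.DataFrame:
    """Generate a survival cohort with a planted group hazard ratio.

    ``covariate='subset_abundance'`` plants the effect on patients whose
    CAF abundance is above its own median (the median-split recovers the
    truth exactly).  ``covariate='bulk_markers'`` draws a latent
    CAF-S5-dominant phenotype (~20% of patients) and generates
    FAP/PDPN/aSMA bulk scores conditioned on it — phenotype patients
    score high on FAP and PDPN and low on aSMA, reflecting the stromal
    composition a bulk sample would average over — and plants the
    hazard effect on the phenotype group.  Event times are exponential;
    censoring is independent exponential with rate tuned to
    ``censoring_rate`` at baseline.

    The returned table is one row per patient with ``time`` (days),
    ``event`` (1 = death), the covariate column(s) and the planted truth
    group in ``true_high`` (or ``true_phenotype``).
    """
    if n_patients < 2:
        raise ValueError("n_patients must be >= 2")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    if not (0 <= censoring_rate < 1):
        raise ValueError("censoring_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    lam0 = math.log(2.0) / baseline_median_days
    table = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n_patients)]})

    if covariate == "subset_abundance":
        abundance = np.exp(rng.normal(2.0, 0.8, n_patients))
        high = abundance > np.median(abundance)
        table["caf_abundance"] = abundance
        table["true_high"] = high.astype(int)
    elif covariate == "bulk_markers":
        high = rng.uniform(size=n_patients) < 0.2
        # bulk scores mirror stromal composition: CAF-S5-dominant
        # patients run high on FAP/PDPN and low on aSMA
        def score(shift_up: bool) -> np.ndarray:
            mu = np.where(high == shift_up, 2.8, 1.8)
            return np.exp(rng.normal(mu, 0.5))
        table["FAP"] = score(True)
        table["PDPN"] = score(True)
        table["aSMA"] = score(False)
        table["true_phenotype"] = np.where(high, "CAF-S5", "other")
    else:
        raise ValueError(f"unknown covariate kind {covariate!r}")

    lam = lam0 * np.where(high, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    if censoring_rate > 0:
        lam_c = lam0 * censoring_rate / (1.0 - censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, n_patients)
    else:
        t_cens = np.full(n_patients, np.inf)
    table["time"] = np.minimum(t_event, t_cens)
    table["event"] = (t_event <= t_cens).astype(int)
    return table
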