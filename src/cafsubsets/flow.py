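"""Flow-cytometry preprocessing: gating, positivity statistics, downsampling.

The flow stage isolates fibroblasts from digested tissue by excluding
dead cells and the epithelial (EpCAM+), haematopoietic (CD45+) and
endothelial (CD31+) lineages, then summarises marker expression as
percent-positive / percent-high and geometric MFI.  Gated samples are
downsampled to a fixed event count and concatenated before clustering;
samples with too few fibroblasts are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import (
    LINEAGE_MARKERS,
    PHENO_MARKERS,
    VIABILITY_MARKER,
    IntensityModel,
    SchemaError,
)

__all__ = [
    "GateConfig",
    "SampleExcludedError",
    "EmptyTableError",
    "gate_fibroblasts",
    "percent_positive",
    "percent_high",
    "geometric_mfi",
    "downsample",
    "concatenate",
    "compare_groups",
    "prepare_cohort",
]

log = logging.getLogger(__name__)

_ALL_MARKERS = (*LINEAGE_MARKERS, *PHENO_MARKERS)


class SampleExcludedError(ValueError):
    """A gated sample has fewer fibroblasts than the inclusion minimum."""


class EmptyTableError(ValueError):
    """A statistic was requested on an empty event table."""


@dataclass
class GateConfig:
    """Numeric gate thresholds and sampling policy.

    ``positivity``/``high`` map each marker to its intensity threshold;
    intensities at or above a threshold count as positive/high (ties are
    positive).  Defaults derive from the fluorescence model: positivity
    at the 99th percentile of the negative level (an isotype-control
    surrogate) and high at the model's high gate.  A sample must contain
    ``min_fibroblasts`` gated events to be analysed, and is downsampled
    to ``downsample_n`` events.
    """

    positivity: dict[str, float] = field(default_factory=dict)
    high: dict[str, float] = field(default_factory=dict)
    viability_threshold: float = 0.0
    downsample_n: int = 300
    min_fibroblasts: int = 300

    def __post_init__(self) -> None:
        if not self.positivity:
            model = IntensityModel()
            self.positivity = {m: model.positivity_threshold for m in _ALL_MARKERS}
            self.high = {m: model.high_threshold for m in _ALL_MARKERS}
            self.viability_threshold = model.positivity_threshold
        for m, thr in self.positivity.items():
            if thr <= 0:
                raise ValueError(f"positivity threshold for {m} must be > 0")
            if m in self.high and self.high[m] < thr:
                raise ValueError(f"high threshold for {m} below positivity")
        if self.viability_threshold <= 0:
            raise ValueError("viability threshold must be > 0")
        if self.downsample_n > self.min_fibroblasts:
            raise ValueError("downsample_n must not exceed min_fibroblasts")


def _require_columns(events: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in events.columns]
    if missing:
        raise SchemaError(f"event table missing columns: {missing}")


def gate_fibroblasts(events: pd.DataFrame, cfg: GateConfig | None = None) -> pd.DataFrame:
    """Gate to viable CD45- EpCAM- CD31- fibroblasts.

    Keeps events whose viability stain is below the viability threshold
    and whose intensity is below the positivity threshold on every
    lineage marker; row order is preserved.
    """
    cfg = cfg or GateConfig()
    _require_columns(events, (VIABILITY_MARKER, *LINEAGE_MARKERS))
    keep = events[VIABILITY_MARKER] < cfg.viability_threshold
    for m in LINEAGE_MARKERS:
        keep &= events[m] < cfg.positivity[m]
    return events.loc[keep]


def percent_positive(events: pd.DataFrame, marker: str, cfg: GateConfig | None = None) -> float:
    """Percent of events at or above the marker's positivity threshold."""
    cfg = cfg or GateConfig()
    if len(events) == 0:
        raise EmptyTableError("percent_positive undefined on an empty table")
    _require_columns(events, (marker,))
    return 100.0 * float((events[marker] >= cfg.positivity[marker]).mean())


def percent_high(events: pd.DataFrame, marker: str, cfg: GateConfig | None = None) -> float:
    """Percent of events at or above the marker's high threshold."""
    cfg = cfg or GateConfig()
    if len(events) == 0:
        raise EmptyTableError("percent_high undefined on an empty table")
    _require_columns(events, (marker,))
    return 100.0 * float((events[marker] >= cfg.high[marker]).mean())


def geometric_mfi(values) -> float:
    """Geometric mean fluorescence intensity, exp(mean(log x))."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise EmptyTableError("geometric MFI undefined on empty input")
    if np.any(arr <= 0):
        raise ValueError("geometric MFI requires strictly positive intensities")
    return float(stats.gmean(arr))


def downsample(events: pd.DataFrame, cfg: GateConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Uniformly downsample a gated sample to ``cfg.downsample_n`` events.

    Raises :class:`SampleExcludedError` when the sample has fewer than
    ``cfg.min_fibroblasts`` events (such samples are excluded from
    analysis). Sampling is without replacement and deterministic given
    the seed.
    """
    cfg = cfg or GateConfig()
    n = len(events)
    if n < cfg.min_fibroblasts:
        raise SampleExcludedError(
            f"sample has {n} fibroblasts < minimum {cfg.min_fibroblasts}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=cfg.downsample_n, replace=False))
    return events.iloc[idx]


def concatenate(samples: list[pd.DataFrame]) -> pd.DataFrame:
    """Row-stack per-sample tables, requiring identical columns."""
    if not samples:
        raise EmptyTableError("nothing to concatenate")
    cols = list(samples[0].columns)
    for i, s in enumerate(samples[1:], start=1):
        if list(s.columns) != cols:
            raise SchemaError(f"sample {i} columns differ from sample 0")
    return pd.concat(samples, ignore_index=True)


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test between two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        return 0.0, 1.0  # degenerate: identical constants
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def prepare_cohort(
    samples: list[pd.DataFrame],
    cfg: GateConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Gate, downsample and concatenate a cohort of flow samples.

    Samples failing the minimum-fibroblast requirement are dropped with
    a logged reason; the survivors are pooled for clustering.
    """
    cfg = cfg or GateConfig()
    rng = np.random.default_rng(seed)
    kept = []
    for s in samples:
        sid = s["sample_id"].iloc[0] if "sample_id" in s and len(s) else "?"
        gated = gate_fibroblasts(s, cfg)
        try:
            kept.append(downsample(gated, cfg, seed=int(rng.integers(2**31))))
        except SampleExcludedError as exc:
            log.warning("excluding sample %s: %s", sid, exc)
    if not kept:
        raise EmptyTableError("no sample passed the fibroblast minimum")
    return concatenate(kept)
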