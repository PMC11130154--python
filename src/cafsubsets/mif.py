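"""Rule-based phenotyping of multiplex-immunofluorescence cell tables.

Each stain gets a single global ON/OFF threshold (one per marker across
the whole tumour collection); cells are then classified by a composite
of these binary single-channel calls.  Two rulesets are shipped: the
flow-derived definitions including CD90, and the default CD90-free
versions used for tissue analysis (CD90 staining is typically too weak
to gate reliably):

* CAF-S1: FAP ON, aSMA ON, FSP1 OFF, PDPN ON
* CAF-S4: FAP OFF, aSMA ON, FSP1 OFF, PDPN OFF
* CAF-S5: FAP ON, aSMA OFF, FSP1 OFF, PDPN ON

Composition is reported as percent of total CAFs, where a CAF is any
stromal cell ON for at least one CAF marker.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .profiles import SchemaError

__all__ = [
    "BinaryRuleset",
    "results_ruleset",
    "methods_ruleset",
    "CAF_MARKERS",
    "otsu_thresholds",
    "call_markers",
    "classify_subset",
    "classify_cells",
    "subset_percentages",
    "percent_positive_stroma",
]

log = logging.getLogger(__name__)

#: CAF markers on the multiplex-IF panel (PanCK marks tumour cells).
CAF_MARKERS: tuple[str, ...] = ("FAP", "aSMA", "PDPN", "FSP1", "CD90")

ON, OFF, IGNORE = "ON", "OFF", "ignore"


@dataclass(frozen=True)
class BinaryRuleset:
    """Composite classifier: per-subset marker ON/OFF requirements.

    Mutual exclusivity is verified at construction by enumerating every
    possible call vector over the non-ignored markers and checking no
    vector satisfies two subsets.
    """

    rules: dict[str, dict[str, str]]
    version: str = "without_CD90"

    def __post_init__(self) -> None:
        for subset, rule in self.rules.items():
            for marker, state in rule.items():
                if state not in (ON, OFF, IGNORE):
                    raise SchemaError(
                        f"{subset}: marker {marker} state {state!r} invalid")
        markers = self.markers()
        for vec in itertools.product([True, False], repeat=len(markers)):
            calls = dict(zip(markers, vec))
            sat = [s for s in self.rules if self._satisfies(s, calls)]
            if len(sat) > 1:
                raise SchemaError(
                    f"rules not mutually exclusive: {calls} satisfies {sat}")

    def markers(self) -> tuple[str, ...]:
        """Markers constrained (non-ignored) by at least one subset rule."""
        out: list[str] = []
        for rule in self.rules.values():
            for m, state in rule.items():
                if state != IGNORE and m not in out:
                    out.append(m)
        return tuple(out)

    def _satisfies(self, subset: str, calls: dict[str, bool]) -> bool:
        for m, state in self.rules[subset].items():
            if state == IGNORE:
                continue
            if m not in calls:
                raise SchemaError(f"call vector missing marker {m}")
            if calls[m] != (state == ON):
                return False
        return True


def results_ruleset() -> BinaryRuleset:
    """Default CD90-free ruleset used for tissue classification."""
    return BinaryRuleset(
        rules={
            "CAF-S1": {"FAP": ON, "aSMA": ON, "FSP1": OFF, "PDPN": ON},
            "CAF-S4": {"FAP": OFF, "aSMA": ON, "FSP1": OFF, "PDPN": OFF},
            "CAF-S5": {"FAP": ON, "aSMA": OFF, "FSP1": OFF, "PDPN": ON},
        },
        version="without_CD90",
    )


def methods_ruleset() -> BinaryRuleset:
    """Flow-derived ruleset that additionally constrains CD90."""
    return BinaryRuleset(
        rules={
            "CAF-S1": {"FAP": ON, "aSMA": ON, "FSP1": OFF, "CD90": ON, "PDPN": ON},
            "CAF-S4": {"FAP": OFF, "aSMA": ON, "FSP1": OFF, "CD90": ON, "PDPN": OFF},
            "CAF-S5": {"FAP": ON, "aSMA": OFF, "FSP1": OFF, "CD90": OFF, "PDPN": ON},
        },
        version="with_CD90",
    )


def otsu_thresholds(cells: pd.DataFrame, markers=CAF_MARKERS) -> dict[str, float]:
    """Global per-marker thresholds by Otsu's criterion.

    Otsu is applied to the pooled log intensities of each marker across
    all cores (one threshold per marker for the whole collection) and
    mapped back to the intensity scale.  A channel with no detectable
    positive population (log intensities better described by one
    Gaussian than two, by BIC) gets a threshold above its maximum, i.e.
    every cell is called OFF: Otsu's split is meaningless on a unimodal
    stain and an unstained channel is the conservative reading.
    """
    from sklearn.mixture import GaussianMixture

    thr = {}
    for m in markers:
        if m not in cells.columns:
            raise SchemaError(f"cell table missing marker {m}")
        vals = cells[m].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"marker {m} has non-positive intensities")
        logs = np.log(vals)
        X = logs.reshape(-1, 1)
        bic1 = GaussianMixture(1, random_state=0).fit(X).bic(X)
        bic2 = GaussianMixture(2, random_state=0, n_init=3).fit(X).bic(X)
        if bic2 < bic1:
            thr[m] = float(np.exp(threshold_otsu(logs)))
        else:
            log.info("marker %s looks unimodal; calling all cells OFF", m)
            thr[m] = float(np.exp(logs.max()) * 1.001)
    return thr


def call_markers(cells: pd.DataFrame, thresholds: dict[str, float]) -> pd.DataFrame:
    """Binary single-channel calls: ON iff intensity >= global threshold."""
    calls = {}
    for m, thr in thresholds.items():
        if m not in cells.columns:
            raise SchemaError(f"cell table missing marker {m}")
        calls[m] = cells[m].to_numpy(dtype=float) >= thr
    return pd.DataFrame(calls, index=cells.index)


def classify_subset(call_vector: dict[str, bool], ruleset: BinaryRuleset) -> str:
    """Classify one call vector: the unique satisfied subset, else 'other'."""
    for subset in ruleset.rules:
        if ruleset._satisfies(subset, call_vector):
            return subset
    return "other"


def classify_cells(
    cells: pd.DataFrame,
    ruleset: BinaryRuleset | None = None,
    thresholds: dict[str, float] | None = None,
) -> pd.Series:
    """Classify every cell in a table; returns a subset label per cell."""
    ruleset = ruleset or results_ruleset()
    if thresholds is None:
        thresholds = otsu_thresholds(cells, ruleset.markers())
    calls = call_markers(cells, thresholds)
    labels = np.full(len(cells), "other", dtype=object)
    for subset, rule in ruleset.rules.items():
        mask = np.ones(len(cells), dtype=bool)
        for m, state in rule.items():
            if state == IGNORE:
                continue
            mask &= calls[m].to_numpy() == (state == ON)
        labels[mask] = subset
    return pd.Series(labels, index=cells.index, name="subset")


def _stromal(cells: pd.DataFrame) -> pd.DataFrame:
    if "compartment" not in cells.columns:
        raise SchemaError("cell table missing 'compartment' column")
    n_missing = int(cells["compartment"].isna().sum())
    if n_missing:
        log.warning("excluding %d cells without a compartment", n_missing)
    return cells[cells["compartment"] == "stroma"]


def subset_percentages(
    cells: pd.DataFrame,
    ruleset: BinaryRuleset | None = None,
    thresholds: dict[str, float] | None = None,
    caf_markers: tuple[str, ...] = CAF_MARKERS,
) -> pd.DataFrame:
    """Per-core subset composition as percent of total CAFs.

    Total CAFs are stromal cells ON for at least one CAF marker; each
    subset's percentage plus the residual ``other`` sums to 100.  Cores
    with zero total CAFs are excluded with a warning.
    """
    ruleset = ruleset or results_ruleset()
    stroma = _stromal(cells)
    markers = [m for m in caf_markers if m in stroma.columns]
    if thresholds is None:
        thresholds = otsu_thresholds(stroma, tuple(markers))
    calls = call_markers(stroma, {m: thresholds[m] for m in markers})
    is_caf = calls.any(axis=1)
    labels = classify_cells(stroma, ruleset, thresholds)

    rows = []
    for core, idx in stroma.groupby("core_id").groups.items():
        caf_idx = idx[is_caf.loc[idx]]
        n_caf = len(caf_idx)
        if n_caf == 0:
            log.warning("core %s has zero total CAFs; excluded", core)
            continue
        row = {"core_id": core, "n_cafs": n_caf}
        counts = labels.loc[caf_idx].value_counts()
        for subset in ruleset.rules:
            row[subset] = 100.0 * counts.get(subset, 0) / n_caf
        row["other"] = 100.0 * counts.get("other", 0) / n_caf
        rows.append(row)
    return pd.DataFrame(rows)


def percent_positive_stroma(
    cells: pd.DataFrame,
    marker: str,
    threshold: float,
) -> float:
    """Percent of stromal cells ON for one marker at a global threshold."""
    stroma = _stromal(cells)
    if len(stroma) == 0:
        raise ValueError("no stromal cells in table")
    if marker not in stroma.columns:
        raise SchemaError(f"cell table missing marker {marker}")
    return 100.0 * float((stroma[marker] >= threshold).mean())
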