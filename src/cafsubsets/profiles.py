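"""Ordinal marker profiles of the five CAF subsets and the fluorescence model.

Cancer-associated fibroblast (CAF) subsets CAF-S1..CAF-S5 are defined by
ordinal expression levels of seven activation markers (FAP, CD29, aSMA,
PDPN, CD90, FSP1, PDGFRb) measured by flow cytometry.  The six-point
ordinal scale runs Neg < Neg-Low < Low < Med < Med-High < High.

:class:`IntensityModel` maps each ordinal level onto a log-normal
fluorescence distribution so that synthetic cytometry events can be
drawn, and cluster geometric MFIs can be discretised back onto the
ordinal scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Ordinal expression levels, weakest to strongest.
ORDINAL_LEVELS: tuple[str, ...] = (
    "Neg", "Neg-Low", "Low", "Med", "Med-High", "High",
)

#: Integer rank of each ordinal level (Neg=0 .. High=5).
LEVEL_RANK: dict[str, int] = {lv: i for i, lv in enumerate(ORDINAL_LEVELS)}

#: The seven phenotyping markers used to define CAF subsets.
PHENO_MARKERS: tuple[str, ...] = (
    "FAP", "CD29", "aSMA", "PDPN", "CD90", "FSP1", "PDGFRb",
)

#: Lineage-exclusion markers: fibroblasts are negative for all three.
LINEAGE_MARKERS: tuple[str, ...] = ("EpCAM", "CD45", "CD31")

#: Viability dye channel (dead cells stain bright).
VIABILITY_MARKER: str = "viability"

SUBSET_NAMES: tuple[str, ...] = (
    "CAF-S1", "CAF-S2", "CAF-S3", "CAF-S4", "CAF-S5",
)


class SchemaError(ValueError):
    """An input table or profile does not match the expected schema."""


@dataclass(frozen=True)
class MarkerProfile:
    """Ordinal expression profile of one CAF subset.

    Parameters
    ----------
    subset_name
        One of ``CAF-S1`` .. ``CAF-S5``.
    levels
        Mapping of each of the seven phenotyping markers to an ordinal
        level; every marker must be present exactly once.
    """

    subset_name: str
    levels: dict[str, str]

    def __post_init__(self) -> None:
        if self.subset_name not in SUBSET_NAMES:
            raise SchemaError(f"unknown subset name: {self.subset_name!r}")
        if set(self.levels) != set(PHENO_MARKERS):
            missing = set(PHENO_MARKERS) - set(self.levels)
            extra = set(self.levels) - set(PHENO_MARKERS)
            raise SchemaError(
                f"profile {self.subset_name}: markers missing={sorted(missing)} "
                f"unknown={sorted(extra)}"
            )
        for marker, level in self.levels.items():
            if level not in LEVEL_RANK:
                raise SchemaError(
                    f"profile {self.subset_name}: marker {marker} has "
                    f"unknown level {level!r}"
                )

    def ranks(self) -> np.ndarray:
        """Integer rank vector over :data:`PHENO_MARKERS` order."""
        return np.array([LEVEL_RANK[self.levels[m]] for m in PHENO_MARKERS])


def default_profiles() -> list[MarkerProfile]:
    """The five published CAF subset profiles.

    CAF-S1 is the FAP-high myofibroblast-like subset, CAF-S2/S3 are
    quiescent-like, CAF-S4 is the FAP-negative contractile subset and
    CAF-S5 is the FAP+/PDPN+ aSMA-negative inflammatory-like subset.
    """
    return [
        MarkerProfile("CAF-S1", {
            "FAP": "High", "CD29": "Med-High", "aSMA": "High",
            "PDPN": "High", "CD90": "Med-High", "FSP1": "Low",
            "PDGFRb": "Med",
        }),
        MarkerProfile("CAF-S2", {
            "FAP": "Neg", "CD29": "Neg-Low", "aSMA": "Neg",
            "PDPN": "Neg", "CD90": "Neg", "FSP1": "Neg",
            "PDGFRb": "Neg",
        }),
        MarkerProfile("CAF-S3", {
            "FAP": "Low", "CD29": "Med", "aSMA": "Neg-Low",
            "PDPN": "Low", "CD90": "Low", "FSP1": "High",
            "PDGFRb": "Low",
        }),
        MarkerProfile("CAF-S4", {
            "FAP": "Neg-Low", "CD29": "High", "aSMA": "Med",
            "PDPN": "Neg", "CD90": "Med-High", "FSP1": "Neg",
            "PDGFRb": "Med-High",
        }),
        MarkerProfile("CAF-S5", {
            "FAP": "Med", "CD29": "Med", "aSMA": "Neg-Low",
            "PDPN": "Med", "CD90": "Low", "FSP1": "Low",
            "PDGFRb": "Med",
        }),
    ]


# Defaults of the fluorescence model: base log-intensity and per-level
# log spacing chosen so adjacent ordinal levels overlap with Bayes error
# well under 0.15 (separation / (2 * sd) = 1/0.6).
_LOG_BASE = math.log(80.0)
_LOG_STEP = 1.0
_LOG_SD = 0.30


@dataclass(frozen=True)
class IntensityModel:
    """Log-normal fluorescence model for the ordinal scale.

    ``level_params`` maps each ordinal level to ``(log_mean, log_sd)``
    of a log-normal intensity distribution (natural-log scale, arbitrary
    fluorescence units).  ``positivity_threshold`` separates negative
    from positive staining; ``high_threshold`` separates positive from
    high staining, mirroring how flow gates are drawn against isotype
    controls.
    """

    level_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            lv: (_LOG_BASE + i * _LOG_STEP, _LOG_SD)
            for i, lv in enumerate(ORDINAL_LEVELS)
        }
    )
    # Isotype-control surrogate: 99th percentile of the Neg level.
    positivity_threshold: float = math.exp(_LOG_BASE + 2.326 * _LOG_SD)
    # Geometric midpoint of the Med-High and High level means.
    high_threshold: float = math.exp(_LOG_BASE + 4.5 * _LOG_STEP)

    def __post_init__(self) -> None:
        if set(self.level_params) != set(ORDINAL_LEVELS):
            raise SchemaError("level_params must cover exactly the six ordinal levels")
        means = [self.level_params[lv][0] for lv in ORDINAL_LEVELS]
        if not all(a < b for a, b in zip(means, means[1:])):
            raise ValueError("level log-means must strictly increase Neg -> High")
        if not (0.0 < self.positivity_threshold < self.high_threshold):
            raise ValueError("need 0 < positivity_threshold < high_threshold")

    def sample(self, level: str, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``size`` intensities for one ordinal level."""
        mu, sd = self.level_params[level]
        return np.exp(rng.normal(mu, sd, size))

    def nearest_level(self, intensity: float) -> str:
        """Discretise a (geometric-mean) intensity to the closest level."""
        if intensity <= 0:
            raise ValueError("intensity must be positive")
        log_i = math.log(intensity)
        return min(
            ORDINAL_LEVELS,
            key=lambda lv: abs(log_i - self.level_params[lv][0]),
        )
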