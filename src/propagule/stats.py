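"""Descriptive statistics around the transmission bottleneck.

Caste-wise abundance summaries (mean ± s.e. of totals and of per-individual
percentage proportions), rare-species fold enrichment between castes,
threshold exceedance among alates, count-based Bray–Curtis dissimilarity,
per-group detection ratios, and the cell-shape circularity helper used for
morphometric comparisons.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .community import DEFAULT_PANEL, IndividualSample, SpeciesGroup, _panel_names

__all__ = [
    "CasteSummary",
    "MorphometricRecord",
    "FoldChange",
    "summarize_castes",
    "fold_change",
    "fraction_above_threshold",
    "bray_curtis",
    "detection_ratio",
    "circularity",
]


@dataclass(frozen=True)
class CasteSummary:
    """Mean ± standard error of totals and proportions for one caste/group.

    Proportions are per-individual fractions (counts / individual total)
    averaged across individuals, so the means sum to ≈1 per caste; they
    are stored as fractions and converted to percentages only for display.
    """

    caste_group: str
    n_individuals: int
    mean_total: float
    se_total: float
    mean_proportion: dict[str, float]
    se_proportion: dict[str, float]


@dataclass(frozen=True)
class FoldChange:
    ratio: float
    fold: int


def _mean_se(values: np.ndarray) -> tuple[float, float]:
    n = len(values)
    mean = float(np.mean(values))
    if n == 1:
        warnings.warn("standard error of a single observation reported as 0", stacklevel=3)
        return mean, 0.0
    return mean, float(np.std(values, ddof=1) / math.sqrt(n))


def summarize_castes(
    samples: Iterable[IndividualSample],
    panel: Sequence[SpeciesGroup] = DEFAULT_PANEL,
) -> list[CasteSummary]:
    """Per-caste mean and s.e. of total abundance and of group proportions.

    Individuals with zero total contribute to the total-abundance summary
    but are excluded from the proportion summary (their composition is
    undefined); a caste whose individuals all have zero totals reports
    zero proportions.  Castes are reported in first-appearance order.
    """
    names = _panel_names(panel)
    by_caste: dict[str, list[IndividualSample]] = {}
    for s in samples:
        by_caste.setdefault(s.caste_group, []).append(s)

    out = []
    for caste, group_samples in by_caste.items():
        totals = np.array([s.total for s in group_samples], dtype=float)
        mean_total, se_total = _mean_se(totals)
        with_counts = [s for s in group_samples if s.total > 0]
        if with_counts:
            props = np.stack(
                [s.count_vector(names) / s.total for s in with_counts]
            )
            mp = {n: float(v) for n, v in zip(names, props.mean(axis=0))}
            if len(with_counts) == 1:
                sp = {n: 0.0 for n in names}
            else:
                se = props.std(axis=0, ddof=1) / math.sqrt(len(with_counts))
                sp = {n: float(v) for n, v in zip(names, se)}
        else:
            mp = {n: 0.0 for n in names}
            sp = {n: 0.0 for n in names}
        out.append(
            CasteSummary(
                caste_group=caste,
                n_individuals=len(group_samples),
                mean_total=mean_total,
                se_total=se_total,
                mean_proportion=mp,
                se_proportion=sp,
            )
        )
    return out


def fold_change(mean_prop_target: float, mean_prop_reference: float) -> FoldChange:
    """Enrichment of a group's mean proportion relative to a reference caste.

    Returns the raw ratio target/reference and its nearest-integer fold —
    e.g. a rare group at 0.48% of the worker community and 2.93% of the
    nymph community is enriched 6.1-fold, an "approximately sixfold"
    increase.
    """
    if mean_prop_reference <= 0:
        raise ValueError("reference proportion must be > 0")
    ratio = mean_prop_target / mean_prop_reference
    return FoldChange(ratio=ratio, fold=round(ratio))


def fraction_above_threshold(
    samples: Iterable[IndividualSample],
    caste_group: str,
    threshold_cells: int,
) -> tuple[int, int, float]:
    """How many individuals of a caste exceed a propagule-size threshold.

    Strict comparison (total > threshold), matching the reading
    "harboured greater than 3500 protist cells".  Returns (k, n, k/n).
    """
    totals = [s.total for s in samples if s.caste_group == caste_group]
    if not totals:
        raise ValueError(f"no samples in caste_group {caste_group!r}")
    k = sum(t > threshold_cells for t in totals)
    n = len(totals)
    return k, n, k / n


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray–Curtis dissimilarity between two count vectors.

    BC(x, y) = 1 - 2 * sum_i min(x_i, y_i) / (sum x + sum y), in [0, 1]:
    0 for identical counts, 1 for disjoint supports.  Vectors must share
    the same species panel (same length and order) and must not both be
    all-zero.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D vectors over the same species panel")
    if np.any(xa < 0) or np.any(ya < 0):
        raise ValueError("counts must be non-negative")
    denom = xa.sum() + ya.sum()
    if denom == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero vectors")
    return float(1.0 - 2.0 * np.minimum(xa, ya).sum() / denom)


def detection_ratio(
    samples: Iterable[IndividualSample],
    caste_group: str,
    species_group: str,
) -> float:
    """Fraction of a caste's individuals in which a group was detected (count > 0)."""
    counts = [s.counts.get(species_group, 0) for s in samples if s.caste_group == caste_group]
    if not counts:
        raise ValueError(f"no samples in caste_group {caste_group!r}")
    return sum(c > 0 for c in counts) / len(counts)


@dataclass(frozen=True)
class MorphometricRecord:
    """Area/perimeter measurement of one protist cell with its circularity."""

    area: float
    perimeter: float
    circularity: float

    @classmethod
    def from_measurements(cls, area: float, perimeter: float) -> "MorphometricRecord":
        return cls(area=area, perimeter=perimeter, circularity=circularity(area, perimeter))


def circularity(area: float, perimeter: float) -> float:
    """Shape circularity 4π·area / perimeter².

    1.0 for a perfect circle, smaller for elongated or folded cells.  By
    the isoperimetric inequality the true value cannot exceed 1; values
    slightly above 1 (pixelated outlines) are clipped with a warning.
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be > 0")
    c = 4.0 * math.pi * area / perimeter**2
    if c > 1.0 + 1e-6:
        warnings.warn(
            f"circularity {c:.6f} exceeds 1; clipping (inconsistent measurement?)",
            stacklevel=2,
        )
    return min(c, 1.0)
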