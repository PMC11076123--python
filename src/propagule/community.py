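"""Data model and I/O for gut protist community counts.

The termite *Reticulitermes speratus* hosts up to 16 morphologically
distinguishable protist species in its hindgut.  For live-cell enumeration
under a haemocytometer these are pooled into 10 countable species groups;
the two large parabasalids (*Trichonympha agilis*, *Teranympha mirabilis*)
are counted over a larger chamber area (3.2 µl) than the rest (0.8 µl), and
the raw chamber count is scaled up to the whole gut-content suspension
(150 µl for workers, 30 µl for nymphs and alates), rounding down to the
nearest integer.

This module provides the domain types (species group panel, raw count
observation, per-individual sample, community composition), the count
scale-up rule, long/wide CSV readers and writers, and the caste-level
composition averaging that feeds the transmission simulation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpeciesGroup",
    "CountObservation",
    "IndividualSample",
    "CommunityComposition",
    "DEFAULT_PANEL",
    "CASTE_GROUPS",
    "SEXES",
    "estimate_population",
    "read_samples",
    "write_samples",
    "average_composition",
    "read_composition",
    "write_composition",
]

CASTE_GROUPS = ("worker", "moulted_worker", "nymph", "A0", "A2", "A7", "A7w")
SEXES = ("male", "female", "unknown")

#: default counted chamber volume (µl) by size class
COUNTED_VOLUME_UL = {"large": 3.2, "other": 0.8}
#: default gut-suspension volume (µl) by caste group
SUSPENSION_VOLUME_UL = {
    "worker": 150.0,
    "moulted_worker": 150.0,
    "nymph": 30.0,
    "A0": 30.0,
    "A2": 30.0,
    "A7": 30.0,
    "A7w": 30.0,
}


@dataclass(frozen=True)
class SpeciesGroup:
    """One countable category of protists.

    Parameters
    ----------
    name
        Short unique label used in data files and composition vectors.
    member_species
        Free-text species names pooled into this category.
    size_class
        ``"large"`` groups are counted over 3.2 µl of the haemocytometer,
        ``"other"`` groups over 0.8 µl.
    """

    name: str
    member_species: tuple[str, ...] = ()
    size_class: str = "other"

    def __post_init__(self) -> None:
        if self.size_class not in ("large", "other"):
            raise ValueError(
                f"size_class must be 'large' or 'other', got {self.size_class!r}"
            )


#: The 10 count-based species groups of the R. speratus hindgut community.
DEFAULT_PANEL: tuple[SpeciesGroup, ...] = (
    SpeciesGroup("Pyrsonympha spp.", ("P. grandis", "P. modesta")),
    SpeciesGroup("D. exilis", ("Dinenympha exilis",)),
    SpeciesGroup("D. porteri type III", ("D. porteri type III",)),
    SpeciesGroup("D. porteri type IV", ("D. porteri type IV",)),
    SpeciesGroup("Dinenympha spp.1", ("D. rugosa", "D. porteri type I", "D. porteri type II")),
    SpeciesGroup("Dinenympha spp.2", ("D. leidyi", "D. parva")),
    SpeciesGroup("Tr. agilis", ("Trichonympha agilis",), size_class="large"),
    SpeciesGroup("Te. mirabilis", ("Teranympha mirabilis",), size_class="large"),
    SpeciesGroup("Holomastigotes sp.", ("Holomastigotes sp.",)),
    SpeciesGroup("small protists", ("Trichomonoides sp.", "Hexamastix sp.", "Microjoenia sp.")),
)


def _panel_names(panel: Sequence[SpeciesGroup]) -> tuple[str, ...]:
    names = tuple(g.name for g in panel)
    if len(set(names)) != len(names):
        raise ValueError("species group names must be unique within a panel")
    return names


@dataclass(frozen=True)
class CountObservation:
    """A raw haemocytometer observation before scale-up.

    ``raw_count`` cells seen in ``counted_volume`` µl of a
    ``suspension_volume`` µl gut-content suspension.
    """

    species_group: str
    raw_count: int
    counted_volume: float
    suspension_volume: float

    def __post_init__(self) -> None:
        if self.raw_count < 0 or int(self.raw_count) != self.raw_count:
            raise ValueError(f"raw_count must be a non-negative integer, got {self.raw_count!r}")
        if self.counted_volume <= 0 or self.suspension_volume <= 0:
            raise ValueError("counted_volume and suspension_volume must be > 0")
        if self.counted_volume > self.suspension_volume:
            raise ValueError(
                "counted_volume cannot exceed suspension_volume "
                f"({self.counted_volume} > {self.suspension_volume})"
            )


def estimate_population(obs: CountObservation) -> int:
    """Scale a chamber count up to the whole suspension.

    Returns ``floor(raw_count * suspension_volume / counted_volume)``: the
    estimated population is rounded *down* to the nearest integer.  The
    arithmetic is exact (decimal volumes are interpreted at their printed
    precision), so e.g. 10 cells in 0.8 µl of 150 µl gives exactly 1875,
    never 1874 from binary floating-point error.
    """
    ratio = Fraction(str(obs.suspension_volume)) / Fraction(str(obs.counted_volume))
    return int(obs.raw_count * ratio)  # int() truncates an exact Fraction downward for >= 0


@dataclass
class IndividualSample:
    """Estimated per-species-group cell counts for one termite."""

    individual_id: str
    colony_id: str
    caste_group: str
    counts: dict[str, int]
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if self.caste_group not in CASTE_GROUPS:
            raise ValueError(
                f"unknown caste_group {self.caste_group!r} for individual "
                f"{self.individual_id!r}; expected one of {CASTE_GROUPS}"
            )
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for individual {self.individual_id!r}")
        for group, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(
                    f"count for {group!r} in individual {self.individual_id!r} "
                    f"must be a non-negative integer, got {c!r}"
                )
        self.counts = {g: int(c) for g, c in self.counts.items()}

    @property
    def total(self) -> int:
        """Total protist population of this individual (sum over groups)."""
        return sum(self.counts.values())

    def count_vector(self, species_groups: Sequence[str]) -> np.ndarray:
        """Counts as an integer vector in panel order (missing groups are 0)."""
        return np.array([self.counts.get(g, 0) for g in species_groups], dtype=np.int64)


@dataclass
class CommunityComposition:
    """A named species-group proportion vector p with provenance.

    Proportions are renormalized to sum to exactly 1 at construction; a
    vector that is all-zero or contains negative entries is rejected.
    """

    species_groups: tuple[str, ...]
    proportions: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.species_groups = tuple(self.species_groups)
        p = np.asarray(self.proportions, dtype=float)
        if p.ndim != 1 or len(p) != len(self.species_groups):
            raise ValueError("proportions must be a 1-D vector matching species_groups")
        if np.any(p < 0) or np.any(~np.isfinite(p)):
            raise ValueError("proportions must be finite and non-negative")
        s = p.sum()
        if s <= 0:
            raise ValueError("proportions must not be all zero")
        self.proportions = p / s

    def __len__(self) -> int:
        return len(self.species_groups)

    def proportion(self, species_group: str) -> float:
        return float(self.proportions[self.species_groups.index(species_group)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.proportions, index=list(self.species_groups), name="proportion")


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_LONG_REQUIRED = ("individual_id", "colony_id", "caste_group", "species_group")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _as_int(value: str, column: str, row: int) -> int:
    try:
        f = float(value)
    except ValueError:
        raise ValueError(f"row {row}: column {column!r} is not a number: {value!r}") from None
    if not f.is_integer():
        raise ValueError(f"row {row}: column {column!r} must be an integer count, got {value!r}")
    return int(f)


def read_samples(
    path: str | Path,
    panel: Sequence[SpeciesGroup] = DEFAULT_PANEL,
) -> list[IndividualSample]:
    """Read per-individual samples from a long- or wide-format CSV/TSV.

    Long format has one row per (individual, species group) with either a
    pre-estimated ``count`` column or a raw-dialect ``raw_count`` column
    (optionally with ``counted_volume`` / ``suspension_volume``; defaults
    from the species size class and caste are used when absent).  Wide
    format, as written by :func:`write_samples`, has one row per individual
    with one column per species group.

    Species groups missing for an individual are filled with 0.  Unknown
    caste or species group labels, duplicate (individual, species) rows and
    non-integer counts raise ``ValueError`` naming the offending row.
    """
    df = _read_table(path)
    names = _panel_names(panel)
    if "species_group" in df.columns:
        return _samples_from_long(df, panel, names)
    if set(names) & set(df.columns):
        return _samples_from_wide(df, names)
    raise ValueError(
        f"{path}: unrecognized layout — need a 'species_group' column (long format) "
        "or one column per species group (wide format)"
    )


def _samples_from_long(
    df: pd.DataFrame, panel: Sequence[SpeciesGroup], names: tuple[str, ...]
) -> list[IndividualSample]:
    missing = [c for c in _LONG_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    raw_dialect = "raw_count" in df.columns
    if not raw_dialect and "count" not in df.columns:
        raise ValueError("need either a 'count' or a 'raw_count' column")
    size_class = {g.name: g.size_class for g in panel}

    seen: set[tuple[str, str]] = set()
    per_individual: dict[str, IndividualSample] = {}
    order: list[str] = []
    for idx, rec in enumerate(df.to_dict("records"), start=2):  # 1-based + header
        iid = rec["individual_id"]
        caste = rec["caste_group"]
        group = rec["species_group"]
        if caste not in CASTE_GROUPS:
            raise ValueError(f"row {idx}: unknown caste_group {caste!r} (individual {iid!r})")
        if group not in names:
            raise ValueError(f"row {idx}: unknown species_group {group!r} (individual {iid!r})")
        key = (iid, group)
        if key in seen:
            raise ValueError(f"row {idx}: duplicate entry for individual {iid!r}, group {group!r}")
        seen.add(key)

        if raw_dialect:
            raw = _as_int(rec["raw_count"], "raw_count", idx)
            counted = (
                float(rec["counted_volume"])
                if rec.get("counted_volume", "") != ""
                else COUNTED_VOLUME_UL[size_class[group]]
            )
            susp = (
                float(rec["suspension_volume"])
                if rec.get("suspension_volume", "") != ""
                else SUSPENSION_VOLUME_UL[caste]
            )
            try:
                count = estimate_population(
                    CountObservation(group, raw, counted, susp)
                )
            except ValueError as e:
                raise ValueError(f"row {idx}: {e}") from None
        else:
            count = _as_int(rec["count"], "count", idx)
            if count < 0:
                raise ValueError(f"row {idx}: negative count for individual {iid!r}")

        if iid not in per_individual:
            order.append(iid)
            per_individual[iid] = IndividualSample(
                individual_id=iid,
                colony_id=rec["colony_id"],
                caste_group=caste,
                sex=rec.get("sex", "unknown") or "unknown",
                counts={n: 0 for n in names},
            )
        sample = per_individual[iid]
        if sample.colony_id != rec["colony_id"] or sample.caste_group != caste:
            raise ValueError(f"row {idx}: inconsistent metadata for individual {iid!r}")
        sample.counts[group] = count
    return [per_individual[i] for i in order]


def _samples_from_wide(df: pd.DataFrame, names: tuple[str, ...]) -> list[IndividualSample]:
    meta = [c for c in ("individual_id", "colony_id", "caste_group") if c not in df.columns]
    if meta:
        raise ValueError(f"missing required columns: {meta}")
    samples = []
    for idx, rec in enumerate(df.to_dict("records"), start=2):
        counts = {n: _as_int(rec[n], n, idx) for n in names if n in rec}
        for n in names:
            counts.setdefault(n, 0)
        samples.append(
            IndividualSample(
                individual_id=rec["individual_id"],
                colony_id=rec["colony_id"],
                caste_group=rec["caste_group"],
                sex=rec.get("sex", "unknown") or "unknown",
                counts=counts,
            )
        )
    return samples


def write_samples(
    samples: Iterable[IndividualSample],
    path: str | Path,
    panel: Sequence[SpeciesGroup] = DEFAULT_PANEL,
) -> None:
    """Write samples as a wide table: one row per individual, one column per group."""
    names = _panel_names(panel)
    path = Path(path)
    rows = []
    for s in samples:
        row: dict[str, object] = {
            "individual_id": s.individual_id,
            "colony_id": s.colony_id,
            "caste_group": s.caste_group,
            "sex": s.sex,
        }
        row.update({n: s.counts.get(n, 0) for n in names})
        row["total"] = s.total
        rows.append(row)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def average_composition(
    samples: Iterable[IndividualSample],
    caste_group: str,
    colonies: Sequence[str] | None = None,
    panel: Sequence[SpeciesGroup] = DEFAULT_PANEL,
    method: str = "individual_mean",
) -> CommunityComposition:
    """Average per-individual communities into one composition vector.

    The default ``individual_mean`` rule converts each matched individual's
    counts to a proportion vector (counts / total), averages those vectors
    arithmetically, and renormalizes — every individual carries equal
    weight regardless of its total abundance.  ``method="pooled"`` instead
    sums raw counts across individuals before normalizing, which weights
    individuals by their totals.

    Raises ``ValueError`` when no sample matches the caste/colony filter or
    when a matched sample has zero total (its proportions are undefined).
    """
    if method not in ("individual_mean", "pooled"):
        raise ValueError(f"unknown method {method!r}")
    names = _panel_names(panel)
    matched = [
        s
        for s in samples
        if s.caste_group == caste_group and (colonies is None or s.colony_id in colonies)
    ]
    if not matched:
        raise ValueError(
            f"no samples match caste_group={caste_group!r}, colonies={colonies!r}"
        )
    zero = [s.individual_id for s in matched if s.total == 0]
    if zero:
        raise ValueError(f"cannot average samples with zero total counts: {zero}")

    counts = np.stack([s.count_vector(names) for s in matched]).astype(float)
    if method == "individual_mean":
        p = (counts / counts.sum(axis=1, keepdims=True)).mean(axis=0)
    else:
        p = counts.sum(axis=0)
    colony_txt = "all colonies" if colonies is None else f"colonies {list(colonies)}"
    source = (
        f"{method} of {len(matched)} {caste_group} individuals, {colony_txt}"
    )
    return CommunityComposition(names, p, source=source)


def write_composition(
    comp: CommunityComposition,
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    """Write a composition as two-column TSV, optionally with a JSON sidecar."""
    df = pd.DataFrame(
        {"species_group": comp.species_groups, "proportion": comp.proportions}
    )
    df.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = {
            "species_groups": list(comp.species_groups),
            "proportions": [float(x) for x in comp.proportions],
            "source": comp.source,
        }
        Path(json_path).write_text(json.dumps(payload, indent=2))


def read_composition(tsv_path: str | Path) -> CommunityComposition:
    df = pd.read_csv(tsv_path, sep="\t")
    if not {"species_group", "proportion"} <= set(df.columns):
        raise ValueError(f"{tsv_path}: expected columns 'species_group' and 'proportion'")
    return CommunityComposition(
        tuple(df["species_group"].astype(str)),
        df["proportion"].to_numpy(dtype=float),
        source=str(tsv_path),
    )
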