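"""Hierarchical generator of per-individual protist count datasets.

Emulates the statistical structure of haemocytometer counts from a
*Reticulitermes speratus* colony survey so that every pipeline stage is
testable without the deposited data:

* caste-specific total abundances — ~79,000 cells in workers collapsing to
  ~5,000–9,000 in nymphs and alates, exactly 0 in freshly moulted workers;
* caste-specific base compositions over the 10 countable species groups,
  with the two rare large parabasalids (Tr. agilis, Te. mirabilis)
  enriched severalfold in nymphs/alates relative to workers;
* individual-level compositional overdispersion (Dirichlet-multinomial);
* a small multiplicative colony effect on composition;
* sexes assigned at random with no effect on composition.

The hierarchy per individual: total ~ lognormal moment-matched to the
caste (mean, sd), rounded; composition ~ Dirichlet(kappa * p); counts ~
multinomial(total, composition).  Everything is deterministic given the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .community import CommunityComposition, DEFAULT_PANEL, IndividualSample, _panel_names

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_dataset",
    "make_default_compositions",
    "default_config",
    "PANEL_NAMES",
    "RARE_GROUP_PERCENTAGES",
]

PANEL_NAMES = _panel_names(DEFAULT_PANEL)

#: Printed mean percentage proportions of the two rarest worker groups per
#: caste/group (Tr. agilis, Te. mirabilis); the calibration anchors of the
#: default compositions.
RARE_GROUP_PERCENTAGES: dict[str, tuple[float, float]] = {
    "worker": (0.48, 0.14),
    "nymph": (2.93, 0.27),
    "A0": (2.93, 0.27),  # eclosion preserves the nymph composition
    "A2": (3.30, 0.29),
    "A7": (2.93, 0.24),
    "A7w": (3.98, 0.31),
}

# Fixed split of the remaining 8 groups (relative weights, sum 1).  A stated
# default standing in for the unpublished per-group table: the community is
# dominated by Pyrsonympha and the abundant Dinenympha forms, with
# Holomastigotes the rarest of the non-focal groups at ~4%.
_OTHER_GROUP_WEIGHTS: dict[str, float] = {
    "Pyrsonympha spp.": 0.17,
    "D. exilis": 0.24,
    "D. porteri type III": 0.07,
    "D. porteri type IV": 0.05,
    "Dinenympha spp.1": 0.21,
    "Dinenympha spp.2": 0.13,
    "Holomastigotes sp.": 0.04,
    "small protists": 0.09,
}

#: Printed caste mean ± s.e. total protist abundances used for calibration.
CASTE_TOTAL_MEAN_SE: dict[str, tuple[float, float]] = {
    "worker": (79248.6, 4432.9),
    "moulted_worker": (0.0, 0.0),
    "nymph": (8992.1, 933.2),
    "A0": (8700.0, 447.2),  # not printed; between nymph and A2, stated assumption
    "A2": (8457.0, 503.8),
    "A7": (5193.5, 370.1),
    "A7w": (6770.2, 428.5),
}

#: study caste sample size used to convert printed s.e. into an sd
REFERENCE_N = 20


def _caste_proportions(caste: str) -> np.ndarray:
    tr_pct, te_pct = RARE_GROUP_PERCENTAGES[caste]
    tr, te = tr_pct / 100.0, te_pct / 100.0
    rest = 1.0 - tr - te
    p = np.empty(len(PANEL_NAMES))
    for i, name in enumerate(PANEL_NAMES):
        if name == "Tr. agilis":
            p[i] = tr
        elif name == "Te. mirabilis":
            p[i] = te
        else:
            p[i] = rest * _OTHER_GROUP_WEIGHTS[name]
    return p


def make_default_compositions() -> tuple[CommunityComposition, CommunityComposition]:
    """Calibrated worker and nymph source compositions.

    The Tr. agilis and Te. mirabilis entries equal the printed caste mean
    percentages (0.48%/0.14% in workers, 2.93%/0.27% in nymphs); the
    remaining 8 groups share the rest under a fixed documented split.  In
    both vectors Te. mirabilis is the rarest group, so it governs the
    minimum propagule size.
    """
    worker = CommunityComposition(
        PANEL_NAMES, _caste_proportions("worker"), source="default worker composition"
    )
    nymph = CommunityComposition(
        PANEL_NAMES, _caste_proportions("nymph"), source="default nymph composition"
    )
    return worker, nymph


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters.

    ``total_mean``/``total_sd`` give the caste-level distribution of total
    abundance (lognormal, moment-matched); defaults derive the sd from the
    printed caste s.e. times sqrt(20), the approximate study caste size.
    ``kappa`` is the Dirichlet concentration controlling individual
    overdispersion around the caste composition (larger = tighter;
    ``math.inf`` disables overdispersion).  ``colony_effect_scale`` is the
    sd of a lognormal multiplicative perturbation of the base proportions,
    drawn once per colony and renormalized.
    """

    n_colonies: int = 2
    n_per_caste: Mapping[str, int] = field(
        default_factory=lambda: {c: 20 for c in CASTE_TOTAL_MEAN_SE}
    )
    total_mean: Mapping[str, float] = field(
        default_factory=lambda: {c: m for c, (m, _) in CASTE_TOTAL_MEAN_SE.items()}
    )
    total_sd: Mapping[str, float] = field(
        default_factory=lambda: {
            c: se * math.sqrt(REFERENCE_N) for c, (_, se) in CASTE_TOTAL_MEAN_SE.items()
        }
    )
    base_proportions: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            c: tuple(_caste_proportions(c)) for c in RARE_GROUP_PERCENTAGES
        }
    )
    kappa: float = 200.0
    colony_effect_scale: float = 0.10
    female_ratio: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_colonies < 1:
            raise ValueError("n_colonies must be >= 1")
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0")
        if not 0 <= self.female_ratio <= 1:
            raise ValueError("female_ratio must be in [0, 1]")
        for caste, p in self.base_proportions.items():
            arr = np.asarray(p, dtype=float)
            if len(arr) != len(PANEL_NAMES):
                raise ValueError(f"base proportions for {caste!r} must have {len(PANEL_NAMES)} entries")
            if np.any(arr <= 0) or abs(arr.sum() - 1.0) > 1e-6:
                raise ValueError(f"base proportions for {caste!r} must be positive and sum to 1")
        for caste in self.n_per_caste:
            if caste not in self.total_mean and caste != "moulted_worker":
                raise ValueError(f"no total-abundance model for caste {caste!r}")


def default_config(**overrides) -> SyntheticConfig:
    """The default study conditions, with keyword overrides."""
    return SyntheticConfig(**overrides)


@dataclass(frozen=True)
class GroundTruth:
    """Realized generator parameters for one seed (for recovery checks)."""

    expected_totals: dict[str, float]
    colony_multipliers: dict[str, tuple[float, ...]]
    expected_proportions: dict[tuple[str, str], tuple[float, ...]]


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def generate_dataset(
    config: SyntheticConfig | None = None,
    seed: int | None = None,
) -> tuple[list[IndividualSample], GroundTruth]:
    """Generate a full per-individual dataset plus its ground truth.

    ``seed`` overrides ``config.seed`` when given.  Castes without a
    protist community model (moulted workers) receive exactly zero counts.
    """
    config = config or SyntheticConfig()
    master = config.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence(master))

    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    colony_ids = (
        roman[: config.n_colonies]
        if config.n_colonies <= len(roman)
        else [f"C{i+1}" for i in range(config.n_colonies)]
    )

    # colony effect: one multiplicative lognormal perturbation vector per colony
    multipliers = {
        cid: np.exp(rng.normal(0.0, config.colony_effect_scale, size=len(PANEL_NAMES)))
        for cid in colony_ids
    }

    expected_props: dict[tuple[str, str], tuple[float, ...]] = {}
    samples: list[IndividualSample] = []
    for caste, n_ind in config.n_per_caste.items():
        has_community = caste in config.base_proportions
        base = (
            np.asarray(config.base_proportions[caste], dtype=float) if has_community else None
        )
        mean = config.total_mean.get(caste, 0.0)
        sd = config.total_sd.get(caste, 0.0)
        for cid in colony_ids:
            if has_community:
                pc = base * multipliers[cid]
                pc = pc / pc.sum()
                expected_props[(caste, cid)] = tuple(float(x) for x in pc)
            # split individuals as evenly as possible across colonies
            n_here = n_ind // len(colony_ids) + (
                1 if colony_ids.index(cid) < n_ind % len(colony_ids) else 0
            )
            for j in range(n_here):
                iid = f"{cid}_{caste}_{j+1:03d}"
                sex = "female" if rng.random() < config.female_ratio else "male"
                if not has_community or mean <= 0:
                    counts = {name: 0 for name in PANEL_NAMES}
                else:
                    mu, sigma = _lognormal_params(mean, sd) if sd > 0 else (math.log(mean), 0.0)
                    total = int(round(rng.lognormal(mu, sigma)))
                    if math.isinf(config.kappa):
                        comp = pc
                    else:
                        comp = rng.dirichlet(config.kappa * pc)
                    drawn = rng.multinomial(total, comp)
                    counts = {name: int(c) for name, c in zip(PANEL_NAMES, drawn)}
                samples.append(
                    IndividualSample(
                        individual_id=iid,
                        colony_id=cid,
                        caste_group=caste,
                        sex=sex,
                        counts=counts,
                    )
                )

    truth = GroundTruth(
        expected_totals={c: config.total_mean.get(c, 0.0) for c in config.n_per_caste},
        colony_multipliers={c: tuple(float(x) for x in m) for c, m in multipliers.items()},
        expected_proportions=expected_props,
    )
    return samples, truth
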