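"""Count scale-up, sample I/O and composition averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from propagule import (
    CommunityComposition,
    CountObservation,
    average_composition,
    estimate_population,
    read_composition,
    read_samples,
    write_composition,
    write_samples,
)
from propagule.synthetic import PANEL_NAMES

from conftest import make_sample


@pytest.mark.parametrize(
    "raw,counted,susp,expected",
    [
        (10, 0.8, 150, 1875),  # 10 * 150 / 0.8
        (0, 3.2, 30, 0),
        (7, 3.2, 30, 65),  # floor(65.625)
        (1, 1.0, 1.0, 1),
    ],
)
def test_population_scale_up(raw, counted, susp, expected):
    assert estimate_population(CountObservation("g", raw, counted, susp)) == expected


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(raw_count=-1, counted_volume=0.8, suspension_volume=30),
        dict(raw_count=1, counted_volume=0.0, suspension_volume=30),
        dict(raw_count=1, counted_volume=0.8, suspension_volume=-30),
        dict(raw_count=1, counted_volume=31.0, suspension_volume=30),
    ],
)
def test_invalid_observations_rejected(kwargs):
    with pytest.raises(ValueError):
        CountObservation("g", **kwargs)


@given(
    raw=st.integers(0, 10_000),
    counted=st.sampled_from([0.8, 3.2, 1.6, 20.0]),
    susp=st.sampled_from([30.0, 150.0, 300.0]),
)
def test_scale_up_monotone_and_floored(raw, counted, susp):
    obs = CountObservation("g", raw, counted, susp)
    est = estimate_population(obs)
    # floor never exceeds the un-rounded estimate
    assert est <= raw * susp / counted + 1e-9
    assert est > raw * susp / counted - 1
    # monotone in raw_count and suspension volume
    assert estimate_population(CountObservation("g", raw + 1, counted, susp)) >= est
    assert estimate_population(CountObservation("g", raw, counted, susp * 2)) >= est
    if susp >= counted:
        assert est >= raw


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _long_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "colony_id",
            "caste_group",
            "sex",
            "species_group",
            "count",
        ],
    )


def test_read_long_estimated_dialect(tmp_path):
    f = tmp_path / "x.csv"
    _long_frame(
        [
            ("a", "I", "worker", "male", "Tr. agilis", 10),
            ("a", "I", "worker", "male", "Te. mirabilis", 5),
        ]
    ).to_csv(f, index=False)
    (sample,) = read_samples(f)
    assert sample.total == 15
    assert sample.counts["Tr. agilis"] == 10
    # missing groups zero-filled
    assert sample.counts["Pyrsonympha spp."] == 0
    assert sample.sex == "male"


def test_unknown_caste_and_group_name_offending_row(tmp_path):
    f = tmp_path / "bad.csv"
    _long_frame([("a", "I", "soldier", "male", "Tr. agilis", 1)]).to_csv(f, index=False)
    with pytest.raises(ValueError, match="soldier"):
        read_samples(f)
    _long_frame([("a", "I", "worker", "male", "Mystery sp.", 1)]).to_csv(f, index=False)
    with pytest.raises(ValueError, match="Mystery"):
        read_samples(f)


def test_duplicate_and_decimal_rows_rejected(tmp_path):
    f = tmp_path / "dup.csv"
    _long_frame(
        [
            ("a", "I", "worker", "male", "Tr. agilis", 1),
            ("a", "I", "worker", "male", "Tr. agilis", 2),
        ]
    ).to_csv(f, index=False)
    with pytest.raises(ValueError, match="duplicate"):
        read_samples(f)
    pd.DataFrame(
        [("a", "I", "worker", "male", "Tr. agilis", 1.5)],
        columns=_long_frame([]).columns,
    ).to_csv(f, index=False)
    with pytest.raises(ValueError, match="integer"):
        read_samples(f)


def test_raw_dialect_applies_scale_up_rowwise(tmp_path, rng):
    """Counts from the raw dialect equal estimate_population of each row."""
    rows = []
    expected = {}
    for i, name in enumerate(PANEL_NAMES[:4]):
        raw = int(rng.integers(0, 40))
        counted, susp = (3.2, 150.0) if i % 2 else (0.8, 30.0)
        rows.append(("a", "I", "worker", "female", name, raw, counted, susp))
        expected[name] = estimate_population(CountObservation(name, raw, counted, susp))
    f = tmp_path / "raw.tsv"
    pd.DataFrame(
        rows,
        columns=[
            "individual_id",
            "colony_id",
            "caste_group",
            "sex",
            "species_group",
            "raw_count",
            "counted_volume",
            "suspension_volume",
        ],
    ).to_csv(f, sep="\t", index=False)
    (sample,) = read_samples(f)
    for name, value in expected.items():
        assert sample.counts[name] == value


def test_raw_dialect_volume_defaults(tmp_path):
    """Omitted volumes fall back to size-class and caste defaults."""
    f = tmp_path / "raw.csv"
    pd.DataFrame(
        [
            ("a", "I", "worker", "", "Tr. agilis", 4),  # large: 3.2 ul of 150 ul
            ("a", "I", "worker", "", "D. exilis", 4),  # other: 0.8 ul of 150 ul
            ("b", "I", "nymph", "", "D. exilis", 4),  # other: 0.8 ul of 30 ul
        ],
        columns=[
            "individual_id",
            "colony_id",
            "caste_group",
            "sex",
            "species_group",
            "raw_count",
        ],
    ).to_csv(f, index=False)
    a, b = read_samples(f)
    assert a.counts["Tr. agilis"] == 187  # floor(4 * 150 / 3.2)
    assert a.counts["D. exilis"] == 750  # 4 * 150 / 0.8
    assert b.counts["D. exilis"] == 150  # 4 * 30 / 0.8


def test_wide_round_trip_bit_exact(tmp_path, rng):
    samples = [
        make_sample(f"s{i}", "worker", {n: int(rng.integers(0, 1000)) for n in PANEL_NAMES})
        for i in range(5)
    ]
    p1 = tmp_path / "wide.csv"
    write_samples(samples, p1)
    back = read_samples(p1)
    p2 = tmp_path / "wide2.csv"
    write_samples(back, p2)
    assert p1.read_text() == p2.read_text()
    for s, b in zip(samples, back):
        assert s.counts == b.counts and s.individual_id == b.individual_id
        assert (s.colony_id, s.caste_group, s.sex) == (b.colony_id, b.caste_group, b.sex)


def test_composition_round_trip(tmp_path):
    comp = CommunityComposition(("a", "b", "c"), np.array([0.2, 0.3, 0.5]), source="t")
    write_composition(comp, tmp_path / "c.tsv", tmp_path / "c.json")
    back = read_composition(tmp_path / "c.tsv")
    assert back.species_groups == comp.species_groups
    np.testing.assert_allclose(back.proportions, comp.proportions)


# ---------------------------------------------------------------------------
# averaging
# ---------------------------------------------------------------------------


def test_average_is_mean_of_individual_proportions():
    samples = [
        make_sample("a", "worker", {"Pyrsonympha spp.": 5, "Tr. agilis": 5}),
        make_sample("b", "worker", {"Pyrsonympha spp.": 90, "Tr. agilis": 10}),
    ]
    comp = average_composition(samples, "worker")
    assert comp.proportion("Pyrsonympha spp.") == pytest.approx(0.7)
    assert comp.proportion("Tr. agilis") == pytest.approx(0.3)


def test_average_single_individual_is_identity():
    s = make_sample("a", "nymph", {"Pyrsonympha spp.": 3, "Te. mirabilis": 1})
    comp = average_composition([s], "nymph")
    assert comp.proportion("Pyrsonympha spp.") == pytest.approx(0.75)


def test_average_matches_spreadsheet_oracle(rng):
    """Independent pandas re-computation of the mean of proportion rows."""
    samples = [
        make_sample(f"s{i}", "worker", {n: int(rng.integers(1, 500)) for n in PANEL_NAMES})
        for i in range(3)
    ]
    comp = average_composition(samples, "worker")
    df = pd.DataFrame([{n: s.counts[n] for n in PANEL_NAMES} for s in samples], dtype=float)
    oracle = df.div(df.sum(axis=1), axis=0).mean(axis=0)
    np.testing.assert_allclose(comp.proportions, oracle.to_numpy(), atol=1e-12)
    assert comp.proportions.sum() == pytest.approx(1.0, abs=1e-9)


def test_average_permutation_equivariant(small_samples):
    a = average_composition(small_samples, "worker")
    b = average_composition(list(reversed(small_samples)), "worker")
    np.testing.assert_allclose(a.proportions, b.proportions)


def test_average_pooled_mode_weights_by_totals(small_samples):
    comp = average_composition(small_samples, "worker", method="pooled")
    # pooled counts: Pyrsonympha 140, Tr. agilis 60 over 200 cells
    assert comp.proportion("Pyrsonympha spp.") == pytest.approx(0.7)


def test_average_filters_and_errors(small_samples):
    comp = average_composition(small_samples, "worker", colonies=["II"])
    assert comp.proportion("Pyrsonympha spp.") == pytest.approx(0.9)
    with pytest.raises(ValueError, match="no samples match"):
        average_composition(small_samples, "A7")
    zero = make_sample("z", "worker", {})
    with pytest.raises(ValueError, match="z"):
        average_composition(small_samples + [zero], "worker")
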