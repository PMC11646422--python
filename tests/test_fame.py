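"""Shorthand parsing, profile invariants and summary statistics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algafuel import (
    FameProfile,
    LipidClass,
    classify,
    mass_percent_of,
    parse_fatty_acid,
    profile_from_mass_percents,
    summarize,
)
from algafuel.exceptions import NotationParseError, ValidationError


@pytest.mark.parametrize(
    "notation, carbons, double_bonds, omega, common_name",
    [
        ("C16:0", 16, 0, None, "palmitic acid"),
        ("C18:3n-6", 18, 3, 6, "gamma-linolenic acid"),
        ("C18:3n-3", 18, 3, 3, "alpha-linolenic acid"),
        ("c14:0", 14, 0, None, "myristic acid"),
        ("  C 22 : 0 ", 22, 0, None, "behenic acid"),
        ("C16:1", 16, 1, None, "palmitoleic acid"),
    ],
)
def test_parse_shorthand(notation, carbons, double_bonds, omega, common_name):
    fa = parse_fatty_acid(notation)
    assert (fa.carbons, fa.double_bonds, fa.omega_series) == (carbons, double_bonds, omega)
    assert fa.common_name == common_name
    assert fa.mass_percent is None


@pytest.mark.parametrize("bad", ["C18", "18:1", "C18:1n", "Cx:0", "", "C18-3n6"])
def test_parse_rejects_malformed(bad):
    with pytest.raises(NotationParseError, match="shorthand"):
        parse_fatty_acid(bad)


def test_parse_rejects_impossible_unsaturation():
    with pytest.raises(ValidationError, match="double bonds"):
        parse_fatty_acid("C4:3")


@pytest.mark.parametrize(
    "notation, expected",
    [("C14:0", LipidClass.SFA), ("C16:1", LipidClass.MUFA),
     ("C18:2", LipidClass.PUFA), ("C22:6n-3", LipidClass.PUFA)],
)
def test_classify(notation, expected):
    assert classify(parse_fatty_acid(notation)) is expected


def test_notation_round_trips_for_reference_acids(reference_profiles):
    for profile in reference_profiles.values():
        for fa in profile.species:
            assert parse_fatty_acid(fa.notation).notation == fa.notation


def test_reference_profiles_close_to_100(reference_profiles):
    assert len(reference_profiles) == 5
    for profile in reference_profiles.values():
        assert profile.total_percent == pytest.approx(100.0, abs=1e-9)


def test_summarize_class_totals_and_adu(reference_profiles):
    s = summarize(reference_profiles["1.0 M NaCl"])
    assert s.sfa_percent == pytest.approx(18.0)
    assert s.mufa_percent == pytest.approx(5.1)
    assert s.pufa_percent == pytest.approx(47.4)
    assert s.adu == pytest.approx(1.401, abs=5e-4)
    assert s.linolenic_percent == pytest.approx(40.2)
    assert s.x_linoleic_plus_linolenic == pytest.approx(47.4)

    s05 = summarize(reference_profiles["0.5 M NaCl"])
    assert s05.adu == pytest.approx(1.042, abs=5e-4)
    assert s05.lcsf == pytest.approx(0.1 * 17.0 + 0.5 * 1.0)


def test_summarize_fully_saturated_profile():
    profile = profile_from_mass_percents("pure palmitic", {"C16:0": 100.0})
    s = summarize(profile)
    assert s.sfa_percent == 100.0
    assert s.adu == 0.0
    assert s.x_linoleic_plus_linolenic == 0.0
    assert s.pufa_ge4db_percent == 0.0


def test_mass_percent_lookup(reference_profiles):
    p10 = reference_profiles["1.0 M NaCl"]
    p05 = reference_profiles["0.5 M NaCl"]
    assert mass_percent_of(p10, "C18:0") == 0.0  # absent ("-" cell)
    assert mass_percent_of(p05, "C16:0") == 17.0
    assert mass_percent_of(p05, "c16 : 0") == 17.0  # canonicalised lookup
    assert mass_percent_of(p05, "C24:0") == 0.0


def test_duplicate_notation_rejected():
    fa = parse_fatty_acid("C16:0")
    with pytest.raises(ValidationError, match="duplicate"):
        FameProfile(
            condition_label="dup",
            species=(fa.with_mass_percent(50.0), fa.with_mass_percent(50.0)),
        )


def test_sum_tolerance_enforced_and_configurable():
    with pytest.raises(ValidationError, match="sums to"):
        profile_from_mass_percents("short", {"C16:0": 90.0})
    profile_from_mass_percents("short", {"C16:0": 90.0}, sum_tolerance=10.5)


# -- property tests ---------------------------------------------------------

_POOL = ["C14:0", "C16:0", "C16:1", "C18:0", "C18:1", "C18:2",
         "C18:3n-6", "C18:3n-3", "C20:5n-3", "C22:0", "C22:6n-3"]


@st.composite
def random_profiles(draw):
    notations = draw(
        st.lists(st.sampled_from(_POOL), min_size=1, max_size=8, unique=True)
    )
    weights = [
        draw(st.floats(0.01, 1.0, allow_nan=False, allow_infinity=False))
        for _ in notations
    ]
    others_w = draw(st.floats(0.0, 1.0))
    total = sum(weights) + others_w
    masses = {n: w / total * 100.0 for n, w in zip(notations, weights)}
    return profile_from_mass_percents(
        "random", masses, others_percent=others_w / total * 100.0,
        sum_tolerance=1e-6,
    )


@settings(max_examples=100, derandomize=True, deadline=None)
@given(random_profiles())
def test_summarize_matches_bruteforce_accumulation(profile):
    """summarize agrees with an independent element-wise accumulation."""
    s = summarize(profile)
    sfa = sum(fa.mass_percent for fa in profile.species if fa.double_bonds == 0)
    mufa = sum(fa.mass_percent for fa in profile.species if fa.double_bonds == 1)
    pufa = sum(fa.mass_percent for fa in profile.species if fa.double_bonds >= 2)
    adu = sum(fa.double_bonds * fa.mass_percent / 100.0 for fa in profile.species)
    assert s.sfa_percent == pytest.approx(sfa, abs=1e-9)
    assert s.mufa_percent == pytest.approx(mufa, abs=1e-9)
    assert s.pufa_percent == pytest.approx(pufa, abs=1e-9)
    assert s.adu == pytest.approx(adu, abs=1e-12)
    assert sfa + mufa + pufa + profile.others_percent == pytest.approx(100.0, abs=1e-6)
    assert s.adu >= 0


@settings(max_examples=50, derandomize=True, deadline=None)
@given(random_profiles())
def test_adu_invariant_under_reordering(profile):
    reordered = FameProfile(
        condition_label=profile.condition_label,
        species=tuple(reversed(profile.species)),
        others_percent=profile.others_percent,
        sum_tolerance=profile.sum_tolerance,
    )
    assert summarize(reordered).adu == pytest.approx(summarize(profile).adu, rel=1e-12)
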