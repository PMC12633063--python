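"""Mass chemistry: printed deltas, additivity, fragment conventions, oracles.

The independent oracle throughout is pyteomics' residue-mass table
(``pyteomics.mass``) combined with brute-force residue-by-residue summation;
the implementation never touches pyteomics.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pmass

from midtail.chem_core import (
    BACKBONES,
    CTERM_CORRECTION_DA,
    ISOTOPE_SPACING_13C,
    MODIFICATIONS,
    PROTON_MASS,
    Composition,
    ModificationSpec,
    Proteoform,
    TMT6PLEX_DELTA_DA,
    composition_mass,
    format_proteoform_key,
    fragment_mz,
    fragment_neutral_mass,
    isotope_envelope,
    load_modifications,
    parse_proteoform_key,
    ppm_error,
    proteoform_mass,
    sortase_cterm_correction,
)
from conftest import random_proteoform

# ---------------------------------------------------------------------------
# independent brute-force oracle over pyteomics' residue-mass table

P_WATER = pmass.calculate_mass(formula="H2O")
P_NH3 = pmass.calculate_mass(formula="NH3")
P_CO = pmass.calculate_mass(formula="CO")
P_H = pmass.calculate_mass(formula="H")


def oracle_proteoform_mass(p: Proteoform) -> float:
    m = sum(pmass.std_aa_mass[aa] for aa in p.sequence) + P_WATER
    m += sum(spec.delta_mass for _, spec in p.placements)
    m += p.sequence.count("H") * 229.162932 + 76.1001
    return m


def oracle_fragment_neutral(p: Proteoform, series: str, index: int) -> float:
    seq = p.sequence
    n = len(seq)
    placements = p.placement_map
    if series in "abc":
        residues = range(1, index + 1)
        offset = {"a": -P_CO, "b": 0.0, "c": P_NH3}[series]
        cterm = 0.0
    else:
        residues = range(n - index + 1, n + 1)
        offset = {"y": P_WATER, "z": P_WATER - P_NH3 + P_H}[series]
        cterm = 76.1001
    m = offset + cterm
    for i in residues:
        m += pmass.std_aa_mass[seq[i - 1]]
        if i in placements:
            m += placements[i].delta_mass
        if seq[i - 1] == "H":
            m += 229.162932
    return m


# ---------------------------------------------------------------------------
# composition and modification masses


@pytest.mark.parametrize(
    "formula, expected",
    [
        ({"C": 1, "H": 2}, 14.015650),
        ({"C": 2, "H": 2, "O": 1}, 42.010565),
        ({"H": 1, "P": 1, "O": 3}, 79.966331),
        ({}, 0.0),
    ],
)
def test_composition_mass_examples(formula, expected):
    assert composition_mass(formula) == pytest.approx(expected, abs=5e-7)


def test_unknown_element_rejected():
    with pytest.raises(KeyError):
        composition_mass({"Xx": 1})
    with pytest.raises(KeyError):
        Composition({"Zz": 2})


def test_formula_parsing():
    assert Composition.from_formula("C2H2O") == {"C": 2, "H": 2, "O": 1}
    with pytest.raises(ValueError):
        Composition.from_formula("C2H2O)")


def test_every_modification_composition_reproduces_its_delta():
    """Each declared delta must round to the composition mass at 6 d.p."""
    for spec in MODIFICATIONS.values():
        if spec.composition is None:
            continue
        assert composition_mass(spec.composition) == pytest.approx(
            spec.delta_mass, abs=5e-7
        ), spec.name


def test_shipped_yaml_table_matches_builtin_defaults():
    loaded = load_modifications()
    assert set(loaded) == set(MODIFICATIONS)
    for abbrev, spec in MODIFICATIONS.items():
        other = loaded[abbrev]
        assert other.delta_mass == pytest.approx(spec.delta_mass, abs=1e-6)
        assert other.targets == spec.targets
        assert other.max_per_peptide == spec.max_per_peptide


def test_modification_spec_rejects_inconsistent_composition():
    with pytest.raises(ValueError):
        ModificationSpec(
            "Bogus", 50.0, frozenset("K"), 1, Composition({"C": 1, "H": 2})
        )


def test_sortase_cterm_correction_matches_literal():
    """Lys + 2,3-diaminopropionamide - H2O - His reproduces 76.1001 Da."""
    assert sortase_cterm_correction() == pytest.approx(CTERM_CORRECTION_DA, abs=1e-4)


# ---------------------------------------------------------------------------
# proteoform masses


def test_unmodified_tail_masses_match_oracle(unmod):
    for backbone in BACKBONES:
        p = Proteoform(backbone)
        assert proteoform_mass(p) == pytest.approx(
            oracle_proteoform_mass(p), abs=1e-4
        )


def test_h33_h31_difference_is_ser_minus_ala():
    diff = proteoform_mass(Proteoform("H3.3")) - proteoform_mass(Proteoform("H3.1"))
    expected = pmass.std_aa_mass["S"] - pmass.std_aa_mass["A"]
    assert diff == pytest.approx(expected, abs=1e-9)


def test_trimethyl_placement_adds_exactly_its_delta(unmod):
    p = parse_proteoform_key("H3K4me3")
    assert proteoform_mass(p) - proteoform_mass(unmod) == pytest.approx(
        42.046950, abs=1e-9
    )


def test_charge8_precursor_falls_in_selection_window(unmod):
    from midtail.chem_core import precursor_mz

    mz = precursor_mz(unmod, 8)
    assert 480.0 <= mz <= 540.0


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_mass_additivity_property(seed):
    """Adding a placement of delta d raises the mass by exactly d."""
    rng = np.random.default_rng(seed)
    p = random_proteoform(rng)
    free = [
        (pos, MODIFICATIONS["ph"])
        for pos, aa in enumerate(p.sequence, start=1)
        if aa in "ST" and pos not in p.placement_map
    ]
    if not free:
        return
    pos, spec = free[int(rng.integers(len(free)))]
    try:
        q = p.with_placement(pos, spec)
    except ValueError:
        return
    assert proteoform_mass(q) - proteoform_mass(p) == pytest.approx(
        spec.delta_mass, abs=1e-9
    )


def test_placement_validation():
    ac = MODIFICATIONS["ac"]
    with pytest.raises(ValueError):
        Proteoform("H3.1", ((2, ac),))  # R2 is not an acetyl target
    with pytest.raises(ValueError):
        Proteoform("H3.1", ((99, ac),))
    me3 = MODIFICATIONS["me3"]
    with pytest.raises(ValueError):  # cap is 3 per peptide
        Proteoform("H3.1", ((4, me3), (9, me3), (14, me3), (18, me3)))


# ---------------------------------------------------------------------------
# proteoform keys


@pytest.mark.parametrize(
    "key, placements",
    [
        ("H3K14ac/K23ac/K27me2", {14: "ac", 23: "ac", 27: "me2"}),
        ("H3unmod", {}),
        ("H3K4me3", {4: "me3"}),
    ],
)
def test_key_parse_format_round_trip(key, placements):
    p = parse_proteoform_key(key)
    assert {pos: spec.abbrev for pos, spec in p.placements} == placements
    assert format_proteoform_key(p) == key


def test_key_canonicalizes_position_order():
    p = parse_proteoform_key("H3K27me2/K14ac/K23ac")
    assert p.key == "H3K14ac/K23ac/K27me2"


def test_key_errors():
    with pytest.raises(ValueError):
        parse_proteoform_key("H3K14xx")
    with pytest.raises(ValueError):
        parse_proteoform_key("H3K5ac")  # residue 5 is Q, not K
    with pytest.raises(ValueError):
        parse_proteoform_key("K14ac")


# ---------------------------------------------------------------------------
# fragments


def test_c1_ion_is_ala_plus_nh3_plus_proton(unmod):
    expected = pmass.std_aa_mass["A"] + P_NH3 + 1.007276
    assert fragment_mz(unmod, "c", 1, 1, fixed_mods=False) == pytest.approx(
        expected, abs=1e-4
    )


def test_full_length_y_relates_to_precursor(unmod):
    """y over the whole chain (index n-1 + residue 1) equals M + proton."""
    y35 = fragment_neutral_mass(unmod, "y", 35)
    first = proteoform_mass(unmod) - y35
    # the remainder is residue 1 (Ala)
    assert first == pytest.approx(pmass.std_aa_mass["A"], abs=1e-4)


def test_fragment_complementarity_exhaustive(unmod):
    """b/y and c/z pairs tile the precursor for every cleavage site."""
    M = proteoform_mass(unmod)
    for i in range(1, 36):
        by = fragment_neutral_mass(unmod, "b", i) + fragment_neutral_mass(
            unmod, "y", 36 - i
        )
        assert by == pytest.approx(M, abs=1e-9)
        cz = fragment_neutral_mass(unmod, "c", i) + fragment_neutral_mass(
            unmod, "z", 36 - i
        )
        # c + z-dot carry one extra hydrogen atom relative to the precursor
        assert cz == pytest.approx(M + P_H, abs=1e-4)


def test_positional_isomers_differ_only_inside_the_window():
    k9 = parse_proteoform_key("H3K9me1")
    k14 = parse_proteoform_key("H3K14me1")
    for i in range(9, 14):
        diff = fragment_mz(k14, "c", i, 1) - fragment_mz(k9, "c", i, 1)
        assert diff == pytest.approx(-14.015650, abs=1e-6)
    for i in list(range(1, 9)) + list(range(14, 36)):
        assert fragment_mz(k14, "c", i, 1) == pytest.approx(
            fragment_mz(k9, "c", i, 1), abs=1e-9
        )


def test_fragment_errors(unmod):
    with pytest.raises(ValueError):
        fragment_neutral_mass(unmod, "c", 36)
    with pytest.raises(ValueError):
        fragment_neutral_mass(unmod, "w", 5)
    with pytest.raises(ValueError):
        fragment_mz(unmod, "c", 5, 0)


def test_neutral_loss_subtracts_exactly(unmod):
    plain = fragment_neutral_mass(unmod, "b", 10)
    lost = fragment_neutral_mass(unmod, "b", 10, {"H": 2, "O": 1})
    assert plain - lost == pytest.approx(P_WATER, abs=1e-9)


# ---------------------------------------------------------------------------
# isotope envelope and ppm


def test_envelope_single_peak_is_normalized(unmod):
    env = isotope_envelope(unmod, 8, 1)
    assert len(env) == 1 and env[0][1] == 1.0


def test_envelope_spacing_at_charge_2():
    env = isotope_envelope(Composition({"C": 10, "H": 20}), 2, 3)
    gap = env[1][0] - env[0][0]
    assert gap == pytest.approx(ISOTOPE_SPACING_13C / 2, abs=1e-9)
    assert gap == pytest.approx(0.501675, abs=5e-6)


def test_glycine_envelope_matches_binomial_oracle():
    comp = Composition({"C": 2, "H": 5, "N": 1, "O": 2})  # glycine molecule
    env = isotope_envelope(comp, 1, 3)
    p = 0.0107
    raw = [math.comb(2, k) * p**k * (1 - p) ** (2 - k) for k in range(3)]
    expected = [r / max(raw) for r in raw]
    for (_, got), want in zip(env, expected):
        assert got == pytest.approx(want, rel=1e-12)


@pytest.mark.parametrize(
    "obs, theo, expected",
    [(500.0, 500.0, 0.0), (500.0075, 500.0, 15.0), (499.9925, 500.0, -15.0)],
)
def test_ppm_error_examples(obs, theo, expected):
    assert ppm_error(obs, theo) == pytest.approx(expected, abs=1e-9)


def test_ppm_error_requires_positive_theoretical():
    with pytest.raises(ValueError):
        ppm_error(500.0, 0.0)


@settings(max_examples=30, derandomize=True)
@given(st.floats(100, 2000), st.floats(100, 2000))
def test_ppm_antisymmetry(a, b):
    assert ppm_error(a, b) * b == pytest.approx(-ppm_error(b, a) * a, rel=1e-9)


# ---------------------------------------------------------------------------
# oracle equivalence on random proteoforms


def test_oracle_equivalence_random_proteoforms():
    """Proteoform and fragment masses agree with brute-force summation over
    pyteomics' residue-mass table to < 1e-4 Da."""
    rng = np.random.default_rng(2024)
    for _ in range(50):
        p = random_proteoform(rng)
        assert abs(proteoform_mass(p) - oracle_proteoform_mass(p)) < 1e-4
        for series in ("a", "b", "c", "y", "z"):
            for index in rng.integers(1, 36, size=3):
                index = int(index)
                got = fragment_neutral_mass(p, series, index)
                want = oracle_fragment_neutral(p, series, index)
                assert abs(got - want) < 1e-4, (p.key, series, index)
                for charge in (1, 2, 3):
                    mz = fragment_mz(p, series, index, charge)
                    assert mz == pytest.approx(
                        (want + charge * PROTON_MASS) / charge, abs=1e-4
                    )
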