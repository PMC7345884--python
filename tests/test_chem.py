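"""Chemistry core: compositions, shorthand parsing, ion m/z arithmetic."""

import pytest
from hypothesis import given, settings, strategies as st

from lipidnet.chem import (
    Composition,
    LipidNameError,
    LipidSpecies,
    composition,
    composition_search,
    format_lipid_name,
    ion_mz,
    mz,
    parse_lipid_name,
)


def ppm(observed: float, expected: float) -> float:
    return abs(observed - expected) / expected * 1e6


class TestComposition:
    def test_formula_roundtrip(self):
        comp = Composition.from_formula("C42H82NO8P")
        assert comp["C"] == 42 and comp["H"] == 82 and comp["N"] == 1
        assert comp.formula() == "C42H82NO8P"

    def test_arithmetic_is_elementwise(self):
        a = Composition.from_formula("C2H4O")
        b = Composition.from_formula("CH2")
        assert (a + b).formula() == "C3H6O"
        assert (a - b).formula() == "CH2O"
        assert (2 * b).formula() == "C2H4"

    def test_subtraction_never_goes_negative(self):
        with pytest.raises(ValueError, match="negative"):
            Composition.from_formula("CH4") - Composition.from_formula("C2H2")

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError):
            Composition(X=1)

    @given(
        st.integers(1, 30), st.integers(0, 60), st.integers(0, 6),
        st.integers(1, 20), st.integers(0, 40),
    )
    @settings(max_examples=100, deadline=None)
    def test_mass_additivity(self, c1, h1, o1, c2, h2):
        """Adding a block shifts the anion m/z by exactly its neutral mass."""
        a = Composition(C=c1, H=h1, O=o1, charge=-1)
        b = Composition(C=c2, H=h2)
        assert abs(mz(a + b) - mz(a) - b.monoisotopic_mass) < 1e-9


class TestParseFormat:
    @pytest.mark.parametrize("name, subclass, resolved", [
        ("PC (16:0/18:1)", "PC", True),
        ("PC(16:0/18:1)", "PC", True),
        ("PE (40:1)", "PE", False),
        ("Cer (d18:1/16:0)", "Cer", True),
        ("SM (d42:1)", "SM", False),
        ("PE-P (16:0/16:1)", "PE-P", True),
        ("PE–P (16:0/16:1)", "PE-P", True),  # en-dash variant
        ("LPC (16:0)", "LPC", True),
    ])
    def test_parse_supported_forms(self, name, subclass, resolved):
        species = parse_lipid_name(name)
        assert species.subclass == subclass
        assert species.sn_resolved is resolved

    def test_parse_populates_chains(self):
        pc = parse_lipid_name("PC (16:0/18:1)")
        assert [(c.carbons, c.double_bonds) for c in pc.chains] == [(16, 0), (18, 1)]
        cer = parse_lipid_name("Cer (d18:1/16:0)")
        assert (cer.base.carbons, cer.base.double_bonds) == (18, 1)
        assert (cer.n_acyl.carbons, cer.n_acyl.double_bonds) == (16, 0)
        pe = parse_lipid_name("PE (40:1)")
        assert (pe.nc, pe.db) == (40, 1)

    @pytest.mark.parametrize("bad", [
        "XX (16:0/18:1)", "PC (16:0/18)", "PC 16:0/18:1", "Cer (18:1/16:0)",
        "PC (16:0/18:1/20:0)", "PC ()",
    ])
    def test_malformed_names_raise(self, bad):
        with pytest.raises(LipidNameError):
            parse_lipid_name(bad)

    @given(st.sampled_from(["PC", "PE", "PS", "PI", "PG", "PA"]),
           st.integers(10, 24), st.integers(0, 4),
           st.integers(10, 24), st.integers(0, 4))
    @settings(max_examples=80, deadline=None)
    def test_roundtrip_glycero(self, sub, c1, d1, c2, d2):
        name = f"{sub} ({c1}:{d1}/{c2}:{d2})"
        assert format_lipid_name(parse_lipid_name(name)) == name

    @given(st.sampled_from(["Cer", "SM", "HexCer"]),
           st.integers(0, 2), st.integers(12, 26), st.integers(0, 2))
    @settings(max_examples=40, deadline=None)
    def test_roundtrip_sphingo(self, sub, bd, ac, ad):
        name = f"{sub} (d18:{bd}/{ac}:{ad})"
        assert format_lipid_name(parse_lipid_name(name)) == name


class TestNeutralComposition:
    @pytest.mark.parametrize("name, formula", [
        ("PC (16:0/18:1)", "C42H82NO8P"),
        ("Cer (d18:1/16:0)", "C34H67NO3"),
        ("LPC (16:0)", "C24H50NO7P"),
        ("PE (16:0/18:1)", "C39H76NO8P"),
        ("PS (16:0/18:1)", "C40H76NO10P"),
        ("PG (16:0/18:1)", "C40H77O10P"),
        ("PI (16:0/18:1)", "C43H81O13P"),
        ("PA (16:0/18:1)", "C37H71O8P"),
        ("SM (d18:1/16:0)", "C39H79N2O6P"),
        ("HexCer (d18:1/16:0)", "C40H77NO8"),
        ("PC-O (16:0/16:0)", "C40H82NO7P"),
    ])
    def test_known_formulas(self, name, formula):
        assert composition(parse_lipid_name(name)).formula() == formula

    def test_sum_level_matches_resolved(self):
        resolved = composition(parse_lipid_name("PE (16:0/18:1)"))
        summed = composition(parse_lipid_name("PE (34:1)"))
        assert resolved == summed

    def test_ether_sum_level_matches_resolved(self):
        resolved = composition(parse_lipid_name("PC-P (16:0/16:1)"))
        summed = composition(parse_lipid_name("PC-P (32:1)"))
        assert resolved == summed


class TestIonMz:
    @pytest.mark.parametrize("formula, charge, expected", [
        ("C3H6O5P", -1, 152.9958),    # glycerophosphate
        ("C5H15NO4P", +1, 184.0733),  # phosphocholine, positive mode
        ("C4H11NO4P", -1, 168.0428),  # demethylated phosphocholine
        ("C6H12O9P", -1, 259.0225),   # inositol phosphate
    ])
    def test_reference_fragments(self, formula, charge, expected):
        observed = mz(Composition.from_formula(formula, charge=charge))
        assert ppm(observed, expected) < 10

    def test_pc_precursor_within_10ppm(self):
        comp = composition(parse_lipid_name("PC (16:0/18:1)"))
        assert ppm(ion_mz(comp, "[M-CH3]-"), 744.5540) < 10

    def test_unicode_minus_ion_label(self):
        comp = composition(parse_lipid_name("PE (16:0/18:1)"))
        assert ion_mz(comp, "[M−H]−") == ion_mz(comp, "[M-H]-")

    def test_mz_requires_single_charge(self):
        with pytest.raises(ValueError):
            mz(Composition.from_formula("C3H6O5P"))


class TestCompositionSearch:
    def test_anchors_ceramide_fragment_formulas(self):
        hits = composition_search(263.2379, 5,
                                  {"C": (0, 20), "H": (0, 40),
                                   "N": (0, 1), "O": (0, 3)})
        assert Composition.from_formula("C18H31O", charge=-1) in \
            [c for c, _ in hits]
        hits = composition_search(254.2486, 5)
        assert Composition.from_formula("C16H32NO", charge=-1) in \
            [c for c, _ in hits]

    def test_neutral_loss_search_finds_water(self):
        hits = composition_search(18.0106, 5, charge=0)
        assert hits[0][0] == Composition.from_formula("H2O")

    def test_empty_result_is_valid(self):
        assert composition_search(100.0, 0.5) == \
            [c for c in composition_search(100.0, 0.5)]  # no raise
        assert composition_search(3.5, 1) == []

    def test_sorted_by_ppm_error(self):
        hits = composition_search(263.2379, 20)
        errors = [abs(d) for _, d in hits]
        assert errors == sorted(errors)
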