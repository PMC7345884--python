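"""Diagnostic product-ion rule sets for negative-mode lipid MS/MS.

For each supported subclass the rule engine generates the expected product
ions of the canonical negative-mode precursor ([M-CH3]- for choline-bearing
lipids, [M-H]- otherwise): head-group fragments, fatty-acyl carboxylates,
ketene (acyl chain) neutral losses, and the sphingolipid S/T/U (fatty-amide)
and Q/P (sphingoid) series.  Ions that the annotation logic relies on carry
``required=True``; ``min_required`` is the number of matched required ions
needed to accept an annotation.

Ether (-O) and plasmalogen (-P) species yield no sn1 carboxylate and no sn1
ketene loss: the sn1 chain is ether-bound and cannot leave as a carboxylate
or ketene.  Their rule sets are therefore strict subsets of the diacyl sets
minus the sn1-chain ions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lipidnet.chem import (
    ChainSpec,
    Composition,
    ETHER_SUBCLASSES,
    ION_SPECIES,
    Linkage,
    LipidSpecies,
    LYSO_SUBCLASSES,
    SphingoidBase,
    composition,
    mz,
    parent_subclass,
    precursor_ion,
)

__all__ = ["DiagnosticIon", "RuleSet", "diagnostic_ions", "sn_intensity_rule",
           "MIN_REQUIRED"]

_WATER = Composition.from_formula("H2O")
_HEXOSE_LOSS = Composition.from_formula("C6H10O5")
_SERINE = Composition.from_formula("C3H5NO2")

# Head-group fragment anions, by diacyl parent subclass.
_HEAD_FRAGMENTS: dict[str, list[tuple[str, str]]] = {
    # (role, formula); all singly charged anions
    "PC": [("head_small", "C4H11NO4P"), ("head_large", "C7H15NO5P")],
    "PE": [("head_small", "C2H7NO4P"), ("head_large", "C5H11NO5P")],
    "PG": [("head_large", "C6H12O7P")],
    "PI": [("head_large", "C6H12O9P")],
}

_GLYCEROPHOSPHATE = Composition.from_formula("C3H6O5P", charge=-1)

# Default number of matched required ions needed to accept an annotation.
# Diacyl PC/PE and Cer follow the six-diagnostic-ion convention; subclasses
# with fewer chain-informative ions use smaller counts.  Config-exposed.
MIN_REQUIRED: dict[str, int] = {
    "PC": 6, "PE": 6, "Cer": 6,
    "PS": 4, "PI": 4, "PA": 4, "PG": 4,
    "PC-O": 4, "PC-P": 4, "PE-O": 4, "PE-P": 4, "PI-O": 4,
    "LPC": 3, "LPE": 3, "SM": 3, "HexCer": 3,
}


@dataclass(frozen=True)
class DiagnosticIon:
    """One rule-generated expected fragment."""

    role: str
    comp: Composition        # charged composition
    mz: float
    required: bool = True

    def __repr__(self) -> str:
        flag = "required" if self.required else "optional"
        return f"DiagnosticIon({self.role}, {self.comp.formula()}, {self.mz:.4f}, {flag})"


@dataclass(frozen=True)
class RuleSet:
    """Expected product-ion set for one lipid species."""

    species: LipidSpecies
    ions: tuple[DiagnosticIon, ...]
    min_required: int
    sn_rule: str | None      # "sn1" / "sn2" / None

    @property
    def subclass(self) -> str:
        return self.species.subclass

    @property
    def required_ions(self) -> tuple[DiagnosticIon, ...]:
        return tuple(i for i in self.ions if i.required)

    def ion(self, role: str) -> DiagnosticIon:
        for i in self.ions:
            if i.role == role:
                return i
        raise KeyError(role)

    def __post_init__(self) -> None:
        roles = [i.role for i in self.ions]
        if len(roles) != len(set(roles)):
            raise ValueError(f"duplicate roles in rule set: {roles}")
        if self.min_required > len(self.required_ions):
            raise ValueError(
                f"min_required {self.min_required} exceeds the "
                f"{len(self.required_ions)} required ions of {self.species.name}"
            )


def sn_intensity_rule(subclass: str) -> str:
    """Which sn position carries the more intense carboxylate fragment.

    PC/PE/PG: the sn2 carboxylate dominates; PS/PI/PA: sn1 dominates.  The
    rule identifies the likely *major regio-isomer* only.  Sphingolipid and
    lyso subclasses have no positional ambiguity and raise.
    """
    parent = parent_subclass(subclass)
    if subclass in LYSO_SUBCLASSES:
        raise ValueError(f"sn rule not applicable to lyso subclass {subclass}")
    if parent in ("PC", "PE", "PG"):
        return "sn2"
    if parent in ("PS", "PI", "PA"):
        return "sn1"
    raise ValueError(f"sn rule not applicable to subclass {subclass}")


def _carboxylate(chain: ChainSpec) -> Composition:
    """Fatty carboxylate anion C_c H_{2c-1-2d} O2^-."""
    c, d = chain.carbons, chain.double_bonds
    return Composition(C=c, H=2 * c - 1 - 2 * d, O=2, charge=-1)


def _ketene(chain: ChainSpec) -> Composition:
    """Neutral acyl ketene C_c H_{2c-2-2d} O (R-CH=C=O)."""
    c, d = chain.carbons, chain.double_bonds
    return Composition(C=c, H=2 * c - 2 - 2 * d, O=1)


def _ion(role: str, comp: Composition, required: bool = True) -> DiagnosticIon:
    return DiagnosticIon(role=role, comp=comp, mz=mz(comp), required=required)


def _sphingo_chain_ions(base: SphingoidBase, acyl: ChainSpec,
                        required: bool = True) -> list[DiagnosticIon]:
    """S/T/U (fatty-amide) and Q/P (sphingoid) fragment series.

    The compositions are fixed by exhaustive formula search against observed
    ceramide fragment m/z values and generalized by chain arithmetic:
    S = C_{nF+2} H_{2nF+2-2dF} N O2^-, T = S - O, U = C_{nF} H_{2nF-2dF} N O^-,
    Q = C_{nB} H_{2nB-3-2dB} O^-, P = Q - C2H2.
    """
    nf, df = acyl.carbons, acyl.double_bonds
    nb, db = base.carbons, base.double_bonds
    s = Composition(C=nf + 2, H=2 * nf + 2 - 2 * df, N=1, O=2, charge=-1)
    t = s - Composition(O=1)
    u = Composition(C=nf, H=2 * nf - 2 * df, N=1, O=1, charge=-1)
    q = Composition(C=nb, H=2 * nb - 3 - 2 * db, O=1, charge=-1)
    p = q - Composition(C=2, H=2)
    return [
        _ion("S", s, required), _ion("T", t, required), _ion("U", u, required),
        _ion("Q", q, required), _ion("P", p, required),
    ]


def diagnostic_ions(lipid: LipidSpecies) -> RuleSet:
    """Generate the expected diagnostic product-ion set for one species.

    Requires an sn-resolved species; sum-level species must be expanded into
    chain combinations first (the annotation layer does this).
    """
    if not lipid.sn_resolved:
        raise ValueError(
            f"{lipid.name!r} is sum-level; expand chain combinations first"
        )
    sub = lipid.subclass
    neutral = composition(lipid)
    prec_species = precursor_ion(sub)
    prec = prec_species.apply(neutral)
    ions: list[DiagnosticIon] = [_ion("precursor", prec)]
    sn_rule: str | None = None

    if lipid.is_sphingolipid:
        assert lipid.base is not None and lipid.n_acyl is not None
        if sub == "Cer":
            ions.append(_ion("precursor-H2O", prec - _WATER, required=False))
            ions.append(_ion("precursor-2H2O", prec - 2 * _WATER, required=False))
            ions.extend(_sphingo_chain_ions(lipid.base, lipid.n_acyl))
        elif sub == "SM":
            head = Composition.from_formula("C4H11NO4P", charge=-1)
            ions.append(_ion("head_small", head))
            stu = _sphingo_chain_ions(lipid.base, lipid.n_acyl, required=False)
            by_role = {i.role: i for i in stu}
            ions.append(_ion("T", by_role["T"].comp, required=True))
            ions.append(by_role["U"])
        else:  # HexCer
            ions.append(_ion("hexose_loss", prec - _HEXOSE_LOSS))
            stu = _sphingo_chain_ions(lipid.base, lipid.n_acyl, required=False)
            by_role = {i.role: i for i in stu}
            ions.append(_ion("S", by_role["S"].comp, required=True))
            for role in ("T", "U", "Q", "P"):
                ions.append(by_role[role])
        return RuleSet(species=lipid, ions=tuple(ions),
                       min_required=MIN_REQUIRED[sub], sn_rule=None)

    # Glycerophospholipids ----------------------------------------------
    parent = parent_subclass(sub)
    is_lyso = sub in LYSO_SUBCLASSES
    is_ether = sub in ETHER_SUBCLASSES

    # head-group fragments
    if parent in _HEAD_FRAGMENTS:
        # the single PI head fragment gains water-loss satellites
        for role, formula in _HEAD_FRAGMENTS[parent]:
            head = Composition.from_formula(formula, charge=-1)
            required = True
            if parent == "PC" and role == "head_large":
                required = False  # present but not among the six PC diagnostics
            ions.append(_ion(role, head, required))
        if parent == "PI":
            head = Composition.from_formula("C6H12O9P", charge=-1)
            ions.append(_ion("head-H2O", head - _WATER))
            ions.append(_ion("head-2H2O", head - 2 * _WATER, required=False))
    if parent == "PS":
        ions.append(_ion("serine_loss", prec - _SERINE))
        ions.append(_ion("glycerophosphate", _GLYCEROPHOSPHATE))
    if parent == "PA":
        ions.append(_ion("glycerophosphate", _GLYCEROPHOSPHATE))

    # chain fragments: carboxylates and ketene losses
    if is_lyso:
        ions.append(_ion("carboxylate_sn1", _carboxylate(lipid.chains[0])))
        return RuleSet(species=lipid, ions=tuple(ions),
                       min_required=MIN_REQUIRED[sub], sn_rule=None)

    sn1, sn2 = lipid.chains
    sn_rule = sn_intensity_rule(sub)
    ketenes_required = parent in ("PC", "PE")
    carbs_required = True
    if sn1.linkage is Linkage.ACYL and not is_ether:
        ions.append(_ion("carboxylate_sn1", _carboxylate(sn1), carbs_required))
    ions.append(_ion("carboxylate_sn2", _carboxylate(sn2), carbs_required))
    if parent in ("PC", "PE", "PG"):
        if not is_ether:
            ions.append(_ion("ketene_loss_sn1", prec - _ketene(sn1),
                             ketenes_required if parent != "PG" else False))
        ions.append(_ion("ketene_loss_sn2", prec - _ketene(sn2),
                         ketenes_required if parent != "PG" else False))
    return RuleSet(species=lipid, ions=tuple(ions),
                   min_required=MIN_REQUIRED[sub], sn_rule=sn_rule)
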