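"""Elemental-composition arithmetic, lipid shorthand parsing, and ion m/z.

This module is the mass-arithmetic foundation of the package.  All lipid and
fragment formulas are expressed as :class:`Composition` objects (element ->
count maps with an integer charge), built from per-subclass structural blocks:
a glycerophosphate core plus head-group and fatty-chain deltas for
glycerophospholipids, and a sphingoid base plus amide-linked acyl chain for
sphingolipids.  Monoisotopic m/z values are computed from IUPAC atomic masses
with the electron mass included, so that singly charged anions/cations carry
the +/- 0.000549 Da electron correction.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

__all__ = [
    "ELEMENT_MASS",
    "ELECTRON_MASS",
    "Composition",
    "Linkage",
    "ChainSpec",
    "SphingoidBase",
    "LipidSpecies",
    "IonSpecies",
    "ION_SPECIES",
    "LipidNameError",
    "parse_lipid_name",
    "format_lipid_name",
    "composition",
    "ion_mz",
    "mz",
    "composition_search",
    "GLYCEROPHOSPHOLIPID_SUBCLASSES",
    "SPHINGOLIPID_SUBCLASSES",
    "LYSO_SUBCLASSES",
    "ETHER_SUBCLASSES",
    "SUBCLASSES",
]

# Monoisotopic atomic masses (Da).  C-12 is exact by definition.
ELEMENT_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740,
    "O": 15.9949146,
    "P": 30.9737615,
}

ELECTRON_MASS = 0.000548579909  # Da


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Composition(Mapping[str, int]):
    """An immutable element->count map with a signed integer charge.

    Supports element-wise addition/subtraction (subtraction raises if any
    count would go negative) and integer scaling.  Counts of zero are
    dropped so equality is well defined.
    """

    __slots__ = ("_counts", "charge")

    def __init__(self, counts: Mapping[str, int] | None = None, charge: int = 0,
                 **kwargs: int) -> None:
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for elem, n in source.items():
                if elem not in ELEMENT_MASS:
                    raise ValueError(f"unsupported element {elem!r}")
                if int(n) != n:
                    raise ValueError(f"non-integer count for {elem}: {n!r}")
                merged[elem] = merged.get(elem, 0) + int(n)
        for elem, n in merged.items():
            if n < 0:
                raise ValueError(f"negative count for {elem}: {n}")
        self._counts: dict[str, int] = {e: n for e, n in merged.items() if n}
        self.charge = int(charge)

    @classmethod
    def from_formula(cls, formula: str, charge: int = 0) -> "Composition":
        """Parse a plain molecular formula such as ``"C4H11NO4P"``."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"malformed formula {formula!r} at {pos}")
            if not match.group(0):
                break
            elem, digits = match.groups()
            counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(formula) or not counts:
            raise ValueError(f"malformed formula {formula!r}")
        return cls(counts, charge=charge)

    # Mapping interface -------------------------------------------------
    def __getitem__(self, elem: str) -> int:
        return self._counts[elem]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, elem: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(elem, default)

    # Arithmetic ---------------------------------------------------------
    def __add__(self, other: "Composition") -> "Composition":
        counts = dict(self._counts)
        for elem, n in other._counts.items():
            counts[elem] = counts.get(elem, 0) + n
        return Composition(counts, charge=self.charge + other.charge)

    def __sub__(self, other: "Composition") -> "Composition":
        counts = dict(self._counts)
        for elem, n in other._counts.items():
            counts[elem] = counts.get(elem, 0) - n
            if counts[elem] < 0:
                raise ValueError(
                    f"subtraction yields negative {elem} count "
                    f"({self!r} - {other!r})"
                )
        return Composition(counts, charge=self.charge - other.charge)

    def __mul__(self, factor: int) -> "Composition":
        return Composition({e: n * factor for e, n in self._counts.items()},
                           charge=self.charge * factor)

    __rmul__ = __mul__

    def replace_charge(self, charge: int) -> "Composition":
        return Composition(self._counts, charge=charge)

    # Mass ---------------------------------------------------------------
    @property
    def monoisotopic_mass(self) -> float:
        """Neutral-frame monoisotopic mass (no electron correction)."""
        return sum(ELEMENT_MASS[e] * n for e, n in self._counts.items())

    # Dunder -------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Composition):
            return NotImplemented
        return self._counts == other._counts and self.charge == other.charge

    def __hash__(self) -> int:
        return hash((frozenset(self._counts.items()), self.charge))

    def formula(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        order = ["C", "H"] + sorted(e for e in self._counts if e not in ("C", "H"))
        parts = []
        for elem in order:
            n = self._counts.get(elem, 0)
            if n == 1:
                parts.append(elem)
            elif n > 1:
                parts.append(f"{elem}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        sign = {0: "", 1: "+", -1: "-"}.get(self.charge, f"{self.charge:+d}")
        return f"Composition({self.formula()}{sign})"


def mz(comp: Composition) -> float:
    """m/z of a singly charged composition, electron mass included.

    Anions gain one electron mass; cations lose one.
    """
    if abs(comp.charge) != 1:
        raise ValueError(f"m/z defined for |charge| == 1, got {comp.charge}")
    return comp.monoisotopic_mass - comp.charge * ELECTRON_MASS


# ---------------------------------------------------------------------------
# Lipid species
# ---------------------------------------------------------------------------

class Linkage(str, Enum):
    """Chain-to-backbone bond type at a glycerol sn position."""

    ACYL = "acyl"               # ester
    ETHER = "ether"             # O-alkyl (PC-O / PE-O / PI-O)
    VINYL_ETHER = "vinyl_ether"  # O-alkenyl / plasmalogen (PC-P / PE-P)


@dataclass(frozen=True)
class ChainSpec:
    """A fatty chain: carbon count, double bonds, and linkage type.

    ``double_bonds`` counts chain unsaturations only; the vinyl-ether double
    bond of plasmalogens is implied by the linkage and not counted here.
    """

    carbons: int
    double_bonds: int = 0
    linkage: Linkage = Linkage.ACYL

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ValueError(f"chain needs >= 1 carbon, got {self.carbons}")
        if self.double_bonds < 0 or self.double_bonds > self.carbons // 2:
            raise ValueError(
                f"implausible unsaturation {self.carbons}:{self.double_bonds}"
            )


@dataclass(frozen=True)
class SphingoidBase:
    """A dihydroxy (d-type) long-chain sphingoid base such as d18:1."""

    carbons: int = 18
    double_bonds: int = 0
    hydroxyl_count: int = 2

    def __post_init__(self) -> None:
        if self.hydroxyl_count != 2:
            raise ValueError("only d-type (dihydroxy) bases are supported")
        if self.double_bonds < 0 or self.double_bonds > self.carbons // 2:
            raise ValueError(
                f"implausible base d{self.carbons}:{self.double_bonds}"
            )


GLYCEROPHOSPHOLIPID_SUBCLASSES = frozenset(
    {"PC", "PE", "PS", "PI", "PG", "PA",
     "LPC", "LPE", "PC-O", "PC-P", "PE-O", "PE-P", "PI-O"}
)
SPHINGOLIPID_SUBCLASSES = frozenset({"Cer", "SM", "HexCer"})
LYSO_SUBCLASSES = frozenset({"LPC", "LPE"})
ETHER_SUBCLASSES = frozenset({"PC-O", "PC-P", "PE-O", "PE-P", "PI-O"})
SUBCLASSES = GLYCEROPHOSPHOLIPID_SUBCLASSES | SPHINGOLIPID_SUBCLASSES

# Subclasses whose canonical negative-mode precursor is the demethylated ion.
_DEMETHYLATED_SUBCLASSES = frozenset({"PC", "LPC", "PC-O", "PC-P", "SM"})


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid at shorthand resolution: subclass plus chain composition.

    Two representations coexist: *sn-resolved* (individual chains known, the
    slash form ``PC (16:0/18:1)``) and *sum-level* (only totals known,
    ``PE (40:1)``).  For sphingolipids the first "chain" is the sphingoid
    base; sum-level sphingolipid totals include the base carbons.
    """

    subclass: str
    chains: tuple[ChainSpec, ...] = ()
    base: SphingoidBase | None = None
    n_acyl: ChainSpec | None = None
    total_carbons: int | None = None
    total_double_bonds: int | None = None
    sn_resolved: bool = False

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASSES:
            raise ValueError(f"unknown lipid subclass {self.subclass!r}")

    # Constructors -------------------------------------------------------
    @classmethod
    def glycero(cls, subclass: str, sn1: ChainSpec, sn2: ChainSpec | None = None,
                ) -> "LipidSpecies":
        chains = (sn1,) if sn2 is None else (sn1, sn2)
        return cls(subclass=subclass, chains=chains, sn_resolved=True)

    @classmethod
    def sphingo(cls, subclass: str, base: SphingoidBase, n_acyl: ChainSpec,
                ) -> "LipidSpecies":
        return cls(subclass=subclass, base=base, n_acyl=n_acyl, sn_resolved=True)

    @classmethod
    def sum_level(cls, subclass: str, carbons: int, double_bonds: int,
                  ) -> "LipidSpecies":
        return cls(subclass=subclass, total_carbons=carbons,
                   total_double_bonds=double_bonds, sn_resolved=False)

    # Introspection ------------------------------------------------------
    @property
    def is_sphingolipid(self) -> bool:
        return self.subclass in SPHINGOLIPID_SUBCLASSES

    @property
    def is_ether(self) -> bool:
        return self.subclass in ETHER_SUBCLASSES

    @property
    def is_lyso(self) -> bool:
        return self.subclass in LYSO_SUBCLASSES

    @property
    def nc(self) -> int:
        """Total chain carbons (sphingoid base included)."""
        if self.sn_resolved:
            if self.is_sphingolipid:
                assert self.base is not None and self.n_acyl is not None
                return self.base.carbons + self.n_acyl.carbons
            return sum(c.carbons for c in self.chains)
        assert self.total_carbons is not None
        return self.total_carbons

    @property
    def db(self) -> int:
        """Total chain double bonds (vinyl-ether bond excluded)."""
        if self.sn_resolved:
            if self.is_sphingolipid:
                assert self.base is not None and self.n_acyl is not None
                return self.base.double_bonds + self.n_acyl.double_bonds
            return sum(c.double_bonds for c in self.chains)
        assert self.total_double_bonds is not None
        return self.total_double_bonds

    @property
    def name(self) -> str:
        return format_lipid_name(self)

    def to_sum_level(self) -> "LipidSpecies":
        return LipidSpecies.sum_level(self.subclass, self.nc, self.db)

    def __str__(self) -> str:
        return self.name


class LipidNameError(ValueError):
    """Raised when a lipid shorthand name cannot be parsed."""


_NAME_RE = re.compile(r"^\s*([A-Za-z]+(?:-[OP])?)\s*\(\s*([^()]*?)\s*\)\s*$")
_CHAIN_RE = re.compile(r"^(d?)(\d+):(\d+)$")


def _parse_chain_token(token: str, name: str) -> tuple[bool, int, int]:
    m = _CHAIN_RE.match(token.strip())
    if m is None:
        raise LipidNameError(
            f"malformed chain descriptor {token!r} in {name!r}"
        )
    return bool(m.group(1)), int(m.group(2)), int(m.group(3))


def parse_lipid_name(name: str) -> LipidSpecies:
    """Parse shorthand such as ``"PC (16:0/18:1)"`` or ``"Cer (d18:1/16:0)"``.

    Accepts the compact form without a space, en/em-dash variants of the
    ether/plasmalogen suffix ("PE–P"), and sum-level totals ("PE (40:1)",
    "SM (d42:1)").  The ``sn_resolved`` flag is set iff the slash form is
    given (for lyso species the single chain is fully resolved).
    """
    normalized = name.replace("–", "-").replace("—", "-")
    m = _NAME_RE.match(normalized)
    if m is None:
        raise LipidNameError(f"cannot parse lipid name {name!r}")
    subclass, inner = m.group(1), m.group(2)
    if subclass not in SUBCLASSES:
        raise LipidNameError(f"unknown subclass token {subclass!r} in {name!r}")
    tokens = [t for t in inner.split("/")]

    if subclass in SPHINGOLIPID_SUBCLASSES:
        has_d, c0, d0 = _parse_chain_token(tokens[0], name)
        if not has_d:
            raise LipidNameError(
                f"sphingolipid descriptor must start with 'd' in {name!r}"
            )
        if len(tokens) == 1:
            return LipidSpecies.sum_level(subclass, c0, d0)
        if len(tokens) != 2:
            raise LipidNameError(f"expected base/acyl in {name!r}")
        has_d2, c1, d1 = _parse_chain_token(tokens[1], name)
        if has_d2:
            raise LipidNameError(f"unexpected 'd' on N-acyl chain in {name!r}")
        return LipidSpecies.sphingo(
            subclass, SphingoidBase(carbons=c0, double_bonds=d0),
            ChainSpec(c1, d1),
        )

    # Glycerophospholipids
    sn1_linkage = Linkage.ACYL
    if subclass.endswith("-O"):
        sn1_linkage = Linkage.ETHER
    elif subclass.endswith("-P"):
        sn1_linkage = Linkage.VINYL_ETHER
    parsed = []
    for tok in tokens:
        has_d, c, d = _parse_chain_token(tok, name)
        if has_d:
            raise LipidNameError(f"unexpected 'd' prefix in {name!r}")
        parsed.append((c, d))
    if len(parsed) == 1:
        if subclass in LYSO_SUBCLASSES:
            return LipidSpecies.glycero(subclass, ChainSpec(*parsed[0]))
        return LipidSpecies.sum_level(subclass, *parsed[0])
    if len(parsed) != 2:
        raise LipidNameError(f"expected one or two chains in {name!r}")
    sn1 = ChainSpec(parsed[0][0], parsed[0][1], linkage=sn1_linkage)
    sn2 = ChainSpec(parsed[1][0], parsed[1][1])
    return LipidSpecies.glycero(subclass, sn1, sn2)


def format_lipid_name(lipid: LipidSpecies) -> str:
    """Canonical shorthand: subclass, space, parenthesised chain descriptor."""
    if lipid.sn_resolved:
        if lipid.is_sphingolipid:
            assert lipid.base is not None and lipid.n_acyl is not None
            b, a = lipid.base, lipid.n_acyl
            return (f"{lipid.subclass} (d{b.carbons}:{b.double_bonds}"
                    f"/{a.carbons}:{a.double_bonds})")
        chains = "/".join(f"{c.carbons}:{c.double_bonds}" for c in lipid.chains)
        return f"{lipid.subclass} ({chains})"
    d_prefix = "d" if lipid.is_sphingolipid else ""
    return (f"{lipid.subclass} ({d_prefix}{lipid.total_carbons}"
            f":{lipid.total_double_bonds})")


# ---------------------------------------------------------------------------
# Neutral-molecule composition
# ---------------------------------------------------------------------------

_GLYCEROPHOSPHATE_CORE = Composition.from_formula("C3H9O6P")  # glycerophosphoric acid
_WATER = Composition.from_formula("H2O")

# Head-group condensation deltas relative to phosphatidic acid.
_HEAD_DELTA: dict[str, Composition] = {
    "PA": Composition(),
    "PC": Composition.from_formula("C5H11N"),
    "PE": Composition.from_formula("C2H5N"),
    "PG": Composition.from_formula("C3H6O2"),
    "PS": Composition.from_formula("C3H5NO2"),
    "PI": Composition.from_formula("C6H10O5"),
}

# Sphingolipid head deltas relative to the free ceramide.
_SPHINGO_HEAD_DELTA: dict[str, Composition] = {
    "Cer": Composition(),
    "SM": Composition.from_formula("C5H12NO3P"),   # phosphocholine, condensed
    "HexCer": Composition.from_formula("C6H10O5"),  # hexose, glycosidic bond
}


def parent_subclass(subclass: str) -> str:
    """Map ether/plasmalogen/lyso subclasses onto their diacyl head parent."""
    if subclass in ("PC-O", "PC-P", "LPC"):
        return "PC"
    if subclass in ("PE-O", "PE-P", "LPE"):
        return "PE"
    if subclass == "PI-O":
        return "PI"
    return subclass


def _chain_block(chain: ChainSpec) -> Composition:
    """Free-chain composition before condensation (loses H2O on linking).

    Acyl chains enter as fatty acids C_c H_{2c-2d} O2; ether chains as fatty
    alcohols (net +2H, -1O versus acyl); vinyl-ether chains as the alcohol
    with one extra double-bond equivalent (net -1O versus acyl).
    """
    c, d = chain.carbons, chain.double_bonds
    if chain.linkage is Linkage.ACYL:
        return Composition(C=c, H=2 * c - 2 * d, O=2)
    if chain.linkage is Linkage.ETHER:
        return Composition(C=c, H=2 * c + 2 - 2 * d, O=1)
    return Composition(C=c, H=2 * c - 2 * d, O=1)  # vinyl ether


def _sphingoid_block(base: SphingoidBase) -> Composition:
    """Free sphingoid base C_n H_{2n+3-2d} N O2 (d-type: two hydroxyls)."""
    return Composition(C=base.carbons, H=2 * base.carbons + 3 - 2 * base.double_bonds,
                       N=1, O=2)


def composition(lipid: LipidSpecies) -> Composition:
    """Neutral monoisotopic composition of a lipid species.

    Works for both sn-resolved and sum-level species: the hydrogen count of
    a diacyl (or amide-linked) lipid depends only on total carbons and total
    double bonds, so sum-level species are treated as all-acyl.  Ether and
    plasmalogen species require the subclass suffix to carry the linkage.
    """
    sub = lipid.subclass
    if lipid.is_sphingolipid:
        head = _SPHINGO_HEAD_DELTA[sub]
        if lipid.sn_resolved:
            assert lipid.base is not None and lipid.n_acyl is not None
            cer = (_sphingoid_block(lipid.base) + _chain_block(lipid.n_acyl)
                   - _WATER)
        else:
            nc, db = lipid.nc, lipid.db
            cer = Composition(C=nc, H=2 * nc + 1 - 2 * db, N=1, O=3)
        return cer + head

    head = _HEAD_DELTA[parent_subclass(sub)]
    if lipid.sn_resolved:
        chains = lipid.chains
        if sub in ETHER_SUBCLASSES and chains[0].linkage is Linkage.ACYL:
            # tolerate species built without an explicit linkage flag
            link = Linkage.ETHER if sub.endswith("-O") else Linkage.VINYL_ETHER
            chains = (ChainSpec(chains[0].carbons, chains[0].double_bonds, link),
                      *chains[1:])
        body = _GLYCEROPHOSPHATE_CORE + head
        for chain in chains:
            body = body + _chain_block(chain) - _WATER
        return body
    if sub in LYSO_SUBCLASSES:
        raise ValueError(f"lyso species {lipid.name!r} is always chain-resolved")
    nc, db = lipid.nc, lipid.db
    body = _GLYCEROPHOSPHATE_CORE + head
    if sub in ETHER_SUBCLASSES:
        ether = Composition(C=nc, H=2 * nc + 2 - 2 * db, O=1)
        if sub.endswith("-P"):
            ether = Composition(C=nc, H=2 * nc - 2 * db, O=1)
        # one ether chain + one acyl chain share the totals; H depends only
        # on totals once the single linkage correction is applied
        acyl_part = Composition(O=2)
        body = body + ether + acyl_part - 2 * _WATER
        return body
    fatty = Composition(C=nc, H=2 * nc - 2 * db, O=4)
    return body + fatty - 2 * _WATER


# ---------------------------------------------------------------------------
# Ion species
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IonSpecies:
    """A charged species derived from a neutral molecule M.

    ``gain``/``loss`` are composition deltas applied to M; ``charge`` is the
    resulting charge (magnitude 1).
    """

    label: str
    charge: int
    gain: Composition = field(default_factory=Composition)
    loss: Composition = field(default_factory=Composition)

    def apply(self, neutral: Composition) -> Composition:
        if neutral.charge != 0:
            raise ValueError("ion species applies to a neutral composition")
        return (neutral + self.gain - self.loss).replace_charge(self.charge)


ION_SPECIES: dict[str, IonSpecies] = {
    "[M-H]-": IonSpecies("[M-H]-", -1, loss=Composition(H=1)),
    "[M-CH3]-": IonSpecies("[M-CH3]-", -1, loss=Composition(C=1, H=3)),
    "[M+HCOO]-": IonSpecies("[M+HCOO]-", -1, gain=Composition(C=1, H=1, O=2)),
    "[M+CH3COO]-": IonSpecies("[M+CH3COO]-", -1,
                              gain=Composition(C=2, H=3, O=2)),
    "[M+H]+": IonSpecies("[M+H]+", +1, gain=Composition(H=1)),
}


def get_ion_species(label: str) -> IonSpecies:
    key = (label.replace("−", "-").replace("–", "-")
           .replace(" ", ""))
    try:
        return ION_SPECIES[key]
    except KeyError:
        raise ValueError(f"unknown ion species {label!r}") from None


def precursor_ion(subclass: str) -> IonSpecies:
    """Canonical negative-mode precursor: [M-CH3]- for choline-bearing
    subclasses (in-source demethylation), [M-H]- otherwise."""
    if subclass in _DEMETHYLATED_SUBCLASSES:
        return ION_SPECIES["[M-CH3]-"]
    return ION_SPECIES["[M-H]-"]


def ion_mz(comp: Composition, ion: IonSpecies | str | None = None) -> float:
    """m/z of ``comp`` under ``ion``; if ``ion`` is None, ``comp`` must
    already be singly charged."""
    if ion is None:
        return mz(comp)
    if isinstance(ion, str):
        ion = get_ion_species(ion)
    return mz(ion.apply(comp))


# ---------------------------------------------------------------------------
# Brute-force composition search
# ---------------------------------------------------------------------------

_DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "C": (0, 50), "H": (0, 100), "N": (0, 2), "O": (0, 12), "P": (0, 1),
}


def composition_search(
    target_mz: float,
    tolerance_ppm: float = 5.0,
    element_bounds: Mapping[str, tuple[int, int]] | None = None,
    charge: int = -1,
) -> list[tuple[Composition, float]]:
    """Exhaustively enumerate compositions matching a target m/z.

    Returns ``(composition, delta_ppm)`` pairs sorted by ``|delta_ppm|``.
    ``charge`` 0 searches neutral masses (for neutral-loss assignment).
    An empty list is a valid result.  This is deliberately a brute-force
    oracle: it anchors fragment formulas independently of the rule engine.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    bounds = dict(_DEFAULT_BOUNDS)
    if element_bounds:
        for elem, rng in element_bounds.items():
            bounds[elem] = (int(rng[0]), int(rng[1]))
    tol_da = target_mz * tolerance_ppm * 1e-6
    target_mass = target_mz + charge * ELECTRON_MASS  # back to nuclear frame
    elems = [e for e in ("C", "N", "O", "P") if bounds[e][1] > 0]
    h_lo, h_hi = bounds["H"]
    h_mass = ELEMENT_MASS["H"]
    out: list[tuple[Composition, float]] = []
    ranges = [range(bounds[e][0], bounds[e][1] + 1) for e in elems]
    for combo in itertools.product(*ranges):
        heavy = sum(ELEMENT_MASS[e] * n for e, n in zip(elems, combo))
        if heavy > target_mass + tol_da:
            continue
        # closed-form hydrogen count
        n_h = round((target_mass - heavy) / h_mass)
        for h in (n_h - 1, n_h, n_h + 1):
            if h < h_lo or h > h_hi:
                continue
            mass = heavy + h * h_mass
            delta = mass - charge * ELECTRON_MASS - target_mz
            if abs(delta) <= tol_da:
                counts = {e: n for e, n in zip(elems, combo) if n}
                if h:
                    counts["H"] = h
                if not counts:
                    continue
                out.append((Composition(counts, charge=charge),
                            delta / target_mz * 1e6))
    out.sort(key=lambda pair: (abs(pair[1]), pair[0].formula()))
    # deduplicate (the +/-1 hydrogen probe can revisit a solution)
    seen: set[Composition] = set()
    unique = []
    for comp, dppm in out:
        if comp not in seen:
            seen.add(comp)
            unique.append((comp, dppm))
    return unique
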