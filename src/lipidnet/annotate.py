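"""End-to-end lipid annotation.

The annotation of one LC-MS feature proceeds in four steps:

1. *Candidate generation*: enumerate sum-level species (subclass x total
   carbons x total double bonds x ion species) whose theoretical precursor
   m/z falls within the piecewise tolerance (0.005 Da below m/z 500,
   10 ppm above) of the observed precursor.
2. *Rule matching*: for each candidate, try all chain splittings compatible
   with the totals, generate the diagnostic-ion rule set, and count matched
   required ions in the MS/MS spectrum.  The winning splitting fixes the
   chains; relative carboxylate intensities assign sn positions (the major
   regio-isomer only).
3. *Isobar disambiguation*: candidates surviving the ion count are checked
   against the per-subclass retention model (5% relative-error rule) and
   ranked by (matched required ions, precursor mass error, tR error).
   Head-group peaks not explained by the winner are tested against
   co-eluting precursors inside the Q1 selection window (1.0 Th) and
   reported as contamination hypotheses, not annotations.
4. *Confidence*: species present in the authentic-standards library are
   reported at identification level 1, others at level 2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from lipidnet.chem import (
    ChainSpec,
    Linkage,
    LipidSpecies,
    SphingoidBase,
    composition,
    ion_mz,
    parent_subclass,
    precursor_ion,
    ETHER_SUBCLASSES,
    LYSO_SUBCLASSES,
    SPHINGOLIPID_SUBCLASSES,
)
from lipidnet.fragments import RuleSet, diagnostic_ions, sn_intensity_rule
from lipidnet.msio import FeatureTable, Spectrum, link_spectra, mz_tolerance
from lipidnet.rt import RTModel, predict_rt, rt_consistent, RT_TOLERANCE

__all__ = [
    "CandidateSpace", "Candidate", "MatchedIon", "Annotation",
    "ContaminationHypothesis", "generate_candidates", "match_spectrum",
    "disambiguate_isobars", "annotate_dataset",
]

FRAGMENT_TOL = 0.02       # Da, MS/MS peak matching
SELECTION_WINDOW = 1.0    # Th, Q1 precursor co-selection window


@dataclass(frozen=True)
class CandidateSpace:
    """Bounds of the candidate enumeration."""

    subclasses: tuple[str, ...] = (
        "PC", "PE", "PS", "PI", "PG", "PA",
        "PC-O", "PC-P", "PE-O", "PE-P", "PI-O",
        "LPC", "LPE", "Cer", "SM", "HexCer",
    )
    diacyl_carbons: tuple[int, int] = (20, 48)
    diacyl_double_bonds: tuple[int, int] = (0, 8)
    chain_carbons: tuple[int, int] = (10, 26)
    chain_double_bonds: tuple[int, int] = (0, 6)
    lyso_carbons: tuple[int, int] = (10, 26)
    sphingoid_bases: tuple[tuple[int, int], ...] = ((18, 0), (18, 1), (18, 2))
    acyl_carbons: tuple[int, int] = (10, 26)

    def iter_sum_level(self) -> Iterable[tuple[LipidSpecies, str]]:
        """Yield (sum-level species, precursor ion label) combinations."""
        for sub in self.subclasses:
            ion = precursor_ion(sub).label
            if sub in LYSO_SUBCLASSES:
                lo, hi = self.lyso_carbons
                for c in range(lo, hi + 1):
                    for d in range(self.chain_double_bonds[0],
                                   self.chain_double_bonds[1] + 1):
                        if d > c // 2:
                            continue
                        yield LipidSpecies.glycero(sub, ChainSpec(c, d)), ion
            elif sub in SPHINGOLIPID_SUBCLASSES:
                base_carbons = sorted({b for b, _ in self.sphingoid_bases})
                max_base_db = max(d for _, d in self.sphingoid_bases)
                lo, hi = self.acyl_carbons
                for bc in base_carbons:
                    for c in range(bc + lo, bc + hi + 1):
                        for d in range(0, max_base_db
                                       + self.chain_double_bonds[1] + 1):
                            yield LipidSpecies.sum_level(sub, c, d), ion
                    break  # totals depend only on the sum; one base suffices
            else:
                lo, hi = self.diacyl_carbons
                for c in range(lo, hi + 1):
                    for d in range(self.diacyl_double_bonds[0],
                                   self.diacyl_double_bonds[1] + 1):
                        yield LipidSpecies.sum_level(sub, c, d), ion


@dataclass(frozen=True)
class Candidate:
    """A precursor-mass-compatible species hypothesis."""

    lipid: LipidSpecies
    ion: str
    theoretical_mz: float
    dppm: float


@dataclass(frozen=True)
class MatchedIon:
    role: str
    theoretical_mz: float
    observed_mz: float
    intensity: float
    dppm: float
    required: bool


@dataclass(frozen=True)
class ContaminationHypothesis:
    """A co-eluting, co-selected precursor explaining an orphan head ion."""

    species: str
    precursor_mz: float
    delta_th: float
    explained_mz: float
    rt_relative_error: float | None


@dataclass(frozen=True)
class Annotation:
    """The outcome of matching one candidate against one spectrum."""

    candidate: Candidate
    species: LipidSpecies               # resolved if a splitting won
    matched_ions: tuple[MatchedIon, ...]
    n_required_matched: int
    min_required: int
    sn_basis: str | None = None         # evidence behind the sn assignment
    sum_level_fallback: bool = False
    rt_relative_error: float | None = None
    rt_checked: bool = False
    msi_level: int | None = None
    status: str = "accepted"            # accepted | rejected_rt | rejected_ions
    co_annotations: tuple["Annotation", ...] = ()

    @property
    def name(self) -> str:
        return self.species.name

    @property
    def matched_intensity(self) -> float:
        return float(sum(m.intensity for m in self.matched_ions))


# ---------------------------------------------------------------------------
# Candidate generation
# ---------------------------------------------------------------------------

class _CandidateIndex:
    """Sorted-by-m/z table of every species in a candidate space."""

    def __init__(self, space: CandidateSpace) -> None:
        entries = []
        for species, ion in space.iter_sum_level():
            try:
                theo = ion_mz(composition(species), ion)
            except ValueError:
                continue
            entries.append((theo, species, ion))
        entries.sort(key=lambda t: (t[0], t[1].name))
        self.mz = np.array([e[0] for e in entries])
        self.entries = entries

    def query(self, target: float, tol: float) -> list[Candidate]:
        lo = np.searchsorted(self.mz, target - tol, side="left")
        hi = np.searchsorted(self.mz, target + tol, side="right")
        out = []
        for theo, species, ion in self.entries[lo:hi]:
            dppm = (theo - target) / target * 1e6
            out.append(Candidate(lipid=species, ion=ion,
                                 theoretical_mz=theo, dppm=dppm))
        out.sort(key=lambda c: (abs(c.dppm), c.lipid.name))
        return out


_INDEX_CACHE: dict[CandidateSpace, _CandidateIndex] = {}


def _index_for(space: CandidateSpace) -> _CandidateIndex:
    if space not in _INDEX_CACHE:
        _INDEX_CACHE[space] = _CandidateIndex(space)
    return _INDEX_CACHE[space]


def generate_candidates(precursor_mz: float,
                        tolerance: float | None = None,
                        space: CandidateSpace | None = None,
                        ) -> list[Candidate]:
    """Enumerate species whose precursor ion matches the observed m/z.

    ``tolerance`` is absolute (Da); when None the piecewise convention is
    used (0.005 Da below m/z 500, 10 ppm above).  Sorted by |dppm|; an
    empty list is a valid result.
    """
    space = space or CandidateSpace()
    tol = tolerance if tolerance is not None else mz_tolerance(precursor_mz)
    return _index_for(space).query(precursor_mz, tol)


# ---------------------------------------------------------------------------
# Spectrum matching
# ---------------------------------------------------------------------------

def _nearest_peak(spectrum: Spectrum, target: float, tol: float,
                  ) -> tuple[float, float] | None:
    """Most intense peak within ``tol`` of ``target`` or None."""
    lo = np.searchsorted(spectrum.mz, target - tol, side="left")
    hi = np.searchsorted(spectrum.mz, target + tol, side="right")
    if hi <= lo:
        return None
    window = slice(lo, hi)
    best = lo + int(np.argmax(spectrum.intensity[window]))
    return float(spectrum.mz[best]), float(spectrum.intensity[best])


def _match_ruleset(spectrum: Spectrum, ruleset: RuleSet, tol: float,
                   ) -> tuple[list[MatchedIon], int]:
    matched: list[MatchedIon] = []
    n_required = 0
    for ion in ruleset.ions:
        hit = _nearest_peak(spectrum, ion.mz, tol)
        if hit is None:
            continue
        obs, inten = hit
        matched.append(MatchedIon(
            role=ion.role, theoretical_mz=ion.mz, observed_mz=obs,
            intensity=inten, dppm=(obs - ion.mz) / ion.mz * 1e6,
            required=ion.required,
        ))
        if ion.required:
            n_required += 1
    return matched, n_required


def _chain_splittings(space: CandidateSpace, total_c: int, total_d: int,
                      ) -> list[tuple[ChainSpec, ChainSpec]]:
    """Unordered acyl chain pairs summing to the sum-level totals."""
    lo, hi = space.chain_carbons
    dlo, dhi = space.chain_double_bonds
    out = []
    for c1 in range(lo, min(hi, total_c - lo) + 1):
        c2 = total_c - c1
        if c2 < c1 or c2 > hi:
            continue
        for d1 in range(dlo, min(dhi, total_d) + 1):
            d2 = total_d - d1
            if d2 < dlo or d2 > dhi:
                continue
            if d1 > c1 // 2 or d2 > c2 // 2:
                continue
            if c1 == c2 and d1 > d2:
                continue  # unordered duplicate
            out.append((ChainSpec(c1, d1), ChainSpec(c2, d2)))
    return out


def _expansions(candidate: Candidate, space: CandidateSpace,
                ) -> list[LipidSpecies]:
    """sn-resolved species compatible with a sum-level candidate."""
    lipid = candidate.lipid
    if lipid.sn_resolved:
        return [lipid]
    sub = lipid.subclass
    total_c, total_d = lipid.nc, lipid.db
    out: list[LipidSpecies] = []
    if sub in SPHINGOLIPID_SUBCLASSES:
        for bc, bd in space.sphingoid_bases:
            ac, ad = total_c - bc, total_d - bd
            if not (space.acyl_carbons[0] <= ac <= space.acyl_carbons[1]):
                continue
            if ad < 0 or ad > space.chain_double_bonds[1] or ad > ac // 2:
                continue
            out.append(LipidSpecies.sphingo(
                sub, SphingoidBase(bc, bd), ChainSpec(ac, ad)))
        return out
    if sub in ETHER_SUBCLASSES:
        link = Linkage.ETHER if sub.endswith("-O") else Linkage.VINYL_ETHER
        lo, hi = space.chain_carbons
        for c1 in range(lo, hi + 1):        # ether chain is always sn1
            c2 = total_c - c1
            if not (lo <= c2 <= hi):
                continue
            for d1 in range(0, min(space.chain_double_bonds[1], total_d) + 1):
                d2 = total_d - d1
                if d2 < 0 or d2 > space.chain_double_bonds[1]:
                    continue
                if d1 > c1 // 2 or d2 > c2 // 2:
                    continue
                out.append(LipidSpecies.glycero(
                    sub, ChainSpec(c1, d1, link), ChainSpec(c2, d2)))
        return out
    for sn1, sn2 in _chain_splittings(space, total_c, total_d):
        out.append(LipidSpecies.glycero(sub, sn1, sn2))
    return out


def _carboxylate_mz(c: int, d: int) -> float:
    from lipidnet.chem import ELEMENT_MASS, ELECTRON_MASS
    return (12.0 * c + (2 * c - 1 - 2 * d) * ELEMENT_MASS["H"]
            + 2 * ELEMENT_MASS["O"] + ELECTRON_MASS)


def _has_peak(spectrum: Spectrum, target: float, tol: float) -> bool:
    lo = np.searchsorted(spectrum.mz, target - tol, side="left")
    return lo < spectrum.mz.size and spectrum.mz[lo] <= target + tol


def _prefilter(spectrum: Spectrum, species: LipidSpecies, tol: float) -> bool:
    """Cheap chain-evidence check before building a full rule set."""
    if species.is_sphingolipid:
        assert species.n_acyl is not None
        nf, df = species.n_acyl.carbons, species.n_acyl.double_bonds
        from lipidnet.chem import ELEMENT_MASS, ELECTRON_MASS
        # T ion C_{nF+2} H_{2nF+2-2dF} N O^-
        t = (12.0 * (nf + 2) + (2 * nf + 2 - 2 * df) * ELEMENT_MASS["H"]
             + ELEMENT_MASS["N"] + ELEMENT_MASS["O"] + ELECTRON_MASS)
        return _has_peak(spectrum, t, tol)
    acyl = [c for c in species.chains if c.linkage is Linkage.ACYL]
    return all(
        _has_peak(spectrum, _carboxylate_mz(c.carbons, c.double_bonds), tol)
        for c in acyl
    )


def _assign_sn(species: LipidSpecies, matched: Sequence[MatchedIon],
               ) -> tuple[LipidSpecies, str | None]:
    """Orient the chains so the more intense carboxylate sits at the major
    sn position of the subclass; ketene-loss intensities break ties."""
    if species.is_sphingolipid or species.is_lyso or species.is_ether:
        return species, None
    if len(species.chains) != 2 or species.chains[0] == species.chains[1]:
        return species, "identical chains" if len(species.chains) == 2 else None
    rule = sn_intensity_rule(species.subclass)
    by_role = {m.role: m for m in matched}
    c1 = by_role.get("carboxylate_sn1")
    c2 = by_role.get("carboxylate_sn2")
    if c1 is None or c2 is None:
        return species, None
    if c1.intensity == c2.intensity:
        k1 = by_role.get("ketene_loss_sn2")  # losing sn2 keeps sn1: major
        k2 = by_role.get("ketene_loss_sn1")
        if k1 is None or k2 is None or k1.intensity == k2.intensity:
            return species, None
        major_is_current_sn2 = k1.intensity > k2.intensity
        basis = "ketene-loss intensity ordering"
    else:
        major_is_current_sn2 = c2.intensity > c1.intensity
        basis = "carboxylate intensity ordering"
    # current orientation has chains (sn1, sn2); decide whether to swap
    want_major_at_sn2 = rule == "sn2"
    if major_is_current_sn2 != want_major_at_sn2:
        species = LipidSpecies.glycero(species.subclass,
                                       species.chains[1], species.chains[0])
    return species, f"{basis} ({rule} major)"


def match_spectrum(spectrum: Spectrum, candidate: Candidate,
                   fragment_tol: float = FRAGMENT_TOL,
                   space: CandidateSpace | None = None) -> Annotation:
    """Match one candidate against a spectrum, resolving chains and sn.

    All chain splittings of a sum-level candidate are scored by matched
    required ions (ties by total matched intensity); every splitting
    reaching ``min_required`` is kept, the best as the primary annotation
    and the rest as co-annotations (several species co-fragmented under one
    precursor, as in DDA co-selection).  If no splitting reaches the
    threshold but precursor and head-group evidence exist, a sum-level
    annotation is emitted at reduced confidence.
    """
    space = space or CandidateSpace()
    scored: list[tuple[int, float, LipidSpecies, list[MatchedIon]]] = []
    for species in _expansions(candidate, space):
        if not _prefilter(spectrum, species, fragment_tol):
            continue
        ruleset = diagnostic_ions(species)
        matched, n_req = _match_ruleset(spectrum, ruleset, fragment_tol)
        total = sum(m.intensity for m in matched)
        scored.append((n_req, total, species, matched))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2].name))

    min_required = _min_required_for(candidate.lipid.subclass)
    passing = [s for s in scored if s[0] >= min_required]
    if passing:
        annotations = []
        for n_req, _, species, matched in passing:
            oriented, basis = _assign_sn(species, matched)
            if oriented is not species:
                # regenerate the rule set so roles follow the orientation
                matched, n_req = _match_ruleset(
                    spectrum, diagnostic_ions(oriented), fragment_tol)
            annotations.append(Annotation(
                candidate=candidate, species=oriented,
                matched_ions=tuple(matched), n_required_matched=n_req,
                min_required=min_required, sn_basis=basis, status="accepted",
            ))
        primary = annotations[0]
        return replace(primary, co_annotations=tuple(annotations[1:]))

    # sum-level fallback: head-group and precursor evidence without a
    # convincing chain splitting
    ruleset = _headgroup_ruleset(candidate, space)
    matched, n_req = _match_ruleset(spectrum, ruleset, fragment_tol)
    roles = {m.role for m in matched}
    has_head = any(r.startswith("head") or r in
                   ("glycerophosphate", "serine_loss", "hexose_loss")
                   for r in roles)
    if "precursor" in roles and has_head:
        return Annotation(
            candidate=candidate, species=candidate.lipid.to_sum_level()
            if not candidate.lipid.is_lyso else candidate.lipid,
            matched_ions=tuple(matched), n_required_matched=n_req,
            min_required=min_required, sum_level_fallback=True,
            status="accepted",
        )
    best = scored[0] if scored else (0, 0.0, candidate.lipid, [])
    return Annotation(
        candidate=candidate, species=best[2], matched_ions=tuple(best[3]),
        n_required_matched=best[0], min_required=min_required,
        status="rejected_ions",
    )


def _min_required_for(subclass: str) -> int:
    from lipidnet.fragments import MIN_REQUIRED
    return MIN_REQUIRED[subclass]


def _headgroup_ruleset(candidate: Candidate, space: CandidateSpace) -> RuleSet:
    """A representative rule set used to probe head-group evidence only."""
    expansions = _expansions(candidate, space)
    if expansions:
        return diagnostic_ions(expansions[0])
    # no valid splitting inside the space: fabricate a single-split probe
    lipid = candidate.lipid
    half = lipid.nc // 2
    return diagnostic_ions(LipidSpecies.glycero(
        lipid.subclass, ChainSpec(half, 0),
        ChainSpec(lipid.nc - half, lipid.db)))


# ---------------------------------------------------------------------------
# Isobar disambiguation
# ---------------------------------------------------------------------------

def disambiguate_isobars(annotations: Sequence[Annotation],
                         rt_models: Mapping[str, RTModel],
                         observed_rt: float | None,
                         tolerance: float = RT_TOLERANCE,
                         ) -> list[Annotation]:
    """Apply the tR consistency rule and rank the surviving annotations.

    Annotations whose subclass has a fitted model and whose relative tR
    error exceeds ``tolerance`` become ``rejected_rt``; subclasses without
    a model are kept but flagged unchecked.  Survivors are ranked by
    (matched required ions, |precursor dppm|, tR error); rejected
    annotations trail in the returned list.
    """
    checked: list[Annotation] = []
    for ann in annotations:
        model = rt_models.get(ann.species.subclass)
        if model is None or observed_rt is None:
            checked.append(replace(ann, rt_checked=False))
            continue
        ok, err = rt_consistent(model, ann.species, observed_rt, tolerance)
        status = ann.status if ok else "rejected_rt"
        checked.append(replace(ann, rt_checked=True, rt_relative_error=err,
                               status=status))

    def sort_key(a: Annotation):
        rejected = a.status != "accepted"
        rt_err = a.rt_relative_error if a.rt_relative_error is not None else 0.0
        return (rejected, a.sum_level_fallback, -a.n_required_matched,
                abs(a.candidate.dppm), rt_err, a.name)

    return sorted(checked, key=sort_key)


_HEAD_PROBE_SPECIES: dict[str, str] = {
    # representative species per subclass, used to enumerate the subclass's
    # chain-independent (head/backbone) diagnostic m/z values
    "PC": "PC (16:0/18:1)", "PE": "PE (16:0/18:1)", "PS": "PS (16:0/18:1)",
    "PI": "PI (16:0/18:1)", "PG": "PG (16:0/18:1)", "PA": "PA (16:0/18:1)",
    "SM": "SM (d18:1/16:0)",
}
_CHAIN_INDEPENDENT_ROLES = {"head_small", "head_large", "head-H2O",
                            "head-2H2O", "glycerophosphate"}


def contamination_hypotheses(spectrum: Spectrum, accepted: Annotation,
                             rt_models: Mapping[str, RTModel],
                             observed_rt: float | None,
                             space: CandidateSpace | None = None,
                             window: float = SELECTION_WINDOW,
                             fragment_tol: float = FRAGMENT_TOL,
                             ) -> list[ContaminationHypothesis]:
    """Explain orphan head-group ions by co-selected precursors.

    A head-group peak present in the spectrum but foreign to the accepted
    annotation's subclass is attributed, when possible, to a co-eluting
    species whose precursor lies within the Q1 selection window of the
    selected precursor and whose predicted tR matches the observed one.
    """
    from lipidnet.chem import parse_lipid_name

    space = space or CandidateSpace()
    own_roles_mz = {round(m.theoretical_mz, 3) for m in accepted.matched_ions}
    hypotheses: list[ContaminationHypothesis] = []
    seen: set[str] = set()
    for sub, probe_name in _HEAD_PROBE_SPECIES.items():
        if parent_subclass(sub) == parent_subclass(accepted.species.subclass):
            continue
        probe = diagnostic_ions(parse_lipid_name(probe_name))
        for ion in probe.ions:
            if ion.role not in _CHAIN_INDEPENDENT_ROLES:
                continue
            if round(ion.mz, 3) in own_roles_mz:
                continue
            hit = _nearest_peak(spectrum, ion.mz, fragment_tol)
            if hit is None:
                continue
            # an orphan head ion of subclass `sub`: look for a co-selected
            # precursor of that subclass inside the selection window
            cands = generate_candidates(spectrum.precursor_mz,
                                        tolerance=window, space=space)
            for cand in cands:
                if cand.lipid.subclass != sub or cand.lipid.name in seen:
                    continue
                delta = abs(cand.theoretical_mz - spectrum.precursor_mz)
                if delta > window or delta <= mz_tolerance(spectrum.precursor_mz):
                    continue  # inside the window but not the feature itself
                rt_err = None
                model = rt_models.get(sub)
                if model is not None and observed_rt is not None:
                    ok, rt_err = rt_consistent(model, cand.lipid, observed_rt)
                    if not ok:
                        continue
                seen.add(cand.lipid.name)
                hypotheses.append(ContaminationHypothesis(
                    species=cand.lipid.name,
                    precursor_mz=cand.theoretical_mz, delta_th=delta,
                    explained_mz=ion.mz, rt_relative_error=rt_err,
                ))
    hypotheses.sort(key=lambda h: (h.delta_th, h.species))
    return hypotheses


# ---------------------------------------------------------------------------
# Dataset-level annotation
# ---------------------------------------------------------------------------

def annotate_dataset(table: FeatureTable, spectra: Sequence[Spectrum],
                     standards_library: Iterable[str] | None = None,
                     rt_models: Mapping[str, RTModel] | None = None,
                     space: CandidateSpace | None = None,
                     fragment_tol: float = FRAGMENT_TOL,
                     rt_tolerance: float = RT_TOLERANCE) -> pd.DataFrame:
    """Annotate every feature of a dataset; returns an audit table.

    ``standards_library`` is a collection of shorthand names of authentic
    standards; accepted annotations found there are level 1, the others
    level 2.  Features without linked spectra or without an accepted
    annotation appear with empty annotation columns.
    """
    rt_models = rt_models or {}
    space = space or CandidateSpace()
    library = {str(n) for n in (standards_library or ())}
    if not table.spectrum_ids or not any(table.spectrum_ids.values()):
        table = link_spectra(table, spectra)
    by_id = {s.id: s for s in spectra}

    rows = []
    for _, feat in table.df.iterrows():
        fid = str(feat["feature_id"])
        row: dict = {"feature_id": fid, "mz": feat["mz"], "rt": feat["rt"],
                     "annotation": None, "subclass": None, "ion": None,
                     "theoretical_mz": None, "dppm": None,
                     "n_required_matched": None, "min_required": None,
                     "sn_basis": None, "sum_level": None,
                     "rt_checked": None, "rt_relative_error": None,
                     "msi_level": None, "status": "no_spectrum",
                     "matched_roles": None, "co_annotations": None,
                     "contamination": None}
        linked = [by_id[sid] for sid in table.spectrum_ids.get(fid, ())
                  if sid in by_id]
        linked = [s for s in linked if s.is_usable]
        if not linked:
            rows.append(row)
            continue
        # most informative spectrum: largest total ion current
        spectrum = max(linked, key=lambda s: (s.intensity.sum(), s.id))
        observed_rt = feat["rt"] if not pd.isna(feat["rt"]) else spectrum.rt

        candidates = generate_candidates(feat["mz"], space=space)
        annotations = [match_spectrum(spectrum, c, fragment_tol, space)
                       for c in candidates]
        ranked = disambiguate_isobars(annotations, rt_models, observed_rt,
                                      rt_tolerance)
        accepted = [a for a in ranked if a.status == "accepted"]
        if not accepted:
            row["status"] = ("rejected_rt" if any(
                a.status == "rejected_rt" for a in ranked) else "rejected_ions")
            rows.append(row)
            continue
        best = accepted[0]
        level = 1 if best.name in library else 2
        contamination = contamination_hypotheses(
            spectrum, best, rt_models, observed_rt, space,
            fragment_tol=fragment_tol)
        row.update({
            "annotation": best.name,
            "subclass": best.species.subclass,
            "ion": best.candidate.ion,
            "theoretical_mz": best.candidate.theoretical_mz,
            "dppm": best.candidate.dppm,
            "n_required_matched": best.n_required_matched,
            "min_required": best.min_required,
            "sn_basis": best.sn_basis,
            "sum_level": bool(best.sum_level_fallback
                              or not best.species.sn_resolved),
            "rt_checked": best.rt_checked,
            "rt_relative_error": best.rt_relative_error,
            "msi_level": level,
            "status": "accepted",
            "matched_roles": ";".join(m.role for m in best.matched_ions),
            "co_annotations": ";".join(a.name for a in best.co_annotations),
            "contamination": ";".join(h.species for h in contamination),
        })
        rows.append(row)
    return pd.DataFrame(rows)
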