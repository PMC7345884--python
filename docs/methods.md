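# Methods

This note documents the models, conventions and numerical choices behind
`lipidnet`, and what the synthetic datasets do and do not establish.

## Mass arithmetic

All masses are monoisotopic, from IUPAC atomic masses (C = 12 exactly,
H = 1.0078250319, N = 14.0030740, O = 15.9949146, P = 30.9737615 Da).
Ion *m/z* includes the electron mass (0.000548579909 Da): anions gain one
electron, cations lose one.  Reference head-group values (e.g.
glycerophosphate 152.9958, phosphocholine cation 184.0733) match this
convention to well under 1 ppm; rule-engine output is compared to
experimental literature values at 10 ppm, the mass accuracy of the Q-TOF
class of instrument those values come from.  Isotope patterns are not
modeled.

Neutral lipid compositions are assembled from structural blocks:
glycerophosphoric acid (C3H9O6P) plus a head-group condensation delta
(choline +C5H11N, ethanolamine +C2H5N, glycerol +C3H6O2, serine +C3H5NO2,
inositol +C6H10O5) plus per-chain blocks condensed with loss of water —
fatty acids C_cH_{2c−2d}O2 for ester linkages, fatty alcohols (net +2H,
−1O) for ethers, and the alcohol with one extra double-bond equivalent for
vinyl ethers (plasmalogens).  Sphingolipids are a d-type (dihydroxy)
sphingoid base C_nH_{2n+3−2d}NO2 amide-linked to a fatty acid, plus
phosphocholine (SM) or a hexose (HexCer).  Because the hydrogen count of an
all-acyl species depends only on chain totals, sum-level species
("PE (40:1)") get exact compositions without knowing the splitting.

One printed literature value disagrees with its own formula: a serine
neutral loss quoted as 87.0326 Da, where C3H5NO2 computes to 87.0320.  The
computed value is used throughout.

## Fragmentation rules

Rule sets describe the collision-energy-ramp (20–40 eV) DDA spectrum of
the canonical negative-mode precursor; collision-energy dependence is not
modeled.  Required-ion counts: 6 for diacyl PC/PE and Cer (the
six-diagnostic-ion convention), 4 for PS/PI/PA/PG and ether/plasmalogen
species, 3 for lyso species, SM and HexCer.  Where the literature does not
itemize a subclass's full ion list, the required set is the head/backbone
ions plus the available chain ions; the counts are config-exposed
(`lipidnet.fragments.MIN_REQUIRED`).

The ceramide S/T/U/Q/P fragment compositions were fixed by exhaustive
formula search (`composition_search`) against observed ceramide fragment
masses and generalized by chain arithmetic:
S = C_{nF+2}H_{2nF+2−2dF}NO2⁻, T = S − O, U = C_{nF}H_{2nF−2dF}NO⁻ from
the N-acyl chain; Q = C_{nB}H_{2nB−3−2dB}O⁻ and P = Q − C2H2 from the
base.  This is derived, not quoted, chemistry.

The *sn* assignment is ordinal only and names the **major regio-isomer**:
a minor fraction of the opposite isomer is indistinguishable without
authentic regio-pure standards.

## Modified cosine and networking

Peaks are weighted by the square root of intensity and L2-normalized per
spectrum (the common molecular-networking convention; the weighting is
config-visible in the tests).  Candidate peak pairs match directly
(|Δm/z| ≤ 0.02 Da) or after shifting by the precursor mass difference (the
neutral-loss channel, switchable via `NetworkParams.use_shift`).  The
one-to-one assignment maximizing the summed weight products is solved
**exactly** as a maximum-weight bipartite matching
(`scipy.optimize.linear_sum_assignment`) rather than greedily: the score
is then provably the optimum over assignments, which the test suite
verifies against an independent backtracking oracle on small spectra and
cross-checks against the greedy matchms implementation on conflict-free
spectra (where the two coincide).

Network topology: edges require cosine strictly above 0.60 **and** ≥ 6
matched peaks; an edge survives only if each endpoint ranks the other
within its top-100 neighbors by cosine (ties broken by higher cosine, then
lexicographic node id); components smaller than 2 nodes are removed.  The
graph is undirected; several adducts of one compound may legitimately form
several nodes.

## Retention model

ECN = NC − k·DB with NC all chain carbons (sphingoid base included) and DB
chain double bonds only — the vinyl-ether bond of plasmalogens is a
linkage feature, not a chain unsaturation, and is never counted.  k is
fitted by grid search over [0.5, 3.0] in steps of 0.01; each k gets a
least-squares fit of t_R = f(ECN) and the smallest residual sum of squares
wins (ties resolve to the smaller k, so refits are deterministic and
order-invariant).  Phospholipid subclasses use a straight line; for
sphingolipid subclasses the lowest polynomial degree (1–3) whose R²
exceeds 0.99 is retained — degree 2 for quadratic-shaped series, degree 1
for linear ones under the same parsimony rule.  Degree is capped at 3
because subclasses are calibrated with 4–13 standards.  Subclass models
are independent; no pooling across head groups.

Annotation support uses a relative-error test,
|observed − predicted| / predicted ≤ 5%, the empirical envelope of
calibrant residuals in the chromatographic regime this models.

## Annotation pipeline

Candidates are enumerated per feature over subclass × total carbons
(20–48 diacyl, 10–26 per chain and for lyso species, d18:0/1/2 bases with
C10–26 N-acyls) × total double bonds (0–8) × the canonical precursor ion,
within a piecewise precursor tolerance of 0.005 Da below *m/z* 500 and
10 ppm above (the same convention links MS/MS spectra to features, with a
0.1 min retention tolerance).  Formate/acetate adducts are modeled as ion
species but not enumerated as candidates by default; the simulator emits
canonical precursors only.

Each sum-level candidate is expanded into chain splittings; a cheap
prefilter (are both carboxylates — or the fatty-amide T ion — present?)
skips hopeless splittings before the full rule set is built.  Splittings
are scored by matched required ions, ties by total matched intensity;
every splitting reaching the subclass minimum is kept — the best as the
primary annotation, the rest as co-annotations (DDA co-selection routinely
fragments two species under one precursor).  If no splitting passes but
precursor and head-group ions match, a sum-level annotation is emitted at
reduced confidence.  Ranking across candidates is
(required ions matched, |precursor Δppm|, t_R error); this tie-break order
is a design choice standing in for expert inspection.  Orphan head-group
ions are attributed to co-selected precursors within the 1.0 Th isolation
window when a retention-consistent species of the head's subclass exists
there, and reported as contamination hypotheses, never annotations.

Identification confidence: level 1 when the accepted species is in the
authentic-standards library (m/z + MS/MS + t_R all matched), level 2
otherwise.

## Synthetic data

The generator emulates the *information content* of DDA negative-mode
spectra, not their physics: every rule-set ion is present with an ordinal
base intensity, the major-position chain fragment is `sn_ratio` (default
3:1) times the minor one, and noise consists of Gaussian m/z jitter
(default 3 ppm, 1σ), multiplicative lognormal intensity noise (CV 0.2),
Gaussian retention jitter (0.02 min), and uniform-random noise peaks
(5 per spectrum, ≤ 8% of the base peak).  Retention truths are linear
(phospholipids) or quadratic (sphingolipids) in ECN; the PE k of 1.25
follows the refitted literature value for that subclass, all other k
values and every coefficient are invented for simulation.  Subclass
intercepts order elution as PI < PG < PS < PC < PE for shared chains, lyso
species elute early, and ether/plasmalogen variants slightly after their
diacyl parent — the separation that lets the 5% retention rule
discriminate an O-alkyl from a vinyl-ether explanation of the same
formula.

The 65-standard mixture (9 subclasses: 13 PC, 11 PE, 6 PS, 6 PI, 6 PG,
5 PA, 8 Cer, 6 SM, 4 HexCer) is a synthetic reconstruction of a commercial
standard kit, spreading chain length and unsaturation per subclass; the
150-species cell panel adds ether, plasmalogen and lyso subclasses.  The
co-selection scenario places a second PE and a demethylated sphingomyelin
inside the 1.0 Th window of a selected PE precursor, with retention truths
positioned so the observed t_R sits at prescribed relative errors (7% for
the isobaric PC decoy, 0.3% for the retained annotations) from the fitted
models — the scenario is parameterized by those published margins.

**What passing tests show — and don't.**  Because simulated spectra are
generated from the same rule sets the annotator matches, closed-loop
recovery demonstrates internal consistency, determinism, and the isobar /
co-selection logic; it does not demonstrate robustness to real-instrument
effects the generator omits (peak-shape and centroiding artifacts,
intensity-dependent mass error, in-source fragmentation beyond
demethylation, chimeric spectra denser than the configured scenarios,
matrix-dependent retention drift).

## Problem sizes and numerical notes

Default test and acceptance runs use the 65-standard mixture and a
150-species panel — the scale of a typical phospholipid/sphingolipid
annotation campaign — with 1000 random spectrum pairs (≤ 12 peaks) for the
assignment-oracle comparison.  Oracle agreement is asserted at 1e−9;
noiseless model recovery at 1e−6 on coefficients and one grid step (0.01)
on k.  Degenerate inputs: empty spectra are rejected by the cosine and
flagged unusable by I/O; all-equal-ECN calibration panels raise; compositions
never go negative (subtraction is checked element-wise).
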