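# Methods

This note documents the models, conventions and numerical choices behind
`ccsscreen`, and what its synthetic-data tests do and do not establish.

## Exact masses and ion species

All masses derive from a monoisotopic element mass table pinned in
`ccsscreen.chem` (IUPAC/CIAAW lightest-isotope values, ≥9 decimal places,
for C, H, N, O, P, S, F, Cl, Br, Si). The table is never read from the
environment, so results are bit-stable.

GC-APCI in positive mode produces two quasi-molecular species depending on
source humidity: the radical molecular cation M⁺• under dry (charge
transfer) conditions and the protonated molecule [M+H]⁺ under wet (proton
transfer) conditions, plus in-source fragment cations. m/z conventions are
explicit about the electron:

* M⁺• : (M − m_e)/z, with m_e = 0.000548580 Da;
* [M+H]⁺ : (M + m_p)/z, with m_p = 1.007276466 Da (the proton mass already
  excludes the electron);
* fragments: odd-electron cation (M − m_e)/z by default, protonated
  even-electron fragment on request (per-fragment flag).

Only z = 1 occurs in this application; the charge divisor is the documented
extension point. Published 5-decimal library m/z values agree with these
conventions to 1e-5 Da.

One lock-mass caveat: the value 223.06365 is described in the source
literature as the hexamethylcyclotrisiloxane "molecular ion", but
arithmetically it is the protonated molecule (C6H18O3Si3 + H⁺ = 223.06365;
the radical cation would be 222.05582). The package computes it as
protonated. The companion siloxane value 355.06693 matches neither species
of decamethylcyclopentasiloxane (C10H30O5Si5) and is not used as an anchor.

## TWIMS calibration

Travelling-wave IMS has no first-principles drift-time→CCS relation;
vendor calibrations are proprietary. The package implements the standard
published protocol as a stand-in, chosen because it is the de-facto
community procedure and is exactly invertible (which the simulator needs):

1. corrected drift time t′d = td − c·√(m/z)/1000, where c (the EDC/transit
   delay coefficient, default 1.4 in examples) is a fixed instrument
   configuration input, not a fitted parameter — fitting it would turn a
   stable linear problem into a 3-parameter nonlinear one for no gain;
2. charge/reduced-mass scaling Ω′ = Ω·√μ/z with μ = m·M_gas/(m+M_gas),
   drift gas N₂ (28.00615 Da) by default, configurable;
3. least-squares straight-line fit of ln Ω′ against ln t′d over ≥3
   calibrants; A = exp(intercept), B = slope. Per-calibrant relative
   residuals are kept on the model as a fit diagnostic.

Decoding: Ω = A·t′d^B·z/√μ; encoding is the algebraic inverse. Round trips
are identities to better than 1e-9 relative; a noise-free fit recovers
generating parameters to 1e-6 relative. Because no calibrant identities or
fit quality are published for the instrument this emulates, only
self-consistency and printed-value round trips are claimable — no numeric
agreement with any vendor calibration.

Degenerate inputs: <3 calibrants, or all corrected drift times equal,
raise; a non-positive corrected drift time is a calibration-domain error.

## Library construction and ΔCCS conventions

Library CCS values are the mean of triplicate injections at two
concentration levels (six values); when the low level gives no signal, the
three high-level values are used. %RSD uses the sample (n−1) standard
deviation — the right estimator at n = 3–6. Which ion species represents a
compound in the dry or wet list is declared library input; a helper picks
the species with the highest median intensity for builders who have raw
intensities, but sensitivity selection on real data is qualitative.

ΔCCS% denominators are fixed per use (the bound verdicts at 2% are
insensitive to the choice at these magnitudes, but a convention must be
stated):

* screening error: (observed − library)/library × 100 — the reference
  standard is the denominator;
* inter-species delta: (CCS[M+H]⁺ − CCS M⁺•)/CCS M⁺• × 100, signed; |Δ|>2%
  flags compounds that a merged dry/wet CCS database cannot serve;
* isomer pairs: |Δ|/min(CCS) × 100, symmetric; discriminable ⟺ Δ > 2%,
  mirroring the screening CCS tolerance (instrument resolving-power
  modelling is out of scope);
* cross-library comparison: (a − b)/b × 100 with buckets |Δ|<1, 1–2, >2.

The bundled `reference_library()` holds the published CCS/species/mode
values for quintozene, TOTP/TMTP/TPTP, endrin, dieldrin, aldrin and
isodrin. Retention times are published only for the tolyl phosphates; the
others carry plausible synthetic DB-5 values, and the fragment lists are
synthetic placeholders — neither ever backs a numeric assertion. The
endrin/dieldrin dry-condition CCS order inverts the wet-condition order;
the values are stored as printed, without interpretation.

## Drift-time alignment

HDMSᴱ acquisition alternates LE and HE functions; fragmentation occurs
after the mobility cell, so fragments inherit the precursor drift time.
Alignment assigns each HE feature to every LE precursor whose windows it
satisfies: |Δdt| ≤ 0.2 ms (published value) and |Δrt| ≤ 0.05 min. The RT
co-elution width is not published; 0.05 min — half the identification RT
tolerance — is the documented assumption, generous against the 0.25 s scan
time. Windows are symmetric and boundary-inclusive (≤); whether the
original processing used one-sided windows is unknown.

Fragments inside several precursor windows are multiply assigned and
flagged `ambiguous_fragment` rather than winner-takes-all: overlapping
precursor chemistry is real, and screening re-scores fragments per
candidate. An assigned ion at or above its precursor m/z is kept but
flagged. Two co-formed species of one compound are considered resolved when
their drift times differ by more than twice the alignment tolerance
(disjoint windows ⇒ provably disjoint fragment sets); at or below that
separation a single merged spectrum flagged `unresolved_species` is
returned, boundary counted unresolved. Features arrive centroided; profile
peak picking and mobility peak-shape deconvolution are out of scope.

## Screening

Identification criteria: precursor mass error < 5 ppm (vs the m/z computed
from the entry formula), RT deviation < 0.1 min, CCS deviation < 2%, plus
fragment evidence. All comparisons are strict (<) because the criteria are
stated as strict bounds; an error exactly at the bound fails.

Level lattice (only level 1 is defined in the source workflow; 2–3 are this
package's documented conventions): level 1 — all three precursor criteria
and ≥1 expected fragment within 5 ppm; level 2 — precursor criteria met,
fragment absent or only matched in the relaxed band (within 4× the mass
tolerance), the latter flagged `fragment_mass_out_of_tolerance` and kept as
a reportable positive rather than rejected — with CCS inside 2% such hits
were treated as positives in practice; level 3 — no usable RT (suspect
mode), mass and CCS within tolerance. Dry and wet screenings are separate
runs against the matching library mode; a mode mix-up raises.

Ranking of multiple candidates per feature (unspecified in the source): the
normalized error sum Σ|error|/tolerance over the three axes, ties broken by
matched-fragment count then compound name — output ordering is fully
deterministic and input-order invariant.

## Synthetic acquisitions

`simulate_sample` builds one LE precursor per spiked library entry at its
library RT and m/z, with drift time = ccs_to_dt(library CCS), and HE
fragments sharing that drift time; matrix interference adds unrelated
features at a constant rate per minute per function, uniform in m/z and
drift time over stated ranges. All randomness flows from one seed.

Noise defaults: 1 ppm m/z (per feature), 0.02 min RT, 0.3% CCS (per
feature, propagated to drift time through the calibration). These sit
inside the published precision envelope of the technique (CCS %RSD under
0.3% for ≥87% of species, under 0.5% for 99%) while stressing the tolerance
logic, and every window is ≥5 standard deviations wide. RT jitter is drawn
once per chromatographic peak and shared by the precursor and its
fragments: they are a single eluting peak, so their apex RT is common —
modelling fragment RT independently would fabricate a co-elution failure
mode the instrument does not have. Intensities are log-normal and cosmetic
(screening uses them only as thresholds). Fragment m/z values come from the
entry's fragment specs, else fixed fractions (0.7, 0.45) of the precursor
m/z — fragmentation chemistry is not modelled.

The optional matrix exclusion margin re-draws matrix peaks that land within
k identification tolerances of any spiked coordinate, giving oracle tests a
guaranteed matrix/truth separation.

What a green simulation test establishes: the pipeline's window logic,
calibration algebra, and tolerance/level decisions are correct, and under
the stated noise the level-1 recovery of spiked compounds is ≥95% with 50
matrix peaks/min. What it does not establish: performance on real
chromatograms (peak shape, co-elution structure, ionization suppression,
real fragmentation), or any of the published real-sample headline numbers
(74 positives in 12 samples; 77% of 135 dual-species compounds within 2%;
precision percentages over 264 compounds) — those need the unavailable raw
data and full supplementary tables, and are replaced here by the
property-based suites.

## Known limitations

* Single-charge ions only; adducts beyond protonation are out of scope.
* The calibration stand-in cannot be validated against vendor output.
* The bundled reference set is the printed subset (7 compounds, 13
  entries), not the full 264-compound library.
* Isotope-pattern scoring, quantification and nontarget annotation are out
  of scope.
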