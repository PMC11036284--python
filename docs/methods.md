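# Methods

`adcmapper` implements a middle-down workflow for localizing lysine-linked
drug payloads on antibody–drug conjugates (ADCs) such as
trastuzumab-emtansine (T-DM1). The drug-linker (DM1 via an MCC linker) is
modelled as a rigid +956.364 Da monoisotopic mass delta on lysine side chains
and chain N-termini; its elemental composition (C47H61ClN4O13S) is kept for
isotope-aware calculations. This note records the models, the numerical
choices, and the limits of what the synthetic tests demonstrate.

## Candidate generation (limited Lys-C digestion)

Limited proteolysis with Lys-C produces large (middle-down) peptides whose
boundaries obey Lys-C specificity — cleavage C-terminal to lysine — with any
number of missed cleavages. The candidate space is therefore every substring
of a chain that starts at position 1 or immediately after a lysine and ends
at a lysine or the chain C-terminus, optionally restricted by a mass window
(default 0.5–20 kDa before payload placement). Payloads are placed
combinatorially on the internal lysines of a peptide, plus the chain
N-terminus for the chain's first peptide, with up to two payloads per
peptide by default (larger combinations are configurable but were not needed:
with an average drug-to-antibody ratio near 3.5 spread over 92 sites, three
payloads on one peptide is rare).

Two deliberate modelling choices:

* **Cleaved C-terminal lysines carry no payload by default.** Lys-C cleavage
  after a conjugated lysine is assumed blocked, so a peptide whose C-terminal
  residue is a cleavage-generated lysine cannot be conjugated there. The flag
  `allow_cterm_K` includes such placements for users who disagree.
* **No proline or other cleavage-suppression rules**: plain Lys-C
  specificity.

Coordinates are 1-based and inclusive; the chain N-terminus is the sentinel
`N_TERM` (0), never "residue 0".

The packaged reference antibody is the public trastuzumab sequence pair: the
heavy chain in its mature des-Lys form (449 aa, 31 lysines — C-terminal
lysine clipping is essentially complete in mature IgG1) and the 214-aa kappa
light chain (13 lysines). Over two copies of each chain this yields
2×(31+1) + 2×(13+1) = 92 candidate conjugation sites.

## Fragment chemistry

Nine terminal ion types are supported with fixed neutral offsets from the
fragment residue-mass sum: b (0), a (−CO), a+1 (a+H), c (+NH3) on the
N-terminal side; y (+H2O), y−1 (y−H), z, x (y+CO−H2), x+1 (x+H) on the
C-terminal side. Activation schemes map to ion-type sets: HCD → b/y,
EThcD → b/y/c/z, UVPD → all nine.

The **z ion is the z-radical** (z• = y − 16.018724 Da) by default — the
species ETD-type engines match — with the even-electron convention
(y − 17.026549) available via `z_radical=False`. Under the even-electron
convention c_i + z_(N−i) equals the precursor mass exactly; under the
radical default the sum is exactly one hydrogen (1.007825 Da) above it. The
a+1/x+1/y−1 satellites are implemented as ±1.007825 Da hydrogen shifts.

**Payloads are all-or-nothing**: a fragment carries the full +956.364 Da for
every conjugation site inside the residue interval it covers, and
partial-payload masses are never generated (payload internal fragmentation
in EThcD/UVPD is not modelled; in HCD the payload is treated as lost from
backbone fragments entirely).

## Spectra, reporters and scan pairing

Runs are centroided mzML. Reading and writing use a compact lxml layer
(non-indexed mzML, uncompressed 64-bit arrays) that round-trips peak lists
and scan metadata losslessly; MGF is available for small plain-text
fixtures. Profile-mode data is rejected with a message advising centroiding.

The acquisition logic modelled: low-resolution HCD screening scans release
payload reporter ions (m/z 453.19, 485.22, 547.22); detection of the trigger
reporter (547.22, within 20 ppm and at least 1% of the base peak — the
tolerance is not instrument-documented, so both knobs are configurable)
fires a high-resolution EThcD or UVPD scan on the same precursor. Pairing
links each triggered scan to the nearest preceding HCD scan with a matching
precursor (10 ppm, equal charge when both are annotated) whose trigger
fired, within a 5 s retention-time window; unmatched triggered scans are
reported as orphans rather than guessed.

## Deconvolution

High-resolution scans are reduced to neutral monoisotopic masses by
averagine envelope fitting. Aggregated isotope distributions are computed by
per-element polynomial convolution (abundances from the NIST table shipped
with pyteomics), scaled to the averagine pseudo-residue
(C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 per 111.1254 Da).

Extraction is greedy from the most intense unconsumed peak. For each
candidate charge (preferring charges implied by the observed neighbour
spacing, with a full charge scan as fallback) and each monoisotopic
alignment within ±2 isotopes of the theoretical apex, observed peaks on the
isotope grid (spacing 1.00286/z) are compared with the theoretical
distribution. The acceptance thresholds follow the published settings —
fit ≥ 0.80, remainder ≤ 0.25, S/N ≥ 3 — with these definitions, which are a
documented approximation of the vendor algorithm (whose exact mathematical
definitions are proprietary):

* *fit*: cosine between observed and theoretical envelope intensities;
* *remainder*: fraction of theoretical envelope intensity at grid slots with
  no observed peak;
* *S/N*: seed intensity over an iterated-MAD noise floor of the surrounding
  100-Th window (outlying signal peaks are stripped before the MAD is
  taken); windows with fewer than five non-envelope peaks are treated as
  noiseless.

The monoisotopic m/z is refined as the intensity-weighted mean over matched
peaks, so masses are recovered to well under 5 ppm even when the
monoisotopic peak itself is below the detection threshold (as it is above
~15 kDa). ±1 Da misassignments that survive are absorbed downstream by the
2.2 Da precursor tolerance, mirroring the published search settings.

## Matching and localization

Matching is charge-agnostic, in neutral-mass space. Candidates within
2.2 Da (absolute) of the precursor neutral mass are scored by greedy
minimal-ppm fragment assignment at 10 ppm, one observed mass per theoretical
fragment; matches are ranked by matched-fragment count, then sequence
coverage (fraction of the N−1 backbone bonds with ≥1 matched fragment), then
absolute precursor error. Co-ranked top candidates are flagged `co_top`
rather than arbitrarily broken. Payload-bearing proteoforms must be matched
in at least 3 of 5 replicates; unmodified peptides are exempt.

Localization rests on **bracketing fragments**: matched fragments from
backbone cleavages between a payload site and its nearest neighbouring
candidate site on either flank, whose payload count proves on which side of
the cleavage the payload sits. When a flank has no candidate neighbour the
flank extends to the peptide terminus. A site call is **unambiguous** when
at least two bracketing fragments pin it — the consistent-site range
collapses to the site itself — in at least two replicates ("multiple
replicates" is quantified as ≥2, configurable; the explicit 3-of-5 isomer
rule suggests 2 is the floor). An alternative placement is ruled out only
when **at least two** matched fragments contradict it; a lone discordant
fragment (spurious match, or a genuine conflict like one payload-bearing and
one payload-free fragment across the same interval) leaves the range open.
**Co-eluting positional isomers** (same peptide, same payload count,
retention apexes within 0.2 min) are each called only with ≥4 matched
fragments whose masses theoretically discriminate the two placements, in ≥3
of 5 replicates; the gate applies per peptide species, so a site
independently pinned by a different peptide is unaffected. Payloads that
cannot be pinned are reported on the smallest lysine range consistent with
the matched fragments. EThcD and UVPD evidence is pooled for calls and
retained per method.

The census counts unique unambiguous positions per chain role and multiplies
by chain copy number for per-antibody totals (19 heavy + 4 light unique
positions over two copies each would give 46 per-antibody sites).
HCD scans are used for screening only and contribute no localization
evidence. As a confidence layer the package provides shuffled-sequence decoy
proteoforms for FDR estimation; this is a stand-in for the original
engine's confidence scoring, which is not replicated.

## Synthetic data generator

The generator emulates the study conditions so every stage is testable
without instrument data: a conjugated antibody population with
Poisson-distributed payload counts (mean DAR 3.5) drawn over the 92 sites
(uniform weights by default), one partial Lys-C digest of that population
(per-molecule cleavage probability 0.5 at unconjugated lysines; conjugated
lysines never cut) shared by all technical replicates, and a per-replicate
DDA loop: MS1 survey scans with averagine-shaped envelopes, top-5 selection
with dynamic exclusion (2 repeats / 7 s window / 30 s duration), HCD scans
in which conjugated precursors carry the three reporters at 50–100% of the
precursor intensity plus payload-stripped b/y fragments, and
reporter-triggered UVPD (or EThcD) scans whose fragments retain payloads.

Choices a reader should know:

* **Fragment detection probability 0.6** per theoretical fragment, capped at
  250 envelopes per scan by simulated intensity — this lands sequence
  coverages in the 40–80% band typical of real middle-down spectra.
* **Retention model**: peptide-specific base elution time, +0.8 min per
  payload (so payload states elute in order), ±0.4 min positional-isomer
  offsets, Gaussian peaks (σ = 0.06 min), 0.02 min replicate jitter.
* **Adjacent-lysine ambiguity** is emulated by a cleavage-suppression list
  (default: the heavy-chain K412/K417 pair): triggered scans of species with
  a payload on either site omit fragments from cleavages between them,
  reproducing the situation where the payload can only be localized to the
  pair.
* **Precursor monoisotopic errors**: with probability 0.1 the annotated
  precursor m/z is shifted by ±1 isotope, exercising the 2.2 Da tolerance.
* **Noise**: 1.5 ppm m/z jitter, 5% intensity CV, 30 spurious low-intensity
  peaks per scan.
* **Population size** defaults to 12 molecules per simulated sample — enough
  to plant ~40 payload events across ~25–35 distinct sites while keeping a
  5-replicate experiment (~7,000 scans) analysable in a couple of minutes on
  one CPU. Seeded runs are byte-identical.

The generator's ground truth records the molecules, every distinct digest
species, all trigger events, and the *recoverable* census: a planted site is
expected unambiguous when some species carrying it (with ≤2 payloads and
with discriminating cleavages not suppressed) was triggered in ≥3
replicates; sites observed only in suppressed adjacent-lysine contexts are
expected as ambiguous ranges.

What the synthetic data does **not** emulate — and hence what passing tests
do not show about real data: chimeric/co-isolated spectra, real isotope
structures of payload-bearing fragments (envelopes are averagine-shaped, so
deconvolution is not stressed by the payload's Cl/S isotopes), electron-
transfer charge-reduction artefacts, internal fragments and neutral losses,
ionization-efficiency differences between species, and retention-time
behaviour beyond simple bookkeeping. Glycoforms, other PTMs and disulfide
connectivity are out of scope throughout.

## Worked-example isotopology

Extracted-ion-chromatogram targets for large peptides are most-abundant-
isotopologue m/z values, not monoisotopic ones. `apex_mz` computes them from
the averagine envelope of the peptide part convolved with the exact
elemental composition of the payloads (whose chlorine and sulfur shift the
apex right by 1–2 isotopes at two payloads). For the 101-residue heavy-chain
peptide A342–K442 at 8+ this gives 1443.33 / 1563.00 / 1682.68 for 0/1/2
payloads; the spacing of the *monoisotopic* 8+ states is exactly
956.364/8 = 119.5455. At ~12.5 kDa the theoretical envelope is nearly flat
across adjacent isotopologues (ratios within ~3%), so an observed apex can
sit one isotope away from the theoretical one.

## Numerical conventions

Monoisotopic constants are hard-coded to six decimals: proton 1.007276 Da,
H 1.007825, H2O 18.010565, CO 27.994915, NH3 17.026549, NH2 16.018724;
isotope-grid spacing 1.00286 Da. Residue masses and element isotope
abundances come from pyteomics. Ties are broken deterministically
everywhere (by m/z, then lexicographic keys); re-running any stage on
identical inputs reproduces outputs byte-for-byte, and the pipeline manifest
records parameter values and SHA-256 hashes of all inputs and outputs.

## Known limitations

* The deconvolution is an averagine re-implementation "in spirit"; it does
  not reproduce vendor Xtract output peak-for-peak.
* Unresolved low-resolution HCD envelopes are not deconvoluted; HCD is
  screening-only.
* The decoy-FDR confidence layer is provided but not calibrated against any
  engine's confidence categories.
* mzML output is non-indexed; very large runs pay a linear scan on read.
* The isomer co-elution test uses retention apexes of accepted matches; with
  fewer than two replicates of a species the apex estimate is a single scan.
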