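# Methods

This note documents the model behind `midtail`, the defaults and why they
were chosen, what the synthetic data generator does and does not emulate,
and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Analyte and mass model

The analyte is the 36-residue N-terminal tail of histone H3 (H3.1 or H3.3,
differing only at residue 31, A↔S), released by sortase transpeptidation
and labeled with a TMT 6-plex tag. The fixed chemistry is modeled as:

- **TMT 6-plex, +229.162932 Da per His.** Composition
  C₈(¹³C)₄H₂₀N(¹⁵N)O₂; the tail has a single His (residue 36).
- **Sortase C-terminal correction, +76.1001 Da**, stored as a literal mass
  on the C-terminus. It equals M(Lys residue) + M(2,3-diaminopropionamide)
  − M(H₂O) − M(His residue): the ligation replaces the tail-terminal His
  environment with a Lys–diaminopropionamide stub. The analytic derivation
  reproduces the literal to 5×10⁻⁵ Da and is exposed as
  `chem_core.sortase_cterm_correction()`.

Variable modifications (all monoisotopic, Da): Methyl +14.015650 (K/R, ≤3),
Dimethyl +28.031300 (K/R, ≤3), Trimethyl +42.046950 (K, ≤3), Phospho
+79.966331 (S/T, ≤2), Acetyl +42.010565 (K, ≤5), Propionyl +56.026215
(K, ≤1, "rare"). Each delta is validated against its elemental composition
at construction (tolerance 1e-4 Da) and the shipped YAML table mirrors the
built-in defaults. Atomic masses are current NIST/AME values; with older
CODATA values the phosphorylation delta computes to 79.966330 rather than
the tabulated 79.966331 at six decimals, so the constant set matters.

A proteoform is a backbone plus positioned placements (1-based index i =
histone residue i, so index 4 is H3K4); its canonical key is
`H3` + position-sorted `residue·index·abbrev` tokens joined by `/`
(`H3K14ac/K23ac/K27me2`), `H3unmod` when bare. The backbone variant is
deliberately not encoded in the key and is tracked separately.

## Fragment ions

EThcD produces c/z-type backbone fragments with some HCD-like a/b/y
contribution. Neutral masses: a = Σresidues − CO, b = Σresidues,
c = b + NH₃; y = Σresidues + H₂O, and **z is implemented as the z• (z+1)
radical** produced by electron-transfer dissociation: z• = y − NH₃ + H.
Complementarity (tested exhaustively over the 36-mer): bᵢ + y₍ₙ₋ᵢ₎ = M and
cᵢ + z•₍ₙ₋ᵢ₎ = M + M(H). C-terminal fragments always carry the sortase
correction; any fragment containing the His carries TMT. Neutral losses
default to H₂O and NH₃ (configurable). m/z uses the proton mass
1.00727646688 Da; A+1 spacing is the ¹³C gap 1.003355 Da.

Isotope envelopes use a carbon-only binomial (¹³C abundance 0.0107) —
adequate for the A/A+1 decision the pipeline makes, deliberately not a
fine-structure model.

## Annotation and confirmation

For each scan, theoretical ions are generated for every candidate
proteoform: all configured series, indices 1..35, charges 1 up to
min(precursor charge − 1, `max_fragment_charge`, default 3), with and
without each neutral loss. Matching tolerance is 15 ppm, **inclusive** (a
nano-ppm epsilon guards the boundary against float rounding). When several
peaks fall inside an ion's tolerance the closest-ppm peak wins, ties to
the higher intensity; a peak accumulates every ion assigned to it, so each
peak is annotated at most once. Peaks inside the reporter window
(125.5–132.0 m/z) are flagged and excluded from fragment matching.

A match is **confirmed** when a peak sits one isotope spacing above it
(observed m/z + 1.003355/z, within the fragment tolerance). The A+1
envelope of a kilodalton-scale fragment is dominated by ¹³C, and other
one-neutron substitutions (¹⁵N at 0.997035) usually land inside the same
ppm window anyway; additional spacings are configurable. Only confirmed
annotations enter quantification; unconfirmed matches are retained in the
per-scan dump for inspection.

Attribution: an annotation is unique to proteoform P when every matched
ion belongs to P; otherwise it is shared among all proteoforms holding an
in-tolerance ion on that peak.

## Per-scan abundance and chimeric apportionment

credit(P) = Σ unique(P) intensity + Σ over shared peaks of
intensity/|sharing set|; fraction(P) = credit(P)/Σ credits. Credits are
conserved (they sum to the confirmed annotated intensity, tested to 1e-9
relative) and fractions sum to 1. Shared intensity is divided **equally**
among the sharing proteoforms — the simplest defensible reading;
an evidence-weighted split was considered and rejected for v1 because it
couples the estimator to itself (the weights would be the quantities being
estimated). The consequence is a structural pull toward uniformity wherever
shared ions dominate, which for positional isomer pairs of the H3 tail is
most of the c/z ladder (only cleavages between the two modified sites
discriminate). The isomer-pair fixtures therefore emit discriminating ions
only (below), isolating the apportionment arithmetic from that known bias.
A scan with zero confirmed intensity is flagged unquantifiable and excluded
downstream; scans with more than `max_psms_per_scan` (default 5, the
acquisition's precursor cap) candidates are excluded with a warning.

## Reporter statistics

Reporter m/z values are derived from the TMT reporter cation compositions
(the C₈H₁₆N⁺ series with alternating ¹³C/¹⁵N substitutions, electron mass
subtracted) and live in config, not code. Extraction takes the closest
in-tolerance peak per channel (15 ppm); missing stays missing, never
imputed.

Channel normalization multiplies each channel by max(channel means)/its
mean, means over **all scans with a kept PSM** (not only coverage-passing
ones), missing entries ignored. The operation is idempotent. Note the
compositional sensitivity: normalization assumes the average tail is
unchanged between channels, so a design where most groups move one way
shifts every fold change by the imbalance. The grid-recovery fixture keeps
its fold-change grid symmetric around zero for exactly this reason.

Scans need ≥2 non-missing reporters in **every** condition (inclusive) to
enter grouping. All log2 normalized reporter signals of a group's scans
are pooled per condition; log2FC = difference of pooled means; p from a
two-sided **Welch** t-test on the pooled values (the unequal-variance
default of the statistical environment typically used for such scripts;
"two-sided t-test" alone underdetermines the variant). No multiplicity
correction by default — results report raw p — with Benjamini–Hochberg
available behind `bh_correction`.

A chimeric scan contributes its full reporter signal to every proteoform
group it is assigned to (default); `weight_by_fraction` instead multiplies
the linear intensity by the scan's proteoform fraction before the log2
transform. The default dilutes true fold changes toward zero in proportion
to chimera rate — visible in the README example — but never manufactures
false ones; the option exists because neither behavior is uniquely
"correct" for co-isolated precursors sharing one reporter readout.

Pooling per-scan per-channel values treats them as independent. If scans
carry a shared brightness factor (they do in real data: sampling amount,
ionization), the test becomes conservative — the factor cancels from the
fold-change estimate but inflates the pooled variance. The simulator
exposes this as `brightness_sigma` (default 0 in the reporter-level
fixtures, whose purpose is to verify nominal type-I control under iid
noise).

## The synthetic data generator

`synthetic.simulate_experiment` emulates the acquisition the pipeline
targets: charge-8 precursors (warned if outside 480–540 m/z), c/z-dominant
fragment spectra (series weights default c=z=1.0, a=b=0.2, y=0.3 — chosen
as a one-knob caricature of EThcD intensity structure, which the real
instrument does not publish), isotope envelopes (3 peaks), TMT reporter
ions equal across channels before fold changes (a 1:1:1:1:1:1 mix),
log-normal reporter noise, chimeric co-isolation (up to 5), uniform m/z
chaff, and decoy PSM rows that always fail exactly one confidence filter.
Everything is driven by one `numpy` Generator seeded from the design.

Two intensity conventions make ground truth exactly recoverable:

1. **Budget proportionality.** A proteoform's total monoisotopic fragment
   current in a scan is its mixing fraction × a base budget, distributed
   over its emitted ions by series weight. Apportionment then recovers the
   mixing fractions exactly in the noise-free case regardless of how many
   ions each proteoform emits.
2. **Envelope on top.** Isotope peaks are appended at binomial ratios
   relative to each monoisotopic peak (rather than splitting the ion's
   intensity across the envelope), so the credited (monoisotopic) intensity
   is independent of per-fragment carbon counts.

`unique_ions_only` (used by the isomer-pair fixtures) emits only ions that
discriminate the co-isolated pair: an ion is withheld when any of its
envelope peaks lies within 3× the fragment tolerance of any theoretical
ion of the partner (full annotation universe, neutral losses included) or
of any other emitted peak. This removes both shared-ion credit and
accidental envelope collisions, so the equal-split estimator is exact and
the fixture measures the apportionment arithmetic, not the shared-ladder
bias documented above.

Fixtures (all deterministic; documented defaults in `make_fixture`):

- `isomer-pair` — 20 noise-free chimeric scans, K9me1/K14me1 at 0.7/0.3.
- `isomer-pair-noisy` — 200 scans, ion dropout 0.1, intensity CV 0.2.
- `null-experiment` — reporter-level, 200 groups, zero fold change,
  σ = 0.3 (log2), 10 scans/group.
- `grid-recovery` — reporter-level, log2FC ∈ {−2,−1,0,1,2} × 40 groups,
  σ = 0.3, 10 scans/group. Fold changes are applied symmetrically about
  the base (treated ×2^(fc/2), control ×2^(−fc/2)) so the balanced grid
  leaves channel means equal in expectation and normalization unbiased.
- `survey` — 1000 scans, 12 proteoforms, 30% chimeras, noise, chaff,
  decoys, and three planted fold changes; the general end-to-end dataset.

The reporter-level fixtures skip fragment simulation entirely: they test
the statistics layer at scale without paying for spectra.

**What the simulator does not emulate** — and what passing tests therefore
do not establish about real data: chromatography and MS1 (no co-elution
structure, no dynamic exclusion), search-engine behavior (PSMs are planted,
scores drawn from simple uniforms, no score-correlated errors), TMT
reporter isotope impurity leakage between channels, fragment intensity
physics beyond series weights (no cleavage-site preferences, no charge-state
correlation), detector noise floors/saturation, and multi-6-plex batch
structure. Results on synthetic data validate the arithmetic and the
statistical behavior of the pipeline, not instrument-level robustness.

## Numerical choices and degenerate inputs

- Tolerances are inclusive at the boundary with a 1e-9 ppm guard.
- Scan ids are opaque strings; joins are exact.
- Unsorted peak lists are sorted with a warning; negative intensities are
  errors.
- A channel with no usable signal makes normalization fail loudly (naming
  the channel) rather than silently dropping it.
- A contrast condition with fewer than two pooled values is flagged
  untestable: log2FC is still reported, p is NaN.
- Zero-credit proteoforms keep fraction 0 and stay in the per-scan map.
- Peak merging in the simulator collapses peaks within 2 mDa into an
  intensity-weighted centroid (below instrument resolution at these m/z).
- Problem sizes in the test suite and acceptance script (1000-scan survey,
  200-scan noisy isomer pair, 200 reporter groups) were chosen as the
  smallest sizes at which the measured statistics are stable, keeping the
  default run fast.

## Known limitations

- Single-histone scope: H3.1/H3.3 tails only; no H4/H2A/H2B backbones.
- No intact-mass deconvolution and no fine-structure isotope model.
- No TMT impurity correction matrix and no cross-6-plex batch modeling.
- Equal shared-intensity splitting biases isomer fractions toward
  uniformity when discriminating ions are scarce (see above); interpret
  chimeric fractions accordingly.
- mzML support is a minimal namespace-aware reader (64/32-bit, zlib or
  uncompressed arrays) plus a matching writer — sufficient for centroided
  MS2 peak data, not a full PSI-MS implementation.
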