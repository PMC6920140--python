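# Methods

This note records the models, numerical choices and open design decisions
behind the package, and what the synthetic-data generators do and do not
emulate.

## Mass model

Peptides are modelled as linear chains of the 20 standard residues with
free amine/acid termini: the intact composition is the sum of residue
formulas plus one water. Each intramolecular disulfide bridge removes two
hydrogen atoms (oxidative bond formation), so a 4-bridge peptide loses 8 H.
Only the *count* of bridges is modelled; connectivity does not affect the
intact mass and is never assigned by the workflow.

Atomic masses are hard-coded CODATA/IUPAC monoisotopic values at ≥9
significant digits (H 1.00782503207, C 12 exact, N 14.0030740048,
O 15.9949146196, S 31.97207100). Charging uses the proton mass
1.00727646688 Da — not the hydrogen atom mass — since electrospray adds
bare protons. The hydrogen *atom* mass is used for the disulfide and
per-cysteine corrections, which remove a bound H. An older web calculator
convention of subtracting 1.00794 Da (average-mass H) per cysteine is kept
available (`constants_mode: legacy-1.00794`) for bit-compatibility; the
difference (<0.12 mDa per cysteine) is far below the 10 ppm matching
tolerance at fragment masses. With modern constants the hepcidin-25
composition C117H172N32O31S8 evaluates to 2777.0632 Da; legacy atomic-mass
tables from the mid-2000s give values ~1 mDa lower, and we make no attempt
to reverse-engineer any particular historical table.

No other post-translational modifications are supported in v1: none occur
in the target peptide class, and adding them would complicate the
per-cysteine fragment correction without a test case.

## Isotope envelopes

Isotope distributions are aggregated per nucleon number (unit-mass
binning), with each bin's mass the abundance-weighted centroid of its
isotopologues. This matches what a ~30,000-resolution TOF resolves —
isotopologue peaks spaced ≈1.0033/z apart without fine structure. The
distribution is built by iterative convolution of per-element isotope
vectors using exponentiation-by-squaring per element; terms below 1e-18
probability are pruned during convolution (keeping tail-bin centroids
accurate to ~1e-10 Da), then the envelope is truncated below a relative
abundance floor (default 1e-4), capped at 12 isotopologues, and
renormalised. The isotopologue grid spacing constant used for charge
assignment is 1.00335 Da (the ¹³C−¹²C gap); real envelopes mix ¹³C, ¹⁵N,
³³S … shifts and are marginally narrower, which is why deconvolution
reports observed peak positions rather than grid projections.

Envelope comparison pairs each theoretical isotopologue with the nearest
unused observed peak within a ppm tolerance (default 10 ppm), greedily in
descending abundance order with ties broken toward higher intensity, and
scores the normalised intensity cosine with unpaired theoretical peaks
contributing zeros. An entirely shifted or missing envelope scores 0.

Charge assignment clusters peaks separated by >1.5 Th, anchors a candidate
grid at the cluster's base peak for each candidate z, and keeps the charge
maximising (on-grid intensity × distinct grid slots), requiring ≥3 slots
within 0.02 Th. Smaller charges win ties (their grids are subsets of
higher-charge grids). This tolerates co-eluting contaminant peaks below
~50% of the base peak, as they fall off-grid. Overlapping envelope
*fitting* is out of scope.

Deconvolution averages the per-observation neutral masses without intensity
weighting and reports the maximum pairwise deviation in ppm; a spread above
20 ppm flags the series as inconsistent but does not fail it.

## Fragments

Only singly-charged b/y ions are predicted by default (b = N-terminal
prefix + z protons, y = C-terminal suffix + water + z protons, over z);
other series and charges sit behind arguments. The disulfide treatment for
fragments is the uniform approximation of subtracting one H per cysteine
contained in the fragment, applied to every cysteine because connectivity
is unknown; disulfide-linked internal fragments are not modelled. Bond
coverage counts an inter-residue bond as supported when either its b or its
complementary y ion is annotated. Leucine and isoleucine are isobaric and
are never distinguished spectrally; discrimination of such variants comes
from the precursor mass (when the substitution is non-isobaric) or from
genomic evidence.

## Candidate ranking

Candidates are scored by signed precursor ppm error (theoretical
4-disulfide monoisotopic mass vs observed neutral mass; sequences with
fewer than 8 cysteines get ⌊nCys/2⌋ bridges rather than an error, so
malformed database rows are still scored) and by MS/MS bond coverage and
matched-ion count. The sort key is (precursor pass, coverage, ion count,
|ppm|, id) — the id tie-break makes reports deterministic. The default
precursor tolerance of 20 ppm is deliberately generous relative to the
sub-2-ppm errors a well-calibrated TOF delivers; the 62 Da and 28 Da gaps
separating the competing hepcidin translations make the verdict insensitive
to this choice across orders of magnitude.

## Genomics

Translation uses the standard nuclear codon table via Biopython (stops as
`*`, unresolvable N-codons as `X`, trailing partial codon dropped).
Reverse translation emits a regex over per-residue codon alternations that
matches exactly the DNA sequences encoding the peptide. The coding-match
search scans both strands with that pattern; for exon-split genes it chains
codon-aligned segments (each ≥4 codons, consecutive segments separated by
1–50,000 bases) in order — a deliberate simplification, not a spliced
aligner with splice-site models. Coordinates are 0-based half-open on the
forward strand (BED convention) with a strand flag; minus-strand hits list
exons in coding order. The default of up to 3 exons reflects the three-exon
structure of the hepcidin gene. Note that annotating a printed antisense
string as a "reverse translation" is a common shorthand; the search treats
such strings as the antisense strand (their reverse complement encodes the
peptide) and finds them as minus-strand hits.

Conservation analysis computes pairwise % identity column-by-column for
equal-length sequences, or over a global alignment (match 1, mismatch 0,
gap −1) otherwise — an explicit simplification of ClustalW-style multiple
alignment. Variant columns (1-based) are only reported for equal-length
input, where columns are unambiguous.

## Quantitation and statistics

Feature alignment clusters peaks greedily in descending area order within
0.10 min retention time and 0.05 Da mass — the tolerances used by the
vendor alignment the workflow replaces. Upstream profile-data integration
settings (noise threshold 3, minimum spectral width 0.05 Da) are recorded
in the config for provenance but never applied: inputs are centroided peak
lists. Calibration is ordinary least squares of response on concentration
over the 8-point 0.6–75 nM design; responses are internal-standard-
normalised area ratios by convention, but a raw-area mode is equally valid
since the workflow's normalisation is a linear rescaling absorbed by the
slope — both are supported because which one the original processing used
is not documented.

The Friedman test ranks within subjects (midranks for ties) and computes

    Q = [ 12/(n·k·(k+1)) · Σ_j R_j² − 3·n·(k+1) ] / C

with the standard tie-correction factor C = 1 − Σ(t³−t)/(n(k³−k)),
referred to χ² with k−1 degrees of freedom. Fully-tied data (C ≤ 0) return
statistic 0 and p = 1. An exact mode enumerates the permutation
distribution by convolving per-block rank-vector permutations over the
column-sum state space; `auto` selects it for n ≤ 6, k ≤ 4. The asymptotic
mode mirrors what mainstream statistics packages report. Incomplete blocks
raise — the caller decides on listwise deletion. Study p-values computed
from real serum (p = 0.014 iron, p = 0.025 hepcidin) require the original
measurements; the test suite instead verifies the implementation against
exact enumeration and calibrates its null rejection rate, and checks trend
detection power on synthetic time courses.

## Synthetic data

The generators emulate the study designs: 5+/4+/3+ envelopes of the
25-residue peptide with lognormal intensity noise (default CV 5%), uniform
m/z jitter (default 2 ppm), optional peak dropout and an optional
contaminant overlaying the high-mass flank of the 3+ envelope at 30% of
base intensity; b/y spectra with dropout and jitter; 100 kb random
genomes with the coding sequence planted as 1–3 codon-aligned exons
(introns 200–20,000 bases) on a random strand; an 8-point 0.6–75 nM
calibration with an 18.75 nM internal standard at 5% response CV and
117 injection-sequence IS areas at 14% CV; and ten-subject time courses
at 0/2/4/6 h. The published figures print no numeric medians, so the
default trajectories are qualitative: hepcidin medians 4→6→9→12 nM rising
monotonically, iron 15→45→35→28 nM spiking after transfusion then
declining, with multiplicative lognormal subject noise (σ = 0.25) — effect
sizes chosen once as a realistic moderate within-subject trend, not as
published values.

What the generators do *not* emulate: chromatographic peak shapes and
profile-mode spectra (all spectra are centroided peak lists), correlated
within-subject noise, instrument drift across an injection sequence,
isotope fine structure, and real intron/exon boundary signals. Passing
tests therefore demonstrate the algorithms' correctness and robustness
under these idealised noise models, not end-to-end performance on raw
instrument files.

## Problem sizes

The test suite runs the seeded simulations at sizes chosen to characterise
behaviour well while staying quick: 100-seed candidate-ranking recovery,
4000-replicate null calibration of the Friedman test, two 100 kb
three-exon genome recoveries, 10–40 seed sweeps elsewhere. The full suite
completes in well under a minute on one CPU.

## Known limitations

- Positive-ion, proton-adduct ionisation only; no adducts, no negative mode,
  no average-mass workflow beyond a convenience function.
- The fragment model ignores disulfide-linked internal fragments and
  neutral losses; annotation of spectra dominated by such ions will
  under-report coverage.
- The exon-chaining search requires codon-aligned exon boundaries; genes
  with phase-1/2 introns splitting a codon across exons are found only as
  partial contiguous matches.
- Feature alignment is greedy; pathological peak densities near the
  tolerance boundary can split clusters that a global optimiser would merge.
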