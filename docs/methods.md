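# Methods

This note documents the model behind `featurespeed`, the conventions
that make its numbers reproducible bit for bit, and what the synthetic
benchmark does and does not demonstrate.

## Coordinates and containers

Nucleotide positions are 0-based half-open in mRNA 5'→3' orientation;
residue positions are 1-based inclusive (the Uniprot feature-table
convention). The anchor of a feature starting at residue *s* is
nucleotide `3·(s−1)`, the first nucleotide of its first codon. Tracks
are float vectors with one value per CDS nucleotide; NaN marks a
missing measurement and propagates through every stage (missing-aware
averaging and smoothing; complete-window requirement in the test).
Transcript and protein identifiers coincide: the model is one
contiguous CDS per transcript, one protein per transcript, which is how
the compact microbial transcriptomes this pipeline targets behave.
Tracks from minus-strand genes must be reversed into mRNA orientation
before they enter the pipeline (`orient_track`); the on-disk format
stores them already oriented.

## Track conditioning

**Occupancy outliers.** Ribosome-profiling coverage contains rare
spikes orders of magnitude above the signal. The filter excludes values
strictly greater than `mean + 1.5·sd`, with mean and sd pooled once
over all finite values of the track in the whole dataset. The pooled sd
is dominated by the spikes themselves, which is exactly why the cut
removes only them: in a typical simulated dataset (rate 10⁻³, scale
10³) the threshold lands near 50 while the signal bulk stays below ~5.
The multiplier could also be read as an absolute cap at `1.5·sd`; the
`mean + k·sd` reading is the implemented one and `k` is configurable.

**Per-base z-scores.** The raw structure score's range differs strongly
by nucleotide identity, so a feature characterized by particular amino
acids (hence particular codons, hence particular base composition)
would inherit a spurious structure pattern. The transform replaces each
value by `(x − μ_b)/σ_b` with μ, σ pooled genome-wide per base
b ∈ {A,C,G,T}. Population (ddof = 0) sd is used everywhere — the choice
is irrelevant at genome scale but makes the post-condition exact:
per-base mean 0 and sd 1 to < 1e-10, asserted in the tests. A base
class with zero variance aborts with an error naming the base.
Normalization applies only to the structure track; occupancy is left in
its arbitrary units (its per-base distributions do not differ by
construction, and Pearson correlations are scale-free anyway).
Whether to z-score per transcript instead of genome-wide is a genuine
open choice; genome-wide matches the single-pool outlier filter and is
what the test suite pins down.

**Translation-discrepancy screen.** Each CDS is translated with the
standard code (terminal stop dropped; internal stops translate to `*`
and mismatch from there on) and compared positionally with the
annotated protein — no indel alignment, since the screen exists to
catch annotation mismatches, not to align. The discrepancy is
`mismatches / max(len_translated, len_protein)` with length differences
counted as mismatches. Records are dropped when the fraction exceeds
0.05 strictly, so a protein with exactly 1 mismatched residue in 20 is
retained; the boundary behaviour is tested.

**Codon-level tRNA track.** One value per residue, looked up from the
codon → fraction-of-total-tRNA table; the stop codon carries no
residue and no value. Wobble rules are deliberately out of scope — the
table is an input, as measured tRNA abundances would be.

## Profiles

All instances of a feature are anchored on their first coding
nucleotide; length variation beyond the anchor is ignored (features are
instantiated at different lengths, so only the start is alignable).
Windows are −50..+100 nt for visualization (the 151-position reading of
"150 nucleotides around the start", weighted downstream, matching the
published axis ranges) and −50..+50 nt for statistics; codon-unit
windows span −16..+33 codons so they cover the same mRNA region.
Positions outside the CDS are missing, kept for averaging (maximizing
the number of contributing instances per position) but disqualifying
for the correlation test, which needs complete vectors. Averaging is a
per-position mean over available values with the contributing count
reported. Smoothing is a centred moving average whose edges shrink
rather than pad; an even window takes the extra position on the right.
`w = 1` is the identity. These conventions are arbitrary but frozen,
so outputs are reproducible exactly.

## The association test

Observed distribution: all pairwise Pearson correlations among the
complete −50/+50 windows of a feature's instances. Background: the same
among 1000 segments of the same length drawn from the pool of all
complete track segments, start positions uniform over (transcript,
offset) pairs — long transcripts proportionally more likely — with
replacement. Pairs in which either vector is constant are dropped and
counted, not scored 0 (Pearson is undefined there). If a feature has
more than 1000 complete windows they are subsampled without replacement
(seeded), keeping pair counts comparable to the background's 499 500.
The two distributions are compared with a one-sided unpaired t-test;
Welch's unequal-variance form is the default (the two samples have very
different sizes and spreads), with the pooled-variance Student form
available as a flag.

Two caveats are inherent to the method and worth stating. First,
correlation values sharing a window are weakly dependent, and windows
of nearby instances can overlap physically; the t-test treats all pairs
as independent. Under matched null simulations the measured type-I
error at α = 0.05 is ≈ 0.04–0.09 (200-replicate batches across seeds),
i.e. mildly anticonservative but close to nominal — the validation
suite asserts the 0.02–0.09 range. Second, features with too few
complete windows (default minimum 10) are skipped and logged rather
than tested; a skipped feature is absent from the report, mirroring how
sparse features are handled in practice.

The tRNA track is profiled but never tested: tRNA concentration is
strongly constrained by amino-acid identity (an amino acid with one or
two codons pins the value), so a fair background would have to be
conditioned on amino-acid composition, which this package does not
attempt.

**Cross-correlation.** Two average profiles on a common axis are
compared at every lag in −L..+L; at lag k the overlap pairs `a[i]` with
`b[i+k]`, so a positive best lag means the second profile is displaced
downstream. Ties break toward smaller |lag|, then toward the negative
lag. Every lag must leave ≥ 3 finite overlapping positions.

**Positive-residue control.** K and R (histidine is not counted —
its side chain is mostly neutral at cytosolic pH) are tallied in the
−16..+33 residue windows around instances and compared with the
proteome-wide fraction by an exact two-sided binomial test. This is a
confounder check: a feature whose occupancy pattern merely reflects
K/R-rich sequence should fail it.

## The synthetic benchmark

The generator emulates the data regime the pipeline targets without
claiming biophysical realism:

* CDS-only transcripts: ATG + sense codons drawn from a base
  composition (default uniform) + one stop; proteins are the exact
  translation. UTR padding exists only to exercise the trimming step.
* Occupancy: per-nucleotide `exp(N(0, s))` with s = 0.5 by default —
  positive, right-skewed, heavy-tailed — times a 10³ spike at rate
  10⁻³, giving the outlier filter real artifacts to remove. The noise
  sd of this track is `sqrt((e^{s²}−1)e^{s²})` ≈ 0.60, the unit in
  which planted amplitudes are expressed.
* Structure: per-base offsets (A −0.6, C +1.0, G +1.3, T −0.9) plus
  `N(0, s)` noise, making per-base z-scoring consequential: skipping it
  leaves a visible base-composition artifact in any profile.
* Features: named residue ranges placed uniformly at random,
  non-overlapping within a feature type (overlap across types is
  allowed, as in real annotations). Infeasible specifications raise a
  placement error rather than silently under-placing.
* Planted signals: a template over relative coordinates (default: unit
  Gaussian bump peaking at +12, width 10 nt — a short deceleration
  just downstream of the feature start) is added to a track at every
  instance, truncated silently at CDS boundaries, and recorded in a
  ground-truth sidecar. Everything is a pure function of (config,
  seed).

What passing the benchmark shows: the pipeline's bookkeeping
(anchoring, orientation, windows, filters) is exact, the test is
calibrated under the generator's null and powerful against planted
feature-locked signals, and displacements between tracks are recovered.
What it does not show: performance under real occupancy autocorrelation
(ribosome footprints smear over ~10 nt), coverage-driven
heteroscedasticity between transcripts, codon-level periodicity, or
feature annotations correlated with sequence composition. The Gaussian/
log-normal noise is a modelling choice, not an empirical claim.

## Problem sizes and experiments

The validation experiments (in `featurespeed.experiments`, re-run by
`scripts/acceptance.py`) use compact regimes chosen so Monte-Carlo
error is well below the probed effects while each experiment stays in
the seconds-to-minutes range: 200 replicates of 20 genes × 600 nt with
30 feature instances for null calibration; 100 replicates with 50
instances and amplitude = 1 noise sd for power; 200 instances for
profile recovery; 30 instances per feature and amplitude = 2 noise sd
("strong", so that every one of the ten features clears the
minimum-window count and all tests are actually performed) for the
ten-feature discrimination experiment. Amplitudes are fixed in units of
the generator's noise sd, so the experiments scale coherently if the
noise is changed.

## Known limitations

* One contiguous CDS per transcript; no multi-exon coordinate mapping.
* Windows from overlapping instances are treated as independent in the
  test (see calibration caveat above).
* No multiple-testing correction across features: reports carry raw
  p-values, as a survey across heterogeneous features conventionally
  does; a Benjamini–Hochberg column can be added downstream if a
  decision procedure is wanted.
* The background draws segments with replacement; without-replacement
  drawing would change nothing detectable at pool sizes ≫ 1000 but is
  not offered.
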