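# Methods

This note documents the model behind `tiffms`, the conventions and
defaults each stage uses, what the simulator does and does not emulate,
and the design choices made where more than one reasonable option existed.

## The matching model

A library peptide ion is described by a 3D tag: its neutral monoisotopic
mass *M*, a reference retention time *t* on the library's RT axis, and the
FAIMS compensation voltage *V* at which it transmits.  A run feature with
monoisotopic m/z *m*, charge *z*, aligned retention time *t'* and CV *V'*
is a candidate for the tag when

* charge matches exactly (a tag is charge-specific),
* |ppm(M', M)| ≤ 6 ppm, where M' = m·z − z·1.007276 and the error is
  computed on neutral mass — this keeps one tolerance consistent across
  charge states,
* |t' − t| ≤ 0.4 min on the *aligned* RT axis, and
* V' = V (after 0.1-V rounding) when CV matching ("3D mode") is enabled.

All tolerance intervals are closed (a boundary value is accepted).  When a
feature has several candidates they are ranked by the normalized distance
d = sqrt((ppm/6)² + (ΔRT/0.4)²); the best candidate is accepted only if
d_best < 0.8·d_runner-up, otherwise the feature is left unmatched as
ambiguous.  Ties in the ranking fall back to higher library intensity and
then lexicographic peptide order, so matching is deterministic.  Within a
run, accepted matches are one-to-one: if several features claim one tag,
only the smallest-distance claim survives.  The 0.8 ambiguity ratio and
the one-to-one rule are this package's own conflict-resolution policy;
both are exposed on `MatchParams`.

2D mode is identical except that the CV clause is dropped.  Because every
3D candidate set is a subset of the corresponding 2D candidate set, the
CV filter can only remove confusable alternatives; this subset property is
asserted in the test suite.

## Retention-time alignment

Features are aligned per (run, CV) pair, since library RTs come from
single-CV analyses.  Anchors are features with *exactly one* library
candidate within 6 ppm inside a coarse ±10 min RT window, same CV and
charge; entries claimed by two features are discarded (unique on both
sides).  The anchor cloud is smoothed with robust LOWESS (span 0.3, two
robustifying iterations) and the smoothed curve is projected onto the
monotone cone with isotonic regression, giving a non-decreasing
piecewise-linear map.  Outside the anchor span the map extrapolates
linearly from the terminal slope (estimated over the outer 10% of the
span) and matched features there are flagged `extrapolated`.  The residual
scale is the normal-consistent MAD, 1.4826 × median |residual|.  Runs (or
CVs) with fewer than 5 anchors fall back to pooled-across-CV anchors, then
to the identity map.

## Entrapment false-match estimation

The library mixes a target species with an entrapment species absent from
the sample; any accepted match to an entrapment peptide is a demonstrable
false transfer.  With E entrapment and T target peptides in the library,
the report carries both

* the raw rate `fmr` = distinct accepted entrapment peptides / distinct
  accepted peptides, and
* `fmr_corrected` = fmr × (1 + T/E), capped at 1 — an entrapment hit
  samples only the E/(T+E) decoy share of the confusable space, so the raw
  rate understates the total false-transfer fraction.

Both are reported (plus raw counts) because published entrapment analyses
do not always state which convention they use.  Peptides are counted by
sequence (charge-collapsed) by default; a flag switches to
(sequence, charge) counting.  At the protein level, a protein counts as
entrapment iff *all* of its accepted peptides are entrapment-species;
because entrapment proteins typically rest on a single false peptide, the
protein-level FDR amplifies the peptide-level rate.

## iBAQ quantification

Protein intensity per run is the summed intensity of accepted features of
its peptides; peptides shared between proteins are assigned razor-style to
the protein with more distinct accepted peptides (ties dropped).  iBAQ
divides by the number of theoretically observable tryptic peptides —
fully tryptic (cleave after K/R, not before P), length 7–30, no missed
cleavages; all three are settings on `DigestParams`.  The post-processing
chain follows the common single-cell convention on log2 values:

* keep proteins with ≤ 50% missing in at least one condition, and/or with
  ≥ 2 valid values in at least one group (both thresholds closed);
* impute each missing cell of a sample from
  Normal(m − 1.8·s, (0.3·s)²), where m and s are the sample's observed
  mean and standard deviation ("width 0.3, downshift 1.8"); columns with
  < 2 observations borrow the global m, s with a warning;
* width-normalize each sample: subtract the median, divide by the IQR,
  with quartiles by linear interpolation (numpy's default, the "type 7"
  convention — this choice affects exact values and is therefore fixed
  and documented).  Zero-IQR columns are median-centered only.

CV% (100·sd/mean) is computed on linear values per protein per group
(≥ 2 observations, else undefined); run-run Pearson correlations on log2
values over pairwise-complete rows.

## Feature detection

XIC tracing groups centroid peaks within 10 ppm of a trace's running
intensity-weighted mean m/z over consecutive scans (≥ 3 scans).  Envelope
assembly is greedy: seed at the most intense unassigned trace, test
charges 7 → 1, accept the first charge whose 1.003355/z spacing explains
at least two co-eluting traces; the monoisotopic m/z is the lowest-m/z
member and intensity sums all member traces.  A lone trace becomes a
singly charged feature flagged low-confidence (downstream matching
excludes z = 1 anyway).  On small runs the greedy result is verified
against an exhaustive search over all consistent trace partitions.  S/N is
the apex peak intensity over the median intensity of peaks in the apex
spectrum not assigned to any envelope (floor 1 count); it is internally
consistent but not comparable to vendor S/N definitions.  RT apex is the
maximum-intensity scan without interpolation.

## The simulator

The simulator encodes the study conditions the method assumes, with
defaults fixed at realistic values:

| parameter | default | rationale |
|---|---|---|
| library | 5,000 target + 2,280 entrapment peptides | ≈ 31% entrapment share, a typical mixed-species design |
| CV levels | −45, −55, −65, −75 V | standard 4-CV cycle |
| gradient | 8–60 min | 60-min gradient, peptides eluting from 8 min |
| m/z range | 350–1500 Th | MS1 scan range |
| mass error | 2 ppm (sd) | post-calibration accuracy, comfortably inside the 6 ppm window |
| RT jitter | 0.1 min (sd) | residual scatter after alignment |
| RT drift | rt_lib = 1.02·rt_run − 0.8 + 0.5·sin(rt_run/12), monotone | smooth between-run drift |
| dropout | 30% | single-cell-level detectability |
| charges | 2 : 3 : 4 = 60 : 30 : 10% | tryptic ESI charge distribution |
| unknown features | 20,000 per run | see below |
| intensities | log-normal, log10 mean 6, sd 0.6 | MS1 feature intensity spread |

Peptides are random tryptic-like sequences (length 7–30, C-terminal K/R,
no internal K/R, no leading P) with exact monoisotopic masses; proteins
are groups of 5 peptides whose concatenation digests back into exactly
those peptides, so the iBAQ denominator is exact by construction.  The
preferred CV is a quantile binning of z(mass) − z(charge) plus Gaussian
noise (1.0 bin-widths): heavier, lower-charge ions prefer more negative
CVs, making CV informative but imperfect, as FAIMS transmission is in
practice.  The noise scale is a knob so tests can span "CV useless" (one
CV level) to "CV decisive".

**Unknown features.**  Real low-input runs contain many MS1 features with
no correct counterpart in the library — contaminants, modified forms,
peptides the library runs never identified; these, not the identified
population, are the raw material of false transfers.  The simulator draws
them from the same physical model (peptide-like masses, the same CV rule,
uniform RT) but from sequences outside the library.  The default of
20,000 per 4-CV run reflects the 10⁴–10⁵ MS1 features a typical search
engine detects per run, and gives expected entrapment false counts of
order 10 per run — large enough for the 2D-vs-3D comparison to have
statistical power at desk scale.  Peptide mass-defect clustering (both
library and unknown masses live in ~1 Da bands) is reproduced naturally
by generating real sequences, and matters: it concentrates masses and
raises the collision probability about an order of magnitude over a
uniform-mass model.

What the simulator does **not** emulate: chimeric/overlapping envelopes,
intensity-dependent mass error, FAIMS transmission efficiency curves (a
peptide appears at exactly one CV), inter-run abundance variation beyond a
small log-normal factor, and MS2 acquisition.  Passing tests therefore
demonstrate the correctness and the direction/magnitude of the CV
filtering effect under the stated assumptions, not instrument-level
performance; absolute FMR values at desk scale (fractions of a percent)
are smaller than on real data, where the unmatched-feature population and
library are both an order of magnitude denser.

## Numerical conventions and degenerate inputs

* CVs are compared after rounding to 0.1 V to absorb float encoding noise.
* Proton mass 1.007276 Da; isotope spacing 1.003355 Da (13C−12C);
  residue masses from the standard monoisotopic table, water
  18.0105647 Da; fixed carbamidomethyl-C +57.02146, oxidized M +15.99491,
  N-terminal acetyl +42.01057.
* mzML is written with uncompressed 64-bit float arrays and read with
  support for 32/64-bit and zlib-compressed arrays; profile-mode spectra
  are rejected with an explicit error, MS2 spectra are ignored.
* Spectra lacking a CV in a partially annotated run are grouped under a
  sentinel key with a warning, not an error; CV-less features are only
  matchable in 2D mode.
* Empty runs, empty matrices, zero-IQR columns, zero-sd imputation
  columns, zero-denominator rates and proteins with zero theoretical
  peptides all take defined, non-raising paths (documented on each
  function).
* Everything is deterministic given the configured seeds: library and run
  simulation, imputation, matching order and tie-breaks, and the whole
  pipeline (identical config ⇒ byte-identical outputs; the pipeline log
  carries no timestamps for this reason, and every output file carries a
  hash of the resolved configuration).

## Problem sizes used in the checks

The packaged verification runs use a library of 5,000 + 2,280 peptides
with one simulated 4-CV run (~23,000 features) per seed for the paired
2D/3D comparison (5–10 seeds), ~200–400 peptide libraries for closed-loop
and invariant checks, 200-anchor alignment recovery over 10 seeds, and a
small 4-run study for the end-to-end determinism and quantification
checks.  These sizes were chosen to exercise every code path at
statistically meaningful counts while keeping a full verification run in
the minutes range on a single CPU.

## Known limitations

* The S/N definition is internal; do not compare its absolute values to
  vendor-reported S/N.
* The greedy envelope assembler can in principle split a low-intensity
  envelope that overlaps a more intense one; the exhaustive-oracle tests
  cover well-separated envelopes only.
* The entrapment correction factor assumes false matches land uniformly
  on the library by composition; strong species-specific mass biases
  would break that assumption.
* Alignment is star-shaped (each run to the library); no joint multi-run
  alignment.
* Identity transfer never crosses charge states.
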