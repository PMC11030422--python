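# Methods

This note documents the models, parameters and numerical choices behind
`tddemux`, and what the synthetic-data tests do and do not establish.

## Data model

A TD-DIA run is a sequence of `k` cycles, each an MS1 scan followed by one
MS/MS scan per isolation window; windows are non-overlapping m/z intervals
tiling the precursor range (`RunLayout`).  Cycle and window indices are
1-based.  Every feature — a single-charge proteoform feature (SCPF) on the
MS1 side, a fragment feature inside one window's LC-MS/MS map — carries a
dense extracted ion chromatogram (XIC) `[a_1..a_k]`, one total-intensity
entry per cycle.  "Observed in cycle i" means `a_i > 0` after noise
filtering; the apex cycle is the argmax with ties broken to the earliest
cycle.  Masses are neutral monoisotopic Daltons everywhere.

An SCPF is assigned to the isolation window containing a strict majority
(> 50%) of its observed isotopic-peak intensity.  With non-overlapping
windows at most one window can qualify; an exact 50/50 split assigns
nowhere.  The overlap is computed on observed envelope intensities, not on
a theoretical isotope model.

## Spectrum-level noise filtering

Each centroided spectrum gets its own noise level `h`: the center of the
modal bin of its intensity histogram.  The binning is equal-width over
`[0, max]` with `max(10, ceil(sqrt(n)))` bins, modal ties resolving to the
lower-intensity bin; a constant spectrum returns that constant.  The bin
policy is this package's choice (exposed as `noise.histogram_bins`): the
rule itself only fixes "modal bin center", not the binning.  Peaks below
`r1*h` (MS1, default `r1 = 3`) or `r2*h` (MS/MS, default `r2 = 1`) are
removed; the boundary value is kept, reading "less than" literally.
Filtering is idempotent and never increases total intensity.

## Pair scoring

Whether a fragment feature belongs to an SCPF is scored from three
attributes computed against the round-1 candidate list `L`:

* **normalized intensity rank** — rank in decreasing intensity order over
  `L`, divided by `|L|`; ties broken by ascending mass then id, so ranks
  are a permutation of `1..|L|`.
* **normalized cycle number** — fragment observed-cycle count divided by
  SCPF observed-cycle count.  Deliberately uncapped: a fragment observed
  in more cycles than its precursor is evidence against the match, and
  capping at 1 would hide it.
* **shared XIC** — both elution profiles are linearly interpolated
  through their per-cycle points, dropped to zero half a cycle beyond
  their first and last observed cycles (a single-cycle feature becomes a
  unit-base triangle, so unit-area normalization is always defined),
  scaled to unit area, and the area under the pointwise minimum is
  reported.  Symmetric, in `[0, 1]`, and 1 exactly for identical
  normalized profiles.

Because the normalized profiles are piecewise linear, the minimum is
integrated *exactly* on the union of the two breakpoint sets plus the
profile crossing points.  An earlier uniform-grid quadrature at 100 points
per cycle was measured at ~3e-5 worst-case error against a fine-grid
oracle on narrow profiles; the exact integral is both cheaper and agrees
with a 2000-point-per-cycle oracle to better than 1e-7, so the grid was
dropped.

The score is a plain maximum-likelihood logistic regression (scikit-learn
fit with `C = inf`, i.e. unregularized; no standardization — the
attributes are already normalized ratios).  Training pairs are labeled
against a catalog of identified proteoforms: positive when the fragment
mass is within 10 ppm (configurable) of a theoretical b/y mass.  The
70:30 train/validation split, the seed, and the held-out balanced
accuracy and ROC-AUC are stored in the model file.  Scoring at run time
uses the closed-form logistic directly; the tests cross-check it against
scikit-learn's `predict_proba` to 1e-12.

## Pseudo-spectrum generation

Per window, SCPFs are processed in decreasing total intensity (ties by
ascending mass, then id, making the greedy loop order-independent for
equal intensities).  Rounds:

1. keep fragments with apex cycle distance ≤ `min{t, floor(c/2)}`,
   `t = 3` by default — for short-eluting precursors (`c = 1`) only
   co-apex fragments survive;
2. keep candidates scoring above 0.55; if fewer than 25 pass, report the
   top 25 of `L` ranked *by score* (score is the active ranking at that
   point, so the fallback uses it rather than raw intensity);
3. split at 1500 Da, keep the 25 best-scoring low masses and `T - 25`
   best-scoring high masses, `T = 2(l - 1)` with
   `l = max(2, round(mass / 111.1254))`.  111.1254 Da is the Averagine
   average residue mass; `l` is clamped so `T ≥ 2`.  For small precursors
   `T` can drop below 25: the low quota is clamped to `min(25, T)` and
   the high quota to zero, preserving the quota's intent (at most `T`
   fragments).

Each retained fragment is removed from the window pool before the next
SCPF runs, so a window's pseudo spectra have pairwise disjoint fragment
sets and each holds at most `max(T, 25)` fragments.  An SCPF whose
round-1 list is empty emits no spectrum (logged).  Reported fragment
intensities are the fragment features' total intensities; the quotas
count features, which are deduplicated masses upstream.

## Duplicate removal and run merging

Search-engine output is ranked by SCPF intensity; following the order,
each identification is compared with *all* better-ranked ones and dropped
when both are from the same protein and
`min(|m1-m2|, |m1-m2-1.00235|, |m1-m2+1.00235|)` is within 10 ppm —
1.00235 Da being the common one-isotope deconvolution error.  The ppm
reference is the larger mass (the symmetric, more permissive choice,
recorded as `dedup.ppm_reference`).  Gas-phase fractions are merged by
pooling per-run deduplicated lists and deduplicating the union.  The
procedure is idempotent and always keeps the most intense member of a
duplicate cluster.

## Synthetic data

`simulate_run` emulates one gas-phase fraction: 720–800 m/z precursor
range in 4 m/z windows (20 MS/MS scans per cycle) over 64 cycles — a
deliberately scaled-down run length; instrument runs are several times
longer but add nothing structurally.  Each proteoform is a random
amino-acid sequence (40–90 residues) whose charge state is
rejection-sampled to land inside its target window; its elution is a
Gaussian sampled at cycle centers, truncated at 1% of peak height
(σ 1.5–3 cycles, peak intensity log-uniform over 10^5.5–10^7).  The b/y
ladder co-elutes with the precursor (configurable apex jitter, default 0)
with geometrically decaying intensities (ratio 0.97) and ±30% log-normal
scatter.  Decoy fragments (200 per window) model chimeric signal: 40%
co-elute with a random precursor of the window — emulating fragments of
unidentified co-isolated proteoforms — and the rest elute anywhere;
masses are uniform over 200–12000 Da.  Co-isolated proteoforms share a
host's window, optionally at a fixed apex separation, and the generator's
truth tables map every feature to its source.

What the generator does **not** model: isotope-resolved peak shapes,
charge-state envelope structure, retention-time drift, fragment masses
from internal/modified ions, and mass-dependent detectability.  Passing
tests therefore demonstrate algorithmic correctness (filters, scoring,
greedy bookkeeping, dedup) and behaviour under controlled co-isolation —
not identification performance on instrument data, where feature
deconvolution quality dominates.

`sample_pair_attributes` provides a parametric labeled-pair sample
(positives: shared XIC ~ Beta(8,2), rank ~ Beta(1.5,5); negatives
reversed) for model-recovery checks with a known, strong effect.

## Problem sizes and degenerate inputs

Default test and acceptance problem sizes — 64-cycle runs, 20–40
proteoforms, ~200 decoys per window, 10,000 parametric pairs, 1,000
oracle comparisons — were chosen so the whole suite runs in well under a
minute while every code path is exercised at realistic per-window
density.  Degenerate inputs are defined rather than rejected where a
definition exists: empty spectra filter to empty, all-zero XICs are
invalid features (errors name the feature), constant spectra define their
own noise level, and an empty pseudo-spectrum list writes a valid
header-only file.

## Known limitations

* Feature extraction (spectral deconvolution and envelope detection) is
  out of scope; `link_envelopes` is a plumbing helper for pre-deconvolved
  per-scan records, not a replacement for a feature finder.
* The mzML reader is minimal by design: centroided spectra, 32/64-bit
  float arrays, zlib or no compression, isolation-window target m/z.  The
  plain-text peak-list format is the canonical fixture format.
* The msalign dialect knob ships `minimal` and `toppic` header sets;
  downstream search engines differ across versions, so the writer does
  not guess one canonical set.
* The logistic score is used raw, with no calibration beyond the model
  itself.
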