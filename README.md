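# tddemux

Demultiplexing of top-down data-independent-acquisition (TD-DIA) mass
spectrometry data into pseudo MS/MS spectra for proteoform identification.

## The problem

In top-down DIA, every precursor ion inside a preset isolation window is
co-fragmented in each cycle, so the MS/MS spectra are multiplexed: fragment
ions of several co-isolated proteoforms are mixed in one scan, and database
search engines built for single-precursor spectra identify little from
them.  `tddemux` converts deconvoluted TD-DIA feature data into *pseudo
non-multiplexed* MS/MS spectra: for each single-charge proteoform feature
(SCPF) it selects the fragment features of its isolation window that
co-elute with it and writes them out as one searchable spectrum.

The package is aimed at computational proteomics users who have per-run
deconvoluted feature tables (precursor SCPFs and per-window fragment
features, each with a per-cycle extracted ion chromatogram) and want
msalign-style pseudo spectra for a top-down search engine such as TopPIC.

## The method

Within one isolation window, SCPFs are processed in decreasing total
intensity.  For the current SCPF with XIC $[a_1,\dots,a_k]$, observed in
$c$ cycles, the remaining fragment pool is filtered in three rounds:

1. **Co-elution gate.** Drop fragments whose apex cycle distance from the
   SCPF exceeds $\min\{t, \lfloor c/2\rfloor\}$ (default $t=3$); survivors
   form the candidate list $L$.
2. **Logistic match score.** Each candidate is scored by
   $P(\text{match}) = \sigma(w^\top x + b)$ on three attributes: its
   normalized intensity rank in $L$, its normalized cycle number, and the
   shared XIC — the area under the pointwise minimum of the two unit-area,
   linearly interpolated elution profiles.  Candidates scoring above a
   cutoff (default 0.55) are kept; if fewer than 25 pass, the top 25 of
   $L$ by score are reported without filtering.  The weights are trained
   by maximum likelihood on pairs labeled against identified proteoforms
   (a pair is positive when the fragment mass matches a b/y-ion mass
   within 10 ppm), with a 70:30 train/validation split.
3. **Mass-group quotas.** Survivors split at 1500 Da; the 25 best-scoring
   low masses and the $T-25$ best-scoring high masses are reported, where
   $T = 2(l-1)$ and the residue count $l$ is estimated from the precursor
   mass via the Averagine average residue mass (111.1254 Da).

Fragments used by one pseudo spectrum are removed from the pool before the
next SCPF is processed (greedy consumption).  A postprocessor removes
duplicate proteoform identifications — same protein, masses equal up to a
±1.00235 Da deconvolution error within 10 ppm — keeping the most intense,
and merges identification lists across gas-phase-fractionated runs.

A fully ground-truthed synthetic TD-DIA run generator
(`tddemux.synthetic_data`) makes the whole pipeline testable without any
instrument data.

## Worked example

Simulate a run, train the pair-scoring model on its labeled pairs, and
demultiplex it:

```sh
$ tddemux simulate --seed 1 --num-proteoforms 10 -o run
wrote 10 SCPFs and 2765 fragment features to run

$ tddemux train --features run/features.tsv --catalog run/catalog.tsv --seed 0 -o model.json
trained on 2082 pairs: balanced accuracy 0.9904, AUC 0.9971 -> model.json

$ tddemux demux --features run/features.tsv --model model.json -o pseudo.msalign --report report.json
wrote 10 pseudo spectra to pseudo.msalign
```

The training line reports held-out validation metrics of the logistic
model on the 2,082 SCPF–fragment pairs formed by the co-elution gate (the
synthetic data are easier than instrument data, hence the high AUC).  The
output contains one msalign-style block per SCPF:

```
BEGIN IONS
ID=0
SPECTRUM_TYPE=PSEUDO
WINDOW_INDEX=3
SCPF_ID=SPF009_z13
PRECURSOR_MASS=9490.400658618579
PRECURSOR_CHARGE=13
PRECURSOR_INTENSITY=46033475.358874574
236.08307800096003	8763398.976287793	1
323.13822480831	11111805.352008771	1
...
END IONS
```

Fragment lines are neutral monoisotopic mass, intensity and charge, sorted
by mass.  `report.json` summarizes per-window counts (SCPFs assigned,
fragments extracted, spectra emitted, round-2 fallback uses).
`tddemux dedup` and `tddemux merge` postprocess identification tables.

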