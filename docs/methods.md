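# Methods

## The model family

A gapped n-mer model is an ordered pattern over {considered (`m`), ignored
(`k`)} laid over a fixed-length binding-site window. Only considered
positions contribute to scoring, which lets a single family of models probe
which positions of a core promoter element (CPE) carry predictive
information and which can be dropped.

Two catalogs are enumerated for 6 bp sites:

* **Anchored catalog (32 models)** — every pattern of length 1–6 whose
  first and last symbols are considered. Models shorter than 6 bp slide
  across the site, creating `6 − len + 1` frames. Numbering is by length
  block (starts 0, 1, 2, 4, 8, 16 for lengths 1–6) plus the binary value of
  the interior symbols (`m` = 1).
* **Full catalog (64 models)** — all length-6 patterns, numbered by reading
  the pattern as a 6-bit binary number, `m` = 1, most significant symbol
  first (`kkkkkk` = 0 … `mmmmmm` = 63). This removes the anchoring bias at
  positions 1 and 6. The all-ignored model 0 exists in the catalog for
  completeness but no scoring matrix can be built from it; matrix builders
  raise, and screening/ranking report it as undefined.

Site positions are reported 1-based (1–6); for initiator elements they map
to −2, −1, +1, +2, +3, +4 relative to the transcription start site (there
is no position 0).

## Matrices

From an alignment of n equal-length sites we build per-position counts with
a +1 pseudocount (configurable; column sums are then n + 4), column-
normalised probabilities, and log-odds weights against a genome background.
The background default splits A/T 0.6 and G/C 0.4 evenly within each pair
(A = T = 0.3, C = G = 0.2), matching the AT-rich fly genome; log base 2 by
default, both recorded in matrix file headers.

A gapped model has two matrix representations, used deliberately in
different places:

* **Background-filled PWM** (scanner): considered columns carry the
  log-odds of the probability matrix, ignored columns carry the background
  itself and hence contribute exactly zero to every window score. This is
  the position-independent form that an external motif scanner would accept
  (a MEME minimal-format export is provided).
* **Joint tuple table** (RZ engine): for each frame, the joint frequency of
  the 4^c tuples at the model's c considered positions, +1 pseudocount per
  cell, row-normalised, optionally pooled over frames with equal weight.
  This form retains within-frame dependence between considered positions.

## RZ screening

A site-length window is scored as the sum over the model's frames of
log2(tuple frequency / background product of the tuple letters); training
sites are scored identically, so the dynamic thresholds are on the same
scale. The threshold at position p ∈ [0,1] is the training score at sorted
index ceil(p·(n−1)): position 0 detects every training site, position 1
only the top scorer, and the designation rule is score ≥ threshold so the
boundary site is always detected. The default threshold positions are 0,
0.25, 0.5, 0.75, 1.

For each model × threshold, hits are counted on real promoters and on
composition-preserving scrambles (uniform letter permutations; one scramble
per promoter by default, configurable, counts averaged over replicates).
The RZ score is real/(real+scrambled): 1 = hits only in real sequences,
0 = only in scrambles, 0.5 = balanced. When both counts are zero the score
is reported missing rather than 0.5, to separate "no signal" from "balanced
signal". Good/poor model classification takes the k highest/lowest RZ
scores per threshold (default k = 3) with ties included at the cutoff.

## Scanner

The scanner reimplements the standard PWM-search contract with **exact**
p-values: at width 6 all 4096 windows are enumerated, each weighted by the
product of its background letter probabilities, giving P(score ≥ s) for
every achievable score. A window is a hit when its tail p-value is at most
the threshold. Scanning is forward-strand only by default (CPEs are
orientation-specific); reverse-complement scanning is available behind a
flag.

* **PPV threshold selection**: candidate thresholds are the achievable tail
  probabilities plus 1.0 (PPV is piecewise constant between them); the
  candidate maximising TP/(TP+FP) over the pooled hits is chosen, ties
  toward the smallest p.
* **Truth rule**: a hit is a true positive when its 6 bp window overlaps
  the annotated element interval by at least one base (intervals are
  0-based half-open internally, 1-based inclusive in reports).
* **True hit ratio** per promoter: TP / (all real hits − mean hits over
  scrambles of that promoter); undefined when the denominator is ≤ 0, in
  which case the record is excluded from the per-model mean and counted.
  The default is 100 scrambles per promoter and a fixed p-value of 0.006
  for leave-parts-out runs.
* **Leave-parts-out**: repeated random train/test splits (default 50
  trials, 102 training records); each trial rebuilds the 64 gapped PWMs
  from the training records' annotated 6-mers and evaluates them on the
  held-out records, recording the per-model mean true hit ratio and the
  top/bottom 5% model sets (3 of 64, ties included). Pearson correlations
  between sets of trials check consistency; models undefined in any set are
  dropped from the correlation.

Models with few considered positions often cannot reach a stringent
p-value at all (the best window's tail probability exceeds it, e.g. most
models with ≤ 3 considered positions at p = 0.006 under the default
background); they produce zero hits and undefined ratios, and are excluded
from rankings rather than scored zero.

## Interdependency test

For each of the C(6,2) × 16 = 240 (position pair, letter pair) hypotheses,
the observed joint count in the alignment is compared against null sets
simulated from the alignment's own position probability matrix (no
pseudocount) with independent columns — 100,000 sets of alignment size by
default. Monte Carlo p-values use the add-one convention
(1 + #as-extreme)/(n_sets + 1), so they are never exactly zero; the upper
and lower one-tailed p-values (over-/under-enrichment) and the doubled-
minimum two-tailed p-value are all reported, with significance flags on the
two-tailed p at α = 0.05, 0.01, 0.001 and no multiple-testing correction.

Because the null is parametrised by marginals estimated from the very
alignment under test, and the null counts are discrete
(Binomial(n, p̂ᵢp̂ⱼ) marginally), the procedure is conservative: under a
true product null the flagged fraction falls well below α (measured ≈0.004
at α = 0.05 over 200 independent-site replicates at n_sets = 5000). The
validity direction — empirical size never exceeding α beyond binomial
noise — holds and is what the test suite asserts; users should read the
flags as "at most α" statements. Power is nonetheless high for realistic
couplings: a 0.3-strength planted pair in 205 sites is detected one-tailed
at α = 0.001 in ≳98% of replicates.

## Synthetic data

The generator emulates the three inputs end to end:

* **Sites** drawn column-independently from a probability matrix. Shipped
  fixtures: an initiator-like matrix (consensus TCAGTY; 0.7 on each
  consensus letter, 0.35/0.35 pyrimidine split at position 6), a TATA-like
  matrix (TATAAA at 0.8), and a recovery matrix (TCAGTT with consensus
  probability 0.9 at chosen positions — default 2 and 5 — and 0.5
  elsewhere) used to plant extra information whose rediscovery the pipeline
  tests.
* **Coupled sites** via mixture forcing: with probability c the coupled
  positions are overwritten with the chosen letter pair. The joint
  probability is then c + (1−c)·pᵢ(a)·pⱼ(b) in closed form, enabling exact
  power calculations; at c = 0 the sampler is bitwise identical to the
  uncoupled one at the same generator state.
* **Promoters**: background-i.i.d. sequences (default 100 bp spanning
  −49…+50 around the TSS) with a 6 bp site written at a known offset
  (default 0-based 47, placing site position 3 on the +1 base) and the
  truth interval recorded.

What the generator does **not** emulate: dinucleotide or isochore
background structure, variable site spacing relative to the TSS, multiple
or overlapping elements per promoter, and the empirical redundancy of
curated promoter databases. Passing tests therefore demonstrate that the
algorithms recover signal they are pointed at under an order-0 background,
not that real-genome predictions reach any particular accuracy.

## Numerical choices

* Window scores accumulate PWM columns sequentially left to right, and the
  exact score distribution accumulates probabilities in lexicographic
  window order with tails cumulated from the top score down, so equal
  windows group bit-identically and library results are reproducible to the
  last bit against independent enumeration.
* Score/threshold comparisons use ≥, so percentile semantics keep the
  boundary training site detected and hit counts are monotone in both the
  threshold position and the p-value.
* All randomness flows through numpy Generators; `RunConfig.rng(stage)`
  derives independent, reproducible per-stage streams from one master seed.
* Degenerate inputs raise early: empty alignments, ragged or non-ACGT
  sites, all-ignored models at matrix builders, thresholds from empty score
  lists, out-of-range frame offsets.

## Test-suite problem sizes

The suite exercises the full algorithms at reduced scale chosen to keep the
default run fast while leaving Monte Carlo bounds meaningful: calibration
uses 200 replicate alignments of 205 sites with 5,000 null sets each; power
uses 50 replicates at 10,000 null sets; pipeline recovery runs 10
leave-parts-out trials on 120 synthetic promoters (60/60 splits, 20
scrambles); the scanner oracle covers 100 random PWMs. Defaults in the
library remain at the full scale (100,000 null sets, 50 trials, 100
scrambles).

## Known limitations

* The RZ window convention scores site-length windows (frame-sums), the
  only scale on which the percentile thresholds are meaningful; a
  model-span window variant would need its own threshold calibration.
* Exact p-values are specific to small widths (4^w enumeration); width 6 is
  instant, but the approach would not scale to wide motifs.
* The interdependency test inherits the conservatism described above; it
  controls, but does not attain, its nominal level.
* Overlapping hit windows are counted per window, not merged.
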