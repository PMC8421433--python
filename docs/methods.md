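# Methods

## Read dissection and the concurrence ratio

A bisulfite read reports the joint methylation state of the CpGs on one DNA
molecule. `methconc` dissects each read's ordered non-missing calls into
maximal same-state runs: runs of methylated CpGs are **M** fragments; a read
whose calls are all unmethylated is a single **U** fragment; runs of
unmethylated CpGs inside a *partially methylated* read are **C**
(concurrence) fragments. Missing calls (`?`) are skipped without breaking a
run — a read is one molecule, and an uninformative base does not interrupt
the molecular state on either side of it.

The weighted concurrence ratio of a region is the C-fragment weight sum over
the all-fragment weight sum, with a fragment's weight its in-region CpG
count. This is identical to the proportion of CpG observations labeled C,
which the test suite exploits as an exact cross-check (the fragment-sum and
per-CpG-count routes are implemented independently and compared on random
fixtures). Consequences of the definition:

* the ratio lies in [0, 1); a single k-CpG read attains at most (k−1)/k;
* it is exactly 0 when every read is concordant, whatever the mean;
* it is defined for a single CpG (share of C labels among its reads).

**Labels from the whole read, weights from the region.** A fragment's label
depends on whether its read is partially methylated — a fact about the
molecule, not about where a region boundary happens to fall. Clipping labels
to the region would relabel the unmethylated portion of a partially
methylated read as U whenever the methylated portion falls outside, which
misstates the molecule. The cost is an edge effect: reads straddling a
boundary between a methylated and an unmethylated domain contribute C labels
to the unmethylated side's margin, so even a perfectly demethylated valley
shows a small positive region-level concurrence, shrinking with region
length (visible in `examples/04_canyon_classification.py`). The unweighted
variant counts a fragment once if any of its CpGs lies in the region.

**Coverage filter.** CpGs covered by fewer than 4 reads are excluded from
every metric (configurable). Region summaries run in a strict mode that
drops a region whose observed CpGs are not all sufficiently covered, or a
lenient mode that drops only the failing CpGs; the mode is recorded in the
output.

## Companion metrics

*Mean methylation* is methylated CpG observations over all CpG observations
at qualifying CpGs. *CHALM* is n_m/(n_m+n_u) over reads, where a methylated
read has ≥1 methylated call among the region's qualifying CpGs.

*Heterogeneity scores* are computed on 4-CpG loci — sliding windows of four
adjacent CpGs of the observed CpG map, supported only by reads with
non-missing calls at all four positions and kept at ≥4 supporting reads.
Entropy is Shannon entropy of the 16 epiallele frequencies; Epipolymorphism
is 1−Σp²; PDR is the fraction of mixed-call reads. A region's score is the
unweighted mean over loci whose first CpG lies in the region (deterministic
membership, no double counting across adjacent regions). Windows pair
consecutive CpGs regardless of bp gap; no maximum span is imposed.

**Entropy base.** The conventional presentation writes the entropy with a
natural logarithm yet quotes a 0–4 range, which over 16 patterns only holds
for base 2. The package defaults to base 2 (maximum exactly 4 bits) and
exposes the base as a parameter. Note the plug-in estimator is biased
downward by ≈(K−1)/(2N ln 2) at N supporting reads, so deep coverage is
needed to observe the maximum empirically.

Because loci require reads covering 4 CpGs while the concurrence ratio uses
every read, heterogeneity scores discard short reads that concurrence
retains; a test asserts this utilization gap on a mixed-length library.

## Joint regulation score

Promoter binding intensities x (log2 RPKM) of a methyltransferase (D) and a
demethylase (T) are standardized across promoters, π = (x−μ)/σ (population
σ by default, switchable), then combined per promoter as the product of
min-max rescaled intensities:

Π = (π^D−π^D_min)/(π^D_max−π^D_min) · (π^T−π^T_min)/(π^T_max−π^T_min)

Π ∈ [0,1], is 0 iff either enzyme is at its minimum, 1 iff both are at their
maxima, and is monotone in each intensity. Four co-occupancy groups
(D±T±) use a per-enzyme median split by default (a configurable quantile);
the original four-group cutoff is not published, and a median split
reproduces a near-balanced partition without inventing one. CpG-density
classes use the CpG ratio (CpGs×bp)/(Cs×Gs) with the common 0.75/0.48
high/low cutoffs, shipped as configurable defaults from the external
promoter-classification convention rather than derived here.

## Replicate-free differential calling (local-fdr)

With one matched pair per condition, per-gene differences d of a promoter
metric are modeled as a mixture of non-differential genes (density f0) and
differential genes. Working on |d| so one threshold serves both directions:

1. restrict to |d| < B (null band, default B = 0.10, the conventional
   methylation-difference threshold);
2. keep the middle third [B/3, 2B/3] — the near-zero peak deviates from a
   half-normal and the upper third mixes in differential genes (a rank-
   tercile alternative is available);
3. fit the half-normal scale σ0 by **truncated** maximum likelihood on that
   interval (the uncorrected MLE on a truncated sample is inconsistent; the
   correction divides the likelihood by the interval mass);
4. estimate the marginal f by Gaussian KDE on all |d| (Silverman bandwidth
   by default), reflected at 0 to respect the non-negative support;
5. local-fdr_j = f0(|d_j|)/f(|d_j|), clipped below at machine epsilon; the
   null proportion p0 ≤ 1 is omitted, making the ratio an upper bound on the
   posterior probability of being non-differential;
6. flag genes below the cutoff (default 0.2) whose sign matches the
   requested direction (direction gating applied after the fdr, matching
   one-sided use).

Flag sets from two metrics are partitioned into concurrence-only (P1),
mean-only (P2) and both (P3). For datasets *with* replicates the package
only exports metric tables for an external differential caller and applies
the strict p < 0.005 filter to its output; it does not re-implement that
test. An optional pre-filter on the minimum |d| (e.g. 0.4 for entropy
changes) can be applied before fitting.

## UMR and canyon calling

CpGs with coverage ≥ 4 and methylation ratio < 10% are undermethylated.
Maximal runs of ≥ 4 consecutive undermethylated CpGs become UMRs spanning
first to last member CpG. Consecutive UMRs merge greedily left-to-right,
iterating to a fixed point, whenever the merged span's coverage-weighted
mean methylation (intervening CpGs included) stays below 10%; the merge
never chains past a span that would lift the mean above the threshold.
UMRs spanning ≥ 3.5 kb are canyons.

**Classification threshold.** The concurrence ratios of 10,000 mutually
non-overlapping random regions (lengths resampled from the canyon length
distribution by default, or fixed) form the genome background. Seven
families — normal, log-normal, beta, gamma, uniform, exponential,
logistic — are fitted by maximum likelihood (scipy), location fixed at 0
for the positive-support families; families whose support excludes an
observed value are skipped with a note. The family minimizing the
Cramér–von Mises distance between the empirical and fitted CDFs wins (ties:
fewer parameters, then declaration order), and the threshold is the winning
fit's 90th percentile. Canyons strictly above it are pCanyons
(Polycomb-like), the rest aCanyons (ties inclusive: "higher than" is read
strictly). Canyon target genes are genes whose promoter (TSS−1 kb to
TSS+500 bp, strand-oriented, TSS base included; mirrored with equal lengths
on minus-strand genes) or gene body (TSS+500 bp to TTS) overlaps the canyon
by ≥1 bp.

## Region statistics

The TSS-anchored methylation matrix uses 120 bins of 100 bp from 2 kb
upstream to 10 kb downstream, read in the direction of transcription
(mirrored genomically for minus-strand genes); bin values are
coverage-weighted means over qualifying CpGs, missing when a bin holds none.
Per-bin Spearman correlations against expression use pairwise-complete genes
with a ≥10-gene floor.

Motif enrichment counts hits per kilobase (CPK) with membership by hit
midpoint (a hit straddling a border is counted once, on the side of its
midpoint); a motif with zero hits in either canyon class receives one
pseudo-hit in both counts and is flagged. TF occupancy difference is the
ratio of the fraction of aCanyons touched by ≥1 peak to the same fraction
for pCanyons (a ratio of proportions; +inf when no pCanyon is occupied).
Hi-C anchor pairs are *self-interacting* only when one region contains both
anchors; pairs touching two *different* regions are labeled
distant-interacting — the self/distant definitions are exhaustive only under
this strict same-region reading, which the docs surface explicitly. Shuffle
controls place one random region per input of identical length, mutually
non-overlapping, seeded.

## Synthetic data generator

Reads are placed uniformly over CpG indices of a synthetic map (fixed or
uniformly jittered spacing; uniform placement over indices avoids spacing
artifacts). Calls follow a two-state Markov chain along the read: the first
CpG is Bernoulli(p); each next CpG copies the previous state with
probability ρ, else draws fresh Bernoulli(p). The stationary level stays p
for every ρ, so ρ is a pure concordance knob. Defaults — 2,000 CpGs at
100 bp spacing, 50× coverage, 4 CpGs per read, p = 0.5, ρ = 0 — describe a
small WGBS-like locus at typical depth with maximally informative
methylation level.

Ground truth is exact: for ρ = 0 the expected weighted concurrence is
(1−p)(1−(1−p)^(k−1)); for ρ > 0 it is computed by enumerating the 2^k read
patterns. Knockout modes lower p toward 0 (methyltransferase loss), raise it
toward 1 (demethylase loss), or drive ρ toward 1 (joint loss → concordant
reads, concurrence → 0). UMR planting overrides p per CpG inside specified
spans. For exact boundary-recovery checks the planted spans use p = 0:
recovery is then structural (every inside CpG is undermethylated in any
sample) rather than dependent on a favorable draw; noisy plantings
(p ≈ 0.02–0.05) exercise the merge rule instead, since finite coverage lets
single CpGs cross the 10% line.

What the generator does **not** emulate: sequencing error, bisulfite
non-conversion, strand bias, PCR duplicates, CpG-density heterogeneity of
real genomes, or spatially correlated methylation beyond the read length.
Passing tests therefore demonstrate correctness of the estimators and
procedures under the stated generative model, not robustness to those
artifacts.

## Numerical choices and degenerate inputs

* Metrics on regions with no qualifying CpG/read/locus are *missing*
  (None/NaN), never 0.
* Standardization and the joint score reject zero variance and degenerate
  (max = min) ranges; background fitting rejects constant samples and
  fewer than 100 values.
* The truncated half-normal MLE optimizes log σ on a bounded interval
  (xatol 1e−10); the KDE bandwidth, if given numerically, is an absolute
  bandwidth in data units.
* Local-fdr values are clipped below at machine epsilon; the marginal
  density at tiny values is floored at the smallest positive double.
* Background/shuffle placement uses rejection sampling with a bounded retry
  budget (default 1,000 tries per region) and fails loudly on saturation.
* Wiggle output is 1-based (variableStep convention); all internal
  coordinates are 0-based half-open. CpG coordinates are forward-strand C
  positions; reverse-strand observations collapse onto them.
* Mate pairs in alignment extraction are counted once per CpG; on a
  conflicting double observation the first mate wins (optionally the call
  becomes missing).

## Problem sizes in tests

The suites run on synthetic libraries of 10⁴–10⁵ reads (2,000–3,000 CpGs at
30–50×), 10,000-value background fits, and 2,000–5,000-gene differential
tables — sizes at which every stochastic assertion has comfortable margin
while the whole suite completes in well under a minute.

## Known limitations

* 5hmC is indistinguishable from 5mC in bisulfite data; the concurrence
  ratio inherits this blindness.
* Region-level concurrence near domain boundaries carries the straddling-
  read edge effect described above.
* The unweighted ratio counts clipped fragments once per region by design;
  whole-read fragment counting is not offered as a separate mode.
* `fit_background` selects among the seven stated families only; heavy-tail
  alternatives are out of scope.
* The replicate-aware differential path delegates to an external caller by
  design and only filters its output.
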