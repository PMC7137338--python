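# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limitations of `methcap`. It describes what
the code computes; every number quoted as an outcome is produced by the
test suite or by `scripts/acceptance.py`, not asserted here.

## 1. Windowed differential-binding model

**Counting.** Each chromosome is tiled with windows of width 200 bp at
starts 0, 10, 20, … (keeping windows with `start + width <= L`). A fragment
increments every window it shares at least one base with. Single-end
records shorter than 200 bp are extended to 200 bp from their 5' end,
strand-aware, because MBD libraries are sequenced as short reads of ~200-bp
sonication fragments; the extension length is configurable and can be
disabled. All interval arithmetic is 0-based, half-open.

**Filtering.** A window is tested when (a) its count sum across samples is
at least 30, (b) its average log2 CPM is at least −1, computed as
`log2(((y + 0.5) / (N_eff + 1)) * 1e6)` averaged over samples (the 0.5 and
+1 stabilize zero counts), and (c) it is not on chrX/chrY (chromosome names
are compared after stripping an optional `chr` prefix, case-insensitively).
Boundary windows exactly at the thresholds are kept (≥ semantics).

**Normalization.** Enrichment data are compositionally biased: a sample
with more captured signal spends a larger share of its reads on enriched
regions, deflating the apparent rate everywhere else. Factors are therefore
estimated by TMM on 10-kb background bins counted from the raw fragments
(non-overlapping tiling), with edgeR's conventions: reference sample by the
75th count percentile, 30% two-sided trim on M-values, 5% on A-values,
inverse-asymptotic-variance weights, and a final rescaling to geometric
mean 1. Effective library size = raw fragment total × factor. A
`norm="totals"` escape hatch skips TMM. Practical caveat found during
development and reproduced in the tests: TMM needs the stable (non-
differential) captured compartment to dominate the usable bins; when
differential material contaminates more than the trim fraction of bins the
factors are biased, which propagates into spurious directional calls.

**NB GLM.** Window counts follow a negative binomial with log link and
log-effective-library-size offsets; the design is a one-way group layout,
so every fit reduces to per-group rate estimation and runs vectorized
across all windows (Fisher scoring on the log rate, 30 iterations, step
clipped to ±5).

*Dispersion.* For a grid of 25 dispersions log-spaced on [1e-4, 20], the
Cox–Reid adjusted profile likelihood `APL_i(α) = ll_i(α) − ½·Σ_g log Σ_{j∈g}
w_j` is evaluated for every window (`w = μ/(1+αμ)` is the working weight;
the adjustment is the determinant term of the group-means design). Windows
are grouped into up to 20 abundance-quantile bins; each window's dispersion
maximizes `APL_i(α) + (d0/d)·mean-APL of its bin`, where `d = n − G` is the
residual degrees of freedom and `d0 = 10` the prior weight — an
empirical-Bayes weighted likelihood that shrinks noisy per-window estimates
toward an abundance-dependent trend without the boundary bias of averaging
per-window maxima. The grid maximum is refined by quadratic interpolation
on the log scale. With fewer than 2 residual df the bin consensus is used
directly.

*Testing.* A contrast (a, b) is tested by a likelihood-ratio test of the
full group-means model against the model in which groups a and b share a
rate, with p from χ²(1). One three-group fit supplies the dispersions; the
pairwise contrasts reuse them (`DMRCaller.fit(..., dispersion=...)`). The
window logFC is `log2(λ_a/λ_b)` of the rate MLEs (exactly offset-invariant);
a group whose counts are all zero receives a 0.5 pseudo-count so the fold
change stays finite. Windows that are all-zero in both contrasted groups
report p = 1, logFC = 0.

**Regions.** Tested windows with gaps ≤ 50 bp (gap = next start − current
hull end) merge transitively per chromosome. The region p-value is the
Simes combination of member-window p-values; region-level FDR is
Benjamini–Hochberg across regions (via statsmodels); significance at
FDR ≤ 0.05. Direction follows the majority sign of member-window logFCs;
exact zeros count to neither side, ties resolve to the smallest-p member's
sign, and a residual tie resolves to "hyper" (deterministic). The region's
aggregate logFC pools member-window counts per contrast group — overlapping
windows weight both groups identically, so the pooled ratio is unbiased and
much less noisy than any single window's estimate; a zero FDR budget flags
nothing even at p = 0.

## 2. Annotation

Genic layers: regulatory = strand-aware 5-kb upstream of the TSS
(`[TSS−5000, TSS)` on +, `[TSS, TSS+5000)` on −) unioned with the 5'UTR;
gene body = end of 5'UTR to start of 3'UTR; 3'UTR as given; intervals
within a layer merge. CpG layers: shores are the 2-kb island flanks minus
islands, shelves the next 2-kb band minus islands and shores, so the family
is pairwise disjoint with precedence island > shore > shelf (flanks of
nearby islands fuse — an inter-island gap narrower than two shore widths is
entirely shore). Shore/shelf widths of 2 kb each follow the common
annotation convention and are configurable.

A region is intragenic (resp. sSISs) when it overlaps any genic (CpG) layer
by ≥ 1 bp; its subclass is the layer with the largest overlap, ties broken
by the fixed orders regulatory > gene_body > utr3 and island > shore >
shelf. These single-category calls make class and subclass counts partition
any region set exactly.

CpG density: for each CpG (position of its C), the O:E ratio
`#CG / (#C·#G/L)` is computed on the 200-bp window centered on it, clipped
at chromosome ends; N bases count toward length but not composition; the
ratio is defined as 0 when `#C·#G = 0`. Classes: low < 0.3 ≤ intermediate
< 0.6 ≤ high. The whole genome is processed via prefix sums.

## 3. Cross-platform concordance

**Beta regression.** For each CpG with coverage in ≥ 2 samples per group
(others are skipped and reported), observed proportions are squeezed into
the open interval by `y' = (y(n−1)+0.5)/n` (n = samples used; uncovered
samples are imputed at the CpG's pooled mean so they carry no group
information) and fitted with a logit-link beta likelihood with a common
per-CpG precision, by damped Fisher scoring on (intercept, group effect,
log precision) with the closed-form expected information — fully vectorized
across CpGs. The p-value is a Wald test of the group coefficient;
non-converged fits report p = 1 (conservative) and are flagged. Fitted
group proportions are mapped back through the inverse squeeze, so the
reported difference is on the original [0, 1] scale. Fits are unweighted by
coverage; the squeeze transform is the standard Smithson–Verkuilen device.

**Propagation.** Nearby CpGs are frequently co-methylated, so every CpG
inside a tested MBD region inherits that region's aggregate logFC and Simes
p (the raw combined p, not the BH-adjusted value, because the downstream
classification rule thresholds a p-value, not an FDR; configurable).
Overlapping regions violate the merge contract and raise.

**Classification** of CpGs covered by both platforms: TE calls hyper/hypo
by the sign of the fitted proportion difference (exact zero, at 1e-12
tolerance, is "none" — exact ties occur with discrete counts and are
honored); MBDE calls hyper/hypo when the propagated logFC has that sign
*and* p < 0.05. Joint classes: hyper-concordant, hypo-concordant, iso (TE
difference exactly 0, MBDE logFC exactly 0 with p ≥ 0.05), otherwise
"other", subclassified (TE-only-hyper, MBDE-only-hypo, discordant, …). The
four joint classes partition the both-covered set exactly.

**Correlation.** Pearson r between MBDE logFC and TE difference within each
density stratum; strata with < 3 records or zero variance report NaN
(undefined), never 0. DMR-set comparison: a region overlaps the other
platform's set when it shares ≥ 1 bp with a same-direction region; each
region counts once regardless of partner multiplicity.

## 4. Synthetic-data generator

The generator produces the full study structure at desk scale:

* **Genome.** One or more chromosomes partitioned into gene "slots". Each
  slot holds a gene (5'UTR 300 bp, body 5 kb, 3'UTR 500 bp, alternating
  strands) whose promoter sits on a 1-kb GC-rich (55%), undepleted CpG
  island (O:E ≈ 1); a 1-kb partially depleted transition zone flanks the
  island on each side (shore-like density, O:E ≈ 0.5); moderate-CpG
  open-sea patches (400 bp) fill the slot's gene-free half. Background is
  40% GC with heavy CpG depletion (CpGs erased C·G → C·T, mimicking
  deamination). All depletion probabilities are configurable per zone.
* **Methylome.** Island CpGs draw baseline levels in [0.05, 0.10],
  everything else in [0.75, 0.85] — islands unmethylated, open sea
  methylated. Planted DMRs shift the affected tumor groups' levels by
  `delta`, clamped to [0, 1]; the normal group is never shifted. An
  optional genome-wide tumor drift (block-constant shift of non-island
  CpGs, identical in both tumor groups) emulates the global low-magnitude
  methylation drift of tumor genomes. Between-sample biological jitter is
  N(0, 0.02) per CpG per sample at generation time (the study provides no
  variability figure; 0.02 keeps replicate β-value scatter in the few-
  percent range typical of methylome replicates).
* **MBD capture.** Candidate molecules (count ~ NB around the configured
  library size, length ~ N(200, 20) truncated at 50 bp, uniform starts)
  methylate each CpG they carry with probability equal to its level; a
  molecule with k methylated CpGs is retained with probability
  `1 − (1−q)^k` (default q = 0.1) — the simplest per-molecule affinity
  model in which coverage grows with methylated-CpG content, which is the
  property the MBDE/TE contrast depends on. One consequence worth knowing:
  isolated methylated background CpGs are weakly captured and seed sparse
  "stray" coverage clusters, just as real MBD data contain low-level
  background peaks.
* **Bisulfite counts.** Per CpG: total ~ NB(mean coverage 30, dispersion
  0.1); methylated ~ beta-binomial(total, level, ρ = 0.02), collapsing to
  binomial at ρ = 0 or level ∈ {0, 1}.
* **Reproducibility.** All draws derive from one seed through keyed
  substreams (stage, group, sample index), so outputs are bit-identical
  under a fixed seed and adding samples never perturbs existing ones.

### Canned scenarios and their sizing

The scenarios fix the emulated study design — 3 normal mucosa, 6 primary
CRC, 12 liver metastases (TE: 3 vs 3) — and were sized by coverage/power
arithmetic so that planted effects are detectable at the pipeline's FDR,
as they were in the emulated study:

* `null` (type-I error): 500-kb genome, 20 genes, 3 vs 3 samples, 60k
  candidate molecules/sample, no planted effects.
* `recovery`: 4-Mb genome, 55 genes, 150k candidates/sample, 50 hyper DMRs
  (island + full shores, delta +0.5) in both tumor groups.
* `tumor`: 3.3-Mb genome, 45 genes, 1.6M candidates/sample, near-zero
  background CpG density (keeps stray regions from dominating the BH
  burden), 30 shared hyper DMRs plus 40 short hypo DMRs (whole patch
  ±150 bp, delta −0.2) affecting only metastases (`shared_hypo=True` makes
  every effect identical in both tumor groups, a true metastasis-vs-primary
  null). Hypo events are deliberately numerous enough that the
  metastasis-specific fraction is stable against the ~1–2 false discoveries
  the 5% FDR budget admits.
* `crossplatform`: 2.5-Mb genome, 35 genes, 250k candidates/sample, one
  CpG-poor patch per slot (O:E ≈ 0.25, low-density class), 30 hyper + 30
  hypo DMRs in primaries, tumor drift N(−0.05, 0.15) per 2-kb block. The
  drift magnitude was chosen to reproduce the intermethod-correlation
  regime observed in real tumor/normal comparisons, where methylation
  differences are ubiquitous rather than confined to discrete DMRs.

### What the generator does not model

Sequencing error, mappability, GC bias, copy number, diploidy, real genome
coordinates, read-level artifacts (the pipeline consumes aligned
intervals), probe design for targeted enrichment, and spatial correlation
of bisulfite errors. Passing tests therefore demonstrate the statistical
machinery under the stated generative assumptions, not robustness to these
real-data complications.

## 5. Known limitations

* The χ²(1) reference for the window LRT is asymptotic; with 3-vs-3 designs
  calibration relies on the dispersion shrinkage (the null scenario checks
  the raw p < 0.05 fraction stays in [0.03, 0.07]).
* Region-level propagation assigns one logFC/p to every CpG in a region;
  CpGs whose true state differs from the region consensus inherit the wrong
  value. This smearing, plus the count noise of low-coverage stray regions,
  caps the cross-platform correlation in the low-density stratum at this
  library scale (the evaluation reports it; typical values sit near 0.4
  versus ≥ 0.65 in the intermediate/high strata).
* TMM requires stable captured material to dominate the background bins;
  see §1.
* The beta regression replaces spatially smoothed bisulfite testing with
  direct per-CpG fits — a deliberate simplification that raises per-CpG
  noise; its Wald p-values are asymptotic and can be optimistic at 3-vs-3
  with low coverage.
* One three-group model with extracted pairwise contrasts is fitted (the
  alternative — separate two-group models per contrast — differs mainly in
  dispersion pooling).
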