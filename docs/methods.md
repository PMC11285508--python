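# Methods

This note records the models, parameter choices and known limitations of
the package, in the order the pipeline runs.

## Coordinates and annotation

Internal coordinates are 0-based half-open; GTF input (1-based closed) is
converted on read and BED6 is the exchange dialect. Peak merging condenses
peaks overlapping by ≥ 1 bp **on the same strand** into their union —
csRNA-seq is strand-resolved, and merging across strands would collapse
divergent promoter pairs. Merging is idempotent and order-independent;
merged peaks are renamed deterministically in (chrom, start, strand)
order with the center at the interval midpoint.

Annotation is center-based: a peak's category is decided by where its
center falls, with priority promoter-TSS > TTS > exon > intron >
intergenic across all overlapping genes. The promoter window is
[TSS−1000, TSS+100] in gene orientation, both bounds inclusive; the TTS
window mirrors it ([TTS−100, TTS+1000]). The TTS mirror and the priority
order are conventions (the category list itself carries no tie rules);
both are configurable. The nearest gene minimizes |distance to TSS| with
lexicographic gene-id tie-break, so output is deterministic.

## Filters and classification

* **Initiation filter**: keep peaks with ≥ 7 reads per 10 million
  (0.7/M) in at least one csRNA sample, boundary inclusive. The
  "at least one sample" scope is a choice; a per-group variant would be
  stricter and is easy to add at the call site.
* **Input-contamination filter**: keep a peak when mean csRNA signal ≥
  2 × max(mean input signal, 0.1/M), all per-million. This is an explicit,
  deliberately simple surrogate for read-level contamination control in
  csRNA peak callers (which use tag-level evidence we do not model); the
  floor avoids division blow-ups at zero input.
* **Stability**: a peak is *stable* when pooled mRNA coverage in its
  strand-oriented −100..+500 bp window is ≥ 5 reads. The threshold is a
  default with no canonical published value; the synthetic generator
  plants coverage 0 vs ≥ 20, so conclusions drawn from it are insensitive
  to the exact cut.
* **Putative enhancers**: unstable peaks whose center is strictly
  > 500 bp from every promoter window edge (conservative edge-distance
  reading of "distal").

## Differential testing

Counts are modeled negative-binomially with a log link, offsets
log(lib_size × TMM factor), and design intercept + ecotype (sulfidic = 1)
+ drainage + species (treatment coding). Aliased design columns are
detected by incremental rank checks and dropped with a warning — with
*P. sulphuraria* only in the sulfidic Pichucalco site the species column
acts as an ecotype×drainage interaction and remains estimable, but a
fully collinear covariate is dropped rather than crashing the fit.

TMM follows the standard recipe: M and A values on library-size-normalized
counts against a reference sample (auto-chosen as the one whose
upper-quartile CPM is closest to the mean), 30% two-sided trim on M, 5% on
A, delta-method precision weights, factors renormalized to product 1.
Because the precision weights depend weakly on absolute counts, factors
are scale-invariant only to ≈ 1%.

Dispersion: the common dispersion maximizes the Cox–Reid adjusted profile
likelihood (a 1-D bounded search over log φ with the mean profile refit by
batched IRLS per evaluation). Tagwise dispersions are method-of-moments
estimates — with the squared-residual term scaled by n/(n−p) to undo
fitted-mean shrinkage — shrunk linearly toward the common value with
weight 0.5 (exposed). This is a simplified stand-in for full
empirical-Bayes machinery: the aim is calibration and parameter recovery,
not numerical equality with any particular reference implementation. On
5 000 null NB features (dispersion 0.1, 6 vs 6 with a drainage covariate)
the likelihood-ratio test rejects at ≈ 0.06 at nominal 0.05 and the
p-value distribution is uniform to KS < 0.03.

Testing: likelihood-ratio chi-square on the ecotype coefficient by
default; a quasi-likelihood-style F test (deviance-scaled, F(1, n−p)) is
available via `test="qlf"` and is used for the mRNA arm, which is the
convention for steady-state expression. log2FC is the ecotype coefficient
/ ln 2; positive means higher in sulfidic. FDR control is
Benjamini–Hochberg step-up.

Identically-constant features yield log2FC = 0 and p = 1 exactly (the
likelihood ratio is 0 by construction and mapped to p = 1).

## Intersection and enrichment

DI peaks (FDR < 0.05) join their nearest gene's DE result. Parallel_up /
parallel_down / divergent require both FDR < 0.05 and the respective sign
pattern; a gene absent from the DE table (filtered before testing) is
classed not_de but counted separately, since "not tested" is not
"tested and null". Category composition of a subset is compared with all
peaks by a G-test goodness of fit (G = 2 Σ O ln(O/E), zero cells
contribute 0, no Williams correction by default; the correction is a
flag).

The candidate-gene test is a two-sided Fisher's exact test in the base-R
convention: the two-sided p sums hypergeometric point probabilities ≤ the
observed table's, and the odds ratio is the conditional MLE with an exact
95% CI (the sample OR ad/bc is reported alongside, since the two can
differ noticeably in small tables).

## Enhancer–gene pairing

Candidates are all (DI putative enhancer, DE gene) pairs with
|TSS − center| < 500 000 on the same scaffold (strict inequality; strand
ignored; multi-pairing allowed in both directions — counts are of
*pairs*, not enhancers). Distance pairing is provably identical to the
expand-and-intersect formulation and is tested against it. After the
same-sign filter (zero fold-changes excluded), one OLS of enhancer log2FC
on gene log2FC is fitted over **all** same-direction pairs — pooling both
directions anchors the line through both sign clusters; a per-direction
mode exists behind a flag. Retention keeps pairs with internally
studentized residual |e_i / (s√(1−h_ii))| ≤ 1, boundary inclusive and
symmetric (pairs "too far above" the line are dropped the same as those
below). Under a bivariate-normal cloud this retains ≈ 68%; planted
high-correlation pairs sit well inside the band because the residual
scale s is set by the much looser cloud of coincidental distance pairs.

## Motif scanning and enrichment

PFM → PWM: p = (count + 0.8·bg) / (colsum + 0.8), weights log2(p/bg),
uniform background. The deficit of a window is
(s_max − score)/(s_max − s_min) ∈ [0, 1]; hits require deficit ≤ 0.15 on
either strand, with N-containing positions scored at the per-column
minimum. The deficit-on-normalized-log-odds definition approximates the
published behaviour of deficit-threshold scanners whose exact transform is
not public; it is exercised against a brute-force per-offset oracle.

Enrichment is sequence-level (≥ 1 hit per sequence) Fisher exact,
two-sided, significant at p < 0.01; a site-count mode was considered and
rejected as more sensitive to window length. The log2 enrichment ratio
uses Haldane-style smoothing ε = 0.5/n per set so null ratios center on 0.
Backgrounds: for promoter sets, all promoter-TSS peaks with FDR > 0.05,
|log2FC| < 0.5 and a non-DE nearest gene (the |·| reading: a literal
signed cutoff would admit strongly downregulated peaks into a
"not differentially initiated" background); for enhancer sets, a seeded
uniform sample of 1 000 non-DI putative enhancers. TF support calls split
dimer names on "::" and match components case-insensitively against DE
gene ids.

## Synthetic data generator

The generator emulates the study design: 2 ecotypes × 3 drainages,
2 csRNA samples per site (12) with matched input libraries, and
17 + 18 mRNA samples; the sulfidic Pichucalco site carries the second
species. Defaults: 10 chromosomes × 1.75 Mb holding 2 500 genes in 7 kb
slots — 2 500 promoter peaks, 1 500 distal enhancer peaks, 1 000 intronic
peaks, 100 input-heavy contaminant peaks (≈ 5 100 peaks total, a scale
chosen to make odds-ratio and retention estimates stable while a full run
stays around ten seconds); NB counts with mean 100, dispersion 0.1,
lognormal library-depth factors (σ = 0.2) and per-peak drainage effects
(σ = 0.25 log2); DI fraction 0.15 at |log2FC| = 2; 10% candidate genes
whose peaks have ×3 DI odds.

Causal order: DI flags are drawn first, per peak, as independent
Bernoullis with the candidate multiplier applied on the odds scale — this
makes the generating candidate odds ratio exactly the configured value.
DE genes then derive from DI promoter peaks (P(DE | DI) = 0.7, matching
sign with probability 0.9) and from DI enhancer peaks, whose (peak, gene)
log2FCs are bivariate normal with correlation 0.9 around ±2; 5% of the
remaining genes are independently DE. Enhancer peaks get zero mRNA window
coverage, everything else ≥ 20, so stability calls are noiseless by
construction. Consensus sequences of two designated motifs are substituted
into the scan windows of DI promoter/enhancer peaks at rate 0.6 and
elsewhere at 0.05; four additional motifs are never planted and serve as
in-run negative controls. Per-sample peak lists are the true peaks with
±10 bp edge jitter; counts are keyed by the ids the package's own
`merge_peaks` assigns to those lists, so the pipeline and the ground truth
speak the same id language. All randomness flows from one seed through
fixed substream indices; identical seeds reproduce every file byte for
byte.

What the generator does **not** model — and hence what passing tests do
not establish about real data: read-level noise and mapping artifacts
(peaks are placed, not called), overlapping genes and nested promoters,
distance-decaying enhancer–target preference (targets are the host slot's
gene), GC- and repeat-structure of real genomes, and library composition
shifts beyond a global depth factor.

## Numerical choices

* IRLS: batched across features (einsum normal equations), ridge 1e−8,
  η clipped to ±30, convergence 1e−10 or 60 iterations.
* Likelihood ratios below 1e−12 are reported as p = 1 (exact-null
  identity).
* PCA signs are fixed by making each PC's largest-magnitude loading
  positive.
* Perfect regression fits (SSR ≤ 1e−12 × var(y)) set all studentized
  residuals to 0 rather than amplifying float noise.
* Fisher p-values come from the exact hypergeometric enumeration (via
  scipy), validated in-suite against an independent enumeration oracle
  for every table with N ≤ 40.

## Known limitations

* The NB test is mildly anti-conservative (≈ 0.06 at nominal 0.05 with 12
  samples); fine for FDR-controlled discovery, but p-values near the
  threshold should not be over-read.
* The contamination filter is compositional (per-million over the peak
  set), so it is meaningful only when contaminant signal is concentrated
  in a minority of peaks.
* Enhancer–gene pairing is distance-based within a scaffold; no contact
  maps, no cross-scaffold links.
* Motif enrichment treats sequences as exchangeable; no GC- or
  composition-matched background correction.
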