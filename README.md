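# nascentreg

Regulatory analysis of nascent transcription for a two-ecotype comparison:
from per-sample transcription-initiation peaks (csRNA-seq) and count
matrices to differentially initiated peaks, their intersection with
differentially expressed genes, putative-enhancer identification,
enhancer–gene pairing, and transcription-factor binding-site (TFBS)
enrichment.

## The problem

Capped-small RNA sequencing (csRNA-seq) captures 5′-capped nascent
transcripts and marks transcription-initiation sites at base-pair
resolution, including unstable species (enhancer RNAs, antisense
transcripts) invisible to steady-state mRNA-seq. Comparing initiation
between *sulfidic* and *non-sulfidic* fish ecotypes across three river
drainages asks which promoters and enhancers respond to a toxic
hydrogen-sulfide environment, whether initiation changes run parallel to
expression changes, and which TF binding motifs sit in the responsive
regions.

The package implements that analysis chain as a tested library plus CLI:

| stage | module |
|---|---|
| GTF/BED/FASTA I/O, peak merging, peak-to-gene annotation | `genome_annotation` |
| TMM normalization, CPM/initiation filters, NB differential testing, BH-FDR, PCA | `counts_differential` |
| stability calls, input-contamination filter, putative enhancers | `peak_classification` |
| DI∩DE joins, parallel/divergent subsets, G-tests, candidate-gene Fisher test | `intersection_analysis` |
| enhancer–gene pairing within 500 kbp, standardized-residual retention | `enhancer_pairing` |
| JASPAR parsing, deficit-thresholded PWM scanning, target-vs-background enrichment | `motif_enrichment` |
| seeded synthetic dataset with ground truth | `synthetic_data` |
| orchestration, config, report | `pipeline` / `cli` |

## Core statistics

**Differential testing.** Counts $y_{gj}$ are modeled as negative binomial
with $\log \mu_{gj} = x_j^\top \beta_g + \log(N_j f_j)$, where $N_j$ is the
library size and $f_j$ the TMM scaling factor, and the design contains
ecotype (sulfidic = 1), drainage and species. Tagwise dispersions are
method-of-moments estimates shrunk toward a common dispersion obtained by
maximizing the Cox–Reid adjusted profile likelihood. The ecotype
coefficient is tested by likelihood-ratio chi-square (default) or a
quasi-likelihood-style F test; significance is FDR < 0.05
(Benjamini–Hochberg).

**Enhancers.** A peak is a putative enhancer when no stable mRNA maps to
its −100..+500 bp window (*unstable*) and its center lies > 500 bp from
every promoter window ([TSS−1000, TSS+100]). DI enhancers are paired with
every DE gene whose TSS lies < 500 kbp away on the same scaffold, filtered
to matching fold-change sign, and retained when within one internally
studentized residual of the OLS fit of enhancer log2FC on gene log2FC.

**Motifs.** JASPAR PFMs become log2-odds PWMs with pseudocount 0.8; a
window scores a hit when its deficit
$(s_{\max}-s)/(s_{\max}-s_{\min}) \le 0.15$ on either strand. Enrichment
is a two-sided Fisher's exact test on the number of target vs background
sequences carrying ≥ 1 hit, significant at p < 0.01.

## Worked example

```sh
nascentreg simulate --seed 1 --out sim/
nascentreg run-all --data-dir sim/ --seed 1 --out out/
nascentreg report --report out/report.json
```

The report (abridged) on this seed:

```
de_genes               653
di_peaks               890
di_peaks_up            447
di_peaks_down          443
pairs_retained         3317
peaks_kept             4926
peaks_merged           5100
putative_enhancers     1475
```

61 200 per-sample peaks condense to 5 100 non-redundant peaks; 4 926
survive the initiation and input-library filters (the 174 removed are
dominated by the generator's planted input-heavy contaminants). 890 peaks
are differentially initiated between ecotypes (FDR < 0.05), 653 genes are
differentially expressed, 1 475 distal unstable peaks are flagged as
putative enhancers, and 3 317 same-direction enhancer–gene pairs fall
within one standardized residual of the regression line. The
`candidate_enrichment.json` output reports the Fisher odds ratio (2.57 on
this seed against a generating odds multiplier of 3) for peaks near
curated candidate genes being differentially initiated, and
`motif_enrichment_*.tsv` recover exactly the two planted motifs in all
four target sets.

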