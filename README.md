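# retroscope

Retroviral integration-site mapping and proviral expression-stability
analysis.

Gammaretroviral vectors integrate preferentially into active promoters and
enhancers; integrase variants (the BET-independent W390A mutation, or a
fused CBX chromodomain) retarget integration away from those features, and
the question becomes whether proviruses still express stably in the
non-preferred chromatin they land in. Answering it computationally takes
four steps, all implemented here for anyone mapping LTR junctions and
scoring proviral expression:

1. **Read processing** — junction reads
   (`barcode + LTR primer region + terminal LTR 9-mer + genomic flank + adapter`)
   are demultiplexed and reduced to their genomic flank by an anchored,
   substitution-tolerant trimming cascade with sharp minimum-overlap and
   minimum-length thresholds, discarding internally-primed (decoy) reads.
2. **Integration-site (IS) calling** — flank alignments that start at the
   read's first base and hit the genome uniquely are reduced to the single
   LTR-proximal base (start on `+`, end − 1 on `−`); positions with ≥ 5
   supporting reads are kept and near-duplicates within 5 bp collapse to
   the best-supported site.
3. **Chromatin profiling** — distances to chromHMM-style segments
   (`bedtools closest -d` semantics), membership in Hi-C subcompartments
   (A1–B3) and lamina-associated domains (LADs), uniform genome-wide
   shuffles as random controls, and the statistics on top: the *Impact*
   effect size comparing two distance distributions,

       ct_diff    = (median(b) − median(a)) / s_pool,   s_pool = RMS of the two 1.4826·MADs
       morph_diff = ½ ∫ |KDE(ã) − KDE(b̃)|,             ã, b̃ standardized per sample
       Impact     = ct_diff if |ct_diff| ≥ morph_diff else sign·morph_diff

   plus targeting frequencies, log2 fold changes vs a reference group, and
   exact binomial enrichment tests against the shuffle frequency.
4. **Expression quantification** — GFP+ gating against a mock control
   (99.9th-percentile gate), fold-change time courses vs the 3-dpi
   baseline, clonal variegation classes, ddPCR Poisson inversion
   (λ = −ln(1 − positives/total)), proviral copies per 100 genome
   equivalents (RPP30/2 genomes), and the active-genome ratio
   (% GFP+ per copy per 100 cells; 1 ≈ all proviruses active).

A first-class synthetic-data module (`retroscope.synthetic`) generates toy
genomes, annotations with exact coverage, planted IS sets with optional
promoter-proximity bias, junction reads with the precise landmark layout,
droplet counts and flow-event mixtures — so the whole pipeline is testable
hermetically, with every stage checked against planted ground truth.

## Worked example

```bash
retroscope simulate --out-dir demo --seed 5 --n-sites 40
cd demo
retroscope trim --in reads.fastq --out flanks.fastq --report trim_report.tsv
retroscope call-is --flanks flanks.fastq --genome genome.fa --out is.bed
```

which prints

```
wrote 709 reads for 40 sites (seed 5) to demo
outcome  reads
 passed    709
called 40 sites -> is.bed
```

All 709 error-free junction reads survive trimming and the caller recovers
exactly the 40 planted sites; `is.bed` lists each as
`chrom  pos  pos+1  name  read_support  strand`, e.g.
`chr1  15181  15182  IS_0  22  +` — an IS at base 15,181 supported by 22
reads. Annotation and statistics follow the same pattern
(`retroscope annotate`, `retroscope enrich`); on a biased-vs-uniform pair
of simulated IS sets `enrich` reports, for the Tss segment class,

```
comparison segment   impact  ct_diff  morph_diff           band  median_ref  median_group
 cbx_vs_wt     Tss 1.279048 1.279048    0.044383 medium-to-high        64.5        2743.0
```

i.e. the uniformly-placed set sits a median 2.7 kb from the nearest
promoter segment versus 65 bp for the promoter-biased set, a
medium-to-high Impact driven by the central-tendency shift. For expression,
`retroscope express --flow flow.csv --mock mock.csv --ddpcr ddpcr.csv`
gates each sample, folds the time course to its 3-dpi baseline and joins
ddPCR copy numbers into active-genome ratios.

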