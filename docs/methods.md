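# Methods

`retroscope` reimplements, as a tested pipeline over synthetic data, the
computational analysis behind a retroviral integration-retargeting study:
LTR-junction reads are reduced to genomic flanks, flanks are aligned and
collapsed into integration sites (ISs), sites are profiled against
chromatin annotations with shuffle-calibrated statistics, and reporter
expression plus ddPCR copy numbers are combined into active-provirus
fractions. This note records the models, conventions and design choices.

## Read model and trimming cascade

A junction read is

    barcode + LTR-primer region + terminal LTR 9-mer + genomic flank + adapter

with defaults `GCTTGCCAAACCTACAGGTG` (primer region), `GGTCTTTCA`
(terminal 9-mer), `ACCACTAGTGTCGAC` (adapter) and `TTCCCCCCTT` as the
internal proviral decoy that marks reads amplified from inside the vector
rather than across the junction. Trimming applies, in order:

1. anchored barcode match (min overlap 8) for demultiplexing, untrimmed
   reads unassigned;
2. anchored LTR-primer trim (min overlap 20), untrimmed discarded
   (`no_primer`);
3. anchored terminal 9-mer trim (min overlap 8), untrimmed discarded
   (`no_terminal`), survivors shorter than 15 bases discarded (`too_short`);
4. 3' adapter removal (min overlap 10; the minimum flank length is enforced
   again afterwards);
5. internal-decoy scan (min overlap 10), matching reads discarded
   (`internal`).

Matching is substitution-only with an error budget of
`floor(max_error_rate x matched_length)`; `max_error_rate` defaults to 0.1,
the customary adapter-trimmer default, since no explicit tolerance is fixed
by the protocol. Partial patterns are honoured at read boundaries (a
pattern prefix at a short read's start, an adapter prefix at the 3' end)
down to each stage's minimum overlap. N bases always count as mismatches —
the simplest defensible rule. Indel-tolerant matching is deliberately out
of scope: the simulator's substitution-only error model exercises the
tolerance logic, and the round-trip tests say nothing about indel-rich
platforms (a documented limitation).

## Integration-site calling

The IS is the single LTR-proximal base where the flank begins: alignment
start on the plus strand, alignment end − 1 on the minus strand. Only
alignments that consume the read from its first base (no 5' soft/hard
clip; for reverse-strand records the read start is the *last* CIGAR
operation) and that hit the genome uniquely (no secondary-score `XS` tag)
are used. In hermetic mode an exact-match scan of the toy genome replaces
the aligner; uniqueness is then literal occurrence count over both strands.

Calling counts reads per exact position, discards positions with fewer
than 5 supporting reads, and collapses retained positions within 5 bp
(|p1 − p2| <= 5) of one another, keeping the best-supported one. Three
conventions had to be fixed where the procedure is under-specified:

- collapse is per strand — opposite-strand sites a few bases apart flank a
  target-site duplication and are biologically distinct;
- chained clusters are resolved greedily by descending support, so a
  dominant site never loses to a weaker neighbour;
- equal-support ties go to the smaller coordinate.

The survivor keeps its own read count; counts are never merged. Calling is
idempotent and order-independent, which the tests assert directly.

## Feature annotation

Feature classes (chromHMM-style segments, Hi-C subcompartments A1–B3,
LADs) are sorted half-open interval sets. Distances are unsigned gaps:
overlap is 0 and a book-ended site is also 0. Some `bedtools closest -d`
dialects print book-ended pairs as 1; the cross-check test maps that
dialect onto ours (ours = bedtools − 1 for non-overlapping pairs). At the
kilobase medians the pipeline summarises, the off-by-one is immaterial.
Sites on a chromosome with no feature of a class yield absent records,
excluded and counted downstream; a fully disjoint chromosome namespace
(e.g. `chr1` sites vs `1` annotations) is a hard error.

Shuffled random controls relocate every site uniformly genome-wide
(chromosome chosen proportional to length, strand preserved). No
gap/blacklist exclusion is modelled and placement is not constrained to the
source chromosome — the plain behaviour of an unconstrained interval
shuffle.

## Impact effect size

Comparing distance distributions `a` (reference) and `b`:

- `ct_diff = (median(b) − median(a)) / s_pool`, where `s_pool` is the root
  mean square of the two normal-consistent MADs (1.4826 x MAD), falling
  back to the pooled SD when both MADs vanish; zero scale with equal
  medians gives 0.
- `morph_diff` = half the L1 distance between Gaussian KDEs of the two
  samples after each is centred at its own median and divided by its own
  scale. Bandwidths follow Silverman's rule on the standardized samples;
  densities are evaluated on a 512-point grid spanning the pooled range
  ± 3 bandwidths. A degenerate (constant) sample is a point mass: shape
  difference 0 against another point mass, 1 against a spread sample.
- `impact` is `ct_diff` when |ct_diff| >= morph_diff, otherwise
  `morph_diff` signed by the central shift (sign of the mean difference
  when medians tie; 0 when both vanish).

This is a fixed, testable formulation of a statistic the original analysis
delegated to an external package whose estimator and bandwidth choices are
not recoverable from the publication; numerical parity with that package is
a conformance goal, not a correctness criterion. The properties that *are*
asserted: exact zero on identical samples, sign antisymmetry under argument
swap, invariance under common positive rescaling, strict monotonicity of
`ct_diff` in a pure location shift, and recovery of the conventional bands
(|Impact| >= 0.5 medium-to-high, < 0.3 low) on planted promoter-proximity
bias versus uniform placement.

## Enrichment statistics

Targeting tables report per-group frequencies over a class family plus an
absorbing `none` class, with log2 fold changes against a named reference
group (undefined — NaN, never infinite — when either frequency is 0).
Enrichment against random targeting is a two-sided exact binomial test of
the observed in-class count against the pooled frequency of the shuffled
control sets; with >= 20 shuffle replicates an empirical permutation
p-value is reported alongside. Benjamini–Hochberg adjustment is applied
across a class family; the original analysis names no multiplicity
procedure, so adjusted and raw values are both kept.

## Expression quantification

- GFP gate: the 99.9th percentile ("higher" interpolation, so the mock's
  own above-gate fraction never exceeds 0.1%) of the viable-event
  intensities of an untransduced mock sample — a reproducible rule standing
  in for a hand-drawn cytometry gate. GFP+ fraction counts events above the
  gate; MFI is the median intensity of the positives.
- Fold-change time courses divide each timepoint's GFP+ fraction by the
  3-dpi baseline; the baseline is exactly 1.
- Clone classification partitions clones at 90% and 50% GFP+ into
  stable / variegated / mostly-silent.
- ddPCR: `lambda = −ln(1 − positives/total)` copies per droplet;
  concentration `lambda / droplet_volume` (0.00085 µL per droplet, the
  QX200 convention, configurable); copies per well scale to the 20 µL
  reaction. Saturated wells are rejected. Technical replicate wells are
  averaged on the copies-per-well scale before any ratio.
- Per-cell copy number uses RPP30 at two copies per diploid genome:
  genome equivalents = RPP30/2, reported per 100 genome equivalents
  (200 RPP30 copies). The printed formula for this normalisation is
  ambiguous in isolation; the 200-copies-per-100-equivalents convention
  fixes it.
- Active-genome ratio = (100 x GFP+ fraction) / copies per 100 cells.
  1 means every detected provirus expresses; Poisson multi-copy cells bias
  the ratio slightly below 1 even under full activity.

## Synthetic data: what it does and does not emulate

Generators are seeded and bit-reproducible. The toy genome is i.i.d.
uniform A/C/G/T; annotations are uniformly placed non-overlapping intervals
whose realized coverage is exact by construction (subcompartment labels are
placed jointly so the family is disjoint; a 50%-coverage LAD set mirrors
the genome fraction expected under random targeting). Planted sites are
uniform or promoter-proximal (exponential distance from a uniformly chosen
interval of a named label, mixing weight `w`); per-site read support is
uniform in [5, 30]. Junction reads follow the exact landmark layout;
minus-strand flanks are the reverse complement upstream of the site so the
aligned flank's coordinates recover the planted base; flanks running off a
chromosome end are truncated and recorded (the minimum-length filter then
removes them, as it would short real fragments). Droplets are Bernoulli
with the Poisson occupancy probability; flow samples are two-component
log-normal mixtures with a viability flag.

Not emulated: realistic sequencing error profiles (indels, homopolymer
errors), PCR duplicates, fragment-length distributions, partial/truncated
read structures, chromatin-dependent sequence composition, and cytometry
spillover. Passing tests therefore demonstrate the correctness of the
*computations* under the stated statistical structure, not robustness to
every artefact of real libraries.

## Validation scenarios and problem sizes

`retroscope.validation` fixes the canonical desk-scale scenarios used by
both the test suite and `scripts/acceptance.py`: a 50-site round trip on a
2 Mb genome (supports 5–30, with a 10% support-4 variant that must drop
exactly those sites); a 1,000-read trimming cohort with 5% decoy and 5%
short-flank reads checked read-by-read against simulator truth; 100
shuffle replicates of 3,000 sites on the 50%-LAD genome tested against the
expected 50%; the Impact identity/shift/planted-bias battery (10^4 draws,
500 sites per IS set); 100 ddPCR wells at 0.1 copies/droplet; and 1,000
null trials of the enrichment test at alpha = 0.05. These sizes keep the
whole suite in the tens of seconds while binomial sampling error stays far
inside every assertion margin.

## Known limitations

- Exact-match hermetic alignment cannot express mismatched or clipped
  alignments; SAM input exercises those filters instead.
- The Impact formulation here is one defensible reading of a
  coarsely-documented statistic; absolute values on real data may differ
  from other implementations even where signs and bands agree.
- Full-scale profile conformance (published median distances and
  subcompartment frequencies) requires the deposited IS coordinates and
  public annotation downloads; the profiling API runs on such files
  unchanged, but the repository ships no copy of them.
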