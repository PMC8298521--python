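# Methods

## The mapping problem

A haploid moss cross between a mutant strain (Gd genetic background) and a
divergent wild type (Vx) yields spores that germinate directly into
scoreable haploid segregants. A single fully penetrant causal locus
segregates 1:1, and a segregant's phenotype (protonemata growing downward
vs upward in darkness) reveals its genotype at that locus without phase
ambiguity. `mossmap` implements the two complementary mapping computations
this design supports — pooled (bulked-segregant) allele-depth mapping and
two-point linkage in individually genotyped segregants — plus the
variant-effect triage that turns a mapped interval into a candidate gene.

## Cross simulator

**Meiosis.** Crossovers per chromosome are Poisson with mean equal to the
genetic length in Morgans, placed uniformly on the genetic map
(no interference). Under this model the probability that two loci d Morgans
apart have discordant parental origins is exactly the Haldane recombination
fraction r = (1 − e^(−2d))/2, so the simulator and the map function used in
linkage analysis are two faces of the same model. Breakpoint genetic
positions are converted to physical coordinates by piecewise-linear
interpolation through the marker (cM, bp) pairs, with constant extrapolation
beyond the terminal markers; two crossovers landing on the same base cancel,
so haplotype segments always tile the chromosome with no zero-length pieces.

**Phenotype.** A segregant carrying the Gd origin at the causal locus is
scored "down" with probability `penetrance` (default 1.0), otherwise "up";
each segregant is independently relabeled "undetermined" with probability
`undetermined_rate` (default 0). Undetermined segregants never enter a bulk
and are dropped from linkage counts.

**Pooled sequencing.** Per marker, total depth ~ Poisson(coverage); each
read derives from a uniformly chosen bulk member's origin allele and is
flipped to the other parental allele with probability `error_rate`. The
implementation draws the exact binomial marginals of this per-read scheme
(Gd templates ~ Binomial(depth, pool Gd fraction), then error flips in both
directions), which is distributionally identical and vectorises over
markers. At the causal marker the expected observed Gd fraction is 1 − e.

**Default conditions.** One 20 Mb chromosome carrying a 100 cM linear map
with 2,000 evenly spaced markers and the causal locus at 10 Mb; 192 progeny
(a realistic spore-capsule yield that makes a 48-member downward bulk
essentially always available under 1:1 segregation); bulk size 48; mean
coverage 50 reads per marker; error rate 0.01. The simulator emulates
marker-level allele depths, not reads: alignment artefacts, depth
overdispersion beyond Poisson, segregation distortion and genotyping error
in individual segregants are outside the model, so passing tests demonstrate
correctness of the mapping computation, not robustness to those real-data
effects (penetrance and `undetermined_rate` are the knobs for probing the
latter).

## Pooled mapping statistic

The per-SNP statistic is the Gd allele-depth fraction gd/(gd+vx), undefined
(and skipped) when both depths are zero. The literal quotient gd/vx would be
≈ 1 at unlinked loci and divergent at the causal locus; the fraction is the
form for which "peak approaches 1" is meaningful, with an unlinked baseline
of 0.5. Windows are bp-anchored and half-open, [k·S, k·S+W), W = 500 kb,
S = 250 kb; a window's value is the unweighted mean of the defined ratios
inside it, masked (reported missing, never zero) below `min_markers` = 5.
Peaks are maximal runs of ≥ `min_run` contiguous unmasked windows with mean
≥ `threshold` (default 0.9); the run spans the reported interval, its
maximal window (leftmost on ties) is the peak window, and peaks sort by
peak value. Threshold, min_run and min_markers have no prescribed values in
the underlying design; the defaults are package choices, all configurable.

Note the expected fraction at map distance d from the causal locus is
(1−r)(1−e) + r·e with r the Haldane fraction — about 0.68 even 50 cM away —
so on a single 100 cM chromosome no marker is truly at baseline. The
unlinked baseline of 0.5 is realised exactly by markers on a second,
physically unlinked chromosome (independent assortment, r = 1/2), which is
how the baseline checks are constructed.

## Two-point linkage and refinement

A segregant is recombinant for a marker when the marker's parental origin
disagrees with the origin implied by the phenotype (down ⇒ Gd, up ⇒ Vx);
r̂ = recombinants / informative. Haldane's d = −50·ln(1−2r) cM converts to
map distance (Kosambi available as an alternative); r ≥ 0.5 is reported
unlinked. The refined interval runs from the nearest marker left of the
fully cosegregating block that still shows ≥ 1 recombinant to the nearest
such marker on the right; a side with no recombinant marker extends to the
chromosome end with a warning. The two-round driver mirrors practice: a
sparse genome-spanning panel first, then every marker inside the round-one
interval. In the original two-round mapping of this locus the two rounds
were reported as "283 kb" in the figure and "238 kb" in the text; that
discrepancy belongs to the source and is recorded here rather than
resolved.

## Variant effects

Codon-level classification uses an explicit standard-nuclear-code table;
tests verify it exhaustively against an independent translate-and-compare
oracle over all 4,096 codon pairs. Strand is handled by mapping the genomic
position to its CDS offset in transcription order and complementing the
alternate base on minus-strand genes; codon index is offset÷3 + 1. Intronic
positions within 2 bp of an exon boundary are splice_site (the canonical
GT/AG positions); the splice window size is a package choice. The candidate
filter keeps missense and stop_gained inside the interval — stop_lost and
start_lost are classified but excluded by default, and splice_site is
behind an off-by-default flag, matching the stated retention rule
("nonsynonymous and nonsense within genes"). SNVs only; indels are out of
scope. Restriction-design arithmetic treats printed positions as abstract
cut coordinates (the internal fragment between adjacent sites has length
equal to their position difference), and kb values are reported to two
half-up decimals, reproducing the 4,642 bp ⇒ 4.64 kb worked example.

## Angle summaries

Bending is measured against the original growth axis, reduced to [0, 360)
(the sign convention of the schematic source is not fixed in text; the
package documents it as counterclockwise-positive and reports in [0, 360)).
The circular mean is atan2 of the mean sine and cosine; the resultant
length R̄ ∈ [0, 1] quantifies concentration, and the mean is reported
undefined when R̄ vanishes (antipodal data). Kinetic curves use the
arithmetic mean ± sample s.d. per timepoint over the filaments present —
appropriate while angles stay within one cycle, which they do here.

## Numerical and design choices

- Coordinates are 1-based, both ends inclusive, everywhere except the
  half-open bp-anchored windows above; BED output converts to 0-based
  half-open on disk.
- All stochastic operations take an explicit generator derived from one
  seed; the pipeline is a pure function of (config, seed) and re-runs are
  byte-identical.
- Bulks are the first n matching segregants in input order (deterministic);
  ties in peak value break leftmost.
- Markers must carry distinct parental alleles; marker and variant
  positions may not fall on an N base.
- SSR-type markers are treated as ordinary codominant biallelic markers.

## Problem sizes

Tests and the acceptance script use the default conditions above: 20
seeded replicates for pooled-mapping and refinement recovery, 10,000
meioses for the Haldane calibration, 1,000 progeny for the segregation
check, and 200 replicate pools for the unlinked-expectation check. The
refinement comparison genotypes 282 vs 48 segregants at a 7-marker local
panel around the causal locus.

## Known limitations

- No read-level simulation (FASTQ), no alignment or variant calling; depth
  tables are the interface.
- Single isoform per gene; no UTR-aware effect subtleties beyond a simple
  utr class; no population-frequency or quality filtering.
- Peak calling reports interval runs, not statistical significance
  envelopes; one bulk only (no ΔSNP-index contrasts).
- The no-interference meiosis model is an assumption, chosen for
  consistency with the Haldane map function, not a fitted property.
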