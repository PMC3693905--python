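# Methods

This note documents the models, algorithms and numerical choices behind
`clovermap`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Genetic model and simulator (`popsim`)

The simulator emulates the study design of a two-population white clover
map-integration experiment: a strict disomic allotetraploid genome of 8
homoeologous chromosome pairs (each pair = two independent diploid
chromosomes; homoeologues never pair at meiosis), two unrelated outbred
F1 populations from highly heterozygous parents, and a 16-genotype
diversity panel.

**Meiosis.** Crossovers are a Poisson process with expectation
(length cM)/100 per chromosome, i.e. Haldane's no-interference model.
This gives exact closed-form expectations for recombinant fractions
(r = (1 − e^(−2d/100))/2), which the test suite uses as oracles.  The
estimation side reports Kosambi distances, as is conventional for
published clover maps; recovery tests therefore compare *orders* and
*correlations* against truth, and map-length recovery is asserted within
15% (the Haldane/Kosambi discrepancy at the simulated marker spacing is
≈3%, well inside that band).

**Markers.** `markers_per_group` loci are evenly spaced along each
linkage group (published groups have fairly uniform density).  Each
marker amplifies its primary homoeolocus and, with probability
`dual_homoeolocus_probability` (default 0.25, matching the ≈25% of
mapped markers that identified homoeoloci), the sister homoeolocus at
the same position.  Allele sizes are integers drawn from a per-homoeolocus
pool of 6 sizes at 2 bp steps; homoeologue 2 is offset by
`homoeologue_size_offset` (default 30 bp > the 10 bp spread, so ranges
are disjoint; set the offset below the spread to produce deliberately
ambiguous size evidence).  Parents draw two alleles per locus with
replacement (≈83% heterozygosity — "highly heterozygous" without being
artificial); `force_heterozygosity` exists for tests that need every
locus informative.  Null alleles (probability 0.05 per allele) are
invisible in all observed calls; missing data (0.02 per marker ×
individual) blanks a whole marker call.  The published study states
neither rate; these defaults are typical of capillary SSR datasets and
are free parameters of the generator.

**Populations and panel.** Each progeny is the union of one maternal and
one paternal gamete.  A fraction of markers (default 0.3, giving ≈6
joining markers per group against the published mean of 7.6 evidence
loci per group) is genotyped in both populations; the rest split evenly.
Panel individuals draw independent genotypes from the same allele pools,
so single-homoeolocus markers can never show more than two alleles while
dual markers usually do.

**Distortion.** Gametic viability selection: a distortion locus assigns
relative viabilities to the carrier parent's two phases at the marker
nearest the stated position, and gametes are rejection-sampled (bounded
attempts; impossible weights raise).  Zygotic selection is not modelled.
Because selection acts on one position, the chi-square signal at linked
loci decays with map distance — the property the scan's signed
−log₁₀(P) profiles visualize.

**What the simulator does not emulate:** genotyping error (beyond
nulls/missingness), segregation of more than two homoeologues
(tetrasomic or mixed inheritance), crossover interference, related
parents, population structure in the panel, and sequence-level SSR
mutation.  Passing recovery tests therefore show the estimators are
correct under clean disomic inheritance at realistic sample sizes, not
that they are robust to assay artefacts absent from the model.

## SSR mining (`ssr`)

Perfect tandem repeats of primitive 2–6 nt motifs, thresholds di ≥ 6 /
others ≥ 5 repeats, reported left-maximal at their shortest-period
representation; `N` breaks arrays.  Coordinates are 0-based half-open.
The scanner is verified against exhaustive enumeration (property test
over random sequences).  Primer feasibility is a geometric screen —
flanks must host a 27 nt primer and some amplicon containing the array
plus two 20 nt primers must fit 95–395 bp; melting temperature is
deliberately out of scope (thermodynamic design belongs to dedicated
primer software).  The quality filter interprets a phred-50 exclusion as
a per-sequence mean (threshold configurable), one of several defensible
readings.  In-silico PCR uses exact-match, convergent-orientation
semantics; product intervals include both primers.

## Linkage analysis (`linkage`)

Segregation typing enumerates the four gamete unions and pools identical
*observable* phenotypes, so null-allele configurations collapse classes
automatically, and the same enumeration yields the transmission decoder
(observable class → transmitting parent's allele slot where unique).
Estimation then reduces every configuration to per-parent meiosis
vectors; the two-point MLE is the pooled recombinant fraction with
per-parent phase chosen by likelihood (ties toward coupling), and LOD
sums per-parent log-likelihood ratios.  Pairs with fewer than 10 scored
meioses are excluded from grouping — at n = 92 this keeps LOD ≥ 8
meaningful.

**Ordering.** Commercial regression-mapping internals are not public, so
ordering is a documented greedy seriation: seed with the highest-LOD
pair, insert each next locus (strongest link first) at the slot
minimizing the LOD-weighted squared error between pairwise Kosambi
distances and path distances, then refine with adjacent swaps, segment
reversals and short block relocations to a local optimum.  Two numerical
guards matter: pairs estimated effectively unlinked (r ≥ 0.45) are
excluded from the objective, because the mapped distance diverges as
r → 0.5 and a handful of such pairs can otherwise dominate the error;
and the distance matrix is repaired by shortest paths through
confidently linked pairs, so candidate orders can be positioned even
where two loci share no informative meioses (e.g. one maternal-only and
one paternal-only locus).  Orientation is canonicalized by placing the
lexicographically smaller terminal locus first.  Acceptance is defined
by recovery on synthetic truth, not by equality with any particular
mapping program.

**Grouping drop-outs.** Under the default study conditions a locus
occasionally has no LOD ≥ 8 edge to any other locus (a terminal,
single-parent-informative locus whose nearest same-parent neighbour is
tens of cM away).  No method can group such a locus at that stringency;
recovery tests therefore compare partitions over loci whose best
pairwise LOD reaches the threshold, and separately assert that these
drop-outs stay below 2% of loci and that recovered components never mix
or split true chromosomes.

**Distortion scan.** Per locus, observed class counts are tested against
the configuration's expected ratios (chi-square, classes − 1 df; exact
multinomial fallback when an expected count falls below 1 at small n).
Parental origin comes from per-parent transmission tests against 1:1;
the signed profile is −log₁₀(P) (positive) for female-derived and
+log₁₀(P) (negative) for male-derived distortion, with the stronger
parent deciding the sign when both are informative.  The criterion for
flagging a distorted locus as *removable* — both flanks non-distorted
and the locus's |signed log₁₀ P| exceeding both flanks' by more than
2 — operationalizes the qualitative "incongruous with flanking loci"
rule; no published formula exists, so the margin is exposed rather than
hidden.

## Homoeologue matching (`homoeologue`, `pipeline`)

SL-HS designation is exact: a single-locus-segregating marker passes iff
no panel individual shows more than two distinct alleles (empty panels
are an error, not a pass).  Pairing evidence has a strict precedence:
SL-HS links that split across both sister groups are a hard conflict
(unresolved, never accepted — enforced in the constructor); otherwise an
SL-HS-linked pairing is accepted unless the net allele-size vote
strictly favours the alternative, in which case the artifact returns
unresolved rather than guessing (a case the source study never
encountered).  Without SL-HS evidence, the pairing maximizing
size-matches minus size-mismatches wins; ties are unresolved.  Allele
size ranges are [min, max] of observed sizes per locus; overlapping
candidate ranges, straddling observations and missing sizes are all
classed ambiguous.  Accepting one pairing fixes the sister pairing by
elimination.

## Map integration (`integration`)

The joining-locus merge defines a consensus frame as the
population-size-weighted mean of the raw anchor positions, affinely
rescales each source map onto it by least squares, and places anchors at
the weighted mean of the rescaled positions (with two anchors this is
exactly the weighted-mean placement).  Non-joining loci interpolate
linearly between flanking anchors; beyond terminal anchors the nearest
segment's scale applies; the result is re-anchored at 0.  Source-map
locus order is preserved by construction, and the strict merge treats
any anchor-order discordance as an error listing the offending loci.
Because tiny order swaps between tightly linked anchors are expected
estimation noise at finite n, the *pipeline* (not the merge) reconciles
conflicts by demoting the minimal set of order-breaking joining loci
(longest concordant subsequence kept as anchors) before calling the
strict merge; demotions are reported.  The least-squares rescaling can
shrink a noisy source map by a few percent, so the integrated span is
bracketed by the source spans only up to that shrinkage.

## Genome statistics (`genomestats`)

Expected length inflates each group's observed length by (m+1)/(m−1);
coverage divides summed observed by summed expected length (totals, not
per-group averages — per-group averaging does not reproduce the
published coverage triplet); saturation is c = 1 − e^(−2dn/G), verified
against Monte-Carlo circle-dropping.  Two documented irreproducibilities
in the published summary table are treated as non-targets: the expected
lengths printed for integrated-map groups 2-1/2-2 and 6-1/6-2 are
interchanged relative to computation from their own rows, and MP1's
per-group expected column cannot be derived from its printed observed
lengths (only MP1's totals are used, via the published expected total
1220.7 cM).  The IM per-group observed lengths also sum to 1273.7
against a printed total of 1273.6 — a rounding artefact carried by the
source table.

## Synteny (`synteny`)

Map and reference coordinates are both proportional (cM along each
conflated homoeologous group — homoeoloci plotted separately rather than
averaged, so homoeologue disagreements stay visible; bp midpoint along
the pseudomolecule, strand kept as metadata).  Hit filtering keeps, per
query, hits at E ≤ 1e−20, at most five by ascending E, then the single
strongest (ties by bit score, then input order).  Co-linearity fits a
Siegel repeated-median line per (group × dominant chromosome) block and
counts hits within a residual band (default 0.1 of normalized length) —
a reproducible stand-in for the by-inspection "linear pattern" judgment,
with the threshold exposed as a flag.  Translocation detection segments
the ordered chromosome labels of a group by a dynamic program equivalent
to exhaustive ≤ 3-breakpoint search (verified against enumeration); a
segmentation is only confident when every segment has ≥ 3 supporting
hits (the minimum secondary support observed in practice), otherwise the
breakpoint budget shrinks and interleaved sequences collapse to a single
low-purity segment.

## Problem sizes

Recovery tests run the full study design — 8 homoeologous pairs × 2
homoeologues × 20 markers over 80 cM, populations of 92 and 184 — over
20 seeds, with 40-seed ordering checks at the 10-locus scale and 50-seed
pooled checks for type-I error and distortion locality.  These sizes
make every stochastic assertion a property of distributions rather than
single draws while keeping the default suite comfortably fast on one
CPU.
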