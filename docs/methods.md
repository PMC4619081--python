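# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the design decisions taken where the problem was
genuinely open.

## Coordinates and formats

All internal coordinates are 0-based half-open; GTF is read as 1-based
inclusive and BED/bedGraph written 0-based half-open.  Signal tracks are
piecewise-constant per-base values; positions not covered by a segment are
0, so every interval query is defined.  Queries past a chromosome's
recorded extent are 0-valued, and the mappability window is truncated at
the recorded extent (the fraction is then computed over the available
positions).

## Candidate-exon catalog

A cassette-exon candidate must be (a) internal in **every** transcript
containing it, (b) not overlapped by any non-identical annotated exon
(strand-blind coordinate overlap), (c) 50–450 bp long, (d) at least 600 nt
from every annotated TSS and TTS of its host gene (distance from the exon
boundary to the site; the strictest reading — `tss_scope="member"` restricts
the check to the exon's own transcripts), (e) flanked by canonical GT..AG
introns in every member transcript, strand-aware, and (f) on chromosomes
1–22 or X.  Flanking-intron junctions are recorded from the
lexicographically smallest member transcript when members disagree; for
typical cassette geometries all members agree.

Splice-site strength is a pluggable scorer; the default is log2 odds
against a uniform background over maxEnt-convention windows (donor 9 nt =
3 exonic + 6 intronic; acceptor 23 nt = 20 intronic + 3 exonic).  Windows
containing N score NaN and drop out of strength comparisons.  MaxEnt-style
matrices can be supplied but are not bundled.

## Inclusion quantification and differential calling

psi = 0.5·JIR/(0.5·JIR + JER), with JIR pooled over the two inclusion
junctions and over replicates.  Orientation is fixed package-wide:
delta_psi = psi(cell2) − psi(cell1) and "more included" means higher in
cell2; differential chromatin signals use the same cell2 − cell1
orientation.

The test is the pair of one-sided Fisher exact tests on the pooled 2x2
read table, evaluated as hypergeometric tail probabilities (vectorised;
the empty table is assigned p = 1 in both tails).  An exon is testable
with >= 1 inclusion read in one cell and >= 1 exclusion read in the other,
assessed after replicate pooling.  BH correction is applied per cell pair
separately to each tail; classes {more, less, notAS} are disjoint and
exhaustive over tested exons (the two one-sided q-values of one table
cannot both fall below alpha <= 0.5).

Replicate reproducibility is enforced by a concordance filter: both
replicate psi values defined and |psi_rep1 − psi_rep2| <= 0.1 (an
irreproducibility-rate analysis stand-in; the threshold is configurable
and the filter can be disabled).  Note that at moderate depths this filter
removes exons by sampling noise alone: at ~50 reads per junction the
between-replicate psi difference has sd ≈ 0.06, so roughly a tenth of
perfectly well-behaved exons fail a 0.1 cutoff.  Recovery benchmarks of
the test itself therefore run with the filter disabled; the discovery
pipeline keeps it on by default.

Regulated exons additionally require an inclusion change >= 0.1 **or**
>= two-fold (symmetric ratio), host-gene CAGE expression fold <= 10 (genes
with zero expression in either cell are excluded), and >= 75 % mappability
in the 900-bp acceptor-centred window ("around the acceptor" is resolved as
centred).  One exon per gene and direction is kept, by the lowest one-sided
p; ties break to the leftmost exon.  For notAS exons the per-gene pick is
the minimal |delta_psi|.

## Chromatin signal

EAS (exonic average signal) is the arithmetic per-base mean over the exon.
The differential signal defaults to log2(EAS2 + 1) − log2(EAS1 + 1); the
raw difference is available (`transform="raw"`).  The log2 form is the
default because it is robust to depth scaling; the pseudocount of 1 keeps
zero-signal intervals finite.  Profile windows are 800 bp around the exon
midpoint, binned at 20 bp (binning granularity is our choice), oriented in
transcription direction, aggregated as mean ± s.e.m.  Group-level
association reports both the signed-rank test of each direction group
against zero and the rank-sum test between groups, Bonferroni-corrected
across features — both variants are in circulation for this analysis, so
both are exposed.

## Promoter-like clustering

Each direction group's differential matrix (H3K9ac, H3K4me3, H3K27ac,
CTCF, control) is z-scored per feature (population SD; zero-variance
columns become zeros with a warning — scaling before k-means is our choice)
and clustered with k-means, k = 4, 100 restarts, fixed seed; cluster ids
are relabelled by descending mean H3K9ac so labels are stable.  Selection
replaces by-inspection cluster picking with an explicit rule: a cluster is
promoter-like iff the mean z of all three acetyl/methyl marks is concordant
with the direction (positive for more-included, negative for less-included)
and >= tau = 1.0 in magnitude.  CTCF and control are clustering features
but never enter the selection rule.  An inertia scan over k in {2..5} is
provided as a diagnostic; k = 4 is the default.

Hold-out validation: on a cell pair not used in discovery, among exons with
|delta_psi| > 0.1 and |sum of the three mark differentials| > 1, the
reported statistic is the fraction whose chromatin-change sign matches the
inclusion-change sign.

### Identifiability limit of the planted-recovery setting

With promoter-like rows shifted by +2 SD on each of the three marks (and a
mild −1 SD control dip), planted and background rows are two unit-variance
Gaussians separated by ||c|| ≈ 3.6 in z-space.  The Neyman–Pearson bound
then caps any classifier's sensitivity at ≈ 0.85 when false positives are
held to 10 out of 1,900 background rows — so demanding >= 90/100 recovered
with <= 10 false calls at a 5 % prevalence is infeasible at that effect
size, for k-means or anything else.  The corresponding acceptance test runs
the +2 SD conditions verbatim and is expected to fail; the machinery itself
is verified at +3 SD, where the subset is identifiable and the pipeline
recovers ~99/100 planted with <~5 false calls.

## Promoter context

CAGE clusters are assigned to the closest TSS within 100 nt (ties go to the
smaller coordinate); gene expression is the summed score of clusters
assigned to any of the gene's TSSs (additive under cluster splits).  The
"used" TSS is the nearest cluster with score >= 1, annotation-independent,
measured interval-to-interval (a qualifying cluster overlapping the exon
gives distance 0).  ChIA-PET interactions count links with >= 1 anchor
overlapping the exon, half-open, no padding by default.  Same-state
extension merges adjacent equally-labelled chromHMM segments and asks
whether the exon midpoint and the used TSS fall in one contiguous run;
coverage gaps break the run.  The TSS locus for the exon-vs-TSS mark-shift
comparison is ±200 bp around the used TSS (configurable; undefined in the
source analyses).  Motif enrichment is an upper-tail hypergeometric test of
foreground hits against foreground + background with BH across motifs; the
occurrence matrix comes from a pluggable scanner or is supplied directly.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the sequence biology of real loci:

- **Genome/annotation**: one chromosome of independently drawn bases;
  each gene has 5 exons (one middle cassette exon), GT..AG introns of
  700–1,200 nt (so internal exons sit > 600 nt from TSS/TTS), internal exon
  lengths 80–300 bp, alternating strands, and two transcripts (inclusion
  and skipping isoform), making the cassette exon internal in every
  transcript containing it.
- **Junction reads**: transcript-coherent Poisson sampling — every intron
  of the inclusion isoform draws Poisson(psi·depth) reads per replicate and
  of the skipping isoform Poisson((1−psi)·depth), so shared introns carry
  Poisson(depth) and the estimator is centred on the true psi with no
  double counting between neighbouring exons.  `depth` is therefore the
  mean read count per junction (default 50, echoing deeply sequenced
  cell-line data).  The coordinate-free generator
  (`simulate_inclusion_counts`) draws the same law per exon.
- **Defaults as study conditions**: 3 % of cassette exons regulated and
  4 % of regulated exons promoter-like, echoing the reported proportions;
  planted |delta_psi| ~ U(0.2, 0.5).
- **Tracks**: per-25-bp-bin log2 values ~ N(3, 1) i.i.d. per mark and cell
  (value = 2^log2); promoter-like exons add +2 SD (default) on the three
  promoter marks in the C-higher cell only, strictly confined to exon bins;
  TSS windows add +4 in all cells; the control track dips mildly (−1) at
  enriched exons.  Effects are additive on log2 signal in noise-SD units,
  which makes the clustering tau directly interpretable.
- **CAGE/loops/segmentation**: clusters with score >= 1 only at used TSSs;
  45 % of promoter-like exons use an alternative, exon-proximal TSS in
  C-higher; Pol-II loops connect promoter-like exons to their used TSS with
  probability 0.9 in C-higher vs 0.3 in C-lower; 40 % of promoter-like
  exons share a chromatin-state run with their TSS.

What the generator does **not** emulate: realistic sequence composition or
motif content, correlated noise between marks, fragment-level ChIP
structure, NMD, isoform-level abundance dynamics, or multi-cassette genes.
Passing tests therefore demonstrate the correctness of the statistical
machinery and the recoverability of planted structure, not performance on
real consortium data.

Determinism: every file is a pure function of (SimConfig, seed); identical
configs give byte-identical bundles.

## Pipeline and evaluation

`run_discovery` executes catalog → calling → differential signal →
clustering → context from one bundle directory and writes a JSON manifest
with a parameter hash and sha256 checksums of all outputs; identical
inputs give identical manifests.  Direction groups smaller than k are not
clustered (no promoter-like calls for that group).  Evaluation against the
truth table reports confusion counts, sensitivity (recovered/planted) and
realized FDR (false calls/calls, undefined when no calls) for regulated
and promoter-like calls, with per-direction breakdowns.

## Problem sizes

Test and acceptance runs use desk-scale problems chosen to make the
statistical properties measurable: 2,000 exons for recovery benchmarks,
2x1,000 comparisons for clustering, 1,000 random fixtures per geometry
oracle, 1,000 replicates for null-coverage checks, and bundles of 15–120
genes for end-to-end runs.

## Known limitations

- The concordance filter's attrition at moderate depth (above) couples the
  effective sensitivity of the full pipeline to sequencing depth.
- Junction counting requires exact intron coordinates; fuzzy splice-site
  matching is out of scope.
- The PWM splice-site scorer is a linear model; a maximum-entropy scorer
  can be plugged in but is not implemented here.
- Alternative 5'/3' splice sites, retained introns and mutually exclusive
  exons are out of scope (cassette exons only).
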