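# Methods

This note documents the models and procedures implemented in `methylrad`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the simulator-based tests do and do not demonstrate.

## The measurement principle

Mrr-like methylation-dependent restriction endonucleases (FspEI, MspJI,
LpnPI, ...) recognise a 5-methyl- or 5-hydroxymethyl-cytosine in a short
single-strand context and cut double-stranded DNA at a fixed distance on the
3' side of the modified base. For FspEI the contexts are C^mC (the methyl-C
is the second cytosine) and ^mCDS (D = A/G/T, S = C/G), with cuts 12 nt away
on the strand carrying the methyl-C and 16 nt on the opposite strand,
leaving 4 nt 5' overhangs. When a site is *symmetrically* methylated — one
methyl-C on each strand in a compatible geometry — the enzyme cuts on both
sides and excises a ~32 nt fragment containing the site. Sequencing those
fragments (tags) and counting reads per site yields a genome-wide, relative
measure of methylation at single-site resolution, with no bisulfite
conversion and no reference genome strictly required.

## In-silico digestion (`enzyme`)

`enumerate_sites` finds every (top-strand methyl-C `t`, bottom-strand
methyl-C `b`) pair where both positions carry a recognition context and the
bidirectional near/far cuts excise a single fragment. With cuts measured 3'
of each methyl-C the fragment is the forward-strand interval
`[b - 16, t + 17)` of length `33 - (b - t)`. Requiring 31-33 nt admits
offsets `b - t` of 1 (32 nt; canonical CCGG) and 2 (31 nt; canonical CCWGG);
offset 0 is impossible (one base cannot be both C and G) and offset 3 falls
below the band. This geometric derivation is the package's reproducible
surrogate for the experimentally determined context list of the enzyme; it
is anchored by the requirement that canonical CCGG and CCWGG sites are
admitted with the expected fragment sizes.

Conventions worth stating:

* Coordinates are 0-based, half-open everywhere internally.
* Sites are anchored on the forward strand; palindromic loci appear once.
* A locus is classified `CCGG` (forward motif CCGG at offset 1, including
  the CCGG inside CCCGG), `CCWGG` (CCAGG/CCTGG at offset 2), else `OTHER`.
* Overlapping registers that share a methyl-C — e.g. the two
  indistinguishable methylation forms of CCCGG — collapse to a single site,
  preferring CCGG over CCWGG over OTHER, then the smaller offset. The rule
  is symmetric under reverse complementation.
* Any N inside the fragment disqualifies the site (the tag would not be
  sequenceable/matchable).

`rtr_subset` models reduced tag representation: an adaptor with a selective
overhang (e.g. 5'-NNNT-3') ligates a fragment end only if the fragment's
5' overhang is antiparallel-complementary to it. Both adaptor-to-end
assignments are tested. Under uniform base composition one selective base
per adaptor retains 1/16 (same adaptor at both ends) or 1/8 (two different
adaptors) of sites; in a genome at GC fraction g the per-end probability of
a selective C or G base is g/2, not 1/4, so retention on real genomes
deviates from these idealised fractions.

## Read QC (`qc`)

Reads are 1x36 nt: a 31-32 nt tag plus 3' adaptor fill. QC removes a
3' adaptor occurrence (leftmost match, at most 1 mismatch, at least 4 nt
overlap; internal occurrences must match the full adaptor prefix), trims
2 nt from *each* end of the insert (ligation-position artefacts; the wording
of the protocol leaves one-versus-both ends open — both is the conservative
choice), and drops reads containing any N or more than five bases under Q10.
The minimum retained insert defaults to 26 nt so that two-mismatch mapping
stays specific; Phred+33 encoding is assumed and configurable. Reads are
assumed pre-demultiplexed (index reads are instrument-side and never appear
in the 36 nt insert).

## Tag mapping (`mapping`)

The reference is one short tag per site, so the mapper is an exact
best-Hamming-distance search rather than a heuristic aligner: every
alignment of the read within every tag window, on both strands, is scored;
the minimum mismatch count (at most 2) wins; a read is `unique` only when a
single site attains the minimum, `multi` otherwise, `unmapped` beyond the
budget. A pigeonhole index (read split into three parts; any hit with at
most 2 mismatches matches one part exactly) accelerates lookups without
changing this contract, and the test suite holds the index equal to a
brute-force scan. Indels are not modelled — tags are fixed-length and the
mismatch-only model matches the protocol's mapping step.

Depth tables count unique reads by default; multi-mapping reads can be
spread fractionally (1/k to each of k best sites) but the conservative
default excludes them, since repetitive regions are exactly where depth
would otherwise be inflated. Library size records all mapped reads and
RPM = count x 1e6 / library size.

## De novo references (`denovo`)

Without a genome, reads are pooled into exact-sequence clusters (sequences
seen fewer than `min_depth` = 2 times are discarded), then merged by single
linkage at Hamming distance <= 2 within equal-length strata, grouping tags
from different alleles of one locus. The representative is the
depth-weighted per-position consensus; position ties go to the deepest
member's base, then lexicographically — making the pipeline deterministic
under input-order permutations. Single linkage can transitively chain
alleles more than 2 mismatches apart; that is the documented behaviour of
stack-style merging. Clusters whose log-depth exceeds the mean by more than
two sample standard deviations are flagged repetitive and excluded from
M-index calibration in de novo mode. CDR site classes are inferred from the
motif near the fragment centre and labelled as inferred.

## Quantification (`quantify`)

**M-index.** `M = log(depth_site) / log(depth_max)`, capped into [0, 1];
`depth_max` is the mean raw depth of the top 2% of detected sites (the
summary statistic is configurable: mean is robust to a single outlier;
median and max are offered). A depth-1 site has M = 0 but counts as
detected; zero-depth sites are absent. Calibration below ~50 detected sites
triggers a warning, and `depth_max <= 1` is an error. The index is a
*relative* measure: monotone in depth and rank-preserving under rescaling,
but not invariant to multiplying all depths by a constant (only a power
transform of depths cancels exactly in the log-ratio, which the property
tests exercise with `calibration="max"`).

**Trinary calls and concordance.** Calls are high (M >= 0.80) / low
(M <= 0.20) / medium. Two libraries are concordant at a shared site if the
calls agree *or* |dM| < 0.1; both components are reported separately so
either reading of the composite rule is recoverable.

**Control-based FPR.** On a known-unmethylated control contig (the
chloroplast, in plants) every enumerable site is a potential false
positive: FPR% = 100 x (control sites at or above a read threshold) /
(possible control sites). FPR is non-increasing in the threshold by
construction.

**Windows and rarefaction.** Genome-wide profiles average M over 200 kb
tiling windows (empty windows are missing, not zero, unless zero-fill is
requested). Rarefaction subsamples the per-site count vector without
replacement (multivariate hypergeometric — equivalent in distribution to
re-mapping a read subsample, and far cheaper), reporting sites detected and
the Pearson correlation of the M-index against the full library over sites
detected at both scales.

## Differential methylation (`diffmeth`)

Two-group testing on site-by-sample count matrices follows the
quantile-adjusted conditional maximum-likelihood family: sites detected in
fewer than 8 samples (overall; a per-group variant is available) are
removed; libraries are equalized by binomial thinning to the geometric-mean
library size (thinning probability capped at 1 — counts cannot be
inflated); a common negative-binomial dispersion is estimated by maximizing
the likelihood conditional on per-site group totals (counts given their
total follow a Dirichlet-multinomial with equal shapes 1/phi) over a
log-spaced grid with bounded refinement, with phi = 0 (Poisson) admissible;
each site is then tested exactly: conditional on the site total, the
group-A total follows a negative hypergeometric law (binomial split at
phi = 0), and the two-sided p-value sums all splits no more likely than the
observed one. Bonferroni (not BH) controls the family-wise error, as the
original protocol prescribes. This is a re-implementation of the method
class with a deliberately simple dispersion estimator; parity with any
particular package's internals is a non-goal — calibration (type-I error
near nominal) and power are the contract, and the phi = 0 path is held
exactly equal to the closed-form conditional binomial in tests.

## Simulator (`simulate`)

The generative model inverts the M-index so quantification is consistent by
construction: site counts are Poisson(depth_max^M*) for truth M* > 0, with
depth_max defaulting to 256 counts. Unmethylated sites (M* = 0, including
all control-contig sites) emit reads only through a background channel:
with probability 0.03 a site emits 1 + Poisson(1.2) reads. These two
defaults were chosen so the simulated control FPR lands at the magnitudes
observed on a real unmethylated chloroplast (~3% of possible sites at
>= 1 read, ~0.1% at >= 5); a single-Poisson background cannot produce both
magnitudes at once, which is why the emission is a two-stage draw. Truth
methylation levels default to a mixture shaped like a plant methylome
(10% unmethylated, 10% low, 65% broad mid-range, 15% near-saturated);
genomes default to GC 0.36 with a 20 kb unmethylated control contig. Reads
are tag or reverse-complement with independent substitution errors
(default 0.1%), adaptor-filled to 36 nt at constant Q30.

What the simulator does *not* emulate: PCR duplicates, ligation bias beyond
overhang selection, indels, quality-score decay along the read, enzyme
kinetics or partial digestion, and hydroxymethylation chemistry. Passing
parameter-recovery tests therefore demonstrates the internal consistency of
the quantification stack under the stated noise model, not performance on
real libraries.

## Problem sizes used in tests

The suite and the acceptance script run at desk scale, chosen to keep the
statistical checks well-powered: enumeration is verified against an
exhaustive pair-geometry oracle on 200 random sequences up to 500 nt;
the mapper against brute force on 200-site catalogs; parameter recovery
uses 2000 sites at depth_max 256 averaged over 20 seeds (Pearson r >= 0.95
required on sites with M* >= 0.2); the differential test is calibrated on
2000-site, 12-vs-12 null matrices (empirical type-I in [0.03, 0.07] at
alpha 0.05) with 10-fold planted shifts for power (>= 80% after
Bonferroni). End-to-end read-level runs use 30-150 kb genomes, where the
full pipeline on error-free reads reproduces the simulator's count table
exactly.

## Known limitations

* OTHER-class enumeration is geometry-derived; the enzyme's experimentally
  determined context preferences may exclude some geometric pairs, so
  absolute OTHER counts on real genomes are upper bounds.
* The M-index is relative; no absolute methylation percentage is produced,
  and sites saturating above depth_max are capped at M = 1.
* Single-linkage CDR merging can chain distinct loci through intermediate
  sequences; repetitive flagging catches only the depth signature.
* The common-dispersion model ignores site-specific (tagwise) dispersion;
  strongly heterogeneous overdispersion would make the exact test
  anticonservative at the most variable sites.
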