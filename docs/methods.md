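# Methods

This note documents the models and procedures implemented in `iescan`, the
defaults and why they were chosen, the numerical details, and what the
synthetic-data generator does and does not emulate.

## Coordinate and record conventions

All internal coordinates are 0-based half-open; every GFF3/text surface is
1-based inclusive, converted in a single shared pair of functions
(`iescan.io.to_gff_coords` / `from_gff_coords`).

An `IesRecord` stores the insertion point `p` (the offset of the T of the
TA retained on the somatic chromosome) and a sequence `seq` that starts
with the left TA and excludes the right TA. The defining identity is

    germline locus = MAC[:p] + seq + MAC[p:],   with MAC[p:p+2] == "TA".

This convention makes the reconstruction identity exact and reproduces the
observed 26 bp minimum and 26–28 bp first size peak. Because an insertion
flanked by repeated bases can slide, every record is reported in
**leftmost-canonical** form: among all placements producing the same
germline string, the smallest `p` whose sequence is TA-led at a somatic TA.
This mirrors standard indel left-alignment and makes detection output
deterministic; the sliding implementation is verified in the tests against
brute-force enumeration of all decompositions.

## MIRAA: breakpoint detection from alignment ends

A read that crosses a germline/somatic junction aligns only partially on
the MAC reference, so its alignment terminates with a soft-clip at the
junction. Only clipped terminations are counted as "alignment ends":
natural read ends occur everywhere at depth-proportional rates and would
swamp the signal. A useful geometric fact: a read entering the insertion
from the left ends its alignment at `p`, and a read leaving it on the right
starts its alignment at `p`, so both orientations reinforce the same
coordinate.

A position is reported when (i) clipped-end count > 15 by default, or
a configurable fraction (default 10%) of observed mean coverage when the
fractional mode is enabled; (ii) it lies more than 500 bp from both
scaffold ends (assembly edges are noisy); (iii) local coverage is below
300× (screens collapsed repeats). Coverage at a position counts alignments
whose clipped span covers it. Candidate positions within 2 bp are merged to
the position with the largest end count (leftmost on ties), reflecting the
±2 bp blur introduced by the staggered 4-base cleavage geometry of
excision.

## MICA: TA-bounded insertion calling from contigs

Pipeline per contig: (1) drop contigs with G+C ≥ 0.5 (AT-rich organisms;
GC-rich contigs are overwhelmingly bacterial contamination); (2) anchor the
contig on the reference with unique 21-mers chained by a longest colinear
increasing subsequence; contigs with near-tied chains on several scaffolds
are skipped (repeat protection); (3) realign each inter-anchor gap globally
with affine-gap scores match +2, mismatch −3, gap open −5, extend −2 (a
length-g gap costs 5 + 2g; in Biopython terms `open_gap_score = -7`,
`extend_gap_score = -2`), taking a 50 bp anchored flank on each side;
(4) extract the maximal contig-only run as the rough insertion and accept
it iff some equivalent placement is TA-bounded (TA-led sequence at a
somatic TA), emitting the leftmost-canonical record. Duplicate calls from
overlapping contigs merge with summed support.

Gaps that cannot supply the full 50 bp anchored flank on each side (contig
or scaffold edges) are skipped rather than realigned: a truncated flank
gives the global aligner freedom to split the insertion into co-optimal
fragments and emit a spurious short TA-bounded piece. Overlapping contigs
re-present such gaps with proper flanks, so coverage, not heuristics,
resolves them. Consequence: an IES within 50 bp of a true scaffold end is
not callable.

There is deliberately **no minimum length filter**: the 26 bp floor is an
observation, not an assumption; records shorter than 26 bp carry a
`shorter_than_26` flag. Records overlapping N bases are rejected. Two IESs
separated by only a few nucleotides defeat the single-insertion gap model
(the combined insertion is not TA-bounded as one block); at most one of
such a pair is recovered, a documented limitation shared with the original
strategy.

TA-indels (low-level excision-error variants) are classified against the
catalogue as `exact_ies`, `internal_alternative` (a TA-bounded sub-segment
sharing one boundary TA), `external_alternative` (one end on an IES
boundary TA, the other at a somatic TA outside it), or `unrelated`.

## Catalogue statistics

**Context.** An IES is assigned exon/intron/intergenic by the half-open
interval containing `p`; a point on an exon's end boundary belongs to the
following interval.

**Size periodicity.** Integer-length counts over [26, 150] are smoothed
with a Gaussian kernel (σ = 1.5 bp) and local maxima detected with a
prominence floor of max(5, 5% of the smoothed maximum); the histogram is
zero-padded so the truncated first peak at the 26 bp edge keeps its
prominence. Because the second peak of the distribution is heavily depleted
and may escape detection, peak indices are inferred by rounding each peak's
distance to the first peak to the nearest multiple of the median inter-peak
difference; the period is the least-squares slope of position on index.
Fits with fewer than three peaks, or with an RMS residual above 1 bp
(irregular spacing), raise an error rather than report a period. The
estimator recovers planted spacings in [8, 14] bp within ±0.3 bp at
n = 40,000 in the tests. Reported diagnostics include the first-peak mass
fraction and the ratio of second-peak mass to its neighbours.

**End consensus.** Both ends are pooled after appending the retained TA to
the stored sequence (so both windows begin with the invariant T, A) and
reverse-complementing the right end. Information content per column is the
Kullback–Leibler divergence from the background q(G) = q(C) = gc/2,
q(A) = q(T) = (1−gc)/2 with gc = 0.28 by default — the composition of the
somatic genome the consensus sits in.

**3n/stop bias.** For IESs in coding sequence, retention in mRNA creates
junction codons; the scan therefore includes codons assembled from up to
two flanking bases on each side, at the annotated phase. The default
genetic code is the ciliate nuclear code (translation table 6): TAA/TAG
encode glutamine and only TGA terminates — under the standard code most
AT-rich IESs would spuriously classify as stop-containing. The χ² statistic
is the two-cell goodness-of-fit of a category's (3n, non-3n) counts against
expectations apportioned by the non-coding null split, df = 1, no
continuity correction.

**Density vs expression.** Genes are ranked by expression and cut into
equal-count bins (30 by default; the alternative equal-width binning is
dominated by the extremes of the expression scale). Bin density is total
IES count over total CDS kilobases; the trend is an OLS fit of density on
bin rank.

**Positional uniformity.** One-sample Kolmogorov–Smirnov test of positions
against Uniform(0, L) using the asymptotic p-value, flagged non-uniform at
p < 0.002, with no correction across scaffolds (each scaffold is a separate
question). Fewer than 10 positions returns an inconclusive verdict. The
tests verify the realized rejection rate under uniformity stays within
[0.001, 0.004] at α = 0.002 over 10,000 replicates.

## Conservation across WGDs

Two IESs in aligned ohnologous genes are conserved when their insertion
points map to alignment columns at most 2 nt apart; the tolerance absorbs
boundary wobble from indel placement in the alignment. Nucleotide
alignments are supported (a built-in global aligner with the same affine
scores can produce them when pre-computed alignments are absent);
back-translated protein alignments are not, which may shift counts slightly
on real data. The summary table reports, per WGD age, genes with an
ohnolog, IES count, IESs conserved in at least one ohnolog, and the
percentage rounded to 0.1.

Clustering of homologous IESs at non-homologous sites replaces
database-dependent E-value cutoffs with raw local-alignment thresholds
suitable for desk-scale catalogues: a pair is similar when the best local
alignment covers ≥ 85% of the longer IES with score ≥ 50 (roughly E < 1e-10
for ~500 bp queries at these scores); a pair is excluded when any
flank-vs-flank local alignment reaches score 40, which signals a duplicated
site rather than element mobility; members with dinucleotide entropy below
1.5 bits are dropped as low-complexity. Clusters are the transitive closure
of the remaining relation.

## The quartet gain/loss model

A quartet is a gene family retained in four copies through the intermediate
and then the recent WGD: two "intermediate branches", each ending in a
recent-WGD sibling pair. IESs across the four genes are grouped by
conserved position (2 nt tolerance, transitive); each group's
presence/absence pattern is oriented so 1100 means both genes of one
intermediate branch. Groups linking two IESs of the same gene are flagged
ambiguous and excluded.

Model assumptions: a shared position implies a single ancestral insertion
(double hits are negligible); the loss rate λ is constant; the two periods
(between the WGDs, and since the recent WGD) have equal durations τ, a
default justified by protein-divergence branch lengths that make the two
spans equivalent (configurable in principle through the likelihood, but the
equal-duration form is the one fitted here); acquisition times are uniform
within a period. Then a full-period survival is s = e^(−λτ) and the mean
survival of an IES acquired at a uniform time within a period is
σ = (1−s)/(λτ) = (s−1)/ln s.

Cohorts and observable patterns (per-cohort probabilities sum to 1,
including the unobservable 0000):

- **g3** (extant at the intermediate WGD): each branch independently keeps
  both terminal copies with s³, exactly one with 2s²(1−s), none with
  q = 1−s + s(1−s)²; combining branches gives p(1111) = s⁶,
  p(1110) = 4s⁵(1−s), p(1100) = 2s³q, p(1010) = 4s⁴(1−s)²,
  p(1000) = 4s²(1−s)q, p(0000) = q². The g3 fraction absorbs survival
  through the pre-WGD period, which is not separately identifiable.
- **g2** (acquired between the WGDs, on one branch): p(1100) = σs²,
  p(1000) = 2σs(1−s), remainder unobserved.
- **g1** (acquired since the recent WGD, on one terminal gene):
  p(1000) = σ.

Since a group is only seen if at least one copy survives, the likelihood
conditions on observation: with per-cohort observation probabilities
P₃ = 1−q², P₂ = σ(1−(1−s)²), P₁ = σ, the observed-pattern distribution is a
mixture with conditional weights w, and the acquisition fractions are
recovered as ρₐ ∝ wₐ/Pₐ.

**Fitting.** The likelihood is maximized over (logit s, softmax weights) by
Nelder–Mead from a fixed 3×3×3 start grid (s₀ ∈ {0.5, 0.8, 0.95}, weight
logits in {−1, 0, 1}²), convergence tolerance 1e-9 on the log-likelihood;
the multi-start is deterministic. Standard errors come from the inverse
observed information on the internal parameterization (central finite
differences) with the delta method for ρ. Degenerate inputs (all counts in
one pattern) return a boundary estimate with a warning. The
`lrt_all_ancient` test compares the full model against w₂ = w₁ = 0 (s free,
2 degrees of freedom).

On the published pattern counts (190, 64, 1304, 10, 558) the fit gives
ρ = (14.4%, 70.9%, 14.6%) with s ≈ 0.914 — within rounding of the published
15/69/16 split; the residual ~1-point differences are expected from
unstated details of the original parameterization (e.g. the
acquisition-time distribution within periods).

## The synthetic-data generator

The generator emulates the statistical structure the detection and
inference stages rely on, as a pure function of (config, seed):

- a somatic genome of i.i.d. bases at 28% G+C, split into scaffolds, with
  non-overlapping single- to three-exon gene models (exons 300–800 bp,
  introns 20–30 bp — short introns as in the organism modelled);
- IESs planted at existing TA dinucleotides (so every planted locus is
  canonicalizable), by default one per kb, at least 300 bp apart and 600 bp
  from scaffold ends; lengths follow a Gaussian-mixture comb with first
  peak at 28 bp, spacing 10.2 bp, per-peak s.d. 1.5 bp, geometric
  peak-weight decay 0.65, the second peak multiplied by 0.05 (the
  "forbidden" peak), truncated at 26 bp; the outer 8 bases of each element
  follow a TAYAGYNR-like weight matrix and the interior G+C is adjusted so
  the element's expected overall G+C equals the configured 20%;
- error-free 108 nt reads at 160× coverage whose MAC alignments are derived
  analytically from the truth table: junction-crossing reads emit
  soft-clipped records (anchored on the longer somatic match when they span
  a whole IES, unmapped below a 25 bp anchor), reads inside an IES are
  unmapped; an optional substitution-error rate exists and defaults to 0,
  because the detection logic — not a mapper's error tolerance — is what is
  under test;
- error-free contigs tiling the germline (2 kb, 1 kb step), so every IES is
  fully flanked in at least one contig;
- quartet histories forward-simulated with explicit per-branch Bernoulli
  survival draws (an IES acquired at uniform time u in a period survives
  its remainder with probability s^(1−u)). This simulator shares no code
  with the analytic pattern probabilities; their agreement is itself a test.

What the generator does **not** emulate: sequencing errors and quality
models, assembly artefacts, repeats and transposon copies, imprecisely
eliminated germline-specific regions, nested or overlapping IESs, and any
joint dependence between IES length and end-consensus strength
(independence is assumed). Passing end-to-end tests therefore demonstrate
the correctness of the detection logic and estimators under the assumed
statistical structure, not robustness to real sequencing pathologies.

## Problem sizes used in the test suite

The end-to-end detection check runs on a 500 kb genome over 5 scaffolds
with 500 planted IESs at 160× coverage — the default per-kb IES density at
a size where every pipeline stage (≈770k simulated alignments, ≈1000
contigs) exercises its streaming paths in seconds. Estimator calibrations
use 50 replicate quartet datasets of n = 2,000 groups, 10,000 KS
replicates, and n = 40,000 lengths for the periodicity sweep. The
acceptance script's refit of the published quartet counts is deterministic
and runs in about a second.

## Known limitations

- MIRAA counts left- and right-clips at the same merged coordinate; if a
  dataset's mapper reported them at distinct offsets the merge window (2 bp)
  would need widening.
- MICA cannot see IESs within 50 bp of a scaffold end, nested IESs, or
  tandem IESs separated by fewer bases than an anchor k-mer.
- The conservation module consumes nucleotide alignments only.
- The gain/loss model ties all survival rates to a single constant λ;
  relaxing rate constancy is only exercised through the degrees of freedom
  of the likelihood-ratio test, not as a separately parameterized model.
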