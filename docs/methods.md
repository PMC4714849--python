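# Methods

This note documents the models, rules and numerical choices behind
`lncforge`, what the synthetic study does and does not emulate, and the
design decisions made where the problem was genuinely open.

## Coordinate and identity conventions

All internal coordinates are 0-based half-open; GTF/GFF3 (1-based inclusive)
and BED (0-based half-open) are converted only at the I/O boundary.
Transcripts must be stranded: unoriented (`.`) transcripts are rejected by
default or dropped with a warning, mirroring the exclusion of unoriented
single-exon transcripts from non-strand-specific libraries.  A transcript's
identity for consensus purposes is its intron chain — scaffold, strand and
the ordered intron intervals — so assemblies that differ only in terminal
exon ends are the same transcript.  No fuzzy splice-site tolerance is
applied: the match is exact, which keeps merging deterministic.  When
witnesses of one chain are merged, the terminal exon boundaries become the
union (minimum first-exon start, maximum last-exon end); witness coverage and
FPKM attributes are dropped because expression is re-estimated on the merged
set.  Loci are single-linkage clusters of same-strand exonic overlap;
antisense overlap never joins a locus, otherwise antisense classification
would be vacuous.

## The identification cascade

Stages, in fixed order, with defaults:

| stage | rule | default |
|---|---|---|
| 1 | sense-exonic overlap with a coding exon (≥ 1 bp, same strand) | — |
| 2 | spliced length; exon count; read coverage; FPKM | ≥ 200 nt; ≥ 2; ≥ 0.8; ≥ 0.1 |
| 3 | longest ORF | ≤ 100 aa |
| 4 | coding probability; any external scorer column | ≤ 0.345; ≤ 0 |
| 5 | protein/domain homology hit E-value | ≥ 1e-6 |
| 6 | distance of the genomic span from either scaffold end | ≥ 2000 nt |
| 7 | class code i / u / x → ilncRNA / lincRNA / lncNAT | — |

Stages 2–6 are pure per-transcript predicates, so the surviving set is
order-invariant; only the stage *attribution* of a transcript failing several
rules depends on the order, which is fixed as above.  FPKM and coverage are
taken as the maximum across tissues — a transcript expressed anywhere is
kept — because the filter applies once to the merged set, not per tissue.
The ORF caller scans the three forward frames only (transcripts are
oriented), requires a strict ATG start and an in-frame stop, excludes the
stop from the length, and breaks ties toward the leftmost start.  Open
(stop-less) ORFs are not counted; this is conservative and deterministic.
Class codes: sense-exonic overlap dominates; antisense exonic overlap gives
`x`; full containment within a single intron of a single reference transcript
(either strand) gives `i`; everything else is `u`.  Homology filtering
consumes a precomputed tabular hit list (query, subject, E-value) rather than
running a search engine, keeping the pipeline free of external databases.

## Coding-potential model

Four features per spliced sequence: longest-ORF length (nt), ORF coverage
(ORF/transcript length), the Fickett TESTCODE statistic, and the mean
in-frame hexamer log-likelihood ratio.  The Fickett tables (position
asymmetry and composition probabilities with their weights) are embedded as
published constants; `N` bases are not counted, and sequences shorter than
200 nt are rejected (they cannot reach this stage anyway).  Hexamer
frequencies are estimated in-frame (step 3, frame 0) from coding ORFs and
over all frames from noncoding sequences, Laplace-smoothed (pseudocount 1)
over the 4096 hexamers; scoring averages the log-ratio over the in-frame
hexamers of the transcript's longest ORF, falling back to frame 0 of the
whole sequence when no ORF exists.  The classifier is a logistic regression
on standardized features, fit deterministically given a seed, with a 30%
held-out split reporting AUC.

The decision threshold defaults to probability 0.345 for comparability with
the CPAT convention, but that constant was calibrated for CPAT's original
training corpus; a `recalibrate` option instead picks the Youden-optimal
threshold on the held-out split.  On the default synthetic corpora the two
classes are essentially separable (held-out AUC ≈ 1.0), so the threshold
choice is uncritical there; on real data it matters and should be
recalibrated.

## Tissue specificity

For a profile `p` over ≥ 2 tissues (normalized to sum 1) and the point-mass
profile `e_t` of tissue `t`, the score is `1 − sqrt(JSD(p, e_t))` with the
Jensen–Shannon divergence in log base 2 and `0·log 0 = 0`; the transcript's
score is the maximum over tissues.  It is 1 exactly when a single tissue is
nonzero and invariant to positive rescaling.  The specificity call uses a
strict comparator (score > 0.25): the boundary side is not specified by the
convention the cutoff comes from, so it is explicit and configurable here.
All-zero profiles are flagged invalid rather than scored.

## Sex bias

Counts are compared per tissue with a two-sided exact binomial test:
conditional on `x_f + x_m` reads, the female count is binomial with success
probability `N_f/(N_f+N_m)` under the null of equal concentration.  This is
the random-sampling null of DEGseq-style single-replicate tests, computed
exactly instead of via a normal approximation.  `log2FC` uses a 0.5
pseudocount on library-size-normalized counts so zeros are defined.  BH-FDR
is applied per tissue across transcripts; a transcript is sex-biased at
|log2FC| > 1 and q < 0.05, in any tissue for the locus roll-up; a
multi-isoform locus is sex-biased when its biased-isoform ratio strictly
exceeds 0.75, while a single-isoform locus inherits its isoform's call.

**Calibration and a known limitation.**  The null calibration study samples
counts from the test's own model (Poisson, i.e. pure library sampling); there
the joint false-call rate is ~0.  Under biological overdispersion (negative
binomial, dispersion 0.1) the single-replicate design is anti-conservative —
the |log2FC| > 1 requirement absorbs some but not all of the extra variance.
This is inherent to sampling-model tests without replicates, not an
implementation artifact; with biological replicates a dispersion-aware test
(e.g. a NB GLM) should replace this stage.  Power under NB dispersion 0.1 for
4-fold effects at mean count 50 is ≈ 0.91–0.93.

## miRNA interactions

Precursor detection intersects mature miRNA coordinates with lncRNA locus
spans (union of isoform spans) on the same strand; full containment in the
exon union is reported as an extra flag since genuine pre-miRNA hairpins are
exonic.  The seed scanner reports canonical sites on the spliced sequence
(T≡U): the 6mer core is the reverse complement of miRNA positions 2–7; a
match to the complement of position 8 immediately 5' of the core upgrades to
7mer-m8; an `A` immediately 3' upgrades to 7mer-A1; both give an 8mer.  Each
core occurrence is reported once at its strongest type.  Thermodynamic
scoring and structure are deliberately out of scope — seed matching is the
shared core of the miRanda/PITA/RNAhybrid family, and an energy model would
require a folding engine.  ceRNA candidates must have their sites fully
inside supplied conserved regions (spliced coordinates) and hit at least
`min_distinct_mirnas` distinct miRNAs (default 1; the knob is not a
reconstruction of any published predictor-combination rule).

## Co-expression network

The network is unsigned: `a_ij = |cor(x_i, x_j)|^β` with β = 9 on
log2(FPKM+1) of transcripts expressed (nonzero) in ≥ 2 samples;
zero-variance transcripts are removed with a warning.  β is fixed rather
than chosen by scale-free fit.  The topological overlap is

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    l_ij = Σ_{u≠i,j} a_iu a_uj,  k_i = Σ_{u≠i} a_iu.

Modules are average-linkage clusters of `1 − TOM` under a *static* tree cut
(height 0.995): the static cut is fully specifiable and deterministic,
unlike dynamic tree cutting, at the cost of less adaptive module boundaries.
Clusters below `min_module_size` (default 30) go to the unassigned grey bin;
recovering very small modules (the smallest meaningful module in comparable
studies had 17 members) requires lowering this knob.  The module eigengene is
the first principal component of the standardized member profiles, unit norm,
sign-oriented so the mean member correlation is positive; module pairs with
eigengene correlation > 0.70 merge iteratively (most correlated first) to a
fixed point.  kME is the member–eigengene correlation; module–trait
significance uses the two-sided t test with n − 2 df.  Enrichment is the
plain upper-tail hypergeometric test with BH-FDR (q < 0.05); no length-bias
(Wallenius) correction is applied, a documented deviation from GOseq-style
enrichment.  Hub lncRNAs: edges are weight ≥ `edge_threshold` (default TOM ≥
0.15, a config knob — published degree rankings depend on an unstated export
threshold); per sub-network, candidates are lncRNAs adjacent to ≥ 1 of its
proteins, ranked by degree in the induced graph (ties by total degree, then
id), top 5 kept; a hub in ≥ 2 sub-networks is inter-network.

## The synthetic study

The simulator emulates the *structure* of a multi-tissue lncRNA survey, not
its scale: 10 scaffolds × 200 kb, 300 mRNAs, 100 clean lncRNAs (50
lincRNA / 20 ilncRNA / 30 lncNAT) and 10 decoys per cascade stage, 8 tissues
× 2 sexes with one library (10⁶ reads) each.  Problem sizes were chosen so
the full study builds in seconds; statistical calibration studies use their
own sizes (10,000 null transcripts; 200 × 40 block designs).  Coding
sequences come from a skewed codon-usage model (one preferred codon per
amino acid), which produces a learnable in-frame hexamer signal; noncoding
background is slightly AT-rich i.i.d. sequence, rejection-sampled to keep
planted lncRNA ORFs ≤ 100 aa.  Decoys are planted per stage: sense-exonic
overlappers; short / single-exon / low-coverage / zero-expression; ORFs of
110–200 aa; coding-like transcripts with 90–99 aa ORFs covering most of
their length; homology-listed; scaffold-end placements.  Expression is
negative binomial (dispersion 0.1) around log-normal baselines with
point-mass profiles for tissue-specific transcripts (zero leakage, so
planted specificity is exactly recoverable), shared latent per-sample
factors for module members (a 4-fold shift in the associated tissue), and a
4-fold sex multiplier for biased transcripts; FPKM is computed from counts
by the standard formula so the two matrices are mutually consistent.
Pseudo-assembler replicates include each transcript with probability 0.95/
0.05 by tissue expression, jitter terminal exon ends by ±50 bp (bounded so
length filters are never tripped by jitter; introns untouched), and force a
configurable fraction of transcripts to appear exactly once to exercise the
stringent filter's false negatives.  Planted interactions write mature
miRNAs into lincRNA exons (plus antisense controls) and seed sites into
conserved windows with controlled flanking bases so the planted site type is
recovered exactly.

What passing on this data does **not** show: robustness to mis-assembly
beyond terminal jitter, to unoriented or mono-exonic transcripts, to
reference annotation errors, to overdispersed specificity leakage, or to the
scale (hundreds of thousands of transcripts) of a real survey; runtime on
real data is dominated by the O(n²) correlation/TOM step and needs blockwise
processing beyond ~10⁴ transcripts.

## Numerical notes

* BH-FDR delegates to `statsmodels.multipletests(method="fdr_bh")`; the exact
  binomial is `scipy.stats.binomtest`; hypergeometric tails use
  `scipy.stats.hypergeom.sf` — each verified against direct-summation oracles
  in the test suite.
* TOM is clipped to [0, 1] against floating-point drift; the dissimilarity
  matrix is symmetrized before linkage.
* Eigengene sign and merge order (largest module keeps its label; most
  correlated pair first) remove the PC-sign and merge-path ambiguities.
* All randomness flows through `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical artifacts.
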