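# Methods

This note documents the models and procedural choices behind each
stage, the synthetic cohort the tests run against, and the limits of
what those tests demonstrate.

## Study system and synthetic cohort

The pipeline targets longitudinal 16S profiles from a three-arm mouse
experiment: healthy controls (PBS), chemically induced colitis (DSS in
drinking water from day 0), and colitis plus a gavaged butyrate
producer treated as an invading taxon (DSS+BPB5). Stool is sampled on
days −1, 2, 4 and 7 with per-cell sample sizes 12/10/12/6 (PBS),
12/12/12/6 (DSS) and 12/11/12/6 (DSS+BPB5) — 123 samples. Attrition is
taken as a fixed design property, not simulated.

The generator (`cagflow.simulate`) draws each sample's latent log
abundances from a logistic-normal model: per-OTU baseline means
~ N(0, 1), a per-subject intercept (SD 0.25, persistent across days, so
repeated measures of one mouse are correlated), and unit-variance noise
with a one-factor block structure — OTUs in the same block share a
latent factor with loading √ρ (default ρ = 0.8, five blocks of ten
among 100 resident OTUs, fifty background OTUs independent). Fractions
are the softmax of the latent logs; counts are multinomial at a depth
uniform on [9 000, 30 000]. Correlation is planted on the latent log
scale, not the count scale, so compositional closure distorts it
exactly the way the SparCC stage must undo.

Treatment effects are block-level log-fold shifts that ramp linearly
from DSS start (day 0) to day 7: two blocks depleted, two enriched,
default magnitude log₂-fold 4 (16-fold at full ramp). A full DSS
dysbiosis collapses whole families far beyond 4-fold, and the
random-forest stage's "class error = 0" gate is only satisfiable when
group pairs are cleanly separable, so fold 16 is the default *study
condition*; fold 4 (log₂ 2) is kept as the calibration point at which
rank tests reach ~85% power at n = 12 per group (latent SD 1 puts that
effect exactly at the detectability boundary, which is what the power
calibration tests probe).

The invader is an extra taxon, not a resident: latent abundance −∞
(fraction exactly 0) outside inoculated groups, and inside them a base
level plus a rise following the effect ramp. In invader groups every
effect runs `shift_lead_days` (default 3) days ahead — day 2 in the
invader arm looks like day 5 in the plain DSS arm — reproducing an
accelerated community shift. The invader's latent noise shares the
factor of one designated enriched block ("invader-led"), making that
block's members the planted positive correlates.

What the generator does *not* emulate: taxonomically realistic 16S
sequence phylogeny, chimeras or primer artifacts, overdispersion beyond
the logistic-normal (no zero inflation beyond multinomial sampling),
mouse dropout, and cage effects. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration under a standard
compositional model — not robustness to every artifact of real
amplicon data.

## Read QC

Rules are applied in order: truncate both mates at the first base with
Q ≤ 2; merge by ungapped overlap scan; keep merged reads longer than
399 bp with expected error ≤ 0.5 ("longer than 399" is read literally
as ≥ 400). The merger evaluates every offset, discards offsets whose
overlap mismatch fraction exceeds 10%, and picks the feasible offset
with the most matching positions (ties: longer overlap, then leftmost).
Scoring raw matches *before* the mismatch filter would let a
full-length random overlap (~25% matches over 250 columns) outvote a
true 60 bp overlap (~59 matches), failing every good pair — hence the
feasible-first order. In the overlap the base with the higher Q wins
and keeps its Q; ties keep the forward base.

Dereplication is exact; singletons are discarded; ties in abundance
order break lexicographically. Clustering is greedy UPARSE-style: scan
uniques by decreasing abundance, join the first centroid at ≥ 97%
global identity, else found a new one. Identity is pinned as
matches / alignment columns with terminal gaps excluded, computed from
a global alignment (match +1, mismatch −1, gap open −2, extend −0.5);
an edit-distance bound (edlib) short-circuits pairs that provably fall
below the threshold. Read mapping assigns each read to its
best-identity centroid at the same cutoff; ties go to the more abundant
centroid. Chimera removal is an explicit no-op hook.

## Diversity and ordination

Rarefaction subsamples without replacement (multivariate
hypergeometric) to depth 9 000; shallower samples are excluded and
recorded. Alpha diversity (observed OTUs, Shannon in bits — log base is
a parameter) is averaged over 1 000 independent subsamples; beta
diversity uses the single seed-0 subsample, since averaging the table
over rarefactions before Bray–Curtis is a defensible alternative we
expose as a choice rather than a default. PCoA Gower-centres the
squared distances and eigendecomposes; negative eigenvalues (Bray–
Curtis is a semimetric) are dropped and counted rather than corrected.
PCA of relative abundances is provided as PCoA of Euclidean distances,
which yields identical scores without a second code path.

## PERMANOVA

One-way pseudo-F from squared dissimilarities with significance from
uniform label permutations, observed statistic included in numerator
and denominator (p ≥ 1/(n_perm+1)); an exact mode enumerates all
distinct assignments for small n. Permutations are unstratified; the
screen that gates random-forest modelling flags raw P < 0.05,
deliberately unadjusted. Degenerate SS_within = 0 yields F = ∞ with p
still defined by permutation ties.

## Random-forest key OTUs

Per screened pair, 1 000 bagged CART trees (√p feature subsampling) on
relative abundances. OOB class error is the majority-vote error over
samples out of bag at least once; "successful" means exactly 0
(`max_class_error` exposes the literal reading as a parameter). MDA for
an OTU is the mean over trees of (OOB accuracy − OOB accuracy with that
OTU's column permuted among the tree's OOB samples); unused features
contribute exactly 0. This matches R randomForest's unscaled
permutation importance (verified numerically). Key OTUs are the union
of MDA > 0.003 across successful models, with provenance retained.

A practical property worth knowing: with ~24 samples, whether OOB
error is *exactly* zero is a property of the dataset (one borderline
animal flips its vote), so any single model passes the gate only
~70–85% of the time even under strong planted effects. The selection
is therefore evaluated — and should be used — as the union over the
screened group pairs, which is also how the gate behaves in the
original workflow.

## SparCC

Log-ratio variances t_ij = Var log(f_i/f_j) are computed from the
covariance of log fractions (unbiased). Under sparsity, basis variances
ω solve M ω = rowsums(t) with M = 1 + diag(p−2); basis correlations are
ρ_ij = (ω_i+ω_j−t_ij)/(2√(ω_iω_j)), clipped to [−1, 1]. Pairs with
|ρ| above 0.1 are excluded from the system iteratively (strongest
first, up to 10 rounds — the cited method's defaults; the source study
names none). Fractions come from Dirichlet posterior resampling of the
counts (add-one smoothing handles zeros); the final estimate is the
element-wise median over 20 iterations (median, not mean, for
robustness to resampling outliers). Non-positive ω estimates are
flagged and the affected OTU's correlations zeroed.

Significance is a permutation null — each OTU's counts shuffled
independently across samples, destroying association while preserving
marginals — with two-sided pseudo-p over 100 replicates (floor 1/101).
Bootstrap resampling of samples would preserve correlation and cannot
form a null, so "bootstrap" is implemented as this permutation scheme.
Null re-estimates use 5 inner iterations rather than 20: the null
median is already stable at that depth and the 100-replicate loop
dominates runtime. Network edges connect pairs with |ρ| > 0.5, signed.

## Co-abundance groups

OTU dissimilarity is d = 1 − ρ (not 1 − |ρ|: anticorrelated OTUs belong
in opposing groups). Ward linkage (Lance–Williams) builds the
dendrogram; a top-down recursion tests each split with the PERMANOVA
pseudo-F of the two child sets on the node's distance submatrix and
accepts it at P < 0.005, descending into children with ≥ 2 members
(singleton children of accepted splits become singleton CAGs). No
multiplicity correction is applied across splits — the rule is a single
fixed threshold.

The split null is the one genuinely open design point. Textbook label
permutation is provably anti-conservative here: Ward *chose* the split
from the same distances, so under a structureless ρ the root split
tests at p ≈ 0.001 in every run and the cut always splits noise. The
default null instead rearranges the observed dissimilarity values over
OTU pairs, re-clusters each shuffled matrix with Ward, and compares the
observed split F against the shuffled trees' root-split F — the best
split the dendrogram would find in structure-free data with the same
dissimilarity spectrum. On iid-noise correlation matrices this is
calibrated (≈ 99% single-CAG rate at α = 0.005) while 5 planted blocks
are recovered with ARI 1.0. The literal variant remains available as
`split_test="label_permutation"`. Shuffle draws per node are
max(299, n_perm/10), keeping the p floor below α at the default
n_perm = 9 999 while bounding the re-clustering cost; node-keyed
random streams make each node's p independent of traversal order, so
raising α can only refine the partition. Known limitation: ρ matrices
*estimated* from truly unstructured counts carry weak per-OTU row
effects from compositional estimation, which this null partly detects;
end-to-end null runs collapse to one CAG in ~80% rather than ~99% of
cases.

CAG profiles are per-sample sums of member relative abundances (they
conserve the key-OTU total by construction). Dynamics are two-group
Kruskal–Wallis tests of each CAG against the reference group (DSS) per
day, BH-adjusted across the whole CAG × day × group family, with stars
at FDR 0.05/0.01/0.005. Invader correlates are the taxa with
ρ > 0.5 (positive) or ρ < −0.5 (negative) against the invader row.

## Univariate statistics

Mann–Whitney U uses the exact null when the combined sample size is
≤ 12 with no ties — the study's group sizes (6–12) straddle the regime
where the normal approximation degrades — and otherwise the normal
approximation with tie and continuity corrections; fully constant data
returns p = 1. Kruskal–Wallis applies the tie correction with a χ²
reference. BH is the step-up rule; families are per analysis (per
contrast for differential OTUs, per CAG table for dynamics).
Differential direction is the sign of the median difference vs the
reference cell.

One compositional caveat documented for users: planting strong
*absolute* increases on a few taxa depresses every other taxon's
relative abundance, so in relative terms the "unchanged" taxa are
genuinely differential. FDR calibration experiments therefore plant
modest (4-fold) effects whose closure spill is negligible; with
16-fold effects on 10% of taxa the nominal null set is not null and no
procedure on relative abundances could hold the FDR against
absolute-abundance truth.

## Pipeline and reproducibility

Stages run in a fixed order, each writing plain-text artifacts (TSV,
GraphML, Newick, JSON) into the run directory; `summary.json` collects
the headline numbers. Every stochastic stage requires an explicit seed
in the config (validation rejects configs without one, and unknown
keys), the log records every parameter actually used, and `resume=True`
reloads existing artifacts so a run can restart per stage without
changing results. Default problem sizes — 123-sample cohort, 9 999
screen permutations, 1 000 trees, 20 SparCC iterations with 100 null
replicates — complete in well under a minute each on one CPU; the test
and acceptance suites use these same sizes except where a calibration
loop repeats a stage hundreds of times, in which case the repeated unit
is scaled to keep whole-suite runtime in minutes (per-case sizes are
stated in the tests).
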