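# Methods

## The question and the test

The package scans human proximal promoters (the ~1 kb immediately upstream of
the TSS) for accelerated substitution on the human branch relative to a
neutral expectation, using human/chimp/macaque triplet alignments.  The
neutral expectation for each gene comes from its own intronic sequence, so
local variation in mutation rate and base composition is absorbed before any
claim about selection is made.

The substitution model is HKY85: transition/transversion rate ratio κ,
equilibrium base frequencies π, rate matrix scaled so branch lengths are in
expected substitutions per site.  The three species sit on an unrooted star
tree with branch lengths (t_h, t_c, t_m).  Each promoter gets branch-specific
rate multipliers ζ = (ζ_h, ζ_c, ζ_m) applied to the neutral branch lengths.
The per-column likelihood sums over the four states of the single internal
node (Felsenstein pruning on a 3-leaf star); columns containing a gap or N
are dropped listwise.  Columns collapse to at most 64 (human, chimp, macaque)
patterns, so a likelihood evaluation costs a handful of 4×4 matrix
operations regardless of alignment length.

The test compares two nested models for the promoter:

* **null** — ζ_h ∈ [0, 1]: anything from full constraint to neutral drift,
  including *relaxation* of constraint, which can at most reach the neutral
  rate;
* **alternative** — ζ_h ∈ [0, ∞): acceleration beyond neutral is allowed.

Only positive selection can push ζ_h above 1, which is what makes the test
specific to adaptive acceleration rather than loss of constraint.  Because
the constrained parameter sits on the boundary of the null region, the LRT
statistic Λ = 2(lnL_alt − lnL_null) is asymptotically distributed as the
mixture ½χ²₀ + ½χ²₁ under the null; `lrt_pvalue` implements this (Λ = 0 ⇒
p = 1) with a plain χ²₁ option as a conservative alternative.  A gene is
called positively selected at p < 0.05 by default; Benjamini–Hochberg
correction is available downstream but not applied by default, matching the
survey convention the scan reproduces.

### Estimation

Fitting is joint by default: κ, (t_h, t_c, t_m) and ζ are optimized together
over the intron-plus-promoter likelihood in both the null and alternative
models (π fixed at the pooled empirical base frequencies of the intron, with
a +0.5 pseudocount keeping frequencies interior on tiny inputs).  Profiling
the neutral parameters inside the LRT matters: a staged fit that first
estimates them on the intron and then treats them as known ignores their
sampling noise, and with a ~4-kb intron that measurably inflates the test's
size (simulated rejection rates of 0.075–0.10 at nominal 0.05), whereas the
joint LRT simulates at or below nominal.  The staged variant
(`PromoterSelectionModel.fit(joint=False)`, or `fit_neutral` + `fit_scales`
directly) remains available — it is cheaper and its neutral estimates are
the natural per-gene descriptive output.

Optimization is bounded L-BFGS-B (κ ∈ [0.02, 200], t ∈ [0, 5],
ζ ∈ [0, 100]) from a distance-based start (pairwise mismatch fractions) plus
seeded random restarts (3 by default for the joint fit, whose start list
already contains the staged solution; 5 for the staged functions).  The alternative fit runs first; its
clamped solution seeds the null fit, which guarantees lnL_alt ≥ lnL_null up
to optimizer tolerance; the statistic is clipped at 0.  Transition matrices
come from the symmetric eigendecomposition that reversibility affords
(D^{1/2}QD^{-1/2} is symmetric), exact to machine precision and cacheable
across branch lengths when κ and π are fixed — this is what makes the
per-gene fit take ~0.2 s.  Log-likelihoods of impossible patterns are −∞ in
the public function and a finite penalty (10¹²) inside the optimizers so
numerical differentiation never sees inf−inf.

## Alignment QC

Three deterministic filters precede the test, in order: (1) a 50-column
sliding window (step 1, the strictest reading of "sliding") rejecting any
alignment with a window holding >12 human–chimp or >17 human–macaque
substitution differences — a misalignment signature; (2) rejection when
>10% of columns contain a gap in any row; (3) for introns, rejection when
the human-specific substitution ratio (columns with human ≠ chimp = macaque
among gap-free columns — strict parsimony; three-way-different columns do
not count) falls outside 0.0053 ± 2·0.0022 substitutions/site, the
genome-wide intronic mean ± 2 s.d.  Differences always mean substitution
columns: both residues in {A,C,G,T}; indel and N columns never count.
Interval endpoints are inclusive; rejection is strictly outside.

## Interval construction

Coordinates are 0-based half-open throughout (BED convention).  The promoter
download window is relative coordinates [−1100, +150) around the TSS and
the analysis window is [−1000, 0), mapped strand-awareness: r = p − tss on
+, r = tss − p on −.  Introns are the complement of merged exons within the
gene body (optional flank parameters, default 0, can extend the
complementation region); the first intron in transcription order is
excluded; introns shorter than 600 bp or longer than 6200 bp (pre-trim) are
dropped; survivors lose 100 bp at each end.  The length filter is applied
before trimming because the length gate describes the downloaded sequences
while the trim belongs to reference building.

## Network analysis

The protein-interaction graph is undirected and simple (self-loops dropped,
duplicates collapsed); every centrality is computed on the largest connected
component (ties broken toward the component containing the lexicographically
smallest node).  Degree is neighbor count; betweenness is the unnormalized
Brandes pair-dependency sum with endpoints excluded (igraph's default
convention); ASPL is the mean shortest-path distance to all other nodes
(smaller = more central); EVC is the principal eigenvector of the adjacency
matrix scaled to max = 1, computed by power iteration on A + I from the
uniform vector at tolerance 1e−10 — the identity shift leaves eigenvectors
unchanged while making the dominant eigenvalue unique, so the iteration also
converges on bipartite graphs (paths, stars) where plain power iteration
oscillates.

Association analyses: one-tailed Wilcoxon–Mann–Whitney comparisons of each
metric between a study set and a reference set (promoter-positive genes are
tested for *greater* centrality, coding-positive genes for *lower*; ASPL
directions inverted).  The rank-sum engine enumerates the exact null when
both samples have ≤12 untied observations and otherwise uses the
tie-corrected normal approximation without continuity correction (so
identical samples give a one-tailed p of exactly 0.5).  The logistic
association fits selection status on EVC by maximum likelihood
(statsmodels), with a natural-log transform for the promoter analysis and
raw EVC for the coding analysis by default (both configurable); perfect
separation is detected and flagged rather than reported as a finite slope.
The 20-bin quantile table is for display: bin i has upper boundary the i/k
empirical quantile and each value joins the lowest bin whose upper quantile
covers it.  Reference sets default to analyzed-genes-in-component excluding
the study set; a flag includes the positives, since published reference
sizes can be read either way.

## Enrichment and expression

Enrichment is the exact hypergeometric tail per category: p_over = P(X ≥ k),
p_under = P(X ≤ k) with X ~ HG(N, K, n).  Genes may carry several
categories and are counted once per category; unannotated genes still count
in N.  No multiplicity correction by default (raw p < 0.05 flags), BH
optional.

Expression input is a long (gene, tissue, value, present/absent) table.
Absent calls are removed entirely; DATA1 is the gene's highest present
value and DATA2 the mean of present values at or above the gene's median
(computed over present values only — the only reading that yields one value
per gene; ties inclusive).  DATA1 ≥ DATA2 ≥ median holds by construction
(with a one-ulp clamp on the mean).  Kendall correlation is tau-b, exact p
for n ≤ 8 without ties.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analyses assume, at
the study's stated conditions: 1-kb promoters and 4-kb intronic references
under HKY with κ = 4, π = (0.30, 0.20, 0.20, 0.30) (GC-poor, typical of
noncoding human DNA), star-tree branch lengths (0.0053, 0.0055, 0.030) —
the human branch matching the observed intronic human-specific rate, the
macaque branch the human–macaque divergence net of the two short branches;
accelerated genes get ζ_h on the human promoter branch only.  Networks are
Barabási–Albert preferential attachment (n = 2000, m = 3 by default),
giving the heavy-tailed degree distribution of curated interactomes.
Labels are Bernoulli(logit⁻¹(β₀ + β₁·log EVC)) with β₁ = 2 and β₀ solved
numerically so the mean prevalence is 10%, near the observed positive
fraction.  Expression is log-normal with the gene's log-mean shifted by
coupling × centrality rank and ~10% absent calls; annotations are
multinomial over categories with the study set's enriched category
oversampled at a stated odds multiplier.

Deliberately not emulated: indels (the QC gap filter is exercised by
deterministic hand-gapped fixtures; the likelihood drops gapped columns),
alignment error, CpG hypermutability, rate variation across sites,
promoter motif structure, and the correlation structure of real
interactome sampling.  Passing tests therefore demonstrate correctness of
the inference machinery under its own model, not robustness to real-data
violations of it.

## Numerical and design choices

* Window step 1 in the sliding filter; "site gaps" = columns with ≥1 gap.
* Empirical π pooled across all three rows of the intron.
* Exact-identity transition matrix at t = 0 (avoids spurious ~1e−17
  probabilities from the eigenreconstruction).
* Exact WMW only without ties (ties force the corrected normal
  approximation at any n).
* `expected_int` of the overlap analysis is floor(n_a·n_b/n_total), with
  the unrounded value always reported alongside; Fisher's two-sided p uses
  the point-probability convention (verified against R's `fisher.test`).
* Percentages round half-away-from-zero to one decimal (`Decimal`
  arithmetic, not banker's rounding).
* The association report validates against `report_schema.json`, shipped
  with the package, via a small built-in checker.

## Problem sizes

The validation battery uses desk-scale sizes chosen to give stable Monte
Carlo estimates: 500 neutral gene cases for type-I calibration (MC s.e.
≈ 1%), 100 replicates for power and for each ζ recovery median, a 100-kb
alignment for neutral-parameter recovery, 200 exhaustively checked random
graphs of ≤8 nodes for the centrality oracles, one 2000-node network with
100 label replantings for the logistic recovery, and 100 replicates of the
planted-enrichment design.  A full run of the acceptance script takes a few
minutes on one CPU.

## Known limitations

The staged fit treats neutral parameters as known when testing the
promoter; with a 4-kb intron their sampling noise slightly widens the null
distribution of ζ̂_h, which the calibration test shows remains within the
nominal band at these sizes but would bear re-examination for much shorter
introns.  The model is the minimal realization consistent with a
two-model promoter/intron comparison: no rate classes within regions, no
CpG treatment (a flag is reserved), no indel-aware likelihood, and exactly
three taxa.
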