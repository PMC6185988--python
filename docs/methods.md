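# Methods

## Setting and data model

The package targets paired pre/post microbiome studies: `n` subjects,
each contributing one pre-exposure and one post-exposure specimen,
profiled as a taxon-by-sample abundance table. The canonical internal
form is per-specimen proportions in [0, 1] (relative abundances);
percentages are only a rendering. Count tables are normalized per
specimen, and taxa absent from every specimen are dropped (with a
logged count) before testing, because their t statistic and fold change
are undefined. Family/genus analyses aggregate the taxon table through
a taxonomy map by summation, which conserves per-specimen totals
exactly.

## The permutation t machinery

Per taxon, `t = (mean(post) − mean(pre)) / sqrt((var(post) + var(pre)) / n)`
with the unbiased (ddof-1) sample variance; a ddof-0 option exists
because "variance" is occasionally read as the population form. Two
degenerate conventions keep NaN out of the pipeline: both variances
zero with equal means gives t = 0; zero variances with a mean gap give
signed infinity, compared under extended-real ordering.

**Unpaired label permutation.** The 2n specimens are pooled and n of
them relabelled "post" uniformly at random, with replacement across the
B draws (default 100,000); an exhaustive mode enumerates all C(2n, n)
assignments and is used as the oracle in tests. The empirical p is the
plain proportion r/B of permuted statistics at least as extreme as the
observed one on the side selected by the observed sign; `p = 0` is
possible under Monte-Carlo, and an optional (r+1)/(B+1) pseudocount
variant is available. Because the tail is selected from the observed
sign, the test rejects at ≈ 2α under a symmetric null — deliberate, and
verified by simulation (see Calibration).

**Paired sign-flip.** Each subject's pre/post values are swapped or
not; all 2^n arrangements (including the identity) are enumerated for
n ≤ 20, beyond which B random flips are drawn. Exhaustive p-values are
exact multiples of 2^−n with floor 2^−n. The sidedness of "at least as
extreme" is configurable: the default mirrors the unpaired rule
(sign-selected one-sided); a two-sided |t| rule is provided because the
phrase is genuinely ambiguous in practice.

**Numerical tie handling.** Permuted statistics are computed by a
vectorized sums-of-squares path after centering each taxon (t is
location-invariant; centering makes a constant taxon give exactly t = 0
in every permutation). Permuted values within a relative tolerance of
1e-7 of the observed statistic count as ties: BLAS kernels sum in
different orders for different batch shapes, so arithmetically
identical relabellings can differ in the last ulps, and strict
comparisons would otherwise drop exact ties (this matters for
near-degenerate taxa whose flip distribution has large atoms). Real
t-value gaps in these discrete nulls are many orders of magnitude
larger than the tolerance.

**Reporting.** Taxa are sorted by ascending unpaired empirical p, ties
broken by |log2 fold change| descending, then name. Infinite fold
changes (taxa absent in exactly one condition) are rendered literally
as `Inf`/`-Inf`. No multiple-testing correction is applied by default,
matching how such screens are usually reported at n = 8; the raw
empirical p is the object of interest.

## Diversity

*Shannon* uses base 2 by default (bits); the base is a parameter since
conventions differ. *Weighted UniFrac* is implemented from the
definition: raw = Σ_b len(b)·|A_b − B_b| over branches, where A_b is
the mass of sample A descending through b; the normalized variant
divides by Σ_j depth(j)·(A_j + B_j) over leaves and lies in [0, 1].
The normalized variant is the default (bounded, hence comparable across
cohorts). Both match scikit-bio's implementation to machine precision
in the tests; scikit-bio is used only as an oracle, plus for newick
parsing and tree traversal. *Jackknife rarefaction* subsamples each
specimen without replacement (multivariate hypergeometric) to
floor(fraction·total) reads — the per-specimen reading of "sampling 1%
of the total sequences"; a pooled interpretation would make specimen
depths covary and is not implemented. The rep-mean matrix is computed
as deviations from the first rep so that fraction = 1.0 reproduces the
full-data matrix bit for bit. *PCoA* is classical Gower scaling
(double-center −½D², eigendecompose); negative eigenvalues are reported
in the spectrum but dropped from coordinates, with no Cailliez/Lingoes
correction — transparency over forced embeddability. The
*within-pair vs between-subject* comparison takes the n same-subject
pre/post distances against the n(n−1)/2 pre-pre distances of distinct
subjects, one-sided rank-sum (within smaller). Paired alpha diversities
are compared by a two-sided Wilcoxon signed-rank; identical vectors
return p = 1 by convention.

## Host-factor battery

Per-subject abundance changes (post − pre, proportion units) are
screened against: numeric covariates (PrEP duration in weeks, age in
years, TFV-DP in fmol/punch) by Spearman correlation; race by
Kruskal–Wallis; binary covariates by Wilcoxon rank-sum. Missing values
("declined to answer") are an explicit level excluded pairwise per
test, with the n actually used reported; tests with fewer than 3 usable
subjects are flagged untestable rather than dropped. With n ≤ 10 the
p-values are exact: Spearman enumerates all n! rank pairings
(vectorized, midranks for ties); Kruskal–Wallis enumerates all distinct
label assignments with the tie-corrected H (singleton levels allowed —
scipy's permutation machinery refuses them); the rank-sum tail is
|U − μ| under full enumeration. Beyond n = 10 the scipy asymptotics are
used.

## The synthetic paired-study generator

The generator emulates the statistical structure of a small paired
rectal-swab amplicon study; it is the package's validation substrate,
not a model of any particular cohort.

Per subject: a baseline composition is drawn from a Dirichlet whose
default parameters give one dominant taxon (~35% of the community,
echoing the *Prevotellaceae*-type dominance of real rectal profiles)
and a power-law (1/k) rank-abundance tail, total concentration 25
(moderate between-subject variability). Each taxon's log-abundance is
jittered by Normal(0, `subject_effect_sd`, default 0.6), *shared by the
subject's pre and post specimens* — this is what makes a subject's pair
more similar than unrelated specimens, as real paired studies observe.
The pre composition is the renormalized jittered baseline; the post
composition multiplies spiked taxa by 2^δ and renormalizes — the
compositional closure (other taxa shrink when one is spiked) is
intentionally present, because the analysis operates on relative
abundances and closure distortion is part of the phenomenon. Read
counts are multinomial at a fixed depth (default 50,000 per specimen, a
typical post-QC MiSeq yield). Defaults: 8 subjects, 30 taxa. Identical
seeds give bit-identical output.

Covariates are sampled independently of the microbiome on the scales of
such cohorts (duration ∈ {48, 60, 72} weeks, ages 20–55, TFV-DP
900–2100 fmol/punch, mostly-yes drug use, occasional missing answers);
an optional monotone coupling to a taxon's deltas supports power
studies. Random trees are rooted bifurcating topologies from uniform
joins with Exp(1) branch lengths (offset 1e-3 to keep UniFrac
denominators well posed).

What the generator does **not** emulate: taxonomic misassignment,
chimeras, variable per-specimen depths, overdispersion beyond
Dirichlet-multinomial, temporal within-subject drift between paired
specimens (pre and post share one baseline; under the null they differ
only by sequencing noise), or correlation structure among covariates.
Passing tests therefore demonstrate correctness of the statistical
machinery under a clean compositional model — not robustness to every
artifact of real amplicon data.

## Validation study conditions

The self-checks run at deliberately modest problem sizes so the whole
suite re-runs in minutes on one core; each was chosen for a statistical
reason, not shrunk from something larger:

* *Monte-Carlo vs exhaustive*: toy instances at n = 2–4 (2n ≤ 8), where
  C(2n, n) ≤ 70 is enumerable, B = 100,000; agreement within 3 binomial
  standard errors.
* *Calibration*: 1,000 null taxa, 8 pairs, exhaustive sign-flip;
  P(p ≤ 0.025) within a 99% binomial band of 0.05 plus the 1/256 grid
  step. The null community uses moderate even shares (α = 5 per taxon)
  at depth 200,000 so every taxon is well resolved and the 256 flip
  statistics are effectively distinct. This matters: for sparse taxa
  the flip distribution has large atoms and the discrete p becomes
  strongly conservative (rejection rates near 0) — a real property of
  permutation tests on rare taxa, documented here as a limitation
  rather than suppressed.
* *Effect recovery*: one taxon spiked at +2.0 log2 units, depth 1e5,
  40 subjects, 100 seeds; the estimate must land within ±0.25 of the
  spike and rank first by empirical p in ≥ 95 seeds. The spiked taxon
  has a small (~1%), well-mixed baseline share (even Dirichlet, α = 2,
  100 taxa): recovery of the nominal δ is only meaningful when the
  closure adjustment log2(1 + p(2^δ − 1)) is small; under the skewed
  default a spiked taxon can occupy >10% of a dominant subject's
  community and the closure itself — not estimation error — exceeds
  the band. The mean recovered fold change (~1.92) sits below 2.0 by
  exactly this closure margin.

## Known limitations

* Cohort-level results of any particular study require that study's
  reads; nothing here re-estimates them.
* The unpaired test treats specimens as exchangeable under the null,
  ignoring the pairing; it is the screening statistic, with the
  sign-flip test as the paired complement.
* Exhaustive sign-flip p-values cannot go below 2^−n (1/256 at n = 8):
  genuine effects in tiny cohorts saturate at that floor.
* UniFrac is computed at the resolution of the input table against a
  matching tree; no OTU picking or tree inference is performed.
* Rank-sum and Kruskal–Wallis p-values for rare taxa inherit the
  conservatism of discrete tests noted above.
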