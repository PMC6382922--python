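# Methods

## Data model and conventions

The unit of analysis is an ASV feature table (samples x features,
non-negative integer counts) with a rooted phylogeny over the ASVs, a
7-rank Greengenes-style taxonomy, and per-sample metadata carrying the
pairing structure (subject, arm, timepoint) plus sex, age, aspirin use, a
batch-mismatch indicator, freezer storage time and two binary adenoma
outcomes. Invariants are enforced at construction: unique identifiers,
non-negative integer counts, at most one sample per subject and timepoint.

Prevalence filtering keeps features with a nonzero count in at least
`floor(f * n_samples)` samples; presence means count >= 1 with no abundance
floor. With `f = 0.33` and 802 samples the threshold is 264. Taxonomic
collapsing sums features whose lineages agree through the requested rank;
features unresolved at that rank are grouped under their most specific
known prefix (marked with a trailing `?`), so per-sample totals are
conserved exactly.

## Diversity

Rarefaction subsamples each sample to a fixed depth without replacement
(one multivariate-hypergeometric draw per sample at a stated seed — a
single-rarefaction design, not an average over rarefactions); samples below
the depth are excluded. Default depth is 900, chosen to retain paired
samples; a Mantel test (Spearman, permutation p with the `(b+1)/(n_perm+1)`
convention) compares distance matrices at 900 against a deeper rarefaction
as a robustness check.

Alpha metrics: observed ASVs and Faith's PD. Beta metrics: Jaccard on
presence/absence, Bray-Curtis on counts, unweighted UniFrac, and
*unnormalised* weighted UniFrac (`sum_b l_b |p_b(x) - p_b(y)|`); a flag
enables the normalised variant. Distance and Faith computations delegate to
scikit-bio; Jaccard/Bray-Curtis go through scipy's pdist on a binarised or
raw count matrix respectively.

PCoA is the classical eigendecomposition of `-1/2 J D^2 J`. All
eigenvalues are reported, negatives included, but `proportion_explained`
divides by the sum of *positive* eigenvalues only. Because a PCoA axis sign
is arbitrary, PC1 is oriented by a deterministic convention before paired
analysis: the taxon with the largest |Spearman correlation| against PC1 is
made positively correlated. Deltas are therefore comparable across runs,
and the paired t statistics are equivariant under the underlying sign flip.

## Paired longitudinal analysis

For each subject with both timepoints, the change (end minus baseline) in a
per-sample measure is computed; incomplete pairs are dropped with a logged
count. Per stratum (arm, optionally arm x sex) a two-sided one-sample t
test asks whether the mean change differs from zero; Benjamini-Hochberg
correction runs over the full family of (metric, stratum) tests submitted
in one call — the family boundary is a design choice, fixed as "everything
tested together". Magnitude (as opposed to direction) of change is
compared between arms by a two-sided Mann-Whitney U on each subject's
within-pair beta-diversity distance.

The ICC uses the one-way random-effects ANOVA estimator with two
observations per subject: `sigma_b^2 = max(0, (MSB - MSW)/2)`,
`sigma_w^2 = MSW`, `icc = sigma_b^2 / (sigma_b^2 + sigma_w^2)`. Negative
between-subject components are truncated at zero, so the ICC lies in
[0, 1]; the estimator is invariant to affine transformation of the metric.
At 500 subjects its sampling SD is ~0.03 (measured by simulation), which is
why recovery checks compare the *mean* estimate across replicate
simulations against the planted value rather than a single draw.

## Differential abundance

ANCOM: for each feature i, W_i counts how many of the pairwise log-ratio
hypotheses `log(x_i/x_j)` (j != i) change significantly between timepoints
— a paired two-sided Wilcoxon signed-rank per pair, BH-corrected within
feature i's row of (D-1) p-values at alpha = 0.05; a feature is "detected"
when `W_i >= 0.7 (D - 1)`. Both alpha and the detection quantile are
exposed. A pseudocount of 1 is added before any log-ratio; W is therefore
invariant to per-sample scaling up to the pseudocount (exactly invariant
for counts well above 1). Fewer than 5 pairs is an error — the signed-rank
null is degenerate below that.

The a-priori panel (default: 18 CRC-associated genera plus the order
Bifidobacteriales, user-overridable) is tested per arm by paired
signed-rank on relative abundance, BH-corrected across the panel within an
arm; a panel label aggregates every feature whose lineage contains it, so
order-level labels sum their genera. The Firmicutes/Bacteroidetes test uses
the per-sample phylum-count ratio, substituting a pseudocount only for zero
denominators so the ratio stays scale-invariant whenever Bacteroidetes
counts are nonzero. All-zero difference vectors yield p = 1 with a flag.

## Co-occurrence networks

SparCC is re-implemented from its defining relations (log-ratio variance
matrix, sparsity-approximated basis-variance solve, correlation from the
variance identity, clipped to [-1, 1]). Defaults: 20 Dirichlet resamples
of the per-sample fractions (posterior with pseudocount 1; the reported rho
is the element-wise median), exclusion threshold 0.1 with at most 10
exclusion rounds; excluded pairs are removed from the linear system, and an
exclusion is skipped if it would drop a feature below two remaining
partners (the system must stay determined). `n_resample=0` gives a
deterministic single-pass estimate on pseudocounted fractions. Fewer than
4 features is an error.

Edge significance: Pearson and Spearman correlations (with standard
t-distribution p-values) on pseudocounted fractions, and a two-sided
permutation p for SparCC (independent per-feature shuffles,
`(b+1)/(n_perm+1)`). An edge is ensemble-significant iff all three p-values
are at or below the threshold (default 0.001, which requires n_perm >= 999
— requesting an unattainable threshold is an error) *and* the three
coefficients agree in sign. Networks are built on each arm's post-treatment
samples; the prevalence filter is applied after rarefaction by default
(config switch), counting all samples in the compared set.

Differential modularity compares the post-placebo (baseline) and post-UDCA
(perturbed) networks on their common node set, entering through |rho| so
positive and negative co-occurrence weigh equally. The gain matrix is
`B_ij = A'_ij/2m' - k_i k_j/(2m)^2` with degrees from the baseline network
(a flag switches the null to perturbed degrees). The objective is the
ordered same-module sum of B, diagonal null term included — the convention
under which the self-comparison limit (perturbed = baseline) equals
ordinary weighted modularity Q exactly, and under which per-node
contributions `c_i = sum_{j in module(i)} B_ij` sum within a module to the
module's objective share. The two-triangle check value Q = 0.5 follows this
same ordered-pair convention.

The optimizer is a generalized Louvain over an arbitrary symmetric gain
matrix: greedy local moves (including splitting a node into a fresh
singleton when its affinity to its module is negative), supernode
aggregation, a flat single-node refinement on the original matrix, and a
community-merge pass iterated to a joint fixed point; ties in gain break
toward the smallest community label. Because the landscape is rugged on
small instances, the search restarts from random partitions — 40 restarts
for <= 16 nodes, 12 otherwise — keeping the best objective; all node
orders and initial partitions derive from one seed. On 1000 random 8-node
instances the search matches the exhaustive-partition optimum (Bell(8) =
4140 partitions) for both objectives. networkx's Louvain serves as an
independent cross-check for standard modularity, never as the
implementation, since it cannot optimise the differential gain matrix.

The differential network keeps edges with positive `|rho_udca| -
|rho_placebo|` (a `signed` mode keeps positive plain differences instead),
annotated with the sign of the underlying treated-arm correlation, and is
partitioned by the same machinery with the network's own degrees. Hubs are
ranked by strength (sum of incident |weights|), ties lexicographic.

## Outcome models

Adenoma outcome is regressed on the per-subject change in a microbiome
measure — for species, the difference of post-rarefaction relative
abundance — adjusted for age, aspirin use, the baseline level and (when not
sex-stratified) sex, with a log-link GLM: Poisson or log-binomial, both fit
by IRLS with Wald p-values. The log-binomial mean can hit the boundary;
fits start from the intercept-only solution and non-convergence is flagged,
never silently replaced. Interactions are assessed by likelihood-ratio
tests on nested fits (chi-square with df = parameter difference); the LRT
calibration check uses the binomial family because the Poisson working
model is underdispersed on binary outcomes and rejects conservatively.
Cohort baseline comparisons use the Pearson chi-square without continuity
correction (df = 1) — the form that reproduces the trial's printed
p-values (0.024, 0.003, 0.004, 0.016) from its printed 2x2 counts — and t
or rank-sum tests for continuous variables. Storage-time checks fit a
random-intercept-per-subject mixed model of storage years on arm (REML)
and Spearman-correlate storage time with each diversity measure per
timepoint.

## Synthetic cohort

The generator emulates the trial's structure: 198/203 subjects per arm with
paired samples (802 total); log-normal sequencing depths (median ~4500,
log-SD 0.8) with a ~2% tail below the 900-read rarefaction depth; sex and
aspirin frequencies at the trial's printed per-arm rates; storage times
near 17.2/14.6 years with subject-level correlation and no coupling to the
microbiome.

Latent per-sample log-abundances are feature baseline + subject random
effect + treated-arm end-of-study shift + unit-variance within-subject
noise; the subject-effect variance is `icc/(1-icc)` so the latent
between/within ratio hits the ICC target (default 0.55, inside the 0.4-0.7
range typical of gut communities). Taxonomy assignment is weighted toward
Bacteroidetes and Clostridial Firmicutes, the dominant gut phyla. Counts
are multinomial draws from the softmax of the latents — the compositional
closure that induces exactly the negative-correlation bias SparCC exists
to correct, which makes the SparCC-vs-Pearson contrast testable.

The treatment shift has two components, both applied only to treated
end-of-study samples. Designated-genus shifts (default 0.8 on the log
scale) raise Streptococcus/Escherichia/Bilophila features and lower
Fusobacterium features — the panel-test signal. A community-axis shift
(default 0.25) raises every Firmicutes feature and lowers every
Bacteroidetes feature — a small but coherent rebalancing of the dominant
phyla, which is what the paired-PC1 tests detect. A *mean* shift was
chosen deliberately over a shared latent *factor*: a factor strong enough
to pin PC1 to the community axis plants dense taxon-taxon correlations
that contaminate the co-occurrence networks, whereas a mean shift is
constant within each arm-by-timepoint group and therefore invisible to
correlation estimation by construction (an optional `gradient_loading`
turns the subject-level factor on, with the idiosyncratic subject effect
shrunk so per-feature ICC is preserved; it defaults to zero). The
sign-recovery test runs at a dominant shift magnitude (1.0), the regime in
which the shift is expected to load on PC1; at the default magnitude the
shift is detectable only at full trial scale and mainly in the
abundance-weighted metrics, mirroring a small real effect.

Correlation blocks add a shared factor to the within-subject noise of
designated features, optionally restricted to treated-arm end samples. The
default hub block is a keystone structure: the factor *is* the hub
feature's own noise, so the hub (labelled *Faecalibacterium prausnitzii*)
correlates with each member at `sqrt(rho)` while members inter-correlate
only at `rho` (default 0.8), and one member (*Ruminococcus gnavus*) loads
negatively. Both hub species are pinned to high baseline abundance —
F. prausnitzii is among the most abundant gut taxa, and a rare hub's
correlations would drown in count noise. Because subject effects are
independent across features, realised taxon-level correlations are diluted
by `1/(1 + sigma_b^2)` (~0.45 at ICC 0.55); the default block rho is set so
realised hub edges land near 0.3-0.4, the strength regime the network
analysis targets. Outcomes are logistic in the two hub species' latent
changes for males (+1.2 for the *R. gnavus*-like species, −1.2 for the
*F. prausnitzii*-like one, ~45% marginal event rate) and intercept-only for
females.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-specific extraction/PCR bias, overdispersion beyond multinomial,
phylogenetic signal in abundances (the tree is an independent birth-death
draw, so UniFrac behaves qualitatively but tree-aware effects are not
planted), and arm differences in depth or storage. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated
generative model, not robustness to those real-data artifacts.

## Problem sizes used in tests and acceptance

Unit and calibration tests run scaled-down cohorts: 20/20 subjects with 40
features for the null battery of the paired-shift tests (500 replicates),
50 random instances for optimizer spot-checks, 20 taxa x 500 samples for
SparCC recovery (50 seeds). Parameter-recovery checks that depend on
network estimation run at the trial's own arm sizes (198/203) with a
reduced feature count (30-40), where the planted hub is recoverable; the
ICC check averages 20 replicate simulations at 500 subjects, reflecting the
estimator's ~0.03 sampling SD at that size. The pipeline integration test
runs 15/15 subjects with 199 permutations at an edge threshold of 0.01
(999 permutations and 0.001 remain the analysis defaults).

## Known limitations

* The SparCC permutation test recomputes the full estimator per
  permutation; at the default 999 permutations this is the slowest step of
  the network stage and scales as `n_perm x n_resample x D^2`.
* The null-noise floor of any basis-correlation estimator at 20 taxa and
  n = 500 places the maximum null |rho| near 0.14; runs should not expect
  every seed to keep it below 0.15 (the exact Pearson oracle on the basis
  data itself fails that bound in ~13% of seeds).
* Log-binomial fits can fail to converge near the boundary (~20% of
  male-only subsets at trial scale); results carry an explicit convergence
  flag and the Poisson family is the robust alternative.
* ANCOM is the classic W-statistic form; bias-corrected successors are out
  of scope.
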