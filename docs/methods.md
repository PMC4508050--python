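# Methods

`gwasnet` re-implements a network-based analysis of case-control GWAS
data: per-SNP association statistics are aggregated into gene-level
P-values with LD awareness, the gene scores weight the nodes of a
protein-protein interaction (PPI) network, a greedy dense module search
(DMS) grows candidate subnetworks from every gene, and modules are kept
only when they are significant against an empirical null in their own
cohort *and* replicate in an independent cohort.  The package ships a
synthetic-data generator so the full pipeline runs, and can be tested,
with no access-restricted genotypes.

## Synthetic study conditions

The generator (`gwasnet.simulate`) emulates a multi-cohort psychiatric
GWAS resource: three independent case-control cohorts of unequal size
and SNP density genotyped on a shared panel, one scale-free PPI network,
and a set of planted disease modules shared by all cohorts.

* **LD model.** SNPs form blocks of `ld_block_size` (default 20).  A
  haplotype's alleles within a block derive from a latent Gaussian with
  exchangeable correlation `ld_rho` (default 0.7) thresholded at
  Phi^-1(MAF), so marginal allele frequencies are exact and one
  parameter controls within-block r².  Real human LD decays with
  distance and has recombination hotspots; block-exchangeable LD is a
  deliberate idealization — passing tests show the statistics handle
  *correlated* SNPs correctly, not that they reproduce human LD maps.
* **Risk model.** Each planted gene carries one causal SNP (its central
  SNP).  Case status is logistic with log-odds
  `log(planted_or)` (default OR 1.6) per risk allele, summed over causal
  SNPs, plus a per-cohort batch intercept with SD `batch_effect_sd`
  (default 0.2 log-odds).  The linear predictor is centred at its
  expectation so case and control quotas fill by rejection sampling.
  One causal SNP per gene (rather than every SNP in the gene) keeps the
  per-gene signal at a realistic scale while leaving the gene-level
  tests to recover it through LD.
* **Coordinates.** Genes are laid out non-overlapping on one synthetic
  chromosome, 10 kb span, 50 kb gaps (more than twice the 20 kb mapping
  flank), with a fixed number of SNPs per gene — the SNP-to-gene map is
  deterministic, which the mapping tests exploit.
* **Per-cohort SNP density** (default 1.0/0.9/0.4) emulates platforms of
  different resolution; causal SNPs are always genotyped so the shared
  signal assumption behind cross-cohort evaluation holds by
  construction.
* **MAF range** defaults to (0.1, 0.5) so that sampling noise does not
  push simulated common variants below the 0.05 MAF filter; the filter
  is exercised separately with rare variants in the unit tests.

## Quality control (`gwasnet.qc`)

Filters run in a fixed order: (i) SNPs with missing rate > 0.05 (before
any sample removal); (ii) samples with missing rate > 0.05 or
heterozygosity outside mean ± 3 SD (computed before removal; zero
variance disables the het rule); (iii) greedy LD pruning (window 50,
step 5, r² > 0.2 — the window parameters are community defaults, the
threshold is the pipeline's) followed by method-of-moments IBD on the
pruned SNPs, removing the lower-call-rate member of any pair with
PI_HAT > 0.185; (iv) differential case/control missingness
(chi-square P < 1e-5), MAF < 0.05, and the exact conditional
Hardy-Weinberg test at P < 1e-6 (all samples by default; controls-only
is a switch).  The pipeline is idempotent in the stable regime; when
thresholds fall inside estimator noise (e.g. IBD on only a few hundred
SNPs) borderline flags can differ between runs, which is a property of
the estimators, not of the filter logic.

Principal components come from a randomized SVD of the mean-imputed,
centred genotypes scaled by sqrt(p(1-p)), restricted to the pruned SNP
collection.  The first 20 PCs are each screened as the sole covariate of
an association scan; the five with the smallest genomic inflation
lambda (median chi-square / 0.4549) are kept.  Screening uses the Rao
score statistic — one shared null fit per PC, no per-SNP iteration —
because it is asymptotically equivalent to the Wald statistic under the
null, which is exactly the regime lambda measures, and roughly 20x
cheaper.  The final per-SNP P-values are always Wald tests from a
batched Newton-Raphson logistic regression (case status on allele count
plus the chosen PCs and study-indicator dummies), with per-SNP
observation masks so missing calls drop samples from that SNP's fit
only.  Non-converged or separated fits are recorded as missing and
counted, not replaced by another statistic.

## Gene-level tests (`gwasnet.genetest`)

SNPs map to a gene when they lie within 20 kb (inclusive) of its span.
LD is estimated from the study genotypes themselves (Pearson correlation
of mean-imputed allele counts, projected to the nearest positive
semi-definite correlation matrix with an eigenvalue floor of 1e-8).

* **Simulation test (VEGAS-style).**  T = sum of chi-square(1) quantiles
  at 1 − p_j over the gene's SNPs; the null distribution is simulated as
  sums of squared MVN(0, LD) draws, with P = (#exceedances + 1)/(n + 1).
  The schedule 10³ → 10⁴ → 10⁵ → 10⁶ escalates while P < 10/n_sims, so
  small P-values get adequate Monte-Carlo resolution and the bulk stays
  cheap.  Input P-values of zero are clamped to 1e-16.
* **Effective-number-of-tests (GATES).**  SNP clusters with pairwise
  r² > 0.8 (single linkage) collapse to their best P-value; the gene P
  is min_j m_e p_(j) / m_e(j) over ascending P-values, with effective
  test counts from eigenvalues of the P-value correlation matrix.  The
  P-value correlation is |r| by default; the published sixth-order
  polynomial in r is available (`pcorr="polynomial"`) — the difference
  is small in practice.
* Benjamini-Hochberg adjustment is the standard step-up procedure
  (delegated to statsmodels, checked against a brute-force
  implementation in the tests).

## Dense module search (`gwasnet.dms`)

Nodes present in both the PPI and the gene table of P-values form the
background; node weights are z = Phi^-1(1 − P) with P clamped away from
0 and 1.  The module score is Z_m = sum(z_i)/sqrt(k).  From every
background gene as seed, the candidate set is all non-members within
shortest-path distance d = 2; the best candidate (largest z, ties to the
smallest gene id for determinism) is accepted while the score grows by
more than the expansion rate r = 0.1.  The growth rule is implemented as
Z_{m+1} > Z_m + r|Z_m|: identical to the textbook Z_m(1+r) for positive
scores, but well-behaved for negative ones, where the literal product
would turn an arbitrarily large r into an arbitrarily weak requirement.
Distance-2 candidates join without their connecting intermediate, so a
module's induced subgraph can be internally disconnected — recorded, not
repaired.  Modules are unbounded in size and duplicates across seeds
are kept until the merge step.

## Module evaluation (`gwasnet.evaluate`)

Greedy maximization inflates every module score, so raw scores are
standardized against an empirical null: scores are median-centred and a
Gaussian N(delta, sigma) is fitted to the central bulk by *central
matching* — Poisson maximum likelihood of histogram counts against a
quadratic in the bin centres (a Gaussian log-density is a quadratic:
curvature gives sigma, tilt gives delta).  The fit window is asymmetric
around the bulk (2.5 initial-scale units left, 1.5 right) because
genuine disease modules enrich only the upper tail.  A truncated-normal
MLE restricted to the central observations was tried first and
abandoned: conditioning away the normalization leaves sigma nearly
unidentified (the profile likelihood is flat to ~2 nats across a 50%
sigma range at n = 10,000).  The central-matching fit recovers
(delta, sigma) = (0, 1) within ±0.03 on standard-normal scores and keeps
sigma within a few percent under 10% right-tail contamination; if the
quadratic is non-concave (degenerate score distributions) a
moment-based fallback (IQR/1.349) is used.  Module P-values are
P = 1 − Phi(((Z_m − median) − delta)/sigma).

Cross evaluation re-scores each discovery module with another cohort's
gene z-weights (members absent from that cohort's background are
dropped, k reduced; modules with no evaluable gene fail that cohort) and
standardizes those evaluation scores against their own central-matched
null — i.e. against the same discovery modules re-weighted, not against
random gene sets.  Selection keeps modules with discovery P < 0.05 and
evaluation P < 0.05 in at least one other cohort.  Under a global null
with two independent evaluation cohorts this dual rule passes about
1 − 0.95² ≈ 9.75% of the discovery-significant modules — the replication
requirement thins false positives but is not a 5% control, and the
selected fraction is high-variance because evaluation scores share genes
across modules.  Selected modules merge into one subnetwork: duplicate
gene sets collapse within a cohort (earliest seed kept), genes carry
per-cohort provenance, and edges are the PPI pairs co-occurring in at
least one selected module, annotated with repeat counts.

## Connectivity and enrichment

`gwasnet.connectivity` counts direct PPI edges within a gene list and
compares against degree-matched resampling: nodes are binned by
log2(degree) with bins merged until each holds at least 20 nodes, and
each permutation redraws the input's bin profile without replacement.
The empirical P is (b+1)/(B+1), so B = 10,000 permutations floor at
just under 1e-4.  This node-resampling null controls the first moment of
the degree sequence; it replaces the heavier edge-rewiring null of the
original DAPPLE tool.  The count of outside genes linked to at least two
input genes is reported descriptively, without its own permutation test.

`gwasnet.enrich` is a hypergeometric upper-tail test of term overlap
against the weighted-PPI background (the universe the module genes were
drawn from — a whole-genome background would overstate enrichment), with
an optional EASE variant (hits decremented by one; off by default),
BH adjustment, and retention at FDR < 0.05 and term size < 350.
Crosstalk takes a user-supplied term-to-group mapping (grouping by
function is a judgement call, not an algorithm), reports the gene
overlap between group unions and each gene's within-group term count.

## Problem sizes and numerical choices

The acceptance runs use three cohorts of 1000 cases/1000 controls,
10,000 SNPs and 1000 genes with three planted 8-gene modules — large
enough that QC, PC screening and the gene tests operate in their
asymptotic regime, small enough to run in minutes on one core.  The
batched logistic solver declares convergence at step size < 1e-6, guards
separation at |beta| > 15, and adds a 1e-10 ridge before solving; the
PSD projection floor is 1e-8; VEGAS clamps input P-values at 1e-16 and
z-transforms clamp gene P-values at 1e-15.  KS-based uniformity checks
need enough samples that the discrete atom at P = 1 (exactly balanced
allele counts between cases and controls) is negligible; the null
calibration fixture uses 2000/2000 samples for this reason.

## Known limitations

* The generator's LD, coordinate layout and scale-free PPI are
  idealizations; recovery results quantify the pipeline's behaviour
  under its own assumptions, not performance on real cohorts.
* IBD estimates need a few thousand pruned SNPs to put PI_HAT noise
  well below the 0.185 threshold; desk-scale fixtures below that produce
  spurious relatedness flags.
* The empirical-null standardization is relative: when essentially all
  modules absorb the same strong genes (dense networks, many strong
  signals within a 2-hop reach), selection discriminates weakly among
  them and recovery is driven by the diversity of the selected set.
* DAVID-era annotation databases and their internal background are not
  reproducible; enrichment results are validated against exact
  hypergeometric enumeration, not against published term tables.
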