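# Methods

## Model and procedure

`lssmap` scores each SNP of a phased chromosome by asking how well the
quantitative trait is explained by a coarse clustering of the haplotypes
that respects their local evolutionary history.

**Local trees.**  Around a focal SNP the package grows the maximal window of
neighbouring SNPs that are mutually compatible with a single rooted tree.
The window grows alternately one SNP left and one SNP right of the focal
SNP (left first), and a side closes permanently when its next SNP conflicts
with any SNP already included.  Compatibility is the *rooted* criterion —
the derived-allele sets of every pair must be nested or disjoint — which is
exactly the condition for a perfect phylogeny rooted at the all-zeros
ancestral haplotype to exist.  (The classical four-gamete test is the
unrooted version; the two differ only for pairs showing gametes 01, 10 and
11 but not 00, which cannot be placed on a 0-rooted tree.  The package
exposes the four-gamete test separately.)  The topology is the unique
laminar-family tree of the distinct derived sets: every non-singleton
derived set becomes one internal edge, haplotypes with identical window
patterns form polytomies, and the root is the all-zeros haplotype —
appropriate for data whose ancestral allele is coded 0, as produced by
coalescent simulators and by ancestral-allele-polarised VCFs.

**Branch lengths.**  Ancestral states over the window are reconstructed by
an exact two-state parsimony dynamic programme (valid on polytomies), with
ties resolved toward the parent's state and root ties to the ancestral 0.
For each edge, p̂ is the proportion of window SNPs at which the endpoint
state vectors differ, and the branch length is the M2-model distance
d̂ = −½ ln(1 − 2p̂).  Two guards keep all depths finite and positive:
p̂ = 0 is replaced by 1/S_w (one unobserved change over the window), and p̂
is capped at 0.5 − 1/(2·max(S_w, 2)), just below the divergence point of
the distance.  The cap's `max(S_w, 2)` exists because a width-one window
would otherwise cap p̂ at zero and collapse every branch; with it, a
single-SNP window yields the p̂ = 0.25 distance on every edge, preserving
the tree's topology information while remaining finite.  Branch lengths are
in expected substitutions per site; only relative depths matter downstream
because the score is invariant to an overall rescaling of V (σ̂² absorbs
it, and the ln det V term shifts by a constant across permutations).

**Clustered covariance.**  The tree is cut into k clusters by its earliest
(k−1) edges — edges ranked by the depth of their parent node, ties by
preorder position.  A cut that would not split a nonempty group off an
existing cluster (e.g. the second child edge of a binary root) is skipped,
so every partition has exactly k nonempty clusters; the number of effective
cuts plus one is the largest usable k.  The covariance matrix keeps only
the broad-scale history: for tips in clusters c(i) and c(j), V_ij is the
depth of the MRCA of the two clusters (within a cluster, the cluster MRCA's
depth), and the diagonal keeps each tip's full root-to-tip depth.  This is
the Brownian-motion covariance of the clustered tree and has O(k²) distinct
off-diagonal values, which is what makes scanning k = 1…15 at every SNP
affordable.  A relative ridge of 1e−8 × mean(diag) is always added so
duplicate haplotypes (identical covariance rows) never make V singular.

**Score.**  With design matrix D (tip-by-cluster indicators) the trait at
the 2·(individuals) tips — each individual's value duplicated on both of
its haplotypes — is modelled as Y ~ N(Dμ, σ²V).  The GLS maximum-likelihood
estimates are closed-form, and the SNP's score is
LSS = max_k {2 ln L − k ln n}: a BIC penalty on the k cluster means (σ² is
not penalized).  Ties in the argmax go to the smallest k.  The ln det V
term is kept in the comparison across k because the likelihood is
conditional on V, which changes with the partition.  The independence
baseline replaces V by the identity and is otherwise identical.

**Significance.**  Permutations shuffle trait values across individuals
(both tips of an individual move together).  The same B permutations are
reused at every SNP, so the per-permutation maxima over loci form a
coherent max-statistic null; the chromosome-level p-value is the proportion
of permutations whose maximum exceeds the observed maximum, and locus
p-values are the analogous per-SNP proportions.  Strict ">" and divisor B
are used, so p = 0 is attainable.  Local trees depend only on genotypes and
are built once per SNP; all B+1 trait vectors are scored against each tree
in one vectorised pass.

## Simulation framework

**Haplotypes** come from the Hudson coalescent with recombination
(`msprime`), infinite-sites binary mutations, ancestral allele 0.  Defaults
are the study conditions: N0 = 20,000 diploids, μ = 2×10⁻¹⁰ per bp per
generation, recombination 1×10⁻⁸ per bp per generation, 1 Mb, 50 diploid
individuals (100 haplotypes).  Watterson's formula gives ≈ 83 expected
segregating sites, matching the 65–105 SNPs typical of the study.  Site
positions are rounded to 1-based integers; the rare collision is resolved
by a deterministic nudge to the next free integer, keeping positions
strictly increasing.  The structured scenario draws the 50 individuals from
six subpopulations (9/9/8/8/8/8) that merge pairwise at cumulative times
0.1, 0.1, 0.1, 0.2 and 1.0 in units of 4·N0 generations with no post-split
migration.  Genealogy node times are converted to 4·N0-generation units, the
natural coalescent time scale, and used directly as OU time — with tree
heights of order one and α between 5 and 10, α × height is of order ten,
i.e. selection is strong relative to the tree depth.

**Traits** evolve along the true genealogy at the causal SNP under the
state-switching OU model with optima θ₁ = 80 (ancestral) and θ₂ = 100
(derived), the root starting at θ₁.  Every constant-optimum branch segment
is drawn from the exact Gaussian OU transition — no Euler discretisation —
and the causal edge is split at the mutation's recorded age.  The causal
SNP is drawn uniformly among SNPs with minor allele frequency in
[0.10, 0.30].  Diploid values are the mean of the two haplotype values
(additive/codominant model; dominant and recessive variants are out of
scope).

**Null model.**  Null replicates keep the trait's phylogenetic character
but remove all association: the trait evolves with a single optimum
(θ₂ = θ₁) along a genealogy drawn from an *independent* coalescent
replicate.  Using a genealogy of the scanned chromosome itself would leave
the trait genuinely associated with that region's trees — in trial runs the
permutation test then rejects far above the nominal level (as it should,
since such data are not null) — so the independent-genealogy construction
is what "no associated SNP" means here.

## What the simulations do and do not show

The generator reproduces the study conditions: neutral mutation and
recombination at uniform rates, panmictic or cleanly split populations,
exactly one biallelic causal variant with a purely additive effect, no
environmental covariates, and perfectly phased, error-free haplotypes.
Passing the benchmark therefore says nothing about phasing error, genotyping
error, multiple or non-additive causal variants, gene-by-environment terms,
or selection — all absent from the model.  Real-data behaviour (e.g. on
outbred-mouse cholesterol data) is outside the test surface.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `kmax` | 15 | largest cluster count scored per SNP |
| `n_permutations` | 200 (100 in the benchmark) | permutation-null size; p-value resolution is 1/B |
| `alpha` | 10 | OU selection strength per unit time (grid 5, 7.5, 10) |
| `sigma_Y` | 10 | OU diffusion SD per √time (grid 10–40); stationary SD is σ_Y/√(2α) |
| `theta1`, `theta2` | 80, 100 | optima for SNP states 0/1; their gap is the asymptotic carrier effect |
| MAF window | [0.10, 0.30] | eligible causal-SNP frequencies |
| ridge | 1e−8 × mean(diag) | keeps V positive definite under duplicate haplotypes |

## Benchmark sizes and expected numbers

The packaged benchmark (`scripts/acceptance.py`, mirrored by the
operating-characteristic tests) uses 25 replicates per panmictic power
cell, 20 per structured cell and 50 null replicates, each scanned with 100
permutations — sizes chosen so the whole benchmark runs in minutes while
keeping binomial standard errors below ~0.1.  Under these conditions the
expected operating characteristics are: type I error near 0.05; power near
0.98 at (α = 10, σ_Y = 10) panmictic and near 0.60 at (α = 5, σ_Y = 40);
and, under six-subpopulation structure, near 1.00 at (α = 10, σ_Y = 10) and
0.97 at (α = 7.5, σ_Y = 20).  All asserted bands in the tests are binomial
intervals around these values at the reduced replicate counts.

## Numerical and design choices

- Cholesky factorisations of V are shared across all trait vectors at a
  SNP; μ̂ uses the normal equations, so σ̂²n = YᵀV⁻¹Y − μ̂ᵀDᵀV⁻¹Y.
- Degenerate inputs: constant traits raise an error; windows always contain
  the focal SNP (width one is valid); monomorphic columns are dropped on
  input with a warning; an all-ones column (derived fixed) carries no split.
- Fitch/parsimony tie-breaks (parent state, root → 0) and the earliest-edge
  tie-break (preorder) are fixed for bit-reproducibility; all randomness
  flows through explicit seeds, and study tables are reproducible from a
  master seed.
- The number of clusters is capped by the partition structure of the tree
  (`k_available`), which on shallow trees can be well below `kmax`.

## Known limitations

- Strict compatibility windows: no tolerance for homoplasy or gene
  conversion inside a window (near-perfect relaxations are not
  implemented).
- The earliest-edges partition is the single partition scored per k; the
  exhaustive search over all k-cluster sets defined by the phylogeny (as in
  independence-score software) is deliberately out of scope.
- Covariance within a cluster is a single value (the cluster MRCA depth);
  finer within-cluster structure is discarded by construction.
- Traits must be phased-haplotype-ready: genotype phasing, imputation and
  multi-allelic sites are not handled.
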