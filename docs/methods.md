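# Methods

This note documents the statistical models and numerical conventions behind
`colepop`, the choices made where several defensible options existed, and
what the synthetic-data tests do and do not establish.

## Data model

Genotypes are diploid dosages of the alternate allele (0/1/2, −1 missing)
at biallelic SNPs with 1-based coordinates. Which allele is "alternate" is
taken from the input and never re-polarised; every statistic in the package
(distance, π, F_ST, PCA, SVD-quartets with probabilistic allele expansion)
is invariant to swapping the two allele labels at a locus, so polarisation
cannot affect results. Multiallelic VCF records are skipped with a warning.
An accession's subgroup may be the explicit token `UNKNOWN`; this is a
statement ("any state"), not missing data, and is treated as the full
alphabet by parsimony.

## Pairwise distance

Per locus, |g₁−g₂|/2 ∈ {0, ½, 1}; per pair, the mean over loci where both
calls are present (pairwise-complete). The number of shared loci is exposed
per pair, and pairs sharing < 100 loci trigger a warning rather than an
error — callers decide. Normalisation to [0, 1] is one global affine map of
the whole matrix (min is the 0 diagonal, so effectively division by the
maximum), the most literal reading of "normalised to 0–1". Without missing
data the raw distance is ¹⁄₂L·L1 and satisfies the triangle inequality;
with heavy, structured missingness pairwise-complete means can in principle
violate it, which is why n_shared_loci is reported.

## Windowed π and ROD

Site π = c₀c₁/C(n, 2) over the n non-missing chromosomes, i.e. the
unbiased per-site heterozygosity. Windows (default 100 kb, step 10 kb) tile
each chromosome from position 1; the window value divides the summed site π
by the *window span in bp* (the VCFtools `--window-pi` convention).
Reduced-representation panels therefore understate absolute per-bp
diversity by roughly the fraction of the genome assayed — only ratios and
comparisons between groups computed on the same panel are meaningful, which
is exactly how ROD = 1 − π_group/π_control uses them. Group mean π is the
unweighted mean over windows (window-mean, not site-mean; both are
computable, window-mean is what the group summary reports). ROD percent is
rounded half away from zero to integer percent.

## Weir–Cockerham F_ST

Per biallelic site the two-population variance components a (among
populations), b (among individuals within populations) and c (within
individuals) of Weir & Cockerham (1984) are computed from the per-group
sample sizes, allele frequencies and observed heterozygote fractions,
using only non-missing calls. Window and genome-wide values are the
"weighted" ratio of sums Σa/Σ(a+b+c) — matching VCFtools
`--weir-fst-pop` — not the mean of per-site ratios; sites with zero total
variance are skipped, and negative estimates are reported as computed. The
genome-wide summary is the ratio over all usable sites, which is the
primary number fed to the band classifier (<0.05 little, [0.05, 0.15)
moderate, [0.15, 0.25) strong, ≥0.25 very strong; negatives are "little").
Note the bands make 0.15 "strong" by the stated thresholds even though a
value printed as 0.15 after rounding may have been just below the boundary;
the classifier follows the thresholds verbatim and does not second-guess
rounding.

Recovery check: under the Balding–Nichols model (below) with two
populations drifted t from a common ancestor, the expected differentiation
is F = 1 − exp(−t); the estimator reproduces F within 20% relative error at
t ∈ {0.01, 0.05, 0.2} with 2 000 loci and 20 diploids per group.

## PCA and Evanno Δk

PCA uses Patterson scaling: centre each locus by its mean dosage, divide by
√(p̂(1−p̂)) with p̂ = mean/2, after mean-imputing missing calls per locus
(the EIGENSOFT default behaviour). Monomorphic loci, and loci constant
after imputation, are dropped. Scores are U·S from the eigendecomposition
of the accession cross-product, identical (to 1e−8, up to sign) to an SVD
of the standardised matrix; the sign convention makes the largest-magnitude
locus loading positive. Variance explained is λᵢ/Σλ over all components.

Δk consumes a (K, replicate, logL) table — real STRUCTURE output or
synthetic — and computes |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) with the
sample standard deviation, defined only for interior K with sd > 0.
The admixture MCMC itself is out of scope.

## SVD-quartets

For one quartet of lineages and one split, the flattening matrix counts
joint site patterns with rows indexed by the left pair's allele states and
columns by the right pair's. Diploids are expanded probabilistically — an
accession of dosage d contributes weight (1 − d/2) to the reference allele
and d/2 to the alternate — so heterozygotes need no random phasing and the
whole computation is deterministic.

Aggregation over members: the sum of pattern-weight products over *all*
one-accession-per-lineage combinations factorises exactly,
Σ_combos Π v(accession) = Π_lineage (Σ_members v), so the package computes
the complete aggregation in closed form at O(sites × members) cost; no
combination cap or subsampling is needed, removing one randomisation source.
Missing members simply drop out of their lineage's per-site sum, which is
identical to skipping every combination containing a missing member.

Scoring: a true species-tree split's flattening has rank ≤ k(k+1)/2 under
the multispecies coalescent for a k-state alphabet. The score is the
Frobenius distance of the Frobenius-normalised flattening to its best
approximation at that rank — rank 3 on the 4×4 flattening of binary-coded
SNPs (the default), rank 10 on the 16×16 flattening of the optional 4-state
nucleotide encoding. A fixed rank 10 would be vacuous for binary data
(every 4×4 matrix has rank ≤ 4, all scores would be exactly 0), so the
threshold is tied to the alphabet. Ties between split scores break in
lexicographic split order.

Assembly maximises the margin-weighted number of satisfied chosen splits
(margin = runner-up score − best score): exhaustively over all (2n−5)!!
topologies for ≤ 8 lineages (with a cached topology-by-quartet split
table), and by greedy stepwise insertion from the best-resolved quartet
followed by best-improvement NNI hill-climbing for 9+ lineages; the two
agree on every fixture tested. If all margins are zero the data are
uninformative and a star tree is returned with a warning.

Bootstrap resamples sites with replacement (multinomial site weights);
support of an internal edge is the percentage of replicate trees containing
the same bipartition. Edges below a support threshold (default 50%)
collapse into polytomies. Rooting is at a designated outgroup lineage; the
tree is otherwise unrooted.

## Fitch parsimony

`fitch_count` is the classical downpass (intersection, else union and count
+1). MPR sets come from a unit-cost Sankoff down/up pass: a state belongs
to a node's set iff its down-cost plus up-cost equals the global minimum —
this is exact, including for UNKNOWN tips (full alphabet). The single
reported assignment is deterministic: keep the parent's state when optimal,
else the first optimal state in alphabet order; its transition edges number
exactly the minimum change count. Polytomies are resolved arbitrarily with
zero-length edges (logged) before the pass, so counts on non-binary trees
depend on that resolution, as in Mesquite-style tracing. Tree inference
itself is out of scope: any rooted Newick works.

## Chronology

"Arbitrarily make ultrametric": node height = the maximum summed branch
length from the node to any descendant tip, branch lengths rewritten as
height differences. This rule is deterministic, idempotent, preserves the
deepest root-to-tip path exactly and never shortens any path — appropriate
when branch lengths are accumulated SNP counts and the deepest paths carry
the most signal. Rate calibration r = height/age, averaged arithmetically
over calibration nodes when several are given; ages are height/r, rounded
to whole years only for reporting. Calendar conversion subtracts the age
from the present year (default 2021; negative values are BCE). The method
deliberately has no clock model, no rate smoothing and no uncertainty — a
crude, transparent extrapolation, and the recovery test (Poisson(r·t) SNP
counts on a known-timed tree, r = 1.24 SNP/yr) shows node times come back
within 15%.

## Synthetic data

The generator emulates the survey design the statistics assume: groups
diverge along a known species tree under Balding–Nichols drift (branch t
turns frequency p into a Beta draw with mean p and variance
(1 − e⁻ᵗ)·p(1−p); ancestral frequencies Uniform(0.05, 0.95)); one lineage's
terminal branch is stretched by 1/severity to create a domestication
bottleneck; accessions are binomial(2, p) draws ("genebank") or crosses of
two gametes from a sharpened frequency pool p^γ/(p^γ + (1−p)^γ), γ = 2
("hybrid" — sharpening pushes frequencies toward fixation, giving F1-like
uniformity; shrinking frequencies toward their mean would *raise*
heterozygosity, the wrong direction, so sharpening is used instead). Loci
are scattered uniformly at random along the chromosome layout
(reduced-representation sparsity) and calls are masked uniformly at the
missing rate. Desk-scale defaults: 8 groups × 12 accessions × 2 000 loci on
three 1 Mb chromosomes, severity 0.2 on the cauliflower analogue, 25%
hybrids, 2% missing, all randomness from one integer seed.

Not modelled: recombination and LD, selection sweeps, admixture/
introgression, restriction-site dropout, genotyping error. A green
recovery test therefore establishes internal consistency of the estimators
under drift-only structure, not robustness to those real-data features.
Diversity orderings (bottleneck lowest, hybrids below genebank) hold in
expectation and are asserted over seed ensembles, never per seed.

## Pipeline

Stages run in a fixed DAG (simulate/load → distances → diversity → F_ST →
PCA → SVDq → trace → date) from one YAML config; pre-flight validation
rejects invalid configs before any stage runs (e.g. dating without any
branch-length tree). Every stage derives its seed from the global seed by a
fixed SeedSequence fan-out, so stages are individually reproducible and a
rerun is bit-identical on all TSV/Newick/JSON outputs. SVDq topologies
carry no branch lengths (model-based branch-length estimation is out of
scope), so the dating stage consumes a branch-length tree supplied as input
— by default the simulation's truth tree.

## Known limitations

* F_ST is two-population only; no multi-population estimator.
* Distances use pairwise-complete loci; extreme structured missingness can
  break metricity.
* The SVDq assembly objective is a quartet-amalgamation heuristic above 8
  lineages; it is exact (exhaustive) at ≤ 8.
* Dating inherits every caveat of single-calibration clock extrapolation;
  reported ages are point estimates with no intervals.
* The Evanno statistic cannot evaluate K = 1 or the largest K surveyed.
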