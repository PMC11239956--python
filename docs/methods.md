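# Methods

This note records the models behind each module, the defaults that
matter, the numerical choices, and what the synthetic data do and do not
establish about real data.

## Molecular variance and Φ statistics

AMOVA decomposes squared pairwise molecular distances between diploid
individuals into hierarchical variance components using the classical
mean-square equations with unequal-sample-size coefficients. For the
two-level design (groups / populations / individuals) the sums of squared
deviations are

    SSD_total = Σ_{i<j} d²_ij / N,
    SSD_WP    = Σ_p Σ_{i<j∈p} d²_ij / n_p,
    SSD_AP    = Σ_g Σ_{i<j∈g} d²_ij / N_g − SSD_WP,
    SSD_AG    = SSD_total − Σ_g Σ_{i<j∈g} d²_ij / N_g,

with expectation coefficients n₁, n₂, n₃ built from the population and
group sizes. Negative variance-component estimates are retained by
default (a truncate-at-zero option exists); this keeps the decomposition
exactly invertible and lets the test suite verify components against a
brute-force double-sum oracle to 1e−10.

**Distance metric.** Two squared-distance conventions are provided.
`allele_mismatch` (the default) is the expected number of allele
differences between two unphased diploids,
d²(i,j) = Σ_l [g_i(2−g_j) + g_j(2−g_i)]/4 — the allele-level treatment
of genotype data. Under the nested island model this makes Φ_CT and Φ_ST
estimate the allele-frequency differentiation F directly (recovery to
within ~0.005 at F_CT = 0.30 in our simulations). `manhattan` treats the
dosage-difference count Σ_l |g_i − g_j| itself as the squared distance
(the treat-the-count-as-d² convention for molecular data); it is kept
because some established programs report that flavor, but it
overestimates F-scale differentiation on diploid dosages (≈0.37 at a
true 0.30), so it is not the default. Loci missing in either member of a
pair are excluded and the partial sum rescaled by L/L_shared
(switchable).

**Permutations.** Φ_ST permutes individuals among populations; Φ_CT
permutes whole populations among groups; Φ_SC permutes individuals among
populations within groups; p = (#{perm ≥ obs} + 1)/(n_perm + 1). The
default count is 10,000 (CLI); the API requires an explicit seed. With
few populations the Φ_CT permutation space is small, so its attainable
p-value is bounded below — a property of the design, not the
implementation.

**Hardy–Weinberg.** The exact conditional (Levene/Haldane) test: the
probability of every heterozygote count compatible with the observed
allele counts is computed from the log-gamma form and all configurations
no more probable than the observed one are summed (full tail mass, no
mid-p correction). The test is conservative by construction; on 10,000
simulated equilibrium loci (n = 50, p = 0.5) the empirical size at
α = 0.05 is ≈0.04.

**Locus statistics.** Unbiased expected heterozygosity uses
2p(1−p)·n/(n−1) on the allele count n; π per variant site equals
unbiased H_e; F_IS = 1 − H_o/H_e where H_e > 0, NaN (flagged) otherwise.
The Stacks-style completeness filter keeps a locus called in ≥ r% of
individuals (default 50) and present in ≥ p populations (default 6,
capped at the number available); both knobs are exposed because the
upstream tooling supports either a per-dataset or per-population
threshold and published pipelines vary.

## DAPC

PCA is computed from the SVD of the column-centered (mean-imputed)
genotype matrix with a largest-|loading|-positive sign convention.
K-means (10 restarts per k, seeded) is scored by
BIC = n·ln(WSS/n) + k·ln(n); ties resolve to smaller k. This criterion
has a genuine interior minimum only when the score space has many
near-noise dimensions (the realistic regime for genotype PCs); in low
dimension WSS falls fast enough that the BIC always prefers more
clusters, which is why the pipeline defaults to retaining ≈ N/3 axes —
retaining ~N axes diluted cluster recovery in our simulations (subgroup
ARI 0.72 vs 1.0). Membership probabilities are the softmax of −½ ×
squared distances to cluster centroids in the discriminant space; the
a-score is the observed reassignment rate minus its permuted-label
expectation.

## Barcode analyses

**K2P.** Sites with gaps, N, or any IUPAC ambiguity in either sequence
are removed per pair (pairwise deletion); saturation (log argument ≤ 0)
raises rather than returning a silent NaN.

**Barcode-gap partition.** Ranked pairwise distances are scanned for the
first significant gap beyond each prior P on a log grid (0.001–0.1, 10
steps): a gap between consecutive distinct distances d_i < d_{i+1} (with
d_{i+1} > P) is significant when its width exceeds 1.5 × max(d_i, P),
i.e. the jump is large relative to the distance scale already reached.
Groups are split by single linkage at the gap midpoint, the scan is
applied once more inside each group (one recursion level — the full
recursive-refinement stage of the original tool is out of scope), and
the consensus is the modal partition across priors. Tiny priors
over-split (as the original method does); the modal consensus absorbs
this. A single group is a valid outcome — it is exactly the negative
result expected when two species share haplotypes.

**Statistical parsimony.** The connection limit is the largest step
count j whose parsimony probability exceeds the confidence level
(default 0.95). The estimator is our own formulation in the
Templeton–Crandall–Sing tradition: per-site substitution counts are
Poisson with the Jukes–Cantor rate whose expected differing-site
fraction equals the observed j/m (λ = −¾ ln(1 − 4j/3m)), a site differs
with the JC visibility probability, and parsimony means no site was hit
more than once:

    P_j = (λe^{−λ}/p)^j · (e^{−λ}/(1−p))^{m−j},  p = j/m.

For 658 bp at 95% the limit is 8 steps. Because visibility saturates at
p = 3/4, the limit approaches ⌈3m/4⌉−1 (not m) as the confidence → 0.
The closed form is verified in the tests against an independent
Monte-Carlo simulation of the same placement model.

**Networks.** Haplotypes (exact string collapse; ambiguities are not
wildcards) are connected by every edge that belongs to at least one
minimum spanning tree (cycle criterion on the strictly-lighter
subgraph), restricted to edges within the parsimony limit. This
minimum-spanning-network construction is a documented approximation of
the probabilistic TCS cladogram estimation.

## Paleodistribution engine

**Climate reduction and hindcasting.** PCA is fitted on z-scored
present-day cells; anchors are standardized with the present-day means
and scales before projection, so axis values are comparable across
times. Each cell × axis series is regressed on the δ18O forcing by OLS
(two parameters — with four anchors, higher-order fits would overfit),
and the fitted lines are evaluated along the forcing at 1-ky steps from
0 to 600 ka and 2-ky steps from 602 to 786 ka (694 slices). When the
anchors are exactly affine in the forcing (as the synthetic world is by
construction) the hindcast reproduces them to < 1e−10.

**Algorithms.** bioclim: per-variable midpoint-ECDF envelope, suitability
= min over variables of 2·min(F̂, 1−F̂); domain: max Gower similarity to
a training presence; ENFA: marginality axis
(mean_presence − mean_background)/(1.96·sd_background) plus
specialization axes from the residual presence covariance, suitability =
upper-tail percentile of the diagonal Mahalanobis distance among the
training presences; maxent-like: L2-penalized logistic discrimination of
presences against background over linear + quadratic features
(a penalized exponential-family model, not the reference Java
implementation); one-class SVM: RBF kernel, ν = 0.1, decision values
rescaled to [0, 1] by the training range. Background: 10,000 uniform
non-masked cells (or all cells when fewer), seeded — no count is
standard in the literature, so this default is prominent and adjustable.

**Thresholds.** Max-sensitivity+specificity over the unique observed
scores, ties resolving to the lowest (most inclusive) cutoff. Presence
scores for thresholding come from spatially buffered leave-one-out
refits (each presence scored by a model fitted on the presences outside
a 3-cell Chebyshev buffer): plain in-sample or point-wise LOO scores are
inflated by spatial autocorrelation — a presence's neighbors remain in
the training set — and the resulting thresholds reject every genuinely
fresh suitable cell, destroying transferability to other time slices.
This is block cross-validation reasoning applied at the smallest useful
scale.

**Ensemble and stages.** The committee is an unweighted majority of the
binarized maps (⌈A/2⌉ of A algorithms; 3 of 5). Glacial/interglacial
composites average the consensus over the slices of each stage type and
binarize at 0.5 (configurable). Two stage tables are provided: the
packaged LR04-derived table (MIS 1–19, 0–790 ka, odd stages
interglacial) for real forcing data, and `MisTable.from_forcing`, which
delimits stages directly from a forcing curve by midrange crossings —
the right choice for synthetic forcings whose cycles do not follow the
observed record. Range metrics use latitude-corrected cell areas and
8-connected components; the corridor flag asks whether one component of
the union of suitable cells touches both species' largest cores.

## The synthetic climate world

The generator emulates a subtropical sky-island landscape and is the
package's test bed for the full engine. Its structure is deliberate:

- **Temperature** is a warm plain (with a weak lat/lon gradient) minus
  five isolated cold Gaussian peaks. Cone geometry makes the area of any
  cold level set grow monotonically downslope — the mechanism by which
  glacial cooling expands a montane species' habitat.
- **Eighteen secondary variables have ~3 effective dimensions**: twelve
  temperature-family layers are affine in temperature plus one shared
  continentality-like field; six precipitation layers mix two shared
  fine-scale regime fields. Real bioclimatic layer sets are similarly
  low-rank; giving every layer an independent field creates a
  high-dimensional climate space that no realistic presence sample can
  cover, and every model then vetoes genuinely suitable cells at other
  times.
- **Responses are pattern-coherent**: each variable's anomaly lies along
  its own present-day spatial pattern (temperature-family slopes are
  α·temperature-slope; precipitation slopes follow the regime patterns),
  with only a small incoherent residual. This is the space-for-time
  assumption that underpins projecting present-trained models to past
  climates; responses orthogonal to the present variance structure
  create no-analog axes that break every algorithm.
- **The niche** is Gaussian, centered by default on the exact present
  climate of the coldest cell (the species is summit-pressed at the
  present interglacial), tight on temperature (0.7 sd) and loose on the
  secondary variables (4 sd). The truth map is the unnormalized Gaussian
  density, so it attains exactly 1.0 at the center cell. Presences are
  sampled without replacement ∝ present-day truth, at most one per cell.
- **The forcing** is a periodic δ18O-like curve (period 100 ky, small
  second harmonic), minimal at t = 0, amplitude 1.2 ‰ by default; with
  the default temperature sensitivities this yields glacial cooling of
  ≈2.0–2.4 °C, consistent with lowland-subtropical estimates for the
  Last Glacial Maximum. Anchor fields are exactly affine in the forcing,
  so the hindcast stage can be verified to machine precision.

What passing tests show — and do not. The glacial-expansion property
(predicted area larger in glacial than interglacial slices, sign test
across 20 seeds) holds in this regime; it is genuinely
regime-dependent. When the climate displacement grows large relative to
the niche breadth (e.g. forcing amplitude at the upper end of the
benthic-stack range with the same sensitivities), the
similarity-based algorithms (envelope, Gower, one-class SVM) stop
recognizing the displaced suitable belt even though the true suitable
area keeps growing — the classic transferability failure under niche
truncation. Passing the property here therefore shows the engine behaves
correctly where its assumptions hold; it does not certify extrapolation
to arbitrary displacements, and on real data the displacement-to-breadth
ratio should be checked before interpreting hindcast range dynamics.
The generators likewise idealize away missing-data structure (MCAR
only), linkage, selection, spatial sampling bias, and dating/alignment
error in the forcing curve.

## Genotype and barcode generators

Genotypes follow the nested Balding–Nichols model: ancestral frequency
p₀ ~ U(0.1, 0.9) per locus, group frequencies Beta-distributed around p₀
at F_CT, population frequencies Beta around the group's at F_SC,
genotypes Binomial(2, p_pop), missingness MCAR. Defaults (2 groups × 3
populations × 20 diploids, 2,000 loci, F_CT = 0.30, F_SC = 0.02) match
the two-species / three-mountain-range design and the differentiation
magnitudes reported for such systems. F_ST realized at 2,000 loci
recovers the targets within ±0.05.

Barcodes: one ancestral 658-bp sequence; with a shared haplotype, 60% of
each species carry it unchanged and the rest get up to 6 substitutions
(overlapping intra/inter distances, no gap); the diverged scenario
separates the two ancestors by 33 substitutions (~5%) with ≤2
within-species substitutions (a clean gap). The two convenience
constructors freeze these as the negative- and positive-control
conditions for delimitation.

## Problem sizes

Tests and the acceptance script run the genotype analyses at the full
study scale (120 × 2,000), the HWE size check at 10,000 loci, DAPC over
10–20 replicate seeds, and the ensemble hindcast on a 40 × 60 grid with
a 10-ky time grid over 20 seeds; the full 694-slice grid is exercised
once for the slice count and the exact-affine verification. These sizes
give stable statistics at interactive runtimes.
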