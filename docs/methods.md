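# Methods

`sparsemet` implements a genomics-assisted sparse-phenotyping analysis for
multi-environment trials (METs): instead of phenotyping every line in a few
environments ("complete phenotyping"), lines are spread thinly over more
environments and the missing cells are predicted by a genomic model; the two
strategies are compared on the breeder's actual target, the response to
selection, simulated from the fitted mixed model.

## Stage-one trial analysis

Each environment is analysed separately with a mixed linear model in which
replicate, row and range are independent random effects. Genotype is fitted
twice: as fixed, giving best linear unbiased estimates (BLUEs) of line means,
and as random, giving the environment's repeatability. Repeatability is
reported on the line-mean basis

    r = sigma_g^2 / (sigma_g^2 + sigma_e^2 / n_reps),

i.e. net of the separable design effects; this is the conventional
repeatability of an RCBD yield trial and the quantity the BLUE-level noise
of the simulator is calibrated to.

Across-environment heritability uses the BLUE table: the model
`BLUE = mu + environment + line + error` (environment and line independent
random effects, REML) and

    h^2 = 1 - cbar / (2 sigma_l^2),

where cbar is the mean variance of a difference between two line BLUPs,
computed from the line block of the inverted mixed-model equations. h^2 is
clipped to [0, 1]; zero line variance returns 0 with a warning.

## Genomic relationships

The genomic relationship matrix is G = ZZ' / (2 sum_j p_j (1 - p_j)), Z the
dosage matrix centred at twice the observed allele frequency, frequencies
always computed on the analysed line subset. Missing dosages are mean-imputed
before centring. Fully inbred panels have diag(G) near 2 (an inbred line
carries two identical gametes), outbred equilibrium panels near 1. A
configurable diagonal ridge (default 1e-6) is added before any inversion:
near-duplicate lines make G numerically singular. Rogers' distance per
biallelic locus reduces to |p1 - p2| of the individual allele frequencies
(0, 1/2, 1 from dosage), averaged over pairwise-complete loci.

## The multi-environment model

Observed BLUE cells follow

    y = 1 mu + Zv v + Zg g + gv + e,
    v ~ N(0, E sv2),  g ~ N(0, G sg2),
    gv ~ N(0, (Zg G Zg') .* (Zv E Zv') sgv2),  e ~ N(0, I se2),

with E = I by default and ".*" the Hadamard product. The interaction is one
random effect per observed cell; with E = I its covariance is block diagonal
by environment with G sub-blocks. Masked cells are removed from y and from
all incidence matrices; predictions for them flow through G (and E). mu is
the only fixed effect — environment means are absorbed by the random v, so
sv2 mostly reflects the spread of environment means.

Variance components are estimated by average-information REML on the
marginal model (tolerance 1e-8 on the restricted log-likelihood, at most 200
iterations, components floored at ~1e-10 relative to the phenotypic
variance). AI steps are halved until the likelihood does not decrease;
components pinned at the floor with a downhill score are held fixed
(active set), and a positivity-preserving fixed-point update is the fallback,
so the accepted likelihood trace is non-decreasing. A blocked Gibbs sampler
is available as an alternative (location effects jointly from the MME
conditional, variances from scaled-inverse-chi-square conditionals; defaults
30,000 iterations / 5,000 burn-in). Its priors are weakly informative
(df0 = 5, scales from an equal split of the phenotypic variance) rather than
flat: with only 3-6 environment levels a flat variance prior produces a
near-improper, heavy-tailed posterior for the environment variance. REML is
the default because it is deterministic and directly testable.

Effects and their prediction error variances come from Henderson's mixed
model equations for (mu, v, g, gv); the g-block of the inverted coefficient
matrix gives PEV(g_hat) = C^gg se2.

An optional variant replaces the identity on environments with a relationship
matrix E estimated as the Pearson correlation of lines commonly observed in
each pair of environments (pairs with fewer than 3 common lines fall back to
0 = independence, with a warning and recorded counts). E is projected to PSD
by eigenvalue clipping with the diagonal rescaled to 1. An all-ones E
collapses the interaction kernel onto the main-effect kernel and is flagged
as confounded.

## Sparse-phenotyping designs

All C(m, 3) base combinations of 3 environments are complete-phenotyping
scenarios (20 for m = 6). Each base is extended by every subset of 1-3
remaining environments. Masking follows CV2 (cell-wise): every line keeps
exactly 3 observations, masking m_total - 3 cells uniformly at random over
all scenario environments, which yields exactly 75/60/50% retention for
4/5/6-environment scenarios and equal phenotyping intensity everywhere. A
minimal connectivity guard (every environment keeps at least 2 observed
lines, redraw with a derived sub-seed, at most 100 attempts) keeps the MME
solvable; beyond that the masks are deliberately unconstrained — no
per-environment balancing is imposed.

## Response to selection

Selection acts on g_hat; gain is realised on g. Under the model,
Omega = var(g, g_hat) has blocks var(g) = G sg2 and
var(g_hat) = cov(g, g_hat) = G sg2 - PEV (standard BLUP identities). Omega is
factored as Gamma Gamma' via eigendecomposition with Gamma = D Lambda^{1/2}
(note: D Lambda does not satisfy Gamma Gamma' = Omega; the square root is
required). Negative eigenvalues within 1e-6 of the largest (relative) are
clipped to zero and reported — this tolerance matches the inversion ridge,
which perturbs Omega at exactly that scale; larger negatives raise, since a
substantially non-PSD Omega signals an upstream bug. A pivoted-Cholesky
factorization is provided as an independent cross-check.

Per run, w = Gamma z with z ~ N(0, I_2n); the top ceil(p n) lines by g_hat
(ties broken by stable line order) are selected and the mean true g of the
selected set recorded; the achieved response at ratio p is the mean over
runs (default 10,000) for p = 0.1 ... 0.9. Each scenario gets its own random
stream derived from (seed, scenario_id), so results do not depend on
execution order.

## The comparison pipeline

For every base: fit the complete scenario and simulate its response curve;
for every extension plan and masking replicate (default 100): mask, refit
(variance components re-estimated per replicate by default; a flag reuses
the unmasked-scenario components), simulate. The sparse replicates are
compared with the complete scenario's achieved response — treated as a
constant reference — by one-sample two-sided Student's t tests per selection
ratio. Verdict `sparse_higher` requires significance with positive mean
difference at every ratio (the conjunction makes the call conservative);
`sparse_lower` symmetrically; otherwise `no_difference`. No multiple-testing
correction is applied by default (a Bonferroni option exists but is off).

Base combinations are grouped by their correlation pattern, checked in order:
(1) any within-base pair at or above the high-positive cutoff (default 0.8);
(2) all pairs positive; (3) exactly one negative pair; (4) two or more
negative pairs. A "rice-style" variant replaces the negative boundary with a
low-positive cutoff (default 0.18) for all-positive panels.

## The synthetic MET generator

The generator emulates a pureline yield panel: fully inbred lines (dosages
0/2; optional residual heterozygosity), families created by Beta-drifting
ancestral allele frequencies (concentration `family_drift`, default 8 — the
smaller, the stronger the family structure), ancestral frequencies uniform
on `maf_range`. Environment-specific true genetic values come from a
marker-effect model: per-marker effect vectors are correlated across
environments according to the requested genetic correlation matrix, scaled
so the realised across-line variance of u_e equals
`genetic_variance_per_env` (the scaling uses the realised centred-dosage
sum of squares, not the HWE denominator, which for inbred panels would
double the variance). Phenotypes are produced either at plot level (RCBD
with replicate/row/range effects, each with variance
`design_variance_fraction * sigma_g^2`, and plot error calibrated so the
line-mean repeatability equals the request) or directly at BLUE level with
noise variance sigma_g^2 (1 - r)/r. Environment means are normal
(`env_mean`, `env_mean_sd`, defaults 4.0 and 0.8 t/ha — typical wheat yield
scale). All stages draw from substreams derived deterministically from one
seed: identical specs give bit-identical data.

Two presets encode the study conditions. The wheat-like preset (189 lines,
8 families, 6 environments, 2 replicates) uses a correlation matrix with one
0.84 pair, four negative pairs (-0.15 to -0.28) and low/moderate positives,
constructed so the 20 bases partition into the four utility groups; the
negatives are slightly milder than the most extreme observed values so the
matrix stays positive semidefinite given the other entries. Default
repeatabilities are 0.70-0.80: BLUE-level correlations attenuate the genetic
correlation by sqrt(r_e r_f), and only high repeatabilities are consistent
with observing a 0.84 correlation between BLUE columns in a 2-replicate
trial. The rice-like preset (160 lines) is all-positive, 0.05-0.67, with one
highly correlated pair and a triple of mutually low-correlated environments.

What the generator does not emulate: linkage disequilibrium beyond family
structure, epistasis, spatial field trends (design effects are independent),
multiple traits, and selection history. Tests passing on these data show the
machinery is correct and the correlation-structure mechanism operates; they
do not certify effect sizes on real panels.

## Numerical choices and degenerate inputs

- Ridge 1e-6 on G / E / interaction blocks before inversion; the MME
  coefficient matrix is solved by Cholesky and failure raises an error
  naming the offending block.
- Variance components at the REML floor are legitimate boundary estimates
  (e.g. sigma_g^2 ~ 0 for a base of mutually negatively correlated
  environments — precisely the case where sparse phenotyping helps most).
- Selected-set size is ceil(p n); ties in g_hat break by line order.
- Monomorphic or all-missing markers are excluded from allele-frequency
  denominators; an all-monomorphic panel raises.
- Unreplicated environments return BLUEs with repeatability flagged
  unavailable (None).
- Pairs of environments with fewer than 3 shared observed lines get NaN
  correlations (stage one) or the independence fallback (E matrix), with
  warnings.

## Problem sizes in the test-suite experiments

The bundled experiments run at reduced scale chosen to keep the full suite
fast while leaving Monte-Carlo error well below the tested effects: variance
recovery at 300 lines x 6 environments over 20 seeds, the qualitative
complete-vs-sparse replication at 100 lines, 10 masking replicates, 1,000
response runs over 5 generator seeds, and selection-theory checks at up to
2,000 lines with 10,000 runs. The pipeline defaults (100 replicates, 10,000
runs) match the full protocol.

## Known limitations

- The unstructured environment-covariance model is out of scope (it is
  numerically fragile under changing masking patterns); the E-matrix variant
  is the supported refinement.
- No optimized/selective phenotyping designs: masks are uniform per line.
- REML point estimates ignore variance-component uncertainty when Omega is
  built; the Gibbs option quantifies it but is slower.
- With few commonly observed lines the E-matrix variant degrades (its
  fallback is independence), so the basic model is the default.
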