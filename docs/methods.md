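# Methods

`breedgain` implements the quantitative-genetics machinery of a
recurrent-selection breeding program for a self-pollinating crop (the
running example is global spring canola): pedigree relationship matrices
with explicit selfing, single-trial spatial mixed models, a
multi-environment factor-analytic pedigree BLUP, overall-performance and
RMSD stability statistics, a dollar-denominated selection index,
optimal-contributions mate selection, and genetic-trend estimation. A
stochastic simulator generates breeding programs with the statistical
structure these models assume, so every stage can be validated against
known truth.

## Pedigree and relationships

Each genotype is recorded with its female and male parents and a
selfing-generation count `fgen`. Selfing is encoded by listing the same
genotype as both parents; `fgen` applies only to base genotypes with
unknown parents and maps to base inbreeding by the selfing-series limit
F = 1 − 0.5^fgen (so `fgen = 5` encodes an inbred variety, F ≈ 0.97, and
`fgen = 10` a doubled haploid, F ≈ 0.999). The additive relationship
matrix A is built by the tabular method, densely — the pedigrees this
package targets are O(10^4) genotypes, comfortably in dense territory, so
no sparse Henderson inverse rules are used. F is the diagonal of A minus
one; the coancestry f between two genotypes is half their A-entry and
equals the expected inbreeding of their offspring. Half-known parentage is
rejected rather than silently treated as unrelated, and `fgen` on a record
with known parents is ignored with a warning (selfing must be explicit).

A seedable gene-dropping simulator (`gene_drop_kinship`, default seed
20160101) provides an independent Monte-Carlo estimate of A for
validation: each base genotype starts with two unique alleles, goes
through `fgen` rounds of simulated selfing, and transmission follows
Mendelian sampling; relationships are estimated as twice the IBD kinship.

## Single-trial spatial model

One trait at one site is modelled as genotype (random, iid) plus optional
random range/row main effects and fixed linear trends, with residual
correlation the Kronecker product of two AR1 processes over the plot grid.
The residual variance is profiled out of the REML likelihood and the
remaining parameters (atanh of the two correlations, log variance ratios)
are maximised with L-BFGS-B; convergence at relative tolerance 1e−12 on
the objective. Missing plots are dropped; correlations come from grid
coordinates, so gaps are exact, not approximated.

Term screening uses a fixed forward ladder — iid → AR1×AR1 → +random
range → +random row → +fixed linear trends — keeping a term when it
improves the model. Variance terms are judged by REML likelihood-ratio
tests at α = 0.05; the fixed trends by a Wald z-test, because REML
likelihoods are not comparable across different fixed-effect structures.
The source material for this design leaves the outlier rule and
significance thresholds unstated, so both are explicit package defaults:
outliers are plots whose standardized conditional residual exceeds 3.5 in
absolute value, and flagging never removes data — that is the caller's
decision.

## Multi-environment factor-analytic pedigree BLUP

The across-site model for one trait has fixed site effects, additive
genotype-by-site effects `ua` with covariance G_a ⊗ A (G_a the p×p
between-site genetic covariance), independent nonadditive
genotype-within-site effects with site-specific variance, and iid plot
residuals with site-specific variance. The base model restricts G_a to a
diagonal; the factor-analytic model of order k writes G_a = ΛΛ' + Ψ.
Traits scored only at some sites (e.g. blackleg in disease nurseries) are
fitted over their observed site set only. Sites whose additive variance
collapses to the zero boundary stay in the model at the boundary rather
than being dropped; a Ψ entry collapsing to zero (Heywood case) is
permitted with a warning.

Spatial terms found in the single-site screen can be carried into the MET
stage as per-site fixed linear trends and random row/column effects; the
AR1×AR1 residual correlation is not carried forward — at the MET stage
residuals are iid within site with site-specific variance. This keeps the
across-site likelihood in closed collapsible form (below) at a small cost
in residual modelling fidelity, which the site-specific variances absorb
in practice.

**Estimation.** Plot records are collapsed exactly to genotype-by-site
cell means: within-cell contrasts contribute a closed-form chi-square term
in the residual variances (plus the mean-collapse Jacobian constant, so
reported likelihoods match plot-level values), and the cell means carry
the rest. The REML log-likelihood is maximised directly over an
unconstrained parametrization (free loadings, log variances) by L-BFGS-B
with the analytic REML score — for every parameter the trace and quadratic
terms reduce to site-block sums of elementwise products, so a gradient
costs about two likelihood evaluations. Initialization is moment-based:
residual variances from pooled within-cell mean squares, and loadings from
the leading eigenvectors of the empirical between-site covariance of cell
means (whose off-diagonals estimate the additive covariance directly).
Tolerances: relative 1e−11 on the objective, gradient 1e−6; 500 iteration
cap. This engine reaches the same optimum as the classical EM-plus-
average-information route with far fewer large-matrix factorizations at
the problem sizes used here.

Identification: loadings are estimated unconstrained and rotated
post-fit by the right singular vectors of Ψ^{−1/2}Λ, which orders factors
by explained variance in the fitted metric and makes Λ'Ψ^{−1}Λ diagonal
(the canonical orientation); each factor's sign is set so its mean loading
is non-negative. The fitted covariance, all site effects, and %VAF are
rotation-invariant.

Bookkeeping: the variance-parameter count is 3p for the base model plus
pk − k(k−1)/2 for FA(k); AIC/BIC are computed from variance parameters
only. Published selection tables in this style sometimes show different
increments (e.g. 44 → 53 → 59 across nine sites), implying site-specific
constraints that are not fully stated; this package uses the clean formula
and documents the mismatch rather than forcing it. Model selection prefers
k+1 over k only when the REML LRT is significant at α = 0.05 *and* the
%VAF gain exceeds 2 percentage points (the base → FA(1) step is judged by
the LRT alone, as the base model has no common factors). %VAF is defined
site-summed: 100 · Σ_j (ΛΛ')_jj / Σ_j (ΛΛ' + Ψ)_jj.

BLUPs of `ua` for every genotype at every site — including pedigree
ancestors and unobserved relatives — come from conditional-mean algebra
through A; prediction error variances from the corresponding conditional
variances. PBV is the across-site mean additive effect in trait units.
Per-site heritability is σ²_a/(σ²_a+σ²_na+σ²_e); per-genotype accuracy is
sqrt(1 − PEV/((1+F)σ²_a)) averaged over sites.

## Overall performance and RMSD stability

From the rotated fit, OP_i = mean(λ₁) · f_i1 — a generalised main effect
valid when the first-factor loadings share one sign; with crossover
interaction (mixed signs, as seed weight shows in the motivating study) OP
is still computed but flagged as not a valid main effect. Stability is
RMSD_i = sqrt((1/p) Σ_j d_ij²) with deviations d_ij = Σ_{k≥2} λ_jk f_ik:
common-factor deviations only — the site-specific Ψ effects are
measurement-like and excluded. Under an FA(2) optimum RMSD is exactly
|f₂| times a constant; an equivalent parametrization of OP via the
regression slope would rescale but not re-rank genotypes.

## Economic index

The index prices each genotype in US$/ha. Grain yield enters through the
price: total GY (population mean + PBV) × grain price. Every other trait
contributes PBV × w$ × total GY, where w$ is a signed percentage of the
grain price per +1 PBV unit; the oil weight defaults to 1.5%/unit from the
market bonification rule (1.5% price premium per 1% seed oil), protein in
meal to double the oil weight, with negative weights on flowering time,
height and glucosinolates. The optional stability term treats RMSD GY as a
"PBV" with a −20% weight. All weights are configurable (breeders adjust
them between cycles); arithmetic is full-precision with rounding only at
presentation.

## Optimal-contributions mate selection

Candidates are hermaphroditic; each may appear in at most `max_uses`
matings (default 30, the typical remnant-seed count). A plan of N ordered
pairs is scored by mean progeny index (midparent values) and achieved
parental coancestry 0.5·c'Ac with contributions c_i = uses_i/(2N). The
gain–coancestry trade-off is expressed as a target angle: 0° = maximum
gain, 90° = minimum coancestry. Because the commercial tool that
popularised this scale does not publish its normalization, this package
defines the angle on the min–max normalised gain–coancestry plane anchored
at two computable endpoints: the exact greedy maximum-gain plan (optimal
because midparent gain depends only on use counts) and a
minimised-coancestry plan (projected-gradient QP on the capped contribution
simplex, rounded to integer uses by largest remainder).

The search is a steady-state evolutionary algorithm over pair lists
(tournament selection, single-point crossover, parent-swap/pair-replace/
allocation-shuffle mutations, cap-repair), with fitness
cos φ·Ĝ − sin φ·Ĉ plus a weight (default −1) on mean progeny inbreeding
and moderate per-occurrence penalties (default 0.02 normalised-fitness
units) on selfings, reciprocals and duplicates. For intermediate targets a
small outer loop adjusts the internal angle φ by bisection until the
achieved position angle matches the target, and the final plan is chosen
from the archive of evaluated populations as the one nearest the target
angle (ties broken by penalty-aware fitness). Defaults: population 200,
2000 generation-sweeps, tournament size 3, mutation rate 0.2/pair; all
seedable and deterministic for a fixed seed.

## Genetic trends

The rate of genetic gain is the OLS slope of candidate PBV or OP over
cycle number; dividing by the cycle length (default 2 years) gives the
annual gain, also reported as a percentage of the population mean.
Individual-record OLS is exactly equivalent to count-weighted regression
of per-cycle means, which is what makes published per-cycle summaries
reconstructable. Both record-level and mean-level standard errors are
obtainable (the slope is identical; the package reports the record-level
convention). The same machinery regresses historical-cultivar values on
release year, and predicted site means on cycles as the environmental-
trend check — a non-significant site-mean slope supports reading the
candidate trend as genetic. Cycles sharing fewer than 10 genotypes with
every other cycle can be excluded as poorly connected (caller's decision,
`exclude_poorly_connected_cycles`).

## Synthetic breeding programs

The simulator is an infinitesimal model — no explicit loci. Each genotype
carries, per trait, two latent additive factor scores; crosses give
midparent plus Mendelian sampling with variance ½(1 − (F_s + F_d)/2) per
unit additive variance, so an F1 of two inbred unrelated founders is
uniform and repeated selfing extinguishes within-family variance. G×E
truth is rank-2 by construction: each site draws a per-trait first-factor
loading around the trait-level value and a zero-centred second-factor
loading (crossover interaction), so an FA(2) fit has a well-defined,
identifiable true optimum. Default trait set, means and units follow the spring-canola
setting (GY t/ha, DTF days, PlHt cm, Oil %, ProM %, GSL µmol/g, OL %, BL
1–9 score, SW100 g); the between-trait additive correlation matrix encodes
a GY/BL/Oil/PlHt/DTF cluster opposed to a ProM/GSL/OL/SW100 cluster, and
additive SDs are set so heritabilities land in the 0.25–0.5 range under
the default noise levels (nonadditive fraction 0.3 of additive variance,
residual 1.2× additive, AR1 correlations 0.4 with half the residual
spatially structured). No variance-component table exists for the real
program, so these are documented assumptions chosen to be qualitatively
realistic, not facts.

Program structure mirrors augmented S0,1 family selection in two-year
cycles: two founder pools (default 32 + 32, fully inbred, configurable
mean divergence), pool-crossed F1s intercrossed into S0 progeny, each S0
selfed once so the phenotyped unit is the S0,1 family, one self progeny of
each used parent carried forward (cross-and-self-sib structure), optional
migrant F1s per cycle, and inbred control genotypes replicated in every
trial — the anchor that lets pedigree BLUP separate genetic from site
effects across cycles, as check cultivars do in real programs. Trials are
p-rep on a range×row grid (a configured fraction of genotypes in single
plots), with AR1×AR1 spatial residual plus nugget, and one site per cycle
optionally acting as a disease nursery whose grain-yield signal is partly
driven by blackleg scores (configurable coupling, default 0.5). Selection
between cycles: random, truncation on true or phenotype-mean values, or
OCS at 45° on the phenotype-mean index. All randomness flows from one seed;
identical seeds give byte-identical archives.

What the simulator does **not** emulate: marker genotypes, explicit
disease epidemiology, NIRS measurement-error structure beyond iid noise,
bloc-design optimisation (plots are randomly allocated, not
design-optimised), or environmental trends over cycles (site means are
drawn around fixed trait means, which is what makes the zero-environmental-
trend validation meaningful). Passing tests therefore demonstrate that the
analysis machinery is correct under the stated model, not that the model
captures every feature of real field data.

## Problem sizes in the test suite

Tests validate each stage at the smallest size where the statistical
property is informative: pedigrees of 30–50 for the gene-dropping check
(200k replicates), grids of 320–480 plots for spatial recovery, 120–260
genotypes × 3–5 sites for REML recovery and model selection, 25–50
candidates for the OCS suites, and 3-cycle programs of ~35 matings/cycle
for the end-to-end gain-recovery round trip (median-over-seeds criteria).
Tolerances come from the statistical claims themselves (Monte-Carlo
standard errors, 2-SE bands, the 20–25% recovery bands) and are not
adjusted per run.

## Known limitations

- The MET engine is dense and collapses to cell means; datasets far beyond
  ~10^4 cells per trait would need sparse or sampling-based REML.
- The OCS angle scale is anchored to package-computed endpoints; numbers
  are self-consistent but not numerically comparable with proprietary
  tools' "degrees".
- OP is reported (with a warning) even when mixed-sign loadings make it
  invalid as a generalised main effect.
- The two-stage treatment of spatial terms (screen per site, carry fixed
  trends and row/column effects but not the residual correlation into the
  MET stage) slightly understates spatial information relative to a joint
  fit.
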