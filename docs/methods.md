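# Methods

## Model

One paternal half-sib family (or several sharing a dam population) observed
at a pair of biallelic SNPs. The sire is heterozygous at both loci with
known, externally phased haplotypes — in *coupling* (A-A / B-B) or
*repulsion* (A-B / B-A). Per offspring the latent data are the paternal
gamete g<sub>p</sub> ∈ {A-A, A-B, B-A, B-B}, with prior
((1−θ)/2, θ/2, θ/2, (1−θ)/2) in coupling orientation (swapped under
repulsion), and the maternal gamete g<sub>m</sub> with prior equal to the
dam haplotype frequencies h = (p<sub>A-A</sub>, p<sub>A-B</sub>,
p<sub>B-A</sub>, p<sub>B-B</sub>). The observed genotype at each locus is
the unordered allele pair, so the nine cell probabilities
π<sub>i,k</sub> are sums of g<sub>p</sub> × g<sub>m</sub> products. We build
π from this gamete decomposition rather than from transcribed closed-form
cell expressions; the two agree symbolically (spot-checked cell by cell) and
the decomposition is what the EM needs anyway.

Equivalent LD parametrization: D<sup>sire</sup> = (1−2θ)/4
(coupling-oriented; θ ∈ [0,1] ↔ D<sup>sire</sup> ∈ [−0.25, 0.25]) and
D<sup>dam</sup> = p<sub>A-A</sub> − p₁p₂ with the classical bounds
L₁ = max{−p₁p₂, −(1−p₁)(1−p₂)} ≤ D<sup>dam</sup> ≤
L₂ = min{p₁(1−p₂), (1−p₁)p₂}.

Assumptions: error-free sire phase; dams drawn from one population (shared
h across families); independent offspring; no segregation distortion
(paternal A-allele frequency 0.5 among offspring).

## EM algorithm

Standard multinomial missing-data EM. E-step: each cell count is
distributed over the gamete combinations producing that cell,
proportionally to the current priors. M-step: θ ← expected recombinant
paternal gametes / N (recombinants oriented per family phase);
h ← expected maternal gamete counts / N. The observed-data log-likelihood
is non-decreasing by construction; the test suite asserts this at every
iteration across 1,000 random fits, which is the correctness check for the
reconstructed updates.

Numerical choices:

- **Convergence** |Δ log LF| < 1e-10 with at most 5,000 iterations (both
  configurable). The surface can be extremely flat — e.g. the balanced
  design D<sup>sire</sup> = D<sup>dam</sup> produces a ridge on which the
  iteration cap, not the tolerance, stops the EM; estimates anywhere on the
  ridge are equivalent to ~1e-5 log-units.
- **Boundary starts are nudged inward by 1e-6** (θ and haplotype
  frequencies). At θ = 0 exactly the recombinant gametes have prior zero,
  the EM could never leave the boundary, and any genotype cell requiring a
  recombinant paternal gamete would be impossible (likelihood −∞). The
  nudge makes the default start (θ = 0, D<sup>dam</sup> = 0) usable without
  changing where the EM converges. Starts that remain impossible raise a
  start-value error advising a jittered restart.
- **Frequencies may reach 0 during iteration** (0·log 0 := 0); no jitter is
  applied mid-run. Probabilities below 1e-300 under a positive count yield
  −∞, not an exception, so mode comparison still works.
- θ is **not** restricted to [0, 0.5] by default: estimates above 0.5 can
  reflect chromatid interference or an erroneous sire phase and are
  informative. `theta_max=0.5` enforces the interference-free space (the
  M-step output is clamped).
- Allele-frequency estimates use homozygotes only,
  p̂ = n<sub>AA</sub>/(n<sub>AA</sub>+n<sub>BB</sub>): the heterozygous
  sire contributes allele A with probability ½ regardless of the maternal
  allele, so AB offspring are uninformative for p.

A vectorized engine runs many independent fits in parallel (replicates of a
simulation study, or all pairs of a chromosome); converged fits leave the
active set so flat-surface stragglers do not dominate. The single-fit API
wraps the same code path and the equivalence is tested.

## Dual start and decision process

Run 1 starts at (θ = 0, D<sup>dam</sup> = 0, h from p̂). The second start
comes from the mode-linking involution D<sup>sire</sup>′ = D<sup>dam</sup> + c,
D<sup>dam</sup>′ = D<sup>sire</sup> − c, c = (1−2p₁)(1−2p₂)/4, applied to
run 1's LD estimates **at the marginal allele-frequency estimates p̂** (not
the EM-fitted frequencies). The distinction matters: with p̂ the procedure
reproduces the published mode-selection frequencies of this estimator
family (≈96% vs ≈93% first-mode selection in the small-θ regime), and it is
p̂ that the start-value construction defines in the first place. If the
complementary point violates |D<sup>sire</sup>| ≤ 0.25, the D<sup>dam</sup>
bounds, or the haplotype simplex, the surface is taken as unimodal and run 2
is skipped; an in-space start on the boundary is nudged inward by 1e-6. A
second run that converges back to the first mode (log LF\* within 1e-9 and
parameters within 1e-6) is collapsed to a unimodal result.

Decision: outside the critical range [0.48, 0.52] (closed; *both*
frequencies must be inside for a pair to count as critical) the proposal
with the larger **combined-cell log-likelihood** wins. log LF\* merges the
zero-count cells with every cell tied at the minimum positive count — the
set-valued argmin is merged in full, keeping the rule order-independent —
which damps the leverage of near-zero haplotype frequencies in small
families. For several families, log LF\* is computed per phase-pooled table
and summed. Exact ties (< 1e-12) fall to the first proposal with a warning.

Critical pairs are decided in a second pass, after all non-critical pairs
are final: for pair (i, k) with i < k, the decided estimates in row i of
the θ̂ matrix are regressed on the mates' relative physical positions
(bp / chromosome length) with a cubic smoothing spline at five effective
degrees of freedom, and the proposal with the smaller squared deviation
from the curve at SNP k's position wins. At least 10 usable neighborhood
points are required (a 5-df smoother needs headroom); sparser rows fall
back to the likelihood comparison with a warning.

### Smoothing spline

Natural cubic smoothing spline minimizing Σ wᵢ(yᵢ − g(xᵢ))² + λ∫g″², with λ
chosen so that the trace of the smoother matrix equals the target df — the
trace is evaluated in closed form from the eigenvalues of the
weight-standardized penalty, and λ is found by root-finding on log λ.
Duplicate abscissae are collapsed to weighted means; evaluation beyond the
data range extends linearly (the natural-spline behavior). The fit matches
R's `smooth.spline(df = 5)` to ~1e-5 on shared inputs (cross-checked in the
test suite). Note a df-5 smoother does *not* reproduce an exact cubic
polynomial — only the penalty null space (linear functions) is unshrunk —
and the reference implementation deviates identically.

## Misplacement scan

θ̂<sub>H</sub>(i): mean of θ̂<sub>i,j</sub> over the s markers ahead of i
(1-based i < m−s), else over the s markers behind it. θ̂<sub>L</sub>(i):
mean over the last s markers for i < m/2, else over the first s. Defaults:
s = 30 (large windows detect cross-chromosome moves but can miss
within-chromosome ones), missing pairs excluded from the mean, and at least
⌈s/2⌉ available entries required, else the statistic is undefined — the
published procedure averages over s but its matrix has blanks; this pins
the gap down. Thresholds are the genome-wide 99% quantile of θ̂<sub>H</sub>
and 1% quantile of θ̂<sub>L</sub>, with linear interpolation between order
statistics (pinned for reproducibility). Flagging is strict (>, <);
maximal runs of consecutive candidates form clusters and non-informative
SNPs strictly enclosed in a run are flagged as well — a deterministic
replacement for the visual inspection step of the original workflow.
Remapping candidates to another assembly is out of scope.

## Synthetic data

Two-locus generator: sire gamete = random haplotype with probability-θ
allele swap; dam gamete from the haplotype distribution implied by
(D<sup>dam</sup>, p₁, p₂). The batch variant draws the multinomial over the
16 gamete combinations directly — distributionally identical, and each
replicate owns a generator spawned from the root seed so any replicate is
independently reproducible.

Study defaults follow the validation design: scenarios
(θ, D<sup>dam</sup>) ∈ {(0.01, 0.05), (0.20, 0.05), (0.40, 0.15)} crossed
with maternal frequencies (0.5, 0.5), (0.4, 0.4), (0.4, 0.6), (0.8, 0.8);
N = 100 or 1,000 offspring; 10,000 replicates in study one; in study two θ
runs over 0…0.5 in steps of 0.005 with 1,000 replicates each, p₂ drawn
U[0.3, 0.7] per replicate and redrawn when (D<sup>dam</sup>, p₁, p₂) would
violate the LD bounds (the original design does not state its handling;
redrawing keeps the nominal D<sup>dam</sup>).

Multi-locus chromosomes: paternal gametes follow a Markov crossover process
over map intervals (no interference), so pairwise rates compose as
θ<sub>ij</sub> = ½(1 − Π(1−2θ<sub>k</sub>)). Dam gametes are a first-order
Markov chain with specified adjacent-pair D<sup>dam</sup>; LD between
non-adjacent loci decays as the product of adjacent correlations. This dam
model is a declared stand-in — the original misplacement validation used
empirical genotypes, and no multi-locus dam model is published for this
setting. Misplacements are planted by permuting the SNP-to-position
assignment (genotypes keep following the true order), which is exactly what
an assembly error does.

The misplacement-recovery study uses a genome of two chromosomes (500 and
300 SNPs, interval θ = 0.005, maternal frequencies U[0.3, 0.7], adjacent
maternal LD 0.03, N = 200), with one 6-SNP cluster moved from map indices
480–485 to 200 and one single SNP from 495 to 100. Two chromosomes are used
so the genome-wide 1%/99% quantile thresholds keep more tail slots than
there are planted SNPs; the moves start near a chromosome end so planted
SNPs are extreme in both window statistics, mirroring how real misplaced
clusters present. Problem sizes throughout (replicate counts in tests,
chromosome lengths) are chosen to keep the full validation suite in the
low minutes on one CPU while leaving Monte-Carlo errors well below the
effects being checked.

## What the synthetic data do and do not show

The generator emulates exactly the mechanism the estimator assumes:
known-phase double-heterozygous sires, a homogeneous dam pool, no
genotyping error, no missing-data structure, evenly spaced markers, and a
smooth recombination landscape. Passing tests therefore demonstrate
correctness of the estimator and scan *under the model*, and the planted
misplacements show sensitivity under clean signal. They do not speak to
phasing errors in the sire haplotypes, genotype-calling artifacts,
family-stratified dam pools, or recombination hot/cold spots — on real
data those raise the noise floor of both the estimates and the scan.

## Known limitations

- The pairwise estimates on a chromosome share offspring and are strongly
  dependent; the window statistics and quantile thresholds treat them as a
  descriptive scan, not a calibrated test (locus-pair asymptotic tests are
  not generally applicable here because expected cells can be zero).
- Sire phasing is an input; phase errors masquerade as θ > 0.5.
- Family-specific recombination rates are not modeled (θ is shared); the
  per-family machinery would support it, but pooling is what the empirical
  design calls for.
- Homozygous-heterozygous sire families are excluded from a pair entirely;
  using them to sharpen haplotype-frequency estimates is possible in
  principle but not implemented.
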