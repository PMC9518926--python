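# Methods

## Model

Time is measured in coalescent units of `2N₀` generations, with `N₀` an
arbitrary reference diploid size. A demographic history is the
piecewise-constant coalescent rate `λ(t) = 1/η(t)`,
`η(t) = N(2N₀t)/N₀`, parameterized by user-supplied change points and one
**log** rate per epoch (positivity by construction; log-rate space is also
where the M-step searches). `λ` is right-continuous: the epoch beginning
at a change point owns the value there, which keeps the integrated rate
and the piecewise ODE coefficients well defined. Scaled per-site rates are
`θ = 4N₀μ` and `ρ = 4N₀r`; the recombination distance between adjacent
bases is one `ρ` unit.

The CHMM hidden state at a base is the interval (out of `S`, boundaries
`t_0 = 0 < … < t_S = ∞`) containing the local genealogy's height, or its
total branch length. Emissions are derived-allele counts `d ∈ {0..n−1}`;
sites where all sampled haplotypes carry the derived allele are recorded
as `d = 0` (mutations above the local MRCA are outside the model).

### Transition probabilities (tree height)

The two-locus ancestral process over states `(k_ab, k_a, k_b, κ)` allows
coalescence among coupled and uncoupled lineages at rates proportional to
`λ(t)` and one recombination (rate `k_ab·ρ/2` while `κ = 0`). The states
`(1,0,0,0)` and `(1,0,0,1)` are absorbing; we give them no outgoing
moves, in particular no formal recombination out of `(1,0,0,0)` —
post-MRCA recombination cannot alter either marginal height. The
distribution solves `dg/dt = g·Qᵖ(t)`, integrated with an explicit
Dormand–Prince 8(5,3) Runge–Kutta scheme (rtol 1e-9, atol 1e-12),
restarted at each rate change point. The joint height CDF is

    P[T_a ≤ τ_a; T_b ≤ τ_b] = g₍₁,₀,₀,₀₎(τ) + g₍₁,₀,₀,₁₎(τ)
        + g₍₁,₀,₁,₁₎(τ)·(1 − e^{−∫_τ^{τ'} λ})          τ = min, τ' = max,

using locus exchangeability for the orientation. The CDF at the infinite
boundary is taken as the eventual-absorption limit: the chain is
time-homogeneous beyond the last change point, so absorption
probabilities are solved exactly as a linear system rather than by
integrating to an arbitrary horizon. Differencing the CDF on the boundary
grid gives the joint mass matrix (negative floating-point differencing
noise is clipped at zero; magnitudes are asserted small), whose
row-normalization is `A` and whose row sums are `Π`.

The single-mutation process `(k, k*)` works identically for emissions;
the probability that a mutation on one of `k*` lineages is carried by `d`
of `n` samples is `C(n−d−1, k*−2)/C(n−1, k*−1)`.

### Branch-length hidden state

Accumulated lengths obey transport systems
`∂_t F + ∂_x F·V_a (+ ∂_y F·V_b) = F·Q(t)` with per-state integer
velocities `v = (k_ab + k_ℓ)·1{k_ab + k_ℓ > 1}` (`v = k` for the
mutation process). Because all velocities are nonnegative integers, a
uniform grid with `dt = dx` advects every state by an exact integer cell
shift — no numerical diffusion along characteristics. The source coupling
is applied as matrix exponentials in a Strang splitting (half source,
shift, half source), second-order in `dt`; the exponentials are cached
per demographic epoch. Initializing `F(0, x) = P[state]` for all `x ≥ 0`
with zero ghost inflow makes the solution equal the plain process
distribution `g(t)` wherever `x ≥ nt` automatically, so no explicit
characteristic boundary surface is needed. The printed boundary condition
for these systems reads as holding for `x ≤ nt`; since `L(t) ≤ nt`
always, the event `{L(t) ≤ x}` is certain exactly when `x ≥ nt`, and we
treat the inequality as direction-flipped.

The joint length CDF `P[L_a ≤ x, L_b ≤ y]` is the absorbing-state mass at
any time `≥ max(x, y)/2` (a locus still short of its MRCA accumulates at
least two length units per unit time, so nothing below the thresholds
changes afterwards). We therefore read the entire CDF matrix from **one**
late solution slice, with evaluation points snapped to grid nodes; this
keeps the finite-difference errors internally consistent, and in the
`ρ → 0` limit the transition matrix collapses to the identity exactly.
The infinite-boundary column uses the one-dimensional marginal solve at
the same resolution. Default grids: 2000 cells (1-D systems), 500 cells
(2-D, i.e. 500³ space-space-time including the implied steps); both are
exposed. Accuracy is anchored by closed-form checks (`L = 2T` for pairs,
hypoexponential totals), grid-refinement convergence tests, and an
independent jump-chain Monte-Carlo oracle. The scheme is first-order at
moving CDF fronts, so successive grid halvings shrink but do not square
away the front error; the chosen defaults put it near 1e-3, an order
below the Monte-Carlo tolerances used in validation.

### Discretizations

For tree height, boundaries are log-equidistant between the 0.5% and
99.5% quantiles of the hypoexponential height law at the harmonic-mean
rate; quantile anchoring keeps every hidden state at appreciable marginal
mass for any `n` (a range anchored at the first-coalescence scale
degenerates for `n ≳ 10`). For branch length, boundaries are the `i/S`
quantiles of the hypoexponential total-length law, making `Π`
approximately uniform. Both ends are overridable.

## Inference

E-step: scaled forward–backward per composite-likelihood subset,
yielding expected initial/transition/emission counts. Sequences are
run-length encoded; homogeneous runs are advanced through powers of
`M_d = A·diag(B[:,d])` via its eigendecomposition, with within-run
expected counts accumulated exactly from spectral pair-power sums
(scale-factored to survive megabase runs) and a per-locus fallback when
the eigenbasis condition number exceeds 1e8. Sufficient statistics are
summed within each subset size (algebraically identical to summing
per-subset objective functions) and across chromosomes.

M-step: Nelder–Mead on the expected complete-data log-likelihood in
log-rate space. The initial simplex adds/subtracts a fixed 0.3 log-units
along coordinate axes for fewer than five parameters, and 5% relative
coordinate perturbations otherwise — the two-regime rule with magnitudes
chosen here, since only the rule itself is prescribed. The step never
returns a point worse than its start. Optional regularization subtracts
`c₁₂·Σ(Δ adjacent log-rates)²` (a reconstruction of the smoothness
penalty; default `c₁₂ = 0`).

The loop stops at a relative composite log-likelihood change below 1e-6
or at the iteration cap (25 for tree height, 15 for branch length, the
package defaults). Initialization is Watterson's estimator
`θ̂ = S/(a_{n−1}·L)` unless a model is supplied. Subsets are seeded
uniform shuffles chunked per size (remainders discarded); explicit,
possibly overlapping subsets can be given as a file, e.g. all 45 pairs of
10 haplotypes.

Pseudo-haploid mode uses the tree height of the underlying `2n`
haplotypes as hidden state and downsamples the `2n` emission layer with
hypergeometric weights `H(d; 2n, d', n)`; mass on the unobservable
all-derived outcome is folded back by row renormalization, consistent
with recording monomorphic sites as `d = 0`.

Two accelerations are available beyond locus-skipping: meta-locus
compression groups `w` consecutive bases into one super-site with
product emissions and a transition built at `w·ρ` (exact at `w = 1`, an
approximation otherwise — our reconstruction, guarded by the `w = 1`
equivalence contract).

## Synthetic data

`simulate_sequence` implements the sequential coalescent directly: first
genealogy from the time-varying coalescent; recombinations at rate
`ρ/2 × tree length` per base; at each event the lineage above a uniform
tree point is detached and re-coalesces at rate `λ(t)` into the remaining
branches (detach-and-recoalesce, not the full ancestral recombination
graph); infinite-sites mutations at `θ/2` per branch length unit per base
(position collisions redrawn). It reproduces Watterson's expected
segregating-site count, pairwise diversity, and the height/length moments
(verified in the tests), and writes VCF with the ancestral allele in the
`AA` tag. What it does **not** emulate: back-coalescence memory beyond
the Markov assumption (SMC', full ARG), gene conversion, recombination
hotspots, sequencing error or missing data — so passing recovery tests
demonstrate correctness of the inference machinery under its own
generative assumptions, not robustness to real-data artifacts.

`sample_from_chmm` draws observation sequences directly from given HMM
matrices, giving mismatch-free EM recovery tests.

Accuracy metrics: `Δ(k)`, the mean absolute log-ratio of estimated to
true size at generation `k` across replicates, and `φ = ∫ Δ d log k`
over the inference discretization extended one log-step on each side.

## Study scales and defaults

The recovery studies in the test suite run at desk scale as the package's
own validation design: a 1 Mbp model-exact recovery at `θ = 5e-3`
(≈5,000 segregating sites, enough information for a 5% check), and a
20 Mbp, 10-haplotype bottleneck (ancestral 10,000 dropping to 2,000 at
4,000 generations, human-like `μ = r = 1.25e-8`) refit with the 2,5,10
composite scheme. The pseudo-haploid study draws 10 pseudo-haploids from
20 simulated haplotypes at the same scale. Default `S = 16` hidden
states.

## Known limitations

* At most one recombination between neighbouring bases and one mutation
  per site; violations grow with subset size and diversity, biasing
  toward shorter trees.
* The branch-length state is substantially slower (2-D PDE per M-step
  evaluation) and, consistent with its information content, less accurate
  than the height state; it is provided for completeness.
* Folded (minor-allele) emissions and genotype likelihoods are not
  supported; polarization requires an `AA` tag or a reference-ancestral
  assumption.
* Piecewise-constant `λ` only; no splines, no time-varying `μ` or `r`.
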