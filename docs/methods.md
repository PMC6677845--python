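# Methods

## Model chain and scope

The package works with the standard hierarchy of well-mixed kinetics
models: the continuous-time Markov chain over copy numbers (simulated
approximately by fixed-step τ-leaping), its diffusion approximation, the
chemical Langevin equation (CLE, simulated by Euler–Maruyama), and — as a
degenerate limit used only in tests — the deterministic reaction-rate
ODEs, which the CLE step reduces to when every normal variate is zero.
Exact SSA/next-reaction simulation, implicit or adaptive-τ leaping, and
master-equation solvers are deliberately out of scope: the object of study
is the decay of *statistical* error with the number of sample paths, for a
fixed discretisation. Discretisation bias is therefore neither measured
nor corrected; the reported RMSE is the square root of the unbiased
between-randomisation variance estimate of the pooled mean, which is the
honest error measure precisely because each estimator arm is unbiased for
its own method-specific target.

## Propensities

Mass action is implemented combinatorially: a_k(X) = c_k ∏_i C(X_i, α_ik),
the number of distinct reactant combinations times the rate constant. The
concentration-style monomial c_k ∏ X_i^α is *not* used; for the Schlögl
triple collision the two differ by the factor (X−1)(X−2)/X² which matters
at hundreds of molecules. On the real-valued CLE states the binomial
coefficient is extended polynomially, x(x−1)…(x−α+1)/α!; the alternative
(plain x^α/α! monomials) changes nothing qualitative at the copy numbers
simulated here but is not what the discrete simulator linearises to, so
the extended form is used for consistency between the two simulators.

Frozen species (the Schlögl reservoirs S2, S3) enter propensities at their
fixed copy number and are pinned after every update. They are carried in
the state vector rather than folded into rate constants so that networks
read the same way they are written.

## Coupling paths to the unit hypercube

Every sample path consumes exactly one uniform per (time step, reaction
channel) pair, flat index j·K + k, so the earliest — best equidistributed —
Sobol' coordinates drive the earliest steps. Poisson and normal increments
are produced by inverse transform (`scipy`'s Poisson percent-point
function, which inverts the regularised incomplete gamma, and `ndtri`).
This makes each simulator a pure function from [0,1)^{K⌈T/τ⌉} to paths:
identical streams give bit-identical trajectories, which is what lets a
digital net stratify path space. A stream of the wrong length is a hard
error; silent truncation would desynchronise the coordinate–step mapping.

Uniform inputs are half-open, u < 1 (clamped at the largest double below
one); the CLE additionally clamps u away from 0 before the normal
quantile. u = 0 maps to zero Poisson events.

## Point sets

Pseudo-random streams come from numpy's PCG64; RQMC streams are Sobol'
nets randomised by a linear matrix scramble plus digital shift
(`scipy.stats.qmc.Sobol`, Matoušek-style), which preserves the base-2
net structure while making every point marginally uniform. Point counts
are powers of two in all experiment harnesses (the balance properties of
digital nets hold only there); other counts work but warn. An
s-dimensional set is always generated by a single engine of dimension s —
gluing independent one-dimensional nets does not produce a net, and a
regression test pins this.

Seeds: a meta-seed is expanded through `numpy.random.SeedSequence` spawning
into one child per randomisation (and per grid size in studies), so
"independent randomisations" is meant in the PRNG-stream sense and every
result is reproducible from one integer.

## Estimators and rate fitting

RQMC uses M independently randomised N-point sets; MC uses one
pseudo-random stream of M·N paths cut into M batches, so both arms consume
MN paths and are summarised by the same formulas. Default M = 32 for
reaction networks and M = 128 for the quadrature toys. M buys only
O(M^(−1/2)) and mainly stabilises the variance estimate; N is where the
low-discrepancy structure acts.

Rate exponents ν are fitted by unweighted least squares of log₂ RMSE on
log₂ N. For "limiting rate" claims the fit is restricted to the upper half
of the size grid; local (3-point sliding window) slopes drive the
regime-transition detector, which reports the first N at whose window the
local exponent drops below 0.75 (halfway between the fast ≈1 and slow
≈1/2 regimes). At M = 16 this detector is noticeably noisy; M = 32 makes
the ε-orderings stable across seeds, which is why the transition
experiments use full M even where a coarser answer would do.

Degenerate RMSE values (exact cancellation, see below) are clipped to the
double-precision rounding floor of the study's largest RMSE before
fitting, purely to keep the log–log fit finite.

## Experiment grids

Reaction-network studies use N = 2⁴ … 2¹² and the quadrature toys
N = 2⁴ … 2¹⁴ — grids chosen so that every documented regime (fast start,
transition, limiting rate) is visible at desk scale; the rates quoted are
stable when the grids are extended. The Schlögl exponent is reported as
the median over three meta-seeds of a full-grid fit (measured ≈ 0.55,
i.e. barely above the MC rate on this 40-dimensional problem, for the
discrete and the continuous simulator alike).

## Negative copy numbers

τ-leaping can overshoot into negative populations. Default policy:
propensities already obey the zero-combinations rule (a_k = 0 when any
reactant is short, including for stray negative values), and any negative
post-update copy number is clamped to zero. This is a deliberately simple
guard standing in for the more elaborate guarded-leap schemes in the
literature; for the systems shipped here it engages only in the Schlögl
runs near the lower stable state and has no visible effect on the fitted
rates. A strict `error` policy is available. CLE states may go negative;
only the argument of the square root is clamped (drift uses the raw
propensity), which is standard Euler–Maruyama practice for the CLE.

## Quadrature testbed

The additive family √(12/s) Σ(x_i−½) and product family √(12^s) ∏(x_i−½)
integrate to 0 with variance 1 in every dimension. Two staircase
transforms inject discreteness: flooring the *input* to multiples of ε
creates axis-aligned discontinuities (mild for digital nets, limiting
rate ≈ N^(−1)); flooring the *output* creates oblique ones (worst case,
limiting rate ≈ N^(−1/2)). Floors are mathematical floors, so negative
values quantise downward; with ε ≥ 2·sup|f| the output floor consequently
yields a two-level function taking values 0 and −ε, not the zero function.
Writing f_ε = F + G with F = f and G = f_ε − f (|G| ≤ ε for the output
floor) decomposes the estimator MSE into a fast continuous term and a slow
term of size O(ε²/N); the crossover at N = O(1/ε) is exactly the observed
switch point, and halving ε quarters the large-N discontinuous MSE.

Two numerical facts shape the defaults here:

- **Dyadic ε is degenerate.** A staircase width 2^(−k) aligns the
  discontinuities with the base-2 net, which then integrates the
  staircase essentially exactly and hides the transition entirely.
  Experiments use non-dyadic widths (0.07 by default; 0.5 for the coarser
  product/output-floor demonstration, whose transition otherwise lies
  beyond desk-scale N).
- **The additive family is super-convergent under this scramble.** Each
  one-dimensional projection of a scrambled-and-shifted net is a
  (0,m,1)-net, so the linear parts cancel to the in-bin deviation: the
  sample mean over a full 2^m set is bounded deterministically by
  √(12s)·2^(−m−1), and the RMSE hits a rounding floor (~1e−8) by
  N ≈ 2¹¹. Fitted rates for the additive family are therefore quoted on
  N ≤ 2¹⁰, where the ≈ N^(−3/2) scrambled-net rate is visible; at very
  small s the cancellation is stronger still and the fitted exponent
  exceeds 3/2. The product family shows the plain ≈ N^(−3/2) limiting
  rate without any of these caveats.

Moment oracles: the untransformed families are validated against a
tensor-product Gauss–Legendre grid (exact for these polynomials; a
composite-midpoint grid of comparable size is *not* accurate to 1e−6 for
the product family and is kept only for the discontinuous transforms).

## What the built-in systems do and do not show

The three networks are chosen so every claim has an analytic anchor:
birth–death has closed-form mean and variance (E[X] = X(0),
V[X] = 2ctX(0), exactly inherited by both discretisations), isomerisation
has an exact conservation law forcing RMSE(X₁) = RMSE(X₂) bit-for-bit
when both observables share point sets, and Schlögl stresses
nonlinearity, bistability and higher dimension. None of them exercises
stiffness, many-species networks, or observables of full trajectories
(only end-time functionals are estimated); conclusions about those lie
outside what the test suite demonstrates.

## Defaults

| parameter | default | meaning |
|---|---|---|
| τ | 0.2 (Schlögl: 0.4) | leap step; fixed, no adaptivity |
| T | 1.6 (Schlögl: 4.0) | time horizon; ⌈T/τ⌉ steps, last step truncated if needed |
| M | 32 networks / 128 quadrature | randomisations pooled per estimate |
| N grid | 2⁴…2¹² / 2⁴…2¹⁴ | paths (points) per randomisation |
| ε (quad) | 0.07 | staircase width, non-dyadic |
| negative policy | clamp | zero-combination propensities + clamp to 0 |

Birth–death scale ε sets X(0) = 1/ε (default 10⁻³ → 10³ molecules); the
rate-rescaled variant c = c₀ε (c₀ = 10) keeps per-step event counts O(c₀τ)
while the copy number grows, separating copy-number effects from
propensity-magnitude effects in the transition experiments.
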