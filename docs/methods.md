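# Methods

## The model

`cleftflux` solves an idealised reaction–diffusion model of synaptic
transmission.  The synaptic cleft (or the dyadic cleft of a cardiac
myocyte) is the space between two parallel membranes a distance
L<sub>z</sub> apart.  The geometry is laterally periodic with periods
L<sub>x</sub>, L<sub>y</sub>; each unit cell carries

* a circular **release opening** of radius R, centred on the pre-synaptic
  face z = 0, through which ligand (acetylcholine, Ca²⁺) enters with a
  prescribed transient flux density u(t);
* a circular **absorbing sink** of radius a, centred on the post-synaptic
  face z = L<sub>z</sub>, representing the receptor patch.

The concentration C(r, t) obeys the diffusion equation ∂C/∂t = D∇²C with
C(r, 0) = 0, Neumann conditions D∂C/∂z = u(t) on the source disk (zero
elsewhere at z = 0), C = 0 on the sink disk and zero flux elsewhere at
z = L<sub>z</sub>.  The quantity of interest is the **response function**
J(t): the total flux absorbed by the sink of one unit cell.

The release model is u(t) = e^(−t/t₀) (amplitude in arbitrary units, which
J inherits); any other release model can be supplied as its Laplace
transform evaluated at real s > 0.

## Analytic solution

Working in Laplace space, the transform Ĉ(r, s) is expanded in the even
periodic basis cos(2lπx/L<sub>x</sub>)cos(2mπy/L<sub>y</sub>) with
z-profiles e^(±γz), γ_lm(s) = √(s/D + (2lπ/L<sub>x</sub>)² +
(2mπ/L<sub>y</sub>)²).  The disk boundary conditions enter through the
cosine-transform coefficients q_lm, p_lm of the two disk indicator
functions (with weights ε₀ = ½, ε_l = 1 otherwise).

The mixed condition on the sink (absorbing on the disk, reflecting
outside) is not separable; it is handled with the **constant-flux
closure**: the sink flux density is taken uniform over the disk with an
unknown Laplace amplitude Q(s), fixed by requiring the disk-averaged
concentration on the sink to vanish.  This yields the closed form

    Q(s) = û(s) · Σ q_lm p_lm/(ε_l ε_m γ_lm sinh γ_lm L_z)
                ───────────────────────────────────────────
                 Σ p_lm² coth(γ_lm L_z)/(ε_l ε_m γ_lm)

and Ĵ(s) = πa²Q(s); J(t) follows by Gaver–Stehfest inversion.  Ligand
conservation is exact in the closure: Ĵ(0) = πR²û(0) = πR²t₀,
independent of a.  A useful two-parameter identity links diffusivity and
release time: J₁(D₂t) = J₂(D₁t) whenever D₁t₀₁ = D₂t₀₂ (the PDE
depends on D and t₀ only through Dt and Dt₀).

## Parameters and defaults

| parameter | meaning | default | unit |
|---|---|---|---|
| L<sub>x</sub>, L<sub>y</sub> | lateral periodicity | 500 | nm |
| L<sub>z</sub> | cleft depth | 50 | nm |
| R | release-disk radius | 20 | nm |
| a | sink-disk radius | 10 (studied 2.5–40) | nm |
| D | ligand diffusivity | 1×10⁵ (studied 0.4–4×10⁵) | nm²/ms |
| t₀ | release decay time | 1 (studied 1–10) | ms |
| lmax | series truncation | 40 | – |
| quad_order | coefficient quadrature | 64 | – |
| stehfest_N | inversion terms | 14 | – |

Units are fixed to nm/ms throughout; the CLI rejects other unit
declarations rather than converting.  The geometric and transport defaults
are the standard neuromuscular-junction values used by the figures this
package reproduces; a = 10 nm, t₀ = 1 ms, D = 10⁵ nm²/ms is the anchor
curve.

## Numerical choices

**Disk coefficients.**  The y-integration over the disk is analytic; the
remaining x-integral is evaluated by Gauss–Legendre quadrature *after the
substitution x = r sin θ*.  Without the substitution the integrand has a
√(r−x) branch point at the disk rim and Gauss–Legendre converges only
algebraically; with it the integrand is entire and 64 points reach the
~1e−12 floor.  An independent Bessel closed form,
c_lm = 8π ε_l ε_m r J₁(k_lm r)/(L<sub>x</sub>L<sub>y</sub>k_lm), derived
from the plane-wave-over-disk integral, serves as the oracle; the two
routes agree to better than 1e−10 relative over the full 41×41 mode grid.

**Hyperbolic stability.**  All sinh/cosh ratios are evaluated through
decaying exponentials (1/sinh x = 2e^(−x)/(1−e^(−2x)), with `expm1` at the
small-x end), so γL<sub>z</sub> up to 1e4 evaluates without overflow and
the s → 0 limit is reached without cancellation.  Mode coefficients are
stored as the scaled products α_lm e^(γL_z) (and plain β_lm), which stay
finite for all γ.

**Series truncation.**  Because the sink indicator is discontinuous, the
closure series converges algebraically, ~1/lmax²: the flux changes by
~0.7% at s = 1 (up to ~1% at s = 100) when lmax goes 40 → 80, and
consecutive doublings shrink the change ~4×.  lmax = 40 is the default
working order; raise it for tighter tails.  The *conservation* limit is
exact at any truncation (it reduces to q₀₀/p₀₀).

**Stehfest inversion.**  N = 14 terms, weights computed once in exact
rational arithmetic and cached.  The method is exact for F = 1/s and
carries a small truncation error for other smooth transforms (≈4e−7 for
1/s², growing with the power).  On decaying exponentials the *relative*
error grows with t/t₀ (≈3e−6 at t = t₀, percent level at 5t₀): reliable
absolute accuracy everywhere, reliable relative accuracy down to roughly
1e−4 of the peak.  The conservation integral is insensitive to this
because the tail mass is itself exponentially small.  J(0) is reported as
0 by convention (the inversion needs t > 0; the initial condition gives
J(0⁺) → 0).

**Conservation integral.**  ∫J dt is computed on a log-spaced grid (40
points/decade from 1 ms×10⁻³) extended decade by decade until J falls
below 1e−6 of its peak, plus a leading triangle at t → 0 and an
exponential-tail extrapolation J_end·τ from the terminal decay rate.
Across the full study grid (a ∈ {2.5…40} nm, t₀ ∈ {1,3,10} ms,
D ∈ {0.4,1,4}×10⁵ nm²/ms) the integral matches πR²t₀ to ≲0.1%.

## Finite-difference cross-check

An independent explicit (FTCS) solver discretises the *original* model —
pointwise C = 0 on the sink disk, not the closure.  Design:

* quarter-cell domain with reflecting walls (exact for centred disks under
  periodicity), cell-centred grid, ghost-mirror Neumann boundaries;
* source influx over the cells inside ρ < R, rescaled so the discrete
  injected total matches πR²∫u dt exactly; injected = absorbed + remaining
  then balances to round-off at every step;
* the sink enters as an outflux DC/(dz/2) per unit area through the top
  face, weighted by the **exact** circle–rectangle overlap fraction of
  each face, which keeps the discrete absorbing area at exactly πa² and
  makes refinement monotone (a binary centre-in-disk staircase wobbles the
  effective sink area by ±20% between the grids used here);
* explicit Euler stepping at 90% of the stability bound
  D·dt·(1/dx²+1/dy²+1/dz²) ≤ ½; the kernel is JIT-compiled, so the
  128×128×32 production grid (1.5 ms, ≈180k steps) runs in about half a
  minute on one core.

The solver was validated against an exactly solvable variant — the whole
post-synaptic face absorbing, for which only the laterally uniform mode
carries net flux and Ĵ = πR²û(s)/cosh(γ₀₀L<sub>z</sub>) — agreeing to
6e−5 of the peak on the production grid.

## Accuracy of the constant-flux closure (known limitation)

Because the finite-difference solver treats the sink exactly while the
analytic solution closes it approximately, their difference *measures the
closure error*.  At the anchor parameters the converged FD peak flux is
≈267 versus ≈249.8 for the analytic curve (lmax = 40), a ≈7% offset —
consistent with the classic result that the constant-flux approximation
underestimates the diffusion-limited capture rate of a disk by
3π²/32 − 1 ≈ −7.5%.  The closure solution is smooth, conservative and
qualitatively faithful (peak orderings, scaling identity, conservation all
hold), but its peak amplitude carries this systematic percent-level
deficit, and grid refinement drives the FD curve toward the exact
solution, not toward the closure.  Users benchmarking numerical codes
against the analytic curve should expect agreement at the closure's
accuracy, not at machine precision.

## What the built-in checks do and do not show

The validation suite exercises the solver at the idealised study
conditions: centred disks, exponential release, perfectly absorbing sink,
no buffering or hydrolysis, no secondary folds, no reversible or
multi-site binding.  Passing checks demonstrate internal consistency
(conservation, closure residual, oracle agreement, FD cross-validation at
the closure's accuracy) — not that the idealised model reproduces any
particular experimental synapse.  The receptor-rate calculators
(k = [1/(4Da) + 1/(πκa²)]⁻¹, a ≈ N_rec·a₀, and the effective face
reactivity K) are parameterisation aids for mapping receptor counts and
reactivities onto (a, κ); they do not feed back into the series solution,
and the linear equivalent-disk rule is valid only for small receptor
numbers (the saturating regime has no closed form here).
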