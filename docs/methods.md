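# Methods

## Model and assumptions

The package models a single gene whose product activates its own
transcription non-cooperatively and binds reversibly to `y` identical decoy
DNA sites.  Four assumptions define the reduction:

1. **Bursty synthesis.**  Proteins are made in instantaneous bursts whose
   sizes are exponentially distributed with mean `b` molecules (the
   continuous limit of the geometric burst-size law that arises when an
   active promoter state is short-lived).  Burst timing is a state-dependent
   Poisson process with hazard a(x) = a0 + a1·xf/(kp + xf).
2. **Quasi-steady-state binding.**  Binding/unbinding to decoys
   equilibrates much faster than protein turnover, so bound protein is the
   deterministic function xb = y·xf/(xf + kb) of free protein and the model
   tracks one variable (total protein x = xf + xb).
3. **Deterministic decay.**  Degradation and binding involve one molecule
   at a time and are treated as a deterministic drift,
   c(x) = xf + γb·(x − xf), between bursts.
4. **Scale separation at the promoter.**  Sequestration by the gene's own
   promoter (1–2 copies) is negligible next to the decoy pool; only decoys
   titrate the protein.

Time is measured in free-protein lifetimes, so γf = 1 is hard-wired and
γb is the single decay-ratio knob; concentrations are in molecules per
cell.

## Parameters

| parameter | meaning | unit | typical / example |
|---|---|---|---|
| a0 | basal burst frequency | bursts per lifetime | 0.75 |
| a1 | regulable burst-frequency increment | bursts per lifetime | 25 |
| kp | promoter dissociation constant | molecules | 500 |
| b  | mean burst size | molecules | 50 |
| y  | decoy site count | molecules | 0–500 |
| kb | decoy dissociation constant | molecules | 1 |
| γb | bound/free decay ratio | – | 1 (equal decay) or 0 (protected) |

The example column is the published worked-example circuit: tight decoy
binding (kb ≪ kp), a basal rate low enough that decoys sequester most basal
product, and a regulable rate high enough to establish the feedback loop.

## Stationary density

The stationary density solves d/dx[c·p] + c·p/b = a·p, i.e.
p(x) = κ/c(x)·exp(−x/b + ∫a/c dx).  Two evaluation paths are provided and
cross-validated:

- **Closed form.**  In the free-protein coordinate the integrand a/c·dx/dxf
  is rational with simple poles at xf = 0, −kp, −kb, −kb−γb·y, so the
  integral is a sum of logarithms and the density a product of powers.  The
  four exponents q1–q4 are the partial-fraction residues; they were derived
  symbolically (sympy) and validated against the quadrature path to ~1e−11
  relative over randomized parameter sets before being frozen into the
  code.  The closed form is rejected (flagged invalid) when poles coincide:
  kp = kb, kp = kb + γb·y, or γb·y = 0, detected at relative tolerance
  1e−9.
- **Quadrature.**  ∫a/c dx is integrated adaptively in the free-protein
  coordinate (smooth integrand; the x→0 singularity sits outside the
  integration range), reference point at total protein 1, the resulting
  constant absorbed into κ.  This path serves every parameter set,
  including the degenerate ones and the protected-decay limit γb = 0, for
  which no closed form is attempted.

**Normalization.**  Densities are tabulated on a log-spaced grid from
x_lo = 1e−4 to x_max = max(20·b·(a0+a1), 10·(y+kb)) and normalized by a
trapezoid rule plus an analytic power-law panel over (0, x_lo] with
exponent q1 − 1 = a0·(kb+y)/(kb+γb·y) − 1 (this origin exponent is valid
for all parameter sets, degenerate cases included).  The default grid has
16384 points, at which resolution the normalization and every
change-of-variable mass check hold to a few parts in 1e7 (budget 1e−6);
evaluation is vectorized, so the dense grid costs ~25 ms.  Log-overflow is
avoided by working in log density and rescaling before exponentiation.
The grid value of κ is reported as metadata.  a0 = 0 is rejected: all
stationary mass then sits at zero protein and no density exists.

**Transforms.**  The free-protein density multiplies by the binding
Jacobian 1 + y·kb/(xf+kb)²; log10 densities by x·ln 10.  Grid integrals of
log-scale densities include the analytic left-tail mass below the first
grid point (the tail is a pure power of 10^z), so mass conservation checks
are meaningful even for heavy left tails at small a0.

## Modality classification

For γb = 1 (c = x) the extremum condition of p(x) in the free-protein
variable is a0 + a1·xf/(kp+xf) − xf/b − y·xf/(b(xf+kb)) − 1 = 0; for the
log10-scale density the same expression without the −1.  Both share the
tangency condition a1·kp/(kp+xf)² − 1/b − y·kb/(b(xf+kb)²) = 0.  Roots are
located by a sign scan on a log-spaced xf grid (1e−4…1e6, 2000 points)
plus Brent bisection to 1e−10 relative; the functions are smooth with few
roots, so brute force is robust.  Root kinds alternate, the first fixed by
the sign of the extremum function at xf → 0+.  Double roots (tangency
value below 1e−8 in magnitude at the root) are inflections and not counted
as extremum pairs.

**Mode-counting convention.**  On the linear scale the density diverges at
x = 0 iff the origin exponent is negative (q1 < 1); that singular basal
peak counts as a mode, matching the figure-level classification of the
phase plane.  At q1 exactly 1 the origin limit is finite and is not
counted.  On the log10 scale only interior maxima count (the log-density
always vanishes at z → −∞ for a0 > 0).  Whether a singular origin counts
as a mode is a convention, not a theorem; this choice makes the bimodal
region bounded on the right by a0 = 1 in the no-decoy cross-section, which
is how the phase diagrams are drawn.

**Boundary curves.**  For each xf on a sweep, the tangency condition is a
quadratic in kp, R·kp² + (2R·xf − a1)·kp + R·xf² = 0 with
R = (1/b)(1 + y·kb/(xf+kb)²); the extremum condition then gives a0
explicitly.  Points with a0 ≤ 0 are dropped.  A design point discovered in
implementation: the two figure-level branches enclosing the bimodal region
are *not* the two quadratic roots — in the published cross-sections the
smaller-kp quadratic root yields a0 ≤ 0 throughout — but the rising and
falling legs (in kp) of the arc traced by a single quadratic root as xf
varies.  `boundary_curve` therefore splits each root's arc at turning
points of kp(xf) and names the resulting monotone legs; the decomposition
is identical on both scales since the tangency condition is shared.
Because the two extremum functions differ by the constant 1, the log-scale
boundary is the linear-scale boundary translated by exactly 1 leftward in
a0 — verified to machine precision rather than assumed.

For γb ≠ 1 the analytic conditions do not apply and modes are counted
directly on the normalized density grid (neighbor comparison with a
relative prominence floor of 1e−12, plus the origin-exponent rule for the
singular peak).

## Deterministic reduction

dx/dt = b·a(x) − c(x).  Steady states solve
b·a0 + b·a1·xf/(kp+xf) = xf + γb·y·xf/(xf+kb), found with the same
scan+bisection scheme as the modality roots so the root sets are directly
comparable.  Stability is read from the sign of the rhs at x·(1 ± 1e−4)
around each root — this avoids differentiating the composite c(x).  For
γb = 1 the balance is b times the log-scale extremum condition, so
bistability ⇔ log-scale bimodality; the package checks the equivalence on
randomized parameter sweeps instead of assuming it.  With y = 0 or γb = 0
the balance is monotone past a single crossing and exactly one steady
state exists.

## Stochastic simulator

The jump-drift process is simulated exactly:

- **Burst times by thinning.**  a(x) ≤ a0 + a1 everywhere, so candidate
  events arrive as a homogeneous Poisson process of rate a0 + a1 and are
  accepted with probability a(x)/(a0+a1) at the candidate-time state.  The
  bound is tight because a is saturating, so acceptance fractions are
  high (≈60–100% in the worked examples).
- **Inter-burst flow.**  c(x) = x exactly when γb = 1 or y = 0, giving the
  closed form x·e^(−t).  Otherwise the flow is integrated in the
  free-protein coordinate, dxf/dt = −c/(dx/dxf), with an adaptive
  Runge–Kutta scheme at relative tolerance 1e−8 (the xf equation is smooth
  and avoids re-inverting the binding relation each step).
- **Reproducibility.**  One seeded PCG64 generator; draw order per
  candidate is (gap, acceptance uniform[, burst size]), so trajectories
  are bit-identical for a given seed.

Stationary samples are the state at uniformly spaced times after a burn-in
of 20 lifetimes from x0 = 0 (relaxation takes a few lifetimes); the default
spacing of 1 lifetime keeps autocorrelation modest.  Agreement with the
analytic law is quantified by the Kolmogorov–Smirnov distance to the
numerically integrated analytic CDF.  With 1e5 samples spanning 1e5
lifetimes the worked-example circuits reach KS ≈ 0.005–0.016; the test
suite's thresholds (0.01 for the gamma limit, 0.02 for the feedback
circuits) include headroom for the residual autocorrelation of 1-lifetime
spacing.

## What the built-in examples do and do not show

All quantitative checks run on the published parameter sets and randomized
draws from plausible ranges (a0 ≤ 4, a1 ≤ 50, kp ≤ 1500, b 10–100,
y ≤ 500, kb 0.1–10, γb 0.2–2); they validate the mathematics of the
reduced model, not its biological fidelity.  In particular the tests say
nothing about circuits where quasi-steady-state binding or the
exponential-burst approximation fails (slow binding, small burst sizes,
explicit mRNA dynamics, promoter-state memory), nor about cooperative
autoregulation.

## Numerical choices and limitations

- Degenerate closed-form cases are served only by quadrature; no special
  closed forms are attempted for them.
- The no-decoy limit is reachable either exactly (y = 0, quadrature) or as
  y → 0 in the closed form; both agree with the gamma law
  Gamma(shape a0, scale b) when a1 = 0.
- Analytic boundary curves exist only for γb = 1; for other γb the phase
  diagram falls back to per-cell density-grid mode counting, which is
  ~100× slower per cell (tens of ms) and limited by grid resolution near
  tangencies.
- The time-dependent distribution is out of scope; dynamics are available
  only through the simulator.
- Moment equations of the model are not closed in the mean and are not
  implemented as an inference surface.
- The CLI's `s1fig` preset perturbs (a1, b) around the decoy cross-section:
  b ∈ {25, 50, 100} at a1 = 25; a1 ∈ {12.5, 25, 50} at b = 50; and
  (a1, b) ∈ {(50, 25), (25, 50), (12.5, 100)} holding the maximal regulable
  production a1·b fixed — a representative grid chosen by the package.
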