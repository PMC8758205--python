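# Methods

`adsorbsim` models the irreversible, diffusion-limited adsorption of dilute
solute molecules at a plane interface, and the systematic gap between what a
discrete-time single-molecule simulation (or a camera with a finite frame
time) counts and what the continuum theory predicts. This note records the
models, the numerical choices, and what the synthetic experiments do and do
not demonstrate.

## Physical model

Molecules are independent point Brownian particles with constant diffusion
coefficient `D` (no interactions, no drift, no desorption anywhere in the
package). The continuum description is the 1D diffusion equation
`dC/dt = D d2C/dx2`; a perfectly absorbing plane exposed at `t = 0` to an
initially uniform solution of number density `c_b` captures

    Gamma(t) = 2 A c_b sqrt(D t / pi)          (continuum sink law)

molecules on area `A`, with subsurface profile `c(x,t) = c_b erf(x /
sqrt(4 D t))`. When the subsurface concentration history `c(tau)` is known,
the back-diffusion convolution (Ward–Tordai form) subtracts
`A sqrt(D/pi) * int_0^t c(tau)/sqrt(t - tau) dtau`.

A *discrete* observer with window `dt` that asks only where each molecule's
Gaussian endpoint lands counts half of that:

    Gamma_1step(dt) = A c_b sqrt(D dt / pi)    (single-PDF count)

The missing factor 2 is the mirror effect: a step whose path touched the
wall but whose endpoint lies back in solution is invisible to endpoint
detection. Resolving each window into many sub-steps (or multiplying by 2)
restores the continuum value. The collision *rate* seen at resolution `dt`
is therefore `2 A c_b sqrt(D/(pi dt))` — resolution-dependent, diverging as
`dt -> 0` because the same molecule is re-counted.

The characteristic time `dtc = pi / (4 D c_b^(2/3))` is the window at which
a molecule's mean one-sided excursion `sqrt(4 D dtc / pi)` equals the mean
inter-molecule spacing `d0 = c_b^(-1/3)`: departing molecules are exactly
replaced by neighbours, so the subsurface density is self-maintained and
the collision rate evaluated there,

    r0 = (4/pi) A c_b^(4/3) D,

is a resolution-free *initial* adsorption rate, 4/3-order in concentration.
Evaluated for a 10-um-diameter disk at 25 pM and `D = 1e-12 m^2/s` it gives
0.37 1/s. The per-site specializations are `k2 = (4/pi) a c_b^(4/3) D`
(ideal stirring maintains `c_b` at the surface forever) and
`k3 = 2 a c_b sqrt(D/(pi dt))` (discrete observation at step `dt`,
first-order in `c_b`).

## Numerical choices

**Constants.** Boltzmann and Avogadro constants are fixed at their exact
CODATA values and are not configurable. All public quantities are SI;
concentration unit conversion happens only at the boundary
(`convert_concentration`).

**Ward–Tordai quadrature.** The kernel `1/sqrt(t - tau)` is singular at
`tau = t`; the substitution `u = sqrt(t - tau)` turns the integral into
`int_0^sqrt(t) 2 c(t - u^2) du`, which is smooth and is evaluated by
composite Simpson with 512 panels by default (configurable). Constant and
linear histories are reproduced to better than 1e-6 relative.

**Crank–Nicolson oracle.** Cell-centered finite volume on a uniform grid,
CN time stepping. A reflective wall is a zero-flux face; an absorbing wall
is a Dirichlet zero at the wall *face* (half-spacing conductance
`2 D / dx`), and the captured mass is accumulated by the trapezoid rule in
time. With this discretization, captured-plus-remaining mass equals the
initial mass as an exact discrete identity (verified to 1e-10 and better),
not merely to truncation order. CN is not L-stable, so a non-smooth initial
profile rings; `startup_steps=2` replaces the first steps by pairs of
backward-Euler half-steps (Rannacher smoothing), which damps those modes
while keeping second-order convergence (verified by the grid-refinement
test: error falls ~4x when dx and dt are halved). Grid parameters for the
oracle tests (nx = 2048–4096, dt chosen so the pulse spreads over >> 10
cells) come from that convergence study.

**Hit detection is by step endpoint, on purpose.** Neither walker uses
Brownian-bridge first-passage corrections. The endpoint count *is* the
discrete model whose mismatch with the continuum law is the subject: with
one step per frame the wall count sits at the single-PDF level, and binning
1000 sub-steps per frame recovers the continuum level to within a residual
`O(sqrt(dt_sub/dt))` bias (~2% at 1000 sub-steps, inside the 5% tolerance
used). Distinct-molecule counting per frame (each molecule at most once per
counter per frame) follows the same convention as the event logs it is
compared against.

**Statistics of counter tests.** Within one run, per-frame counts are
strongly serially correlated: the molecule density within a step-length of
a wall or plane relaxes only on the box-diffusion time `L^2/D` (hundreds of
frames at the test conditions), so the naive per-frame standard error is
far too small. All stochastic counter tests therefore use independent seeds
as the replication unit and quote the standard error across seed means.

## SAM experiment

A 1D column of height `L` over a floor carrying `n_sites = A/a` binding
sites. Each step, every molecule whose endpoint crosses the floor draws one
uniformly random site: empty -> irreversible capture, occupied -> specular
reflection back into solution. Uniform random site choice implements the
mean-field rejection probability = coverage; the 1D bulk has no lateral
coordinate, so no site geometry is modelled. The reservoir `A L c_b` must
exceed 5x the site count so bulk depletion does not distort the curve.

Canonical condition (`SAM_DEFAULTS`): `c_b` = 1 mM, `D = 5e-10 m^2/s`
(small molecule in water), `a = 0.25 nm^2`, `A = 1e-15 m^2` (4000 sites),
`L = 0.1 mm`, `dt = 1e-5 s`, `t_end = 0.15 s`. Saturation takes ~0.07 s.
The step was chosen by a resolution requirement, not by runtime: a discrete
absorbing simulation approaches the continuum sink law with a start-up bias
of order `beta sqrt(pi dt / 2 t)` (`beta ~ 0.58`, the usual discrete-barrier
offset), so the step must make that bias small compared with the 10%
deviation threshold over the coverage range of interest. At `dt = 1e-5`
(~1.5e4 steps to saturation) the bias is below 5% beyond 20% coverage; a
10x coarser step leaves the trace hovering at the threshold through
mid-coverage, where the discretization artifact is indistinguishable from
the site-blocking signal being measured.

The headline statistic compares the simulated trace with the continuum sink
law computed from the same `(A, c_b, D)`. Because the early frames always
carry the start-up bias, "first sustained deviation" is defined backward:
the onset is the first frame of the final contiguous block (>= 5 frames,
extending to the end of the trace) with relative deviation
`|Gamma_sim - Gamma_sink| / Gamma_sim > 10%`. Under the canonical condition
the onset falls at ~97% of saturation: site blocking (which suppresses
capture) and the slowing of the gradient by rejected molecules (which
enhances the subsurface supply) cancel over nearly the whole filling. The
fitted `k1` (saturating exponential, amplitude fixed at `n_sites`) is ~2.4
orders of magnitude below the ideal-stirring `k2` here; the size of that
gap is strongly condition-dependent (it grows with the developed gradient),
so only its sign and order of magnitude are asserted.

## Biosensor experiment

Probes diffuse in a reflective cube (default side 2 um) whose floor carries
one circular spot of radius 10 nm with 150 sites of ~2 nm^2. Per step each
free molecule takes an independent Gaussian displacement per axis
(`sigma = sqrt(2 D dt)` each); wall crossings reflect, except a floor
crossing whose lateral endpoint lies inside the spot, which draws one
random site (empty -> capture, occupied -> reflect). The occupancy trace is
fitted with `150 (1 - exp(-k1 t))`, and `2 k1` is compared with `k3`
evaluated at the per-site area `pi (10 nm)^2 / 150`; the factor 2 applies
the mirror correction that endpoint detection omits, appropriate because
the surrounding surface is overwhelmingly reflective and maintains the
subsurface concentration. At 1 uM, `D = 1e-10 m^2/s`, `dt = 1e-3 s` the
measured `2 k1 / k3` is 1.01–1.06 (mean over 10 seeds, SE ~0.02); the few
percent of excess comes from fitting the non-exponential early transient
and is well within the seed scatter of the statistic. `k1` itself is
first-order in concentration (log–log slope 1.0 within 0.1 over a decade).
The default box is desk-scale; the statistic is insensitive to box size
once depletion is negligible (<4% of probes bound at the default), which is
what makes `k3` geometry-free.

## What the synthetic experiments do not show

The generators emulate ideal dilute Brownian transport. They contain no
hydrodynamics (convection, stirring, flow — ideal stirring enters only as
the closed-form `k2`), no probe–probe interactions or site cooperativity,
no desorption or reversible binding, no energy barrier at the surface, and
no near-wall non-Gaussian diffusion. Passing tests therefore demonstrate
internal consistency between the discrete single-molecule model, the
continuum laws, and the deterministic PDE solution — not agreement with any
particular laboratory system, where the above effects can dominate (the
SAM `k1/k2` gap in particular varies by orders of magnitude with
conditions).

## Degenerate inputs and tie-breaks

Nonpositive physical parameters raise `ValueError` everywhere. The
propagator at `t = 0` (delta limit) is not represented. An all-zero trace
yields a non-converged fit, never a crash; traces shorter than 5 frames
skip fitting. A zero-radius spot adsorbs nothing and reports `k3 = NaN`.
When several molecules hit the floor in one step they draw sites in array
order; at the default occupancies the order is immaterial (mean-field
rejection), and runs are bit-reproducible for a fixed seed regardless.
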