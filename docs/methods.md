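# Methods

`rodcascade` simulates the phototransduction cascade of a mammalian rod
outer segment, with the defining feature that the phosphodiesterase
PDE6 is activated *dimerically*: a holomer is essentially inactive with
zero or one transducin bound (states E and E\*) and hydrolyses cGMP
only in the doubly bound state E\*\*. This note documents the model,
the numerical choices, and what the package's tests do and do not
establish.

## Reaction scheme on a disc surface

A photoisomerized rhodopsin R\* creates activated transducin G\* at
rate `nu_Gst` (1250 s⁻¹ at full activity) for as long as it remains
active. Free G\* diffuses laterally, binds E to form E\* and binds E\*
to form E\*\*; all contacts are treated as diffusion limited. Shut-off
is by GTP hydrolysis: E\*\* → E\* at `k_Estst` = 5 s⁻¹, E\* → E at
`k_Est` = 2.5 s⁻¹, and free G\* decays at `k_Gst` = 1 s⁻¹. The PDE
complement per surface is conserved: E + E\* + E\*\* = `E_tot` (106 at
the default density and disc diameter).

R\* shut-off is binary and abrupt: activity is constant until arrestin
binds, which requires M = 3 phosphorylation steps, all M + 1 reactions
sharing the rate `mu` = 60 s⁻¹. The lifetime of full activity is
therefore gamma-distributed with shape M + 1 and rate `mu` (mean
(M+1)/mu ≈ 66.7 ms), and the summed lifetime of Q synchronous R\* is
gamma with shape Q(M+1) — evaluated through `scipy.stats.gamma`, which
is stable at the large shapes (≥ 120) where factorial formulas
overflow. A small probability `p_aberr` = 0.002 marks an R\* as
*aberrant*: it bypasses the phosphorylation clock, retains fractional
activity `a_aberr` = 0.25, and shuts off abruptly after an
exponentially distributed lifetime of mean `tau_aberr` = 4 s. The
exponential choice is the simplest law consistent with an abrupt,
memoryless failure of the normal mechanism; it is isolated in
`sample_aberrant_lifetime` and easy to swap.

The transducin pool of a surface (`G0_surface` ≈ 3318) is finite and
not replenished on the simulated ≤ 15 s timescale. The creation rate is
throttled by the depletion factor (g/(g+Km))·(1+Km), g the remaining
pool fraction and `K_m_dep` = 0.14; the resulting depletion time course
has a closed form in the principal-branch Lambert W function, and obeys
an exact time-scaling law (rate Q·nu for time t ≡ rate nu for time
Q·t). The saturation constant is itself validated by the package's own
2D experiment (below).

## Three disc engines

**Method 1 — 2D lattice Monte Carlo** (`disc_spatial`). Molecules walk
on a square lattice (spacing 5 nm, tick 0.5 µs) restricted to the
inscribed circle of the 1.3 µm disc, reflecting at the rim. A molecule
with diffusion coefficient D moves with total probability 4·D·Δt/Δx²
per tick (≤ 0.18 for the fastest species), uniformly over the four
neighbours, which reproduces D = Δx²·p/(4Δt). Contact means
co-occupancy of a site after a move (either partner moving in), and
reaction is immediate. Same-species stacking is allowed; the occupancy
grids keep one representative index per site, so a transiently stacked
molecule can be invisible to collisions for the few microseconds until
its next move — negligible at the simulated densities (~106 PDE on
~53 000 sites). Per-molecule Bernoulli move decisions are realized by
drawing the number of movers per tick from a binomial and assigning
the moves to uniformly chosen molecules; this is exact except for
O(p/n) double-selection within a tick and is what makes the engine
tractable in compiled form. First-order decays use per-tick
probabilities k·Δt (≤ 2.5×10⁻⁶): because the total per-tick decay
probability n·k·Δt stays below ~10⁻³, at most one decay event is drawn
per tick per decay class, which under-counts coincident decays by
O((n·k·Δt)²) ≈ 10⁻⁴ relative — far below Monte-Carlo resolution.
Emitted G\* appears at the R\* position and is eligible to react from
its first move. R\* becomes inert at shut-off (arrestin-bound) and is
no longer walked, which affects no observable.

The per-pair encounter rate that *emerges* from this rule is the
recurrent-walk (first-passage) rate, which in 2D is close to
(D₁+D₂)/A — the same constant used by the mass-action engine — rather
than the naive co-occupancy rate 4(D₁+D₂)/A; the agreement of the two
engines beyond the homogenization time (tested at Q = 10) is the
package's check that this microscopic calibration is right.

**Method 2 — mass-action ODEs** (`disc_bulk`). Once the reactants are
spatially homogeneous, the disc obeys r₁ = k₁·G\*·E, r₂ = k₂·G\*·E\*
with k₁ = (D_G\*+D_E)/A and k₂ = (D_G\*+D_E\*)/A. A trial samples the
Q lifetimes and integrates the ODEs with the piecewise-constant R\*
source. Because homogeneity fails during the onset, k₁ is reduced
5-fold until 400 ms after the flash — an empirical correction
calibrated against method 1, switched discontinuously at exactly
0.4 s (both factor and window are exposed as parameters; no theoretical
derivation is claimed for them). E is eliminated through the
conservation law, so E + E\* + E\*\* = E_tot holds exactly.

The integrator is a numba-compiled adaptive Dormand–Prince 5(4) pair
(rtol 10⁻⁸, atol 10⁻⁹ molecules) with the integration split at every
R\* shut-off event and at the 0.4 s switch, and cubic-Hermite sampling
onto the 1 ms output grid. The system's stiffness is mild (fastest
eigenvalue ~k₂·G\* ≈ 10⁴ s⁻¹, resolved by the accuracy-limited steps),
and the compiled explicit solver makes a trial ~0.5 ms, which is what
allows 10⁴–10⁵ trials in the bright-flash pipelines. States are clipped
at zero after sampling, with a guard against any undershoot beyond
tolerance.

A *time-shift fast path* reproduces the method-2 mean for Q ≥ 10 from a
single deterministic solution: the disc ODEs are solved once from a
large free-G\* bolus (10⁴), the gamma distribution of summed lifetimes
is mapped through the depletion law to a distribution of totals
created, each total is converted to a time-shift along the base
solution, and the shifted waveforms are averaged over equal-mass
quantiles. The constant activation-delay offset is taken as the
analytic temporal centroid of G\* creation, E[L²]/(2E[L]) = (M+2)/(2µ)
≈ 41.7 ms for the gamma lifetime law. The method is refused for Q < 6,
where E\*\* does not saturate and the bolus approximation is invalid.

**Method 3 — whole outer segment with aberrant events**
(`outer_segment`). A flash of Φ isomerizations delivers
Poisson-distributed counts to the N_surfs = 1320 surfaces
(φ = Φ/N_surfs per surface). Normal and aberrant events are drawn as
independent Poisson streams (thinning, exactly equivalent to per-event
Bernoulli marking); each active surface is simulated with the
mass-action engine using its mixed timelines, and its E\*\* activity is
deposited in its longitudinal compartment, surfaces being assigned
evenly to the n_x = 100 compartments (13–14 each). Surfaces without
events are skipped, so cost scales with φ. Whether per-surface counts
should be redrawn each trial is not dictated by anything physical; the
package redraws per trial.

## Downstream model

The cytoplasmic equations are the standard forms:

    d[cG]/dt = alpha_max / (1 + (Ca/K_GCAP)^m)  -  (beta_dark + beta_E** · E**_tot(t)) · [cG]
    J_cG = J_cG,max · cG^n / (cG^n + K_cG^n)
    J_ex = J_ex,max · Ca / (Ca + K_ex)
    d[Ca]/dt = [ f_Ca·J_cG/(2 F V_cyto) - J_ex/(F V_cyto) ] / B_Ca

with F = 96 485 C mol⁻¹, Ca²⁺ carrying two charges through the CNG
channel and the exchanger stoichiometry folded into `J_ex_max`. These
forms are pinned by a self-consistency requirement: they reproduce the
calculated resting state (cG 4.12 µM, Ca 322 nM, cyclase rate
16.5 µM s⁻¹, dark current 18.4 pA) to better than 1%, and the dark
balance f_Ca·J_cG/2 = J_ex holds identically. `beta_Estst`
(0.017 s⁻¹) is applied per E\*\* molecule directly; cytoplasmic cGMP
buffering appears only in the biochemical cross-check
k_cat/(K_m·N_Av·V_cyto·B_cG) ≈ 0.0195 s⁻¹, not as a divisor in the
dynamics. The spatial variant integrates the same terms in n_x
compartments with cGMP and Ca²⁺ diffusion (40 and 2 µm² s⁻¹), no-flux
ends, and 1/n_x of the membrane conductances per compartment; a
uniform drive reproduces the lumped model to < 0.1%. Both integrators
(LSODA) cap their internal step at 5 ms (configurable): starting from
the dark equilibrium the derivative is near zero, and an unbounded
solver can step clean over a delayed drive onset. The dark solve
reduces the two balances to one monotone scalar root (Ca expressed
through the flux balance), bracketed and solved to machine precision;
`dark_adapt` additionally verifies stationarity under drive-free
integration.

The exchanger electrogenicity convention is not uniquely determined by
the downstream parameter table alone; the convention above is the one
under which the tabulated dark values are mutually consistent, which is
the criterion used to fix it.

## Analyses

*Rising phase.* The E\*\* onset is fitted with a ramp Q·nu_E\*\*·t
convolved with two exponential delays, τ₁ fixed at 1/nu_Gst = 0.8 ms,
fitting (nu_E\*\*, τ₂) by least squares over the elliptical region
(t/30 ms)² + (E\*\*/0.35·E_tot)² ≤ 1, t ≥ 0.

*Super-linearity.* Tail amplitudes at a fixed time (default 700 ms)
follow R_Q = R₁·Q·(1+ρ)^(Q−1); the fit is linear in log space over
Q ≤ 4 (beyond which PDE saturation compresses amplitudes), giving
ρ ≈ 0.32 and R₁ ≈ 1.4 E\*\* from the simulated tails. The identity
Σ_Q p_Q R_Q = φ·e^{ρφ}·R₁ links the per-Q law to the Poisson mixture.

*Time in saturation.* T_sat is the last time the current is at or below
the criterion fraction (default 10%) of the dark current, located by
linear interpolation (if a sample touches the criterion exactly, that
sample time is used); a response that never reaches the criterion
returns a distinguished "not saturated" value rather than raising.
The two "dominant time constant" lines are fitted by ordinary least
squares on (ln Φ, T_sat) over fixed, configurable windows —
Φ ∈ [300, 3000] and [10 000, 62 500] by default, replacing the
by-eye fits of common practice with a reproducible rule — and their
intersection defines Φ_trans. The analytic prediction
T_sat ≈ (ln φ + ρφ)/k_E\*\* + t_offset (offset 585 ms, the time the
Q = 1 mean E\*\* trace crosses the saturation level ≈ 2.6 E\*\*) is
compared with simulation over Φ ∈ [500, 3000]: a lower cutoff is
structurally required because the asymptotic law keeps a finite offset
while the simulated T_sat → 0 at the just-saturating end, so relative
agreement is only meaningful once responses are well saturated
(T_sat ≳ 0.4 s). Its tangent slope is (1 + ρΦ/N_surfs)/k_E\*\*, a
factor 1.24 above 1/k_E\*\* at Φ = 1000 — the model's explanation for
the first dominant time constant exceeding the 200 ms E\*\* decay.
Electrical tails are fitted over the fractional-response window
[0.5%, 10%]; E\*\* tails over [0.5, 5] molecules.

## Validation experiments the package runs on itself

- **Dark fixed point**: the root-solved dark state is stationary under
  the integrator to 10⁻⁶ relative over 10 s.
- **Depletion**: the Lambert-W closed form matches direct integration
  of the depletion ODE to 10⁻⁶; fitting it to the package's own 2D
  depletion experiment (R\* + diffusing G holomers, shut-off disabled,
  PDE removed, exponential activation delay of mean 1/nu_Gst after
  contact) recovers K_m ≈ 0.14, and mean trajectories for different Q
  superimpose under time scaling ∝ Q. The experiment's realized initial
  rate sits a few percent below Q·nu_Gst because the diffusional
  contact wait (including the local depletion halo around each R\*)
  adds to the activation delay; the fit therefore treats the initial
  rate as a second free parameter, recovered within 5% of Q·nu_Gst.
- **Engine cross-validation**: methods 1 and 2 agree on the mean Q = 10
  recovery within ~3 molecules beyond 0.5 s. The comparison uses
  matched R\* timelines in both engines (common random numbers):
  the dominant trial-to-trial variance is the shared lifetime
  randomness (sd ~25 molecules on the steep recovery), so pairing
  isolates the engine difference actually under test. Measured over
  200 independent pairs, the systematic offset is ~1.2 molecules at
  the steepest point of the recovery.
- **Single-photon response**: the lattice engine yields a mean E\*\*
  peak of ~23.8 molecules. The electrical amplitude (~3.8% of the dark
  current, ~0.7 pA) is obtained by integrating the longitudinal
  downstream model for each trial's localized E\*\* drive and averaging
  the individual responses: local cGMP depletion compresses the
  response of a localized drive, so the lumped model applied to the
  mean drive overestimates the amplitude by ~25%.

## Problem sizes and tolerances used by the test suite

Monte-Carlo checks run at reduced but stated scales, chosen so each
statistical assertion holds with ≥ 3-sigma headroom: 100 lattice trials
for the single-photon response (tolerances 10% on the E\*\* peak, 15%
on the electrical amplitude), 200 matched pairs for the engine
cross-check, 1000 mass-action trials per Q for tail constants (±2%)
and super-linearity (ρ ± 0.07), 120 trials per Q and 0.1-log₁₀ spacing
for the T_sat surface (fitted parameters ±20%), and ~10 trials per Q
for the depletion fits (K_m ± 0.03; the pool of ~3300 molecules makes
trial noise ≲ 2%). The 200-pair count for the cross-check reflects
that its max-over-samples statistic on a 1-ms grid has a heavy upper
tail under lattice sampling noise (50-pair batches range 1.4–3.3
molecules even though the systematic offset is ~1.2); 200 pairs bring
the noise ceiling well under the 3-molecule band. The acceptance
script runs the T_sat pipeline at 0.05-log₁₀ spacing with 200 trials
per Q.

## What the synthetic conditions do and do not show

All inputs are generated by the model itself under the standard
parameter tables; there is no fitting to recordings anywhere in the
package. Passing tests therefore demonstrate internal consistency of
the engines, the analytic laws, and the published operating point —
not that the parameters describe any particular cell. Known
limitations: no photon-to-isomerization optics (Φ is specified in
isomerizations); no rhodopsin regeneration, arrestin release or
transducin replenishment; no membrane voltage or capacitance (the
"current" is the CNG-plus-exchanger suction-pipette convention); the
lattice rule's microscopic details (4-neighbour moves, same-site
stacking) are explicit choices that could be varied; and the 5-fold
k₁ onset correction is empirical. Cone photoreceptors and mutant PDE6
variants are out of scope.
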