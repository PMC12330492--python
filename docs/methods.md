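# Methods

## The permeant model

The permeant is reduced to two coupled coordinates: its center-of-mass
position z along the membrane normal (Å from the bilayer center, positive
on the extracellular side) and a two-state protonation label λ ∈ {0, 1}
(0 = protonated/charged amine, 1 = deprotonated/neutral).  This is the
desk-scale stand-in for constant-pH λ-dynamics, in which λ = sin²θ is a
continuous coordinate propagated with the atoms; at this scale only the
state occupancy matters, so λ is a jump process.

**Free energy.**  The neutral-state profile is a Gaussian central barrier
plus Gaussian interface wells,

    G₁(z) = A·exp(−z²/2σ_b²) − W·[exp(−(z−m)²/2σ_w²) + exp(−(z+m)²/2σ_w²)]

with m = 20 Å (membrane half-width), σ_b = 6 Å, σ_w = 3 Å, well depth
W = 2 kcal/mol by default.  The charged state pays an extra penalty
inside the membrane, G₀(z) = G₁(z) + P·S(z), where S(z) is a normalized
logistic switch in |z| (exactly 1 at the center, exactly 0 for
|z| ≥ m + 5 Å; midpoint 12 Å, width 1.5 Å).  Both profiles are zero in
bulk.  The same switch drives the z-dependent pKa,

    pKa(z) = pKa_solution − Δ·S(z),     Δ = 6 by default,

so a permeant with solution pKa 8.4 begins to favor the neutral form
around z ≈ 15 Å and is essentially fully neutral below z ≈ 10 Å at
pH 7.5 — deprotonation completes before the core, and the charged
species effectively cannot cross.

**Thermodynamic consistency.**  The default charged penalty is
P = ln10·kT·Δ (≈ 8.24 kcal/mol at 300 K).  With that choice the energy
gap between the states, P·S(z), corresponds exactly to the pKa shift
Δ·S(z), the joint (z, λ) process is reversible, and its stationary
density is the titration-marginalized Boltzmann density

    p(z) ∝ exp(−G₀(z)/kT) + 10^(pH − pKa_sol)·exp(−G₁(z)/kT),

which `boltzmann_density` evaluates by quadrature and the equilibrium
tests use as an exact oracle.  The two parameters remain independent
fields; setting them inconsistently gives well-defined dynamics whose
stationary state is no longer the quadrature density.

**Barrier calibration of the presets.**  Observed permeant free-energy
profiles are computed from the marginalized z-density, which for a
mostly-charged solution population sits kT·ln(1 + 10^(pKa−pH)) above the
neutral-state profile in the core (relative to bulk).  The named presets
therefore calibrate the neutral-state amplitude A so that the
*marginalized* barrier at pH 7.5 equals the nominal barrier height —
7.8 / 14.2 / 24.8 / 33.4 kcal/mol for the fentanyl / morphine /
isotonitazene / naloxone presets (solution pKa 8.4 / 8.2 / 8.7 / 7.9),
and 3 / 5 / 7 / 9 kcal/mol for the scaled-down family used in worked
examples and statistical checks, where the full barriers would make sink
arrivals unobservably rare.  An uncalibrated `ToyLandscape` interprets
`barrier_height` directly as the neutral-state maximum.

**Dynamics.**  z follows overdamped Euler–Maruyama steps on the
state-dependent profile; λ flips are attempted at `attempt_rate`
(0.1 ps⁻¹) and accepted with probability f (deprotonation) or 1−f
(protonation), f = 1/(1+10^(pKa(z)−pH)), which enforces detailed balance
k_deprot/k_prot = 10^(pH−pKa(z)) and makes the pinned-walker stationary
deprotonated fraction exactly the Henderson–Hasselbalch value.  The
default diffusion coefficient is D = 0.002 Å²/ps — a membrane-interior
value (2×10⁻⁷ cm²/s) chosen deliberately so that a 100 ps WE segment
displaces walkers by about one membrane bin (σ ≈ 0.6 Å): weighted
ensembles transport probability through their bin ladder only when
per-segment motion is commensurate with the bin spacing.  With a
water-like D the segment dynamics fully relax into the interface well
every iteration and crossing statistics collapse to rare single-segment
bursts.  Default time step 10 ps (per-step displacement ≈ 0.2 Å plus
drift; a stability warning fires if a step can exceed the membrane bin
width); hop attempts are evaluated on a ~1 ps sub-schedule, far below
the ~10 ps waiting time at the default attempt rate.

The deprotonation timescale (~ns at the default attempt rate) is far
shorter than traversal (~ms for the scaled presets), preserving the
physical separation in which titration is fast relative to permeation.

## The weighted-ensemble protocol

Bins: 0.5 Å spacing inside |z| ≤ 20 Å, 5 Å spacing in solvent out to the
recycle boundaries at z = 55 and −25 Å (88 bins with the defaults; the
documented construction cannot reproduce one printed total of 85 exactly,
so the count is reported, not asserted).  Bins are added dynamically at
the membrane–extracellular interface (20 < z < 25): any occupied bin in
that window wider than the membrane spacing is split at its midpoint
until none remains; a protocol variant (`prefill_dynamic`, used by the
second trial of the experiment) tiles the window at membrane spacing
from the start.

Each iteration: propagate every walker for τ = 100 ps → update lineages
(extracellular z > 20, intracellular z < −20; the flux tally is the
weight whose lineage newly flips extracellular→intracellular this
iteration, and an analogous two-dimensional (bilayer, λ-threshold)
lineage feeds the deprotonation rate) → recycle walkers beyond the outer
boundaries to the source (z = 30 Å, solution-equilibrium λ, fresh
observables, identical weight; recycling precedes binning within the
iteration) → assign to bins (half-open intervals, overflow clamped with
a warning) → resample each occupied bin to the target count (4):
splitting replicates the highest-weight walker into equal halves;
merging combines the two lowest-weight walkers with the survivor chosen
with probability proportional to weight.  Resampling conserves per-bin
weight to 1e-12 and is unbiased for the expected weight of any tagged
subpopulation (tested by Monte-Carlo).  Total weight is checked to 1e-9
every iteration.  Everything is driven by a single seeded generator;
random draws for the stepping kernel are pre-generated, so the
JIT-compiled and numpy kernels consume identical streams.

`p_ext` is the weight fraction of walkers whose most recently visited
macrostate is extracellular (1.0 by convention before any walker has a
macrostate history); in the source–sink configuration it stays within a
couple of percent of 1.

## Flux analysis

Per-iteration flux f_i = (newly intracellular weight)_i / τ in s⁻¹.
Over the analysis window (default: final 50 iterations),

    Pm = mean(f) · ld · 1e-8 cm/Å,    MFPT = p_ext / mean(f),

with ld = 22.5 Å (half the water-buffer height, the depth of the
effective reaction volume).  95% intervals use mean ± 1.96·SE on the
*flux* scale and are transformed through both formulas; the convention
is recorded in the output because the interval scale is a genuine choice
(flux, Pm and log Pm give different intervals).  Zero mean flux yields
Pm = 0, MFPT = ∞ and a `no_permeation_events` flag rather than a number.
Run comparison uses a two-sided Welch t-test on the final-window fluxes
(the unequal-variance form is the safe reading of a two-sample t-test
between WE trials).

WE flux series are strongly autocorrelated and heavy-tailed: single
high-weight lineages produce bursts spanning decades.  The oracle
cross-check therefore estimates the WE uncertainty across replicate runs
(6 seeds) rather than from the within-run SE, and compares against
direct (unsplit) brute-force first-passage simulation of the *same*
process semantics — propagation in τ-chunks, sink and recycle checks at
chunk ends — in `permweight.direct`.  Both estimators need the bulk
relaxation time (~L²/D, over a thousand iterations at the oracle-test
settings) before their steady states are comparable.

## Profiles

F(z) = −kT·ln p(z) from weight-summed histograms over the pooled window,
min-shifted to zero; empty bins stay NaN and are never interpolated
silently (plotting can interpolate behind a flag).  Bin masses are
accumulated per-bin (`np.add.at`) rather than with numpy's cumulative-sum
histogram, which silently drops weights below ~1e-16 of the running
total — WE weights legitimately span 30 orders of magnitude.
Symmetrization averages *probabilities* pairwise about z = 0 (preserving
normalization) and then re-transforms; channel values are combined with
probability weighting; the operation is idempotent.  Deprotonation
profiles report the weighted mean λ (continuous convention); rate
estimation uses the λ < 0.2 / λ > 0.8 thresholds — the two conventions
are deliberately distinct.  The local-thickness channel is referenced to
its bulk (|z| > 30 Å) mean.  Orientational free energy is computed per
z-region, with the default regions (31, 35), (18, 22) and (−2, 2) Å.

kT at 300 K is 0.5961 kcal/mol (R = 1.9872×10⁻³ kcal/mol/K).

Profiles computed from a recycling (source–sink) run describe the
nonequilibrium steady-state density, not the equilibrium one: the
downhill side of the barrier is depleted by the sink, so the apparent
barrier read from such a profile exceeds the equilibrium value.  The
equilibrium comparison against the Boltzmann oracle therefore uses
sink-free runs.

## Synthetic observables

Hydration, H-bond and contact counts are Poisson draws around smooth
conditional means of |z| (fast-desolvating presets reach zero hydration
below |z| ≈ 5 Å; slow ones retain 1–2 waters until |z| ≈ 3 Å); the
local-thickness change is a Gaussian around a charged-state-dependent
thinning profile (deep thinning for the slow-titrating presets); the
orientation angle is a 30°/160° bimodal mixture inside the interface
band (16 ≤ |z| ≤ 24 Å) and uniform elsewhere.  These emulate the
qualitative z-dependence of real permeants but contain no geometry:
passing profile tests demonstrates that the estimators recover the
generating means and shapes under WE weighting — not that any real
molecule behaves this way.

## Assay post-processing

CHI calibration is ordinary least squares of literature CHI on retention
time; the calibration object carries the Pearson r and is usable only
when r > 0.99 (the instrument-suitability convention).  Column
suitability requires every test compound within ±5 CHI of its literature
value, read as inclusive.  The shipped calibrant tables in the tests are
synthetic.  BRET correction subtracts the vehicle ratio from
em535/em475 ("corrected for the vehicle" is ambiguous between
subtraction and division; subtraction matches baseline-corrected ratio
traces and is recorded in the output).

## Problem sizes used by the test suite

Chosen once as the package's study conditions: titration-fit recovery
uses 1.2×10⁵ attempted moves per pH at six pH values; the oracle
equivalence check runs 6 WE replicas of 2500 iterations (τ = 25 ps,
window 1500) against 64 brute-force walkers on the 3 kcal/mol landscape
with D = 0.02 Å²/ps and shallow (0.5 kcal/mol) wells; rank-order
recovery runs the two-trial experiment (600 iterations, window 300,
target count 8 — the larger target suppresses the single-lineage weight
bursts that otherwise invert the two slowest presets in a few percent of
seeds) over 20 seeds; Boltzmann recovery uses a sink-free run of 2500
iterations on a symmetric reflecting domain seeded uniformly, so that no
slow antisymmetric relaxation mode is excited.

## Known limitations

- One spatial dimension: no lateral diffusion, membrane deformation
  feedback, or permeant flexibility; observables are emulated, not
  computed.
- Binary λ: mixed protonation states (0.2 ≤ λ ≤ 0.8) never occur in the
  toy dynamics, though the analysis layer supports them.
- The logistic pKa(z) shift and Gaussian landscape shapes are modeling
  choices; real profiles are neither symmetric nor single-barrier in
  general.
- WE flux estimates on high-barrier presets carry large statistical
  uncertainty at desk-scale run lengths; the rank order is robust, the
  absolute values are not — mirroring the behavior of the full-scale
  methodology.
- The within-run flux SE underestimates the true uncertainty because of
  autocorrelation; replicate runs are the reliable route to intervals.
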