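# Model and methods

`plaquesim` is a hybrid particle/continuum simulator of supragingival plaque
acidity.  Discrete spherical particles — bacterial aggregates of two
physiologies, aciduric (**A**) and nonaciduric (**NA**) — sit in a rectangular
box `L x L x H` with the tooth surface at `z = 0` and the saliva–air
interface at `z = H`.  Two solute concentration fields span the box: dietary
sugar `[Gl]` (readily fermented carbohydrate) and the undissociated acid
metabolite `[acid]`.  Dietary intakes drive the system by pinning the
interface sugar concentration to a pulse that ramps up quickly and then
decays exponentially with clearance half-time `t1/2`; hyposalivation is
modelled solely as a longer `t1/2`.  The integrated interface concentration
per pulse is held fixed across `t1/2`, so clearance speed is varied
independently of the amount of sugar consumed.

## Governing relations

**Metabolism.**  A particle of mass `m` converts sugar to acid at

    r = m * mu_max * [Gl]_eff/([Gl]_eff + K_Gl) * 4 h K_acid/(h + K_acid)^2

with `h = [H+]` and `[Gl]_eff = [Gl]_local + [polyGl]`, where `[polyGl]` is a
constant, spatially uniform background carbohydrate representing endogenous
nutrient sources between meals.  The pH factor equals 1 exactly at
`h = K_acid` (the preferred acidity) and is symmetric in pH about
`-log10 K_acid`; both factors are at most one, so `r <= m mu_max`.

**Growth, division, death.**  A fixed yield fraction `Y` of the converted
mass becomes biomass (same `Y` for both types).  Particles exceeding the
critical diameter `d_crit` split into two equal-mass daughters displaced by
one daughter radius along a random direction.  Acid kills particles at rate
`1e7 * K_death * [H+]`, with `K_death(NA) = 2 K_death(A)` exactly; removal is
drawn per step with probability `1 - exp(-rate dt)` (exact for any step
length).  Removed biomass vanishes.

**Mechanics.**  After growth, division and death, overlapping spheres are
relaxed by symmetric pairwise shoving (all overlapping pairs displaced
simultaneously along their centre lines, wrapped periodically in x/y and
reflected off the tooth plane) until the largest relative overlap is at most
`shove_tol`.  The simultaneous (Jacobi-style) update is order-free, so no
randomised sweep order is needed for unbiasedness.  Constant film thickness
is maintained by deleting particles whose centres exceed `B` after
stabilisation.

**Chemistry.**  The fluid is assumed to be at chemical equilibrium at all
times: pH is a memoryless function of the local undissociated-acid
concentration through a saturating three-parameter buffering curve
`pH = pH_rest - (pH_rest - pH_floor) * a/(a + K_buf)` (defaults: rest 7.0,
floor 3.5, `K_buf = 50 mol m^-3`).  A tabulated curve with monotone (PCHIP)
interpolation can be substituted when a measured buffering curve is
available.

**Fields and boundary conditions.**  Both solutes obey reaction–diffusion
equations with zero flux at the tooth plane, Dirichlet values at the
interface (`[Gl] = ` pulse value, `[acid] = 0`) and lateral periodicity.
Per-particle conversion rates are deposited on the lattice by nearest-voxel
assignment (exactly conservative); the acid source is `(1 - Y) r` by mass
(a config flag switches to `r` for sensitivity checks).

## Numerical scheme

The default integration is a dual-timescale, semi-implicit hybrid:

* **Sugar** is solved quasi-steadily each biology step.  With
  `D_Gl = 600 um^2/s` the sugar field equilibrates across the 60-um box in
  a few seconds — far below the minutes-scale pulse dynamics — so the steady
  problem is solved directly (one sparse LU factorisation of the discrete
  Laplacian per grid, reused for every solve) self-consistently with the
  Monod sinks via a damped Picard iteration (tolerance 1e-3, at most 8
  iterations, typically 2–3).
* **Acid** takes one backward-Euler step per biology step.  Its effective
  diffusivity is small (`D_acid = 7.5 um^2/s`) because reversible binding to
  the buffering matrix retards acid transport; the resulting washout time of
  `(2H/pi)^2 / D_acid ≈ 3 min` produces the minutes-long Stephan recovery
  tail that instantaneous acid equilibration cannot.
* A fully explicit transient mode (FTCS at the diffusive stability bound,
  with sink throttling so no voxel goes negative) and a fully quasi-steady
  mode are provided as config switches; the default agrees with the explicit
  scheme to < 0.05 pH away from pulse onsets (tested).

Biology advances with `dt_bio = 30 s` while a pulse is active — a window
covering the interface decay to a few per cent of `K_Gl` plus four acid
washout times, a deterministic function of the schedule so runs are
resumable — and `dt_bio_idle = 600 s` between pulses.  The update order per
step is: sample fields → metabolism → deposit rates → advance fields → grow
→ divide → die → shove → trim.

**Randomness.**  One root seed spawns independent child streams (initial
placement, division directions, death draws, shove tie-breaks), so toggling
one stochastic element does not perturb the others.  Identical (parameters,
seed) give bit-identical runs; a run snapshotted to the HDF5 resume
container and continued is bit-identical to an uninterrupted one (tested).

## Geometry, units, defaults

Lengths in um, time in s, concentrations in mol m^-3, particle mass in pg;
`[H+]` appears in mol L^-1 and is produced only inside the chemistry module.
The desk-scale box is 36 x 36 x 60 um with a 24-um film ceiling and a 6-um
lattice (at least one particle diameter, as required by nearest-voxel
deposition).  Films start from 130 particles (5 % A for the symbiotic state),
masses jittered ±30 % around half the critical mass so divisions
desynchronise; mass↔radius uses a fixed aggregate dry-mass density
`rho = 0.1 pg um^-3`, chosen so a fresh particle is one division below
`d_crit = 6 um`.

## Calibration

The kinetic, buffering and dietary constants are not measurements; they are
a calibration ledger (shipped in `configs/default.yaml`) tuned once so the
desk-scale model reproduces the headline behaviour of plaque-pH physiology:

* a symbiotic film (95 % NA) bottoms out between pH 5.5 and 6.2 during a
  pulse, spends more than 15 min below the dentin critical pH 6.2, and that
  time roughly doubles from `t1/2 = 2` to 6 min;
* a 50/50 film dips below the enamel critical pH 5.5, with times below each
  threshold 5–10x `t1/2`;
* the symbiosis→dysbiosis crossover sits near 6 intakes/day at
  `t1/2 = 2 min` and near 3/day at `t1/2 = 6 min`.

The calibration used two separations of scale.  First, pulse shape: the
sub-threshold durations follow `t1/2 * log2(peak/G*)` plus the acid washout
lag, which fixes the dose (112 mol m^-3 min, i.e. a ~39 mM peak at
`t1/2 = 2 min`), `K_Gl = 0.1 mol m^-3` and `D_acid`.  Second, ecology: the
aciduric fraction drifts at a rate `a * f - b` per day (pulse advantage `a`
per intake at frequency `f`, rest-phase nonaciduric advantage `b` from
`[polyGl]` metabolism near neutrality).  Because the rest pH self-adjusts to
the film's own acid production, `b` saturates around 0.15/day regardless of
production scale; the crossover is therefore set by the pulse advantage,
i.e. by how far A's preferred pH (5.0) sits below the symbiotic pulse
plateau (~5.9).  The measured 50-day crossover lies above the drift balance
point because a film starting at 5 % A must traverse ~3 logit units of
composition within the protocol.

## The scaled 50-day protocol

Ecological experiments compress 50 days by multiplying the growth yield and
the death prefactor by `accel = 12.5` and simulating 4 days: each pulse then
carries 12.5 days' worth of growth and death while all rate *ratios*
(growth:death, NA:A) are preserved, so the cumulative selection per
represented day is invariant.  The scaled protocol also uses a 1.5x coarser
biology step (45 s / 900 s), which leaves single-pulse metrics unchanged to
within their seed scatter.  Problem sizes throughout (130 particles, 6x6x11
lattice, 4 simulated days per 50 represented days) are the package's
desk-scale configuration; `accel`, box size and particle count are exposed
for larger runs.

## What the synthetic film does and does not capture

The generator emulates a two-physiology community with fixed total
thickness, pulsed nutrient driving and acid-mediated selection.  It does not
include extracellular-matrix mechanics beyond sphere overlap, salivary shear
or flow, explicit acid speciation or bicarbonate kinetics, fluoride, or
tooth demineralisation and its buffering by dissolved mineral — so passing
tests show the *mechanisms* (clearance-controlled acid exposure, frequency-
and clearance-driven dysbiosis) behave correctly at desk scale, not that the
constants transfer quantitatively to a clinical film.  With only ~6 aciduric
founders, demographic extinction occasionally removes the aciduric lineage
in single runs near the crossover; replicate averaging (3 replicates in the
standard protocol) absorbs this, but single-replicate sweeps are noisy there.

## Design choices where the design was open

* Exact-count type assignment by default (a 95/5 film always starts with
  exactly 5 % A); per-particle Bernoulli assignment is available.
* The pulse rise is a 30-s linear ramp; the decay clock starts at mid-ramp,
  making the realised dose match the nominal one to second order in
  `rise/t1/2` (<0.4 % here) while preserving `peak = dose ln2 / t1/2` and
  exact halving from the ramp end.  Overlapping pulses replace (never sum)
  the residual profile.
* "Tooth-surface pH" is the mean pH of the lattice layer adjacent to z = 0;
  composition is a number fraction (a mass-weighted variant exists).
* Division splits mass exactly 50/50; dead biomass leaves no debris.
* Degenerate inputs: coincident sphere centres are separated along a random
  direction; sugar sinks are throttled to the available concentration; the
  steady solver scales down frozen sinks in voxels that would go negative.

## Known limitations

Quantities are desk-scale calibrated, not parameter-free predictions; the
lateral box (6 voxels) cannot resolve lateral patterning; the quasi-steady
sugar treatment assumes no advection; and the acceptance-level crossover
frequencies inherit ±0.5/day of replicate scatter from the small film.
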