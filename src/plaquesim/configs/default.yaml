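# plaquesim calibrated default parameter set (schema 1).
#
# These values are a calibration ledger: they were tuned (see docs/methods.md,
# "Calibration") so that the desk-scale model reproduces the headline plaque-pH
# behaviour -- symbiotic single pulses bottom out between pH 5.5 and 6.2, spend
# >15 min below the dentin critical pH 6.2 with the sub-6.2 time roughly
# doubling from t1/2 = 2 to 6 min, and the symbiosis->dysbiosis crossover sits
# near 6 intakes/day at t1/2 = 2 min and near 3/day at t1/2 = 6 min.
schema_version: 1
geometry:
  L: 36.0          # lateral box size, um (periodic in x and y)
  H: 60.0          # box height: tooth surface z=0, saliva-air interface z=H
  B: 24.0          # biofilm thickness ceiling, um
  grid_spacing: 6.0
types:
  A:               # aciduric: acid tolerant, prefers low pH
    mu_max: 4.5e-3     # s^-1, per unit particle mass
    K_Gl: 0.1          # mol m^-3
    preferred_ph: 5.0
    K_death: 2.5e-8
  NA:              # nonaciduric: prefers neutrality, dies twice as fast in acid
    mu_max: 2.0e-3
    K_Gl: 0.1
    preferred_ph: 7.0
    K_death: 5.0e-8    # exactly 2x K_death of A
growth:
  Y: 0.025         # growth yield: fraction of converted sugar mass -> biomass
  death_prefactor: 1.0e7
solutes:
  poly_gl: 0.0095  # background carbohydrate [polyGl], mol m^-3
  D_Gl: 600.0      # um^2 s^-1
  D_acid: 7.5      # um^2 s^-1, effective (buffer-retarded) acid transport
  gl_molar_mass: 180.0
  acid_molar_mass: 90.0
  acid_stoichiometry: one_minus_y
particles:
  d_crit: 6.0      # critical division diameter, um
  rho: 0.1         # pg um^-3 (dry-mass density of an aggregate)
  shove_tol: 0.05
  shove_max_iter: 150
buffering:
  ph_rest: 7.0
  ph_floor: 3.5
  K_buf: 50.0      # mol m^-3 at half-maximal pH drop
numerics:
  dt_bio: 30.0       # biology step while a pulse is active, s
  dt_bio_idle: 600.0 # biology step between pulses, s
  dt_chem: null      # explicit field step; null -> diffusive stability bound
  field_mode: semi_implicit
  picard_tol: 1.0e-3
  picard_max_iter: 8
schedule:
  freq_per_day: 4
  t_half_min: 2.0
  total_dose: 112.0  # integrated interface sugar per pulse, mol m^-3 min
  rise_time_s: 30.0
init:
  n_particles: 130
  frac_A: 0.05
seed: 0
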