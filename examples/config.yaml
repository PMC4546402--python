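# Example pipeline configuration (all keys optional except the seed,
# which may instead be given on the command line with --seed).
# Unknown keys are rejected.

seed: 1
tm3_variant: printed   # or "range" (appends Tyr238)

# helices:            # override the default BTL helix set entirely
#   - name: TM1
#     sequence: ...
#     start: 24
#     end: 48
#     allowed_axes: z
#     n_term_side: extracellular

restraints:
  diameter_target: 26.0       # Angstrom
  membrane_thickness: 30.0    # Angstrom
  clash_distance: 4.0         # Angstrom
  contact_window: [4.0, 6.5]  # Angstrom
  # all term weights default to 1.0; e.g.:
  # interaction_weight: 2.0
  # contact_restraints:
  #   - {resnum_i: 81, resnum_j: 223, distance_upper: 8.0, certainty: 1.0}

mc:
  t_high: 5.0          # annealing ladder start (score units)
  t_low: 0.2
  n_rungs: 10
  steps_per_rung: 1000
  record_stride: 20
  axial_rotation_max: 30.0   # degrees
  tilt_step_max: 5.0         # degrees (tilt-vector components)
  translation_step_max: 1.0  # Angstrom
  n_restarts: 1

clustering_cutoff: 2.0   # Angstrom, complete-linkage cut
top_k: 100               # size of the low-score subset in tables
initial_side: 10.0       # Angstrom, starting square side
crossing_angle_max: 40.0 # degrees, analysis-time hard filter
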