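# Desk-scale demo configuration: a 60 x 60 km synthetic study region
# with 40 mammal species, 5 phylogenies, an Indigenous-dominant tenure
# mosaic and 4-km hexagonal planning units.  `latentplan run-all
# --config examples/demo_config.yaml` drives the full pipeline.
seed: 1
simulate:
  grid_nrows: 60
  grid_ncols: 60
  cell_size: 1.0
  n_species: 40
  n_trees: 5
  pa_fraction: 0.12
  suppressed_fraction: 0.10
  autocorr_sigma: 6.0
  boundary_notch: true
true_model:
  beta:
    body_mass_g: 0.5
    body_mass_g_sq: -0.25
    age_first_repro_d: 0.6
    litters_per_year: 0.3
    range_size_km2: -0.6
    fox_overlap: 0.5
    fire_total: 0.9
    fire_lds: -0.7
  w_phylo: 0.4
  w_space: 0.2
  sigma2: 2.0
  spatial_range: 20.0
  suppression_shift: 3
risk:
  w_phylo: 0.4
  w_space: 0.2
  rho: 20.0
  skew_threshold: 1.0
  vif_threshold: 5.0
  delta_aicc: 2.0
  profile_covariance: false
planning:
  hex_side_km: 4.0
  w_floor: 0.01
targets:
  latent_threshold: 1.50
  status_threshold: 7
  area_proportion_range: [0.15, 0.7]
prioritize:
  gap: 0.0
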