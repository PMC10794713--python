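# Demo pipeline configuration: every stage runs on synthetic inputs.
log_level: INFO
simulate:
  seed: 1
  trajectory:
    n_rings: 8
    box_edge: 50.0
    min_spacing: 16.0
    cluster_mode: orthogonal
    cluster_onset: 0.5
    n_frames: 60
  lengths:
    components:
      - [0.55, 61.0, 6.0]
      - [0.25, 134.0, 10.0]
      - [0.12, 199.0, 14.0]
      - [0.08, 267.0, 18.0]
    n_samples: 2000
  melt:
    tm_true: 55.0
    t_range: [25.0, 95.0, 1.0]
    amplitude: 1000.0
    slope: 0.5
    noise_sd: 10.0
  rnaquant:
    references:
      - [CP, 807, CP]
      - [p97, 2421, p97]
      - [rrsA, 1542, rRNA]
      - [hns, 414, other]
    composition: [0.70, 0.05, 0.15, 0.10]
    read_length_dist: [400.0, 80.0]
    three_prime_bias: 1.0
    n_reads: 4000
    mapq_high_fraction: 0.9
geometry:
  params_table: null          # null -> bundled symmetry table
  rna_nt: 807
  nt_per_subunit: 5
  length_rise_label: VLP_T43C_D136C
  axial_pair: [VLP_r, trCP_H2T]
rings:
  contact_threshold: 12.0
lengths:
  n_components: 4
  n_restarts: 5
  multiple_rel_tol: 0.12
melt:
  mode: min
rnaquant:
  mapq: 60
  three_prime_window: 50
  smooth_window: 40
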