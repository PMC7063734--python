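# Default pipeline configuration. User YAML files are merged over this.

filter:
  require_productive: true
  allowed_v_families: [IGHV1]
  allowed_isotypes: [IGHM, IGHG]

# Field-name -> column-name overrides for non-standard input tables.
column_map: {}

# Physicochemical amino-acid classes used for the similarity score.
similarity_groups:
  aliphatic: GAVLI
  aromatic: FYW
  sulfur: CM
  hydroxyl: ST
  basic: KRH
  acid_amide: DENQ
  proline: P

# Phylogenetic clan of each IGHV family.
clan_families:
  IGHV1: I
  IGHV5: I
  IGHV7: I
  IGHV2: II
  IGHV4: II
  IGHV6: II
  IGHV3: III

# Demonstration subset definitions (synthetic patterns). Replace with the
# curated major-subset motifs for real analyses; see subsets_template.yaml
# for the IGHV1-relevant subset skeleton.
subsets:
  - subset_id: "#D1"
    cdr3_length_aa: 13
    pattern: "ARDLGW"
    pattern_offset: 2
    clan: I
    typical_v_genes: [IGHV1-69]
    min_identity: 0.5
    min_similarity: 0.7
  - subset_id: "#D2"
    cdr3_length_aa: 17
    pattern: "GYYDSSG"
    pattern_offset: 4
    clan: I
    typical_v_genes: [IGHV1-2, IGHV1-18]
    min_identity: 0.5
    min_similarity: 0.7

clustering:
  mode: per_group        # one threshold per (sample, population) group
  bandwidth: 0.02
  grid_size: 512
  fallback_threshold: 0.15
  min_distances: 50
  fixed_threshold: null  # set to bypass threshold detection

stereotype_scan:
  full_cdr3: false           # score the pattern window only
  representatives_only: false

shm:
  cutoff_pct: 1.0

stats:
  mc_iterations: 10000
  decimals: 2

simulation:
  seed: 0
  n_background_clones: 300
  clone_size_geometric_p: 0.6666666666666666
  within_clone_divergence: 0.05
  between_clone_min_divergence: 0.40
  shm_mutated_fraction: 0.3
  shm_identity_range_mutated: [92.0, 98.9]
  junction_length_weights:
    39: 0.2
    45: 0.3
    51: 0.3
    57: 0.2
  isotype_weights:
    IGHM: 0.9
    IGHG: 0.1
  population_weights:
    FM: 1.0
  sample_id: SIM1
  duplicate_zipf_a: 2.0
  duplicate_max: 1000
  emit_v_sequences: false
  v_length: 300
  max_rejection_tries: 5000
  spikes:
    - subset_id: "#D1"
      n_clones: 8
      typical_fraction: 0.75
      identity_level: 1.0
      similarity_level: 1.0
    - subset_id: "#D2"
      n_clones: 5
      typical_fraction: 0.6
      identity_level: 1.0
      similarity_level: 1.0
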