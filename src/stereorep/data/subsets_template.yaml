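# Template for the nine IGHV1-relevant CLL major stereotyped subsets.
# Consensus patterns, offsets and CDR3 lengths must be completed from the
# curated stereotype subset literature before real-data use: entries with
# a null pattern are skipped at load time. typical_v_genes lists the IGHV
# genes characteristically used by CLL clones of each subset; complete or
# amend them from the same source.

subsets:
  - subset_id: "#1"
    cdr3_length_aa: 13
    pattern: null
    pattern_offset: 0
    clan: I
    typical_v_genes: [IGHV1-2, IGHV1-3, IGHV1-18, IGHV5-a, IGHV7-4-1]
  - subset_id: "#1-99"
    cdr3_length_aa: 13
    pattern: null
    pattern_offset: 0
    clan: I
    typical_v_genes: [IGHV1-2]
  - subset_id: "#3"
    cdr3_length_aa: 22
    pattern: null
    pattern_offset: 0
    clan: I
    typical_v_genes: [IGHV1-69]
  - subset_id: "#5"
    cdr3_length_aa: 20
    pattern: null
    pattern_offset: 0
    clan: I
    typical_v_genes: [IGHV1-69]
  - subset_id: "#6"
    cdr3_length_aa: 21
    pattern: null
    pattern_offset: 0
    clan: I
    typical_v_genes: [IGHV1-69]
  - subset_id: "#7H"
    cdr3_length_aa: 23
    pattern: null
    pattern_offset: 0
    clan: I
    typical_v_genes: [IGHV1-69]
  - subset_id: "#12"
    cdr3_length_aa: 19
    pattern: null
    pattern_offset: 0
    clan: I
    typical_v_genes: [IGHV1-69]
  - subset_id: "#28A"
    cdr3_length_aa: 15
    pattern: null
    pattern_offset: 0
    clan: I
    typical_v_genes: [IGHV1-69]
  - subset_id: "#59"
    cdr3_length_aa: 13
    pattern: null
    pattern_offset: 0
    clan: I
    typical_v_genes: [IGHV1-58]
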