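# stereorep

Detection of CLL-biased stereotyped immunoglobulin heavy-chain
rearrangements in normal B-cell repertoires. The package implements the
full analysis chain on annotated AIRR-dialect rearrangement tables:

- **repertoire I/O** (`stereorep.io`) — AIRR Rearrangement TSV reading and
  writing, record validation, productivity / IGHV-family / isotype filters
  with per-reason rejection tallies.
- **stereotype matching** (`stereorep.stereotypes`) — assignment of VH
  CDR3s to configured stereotyped subsets under exact-length, clan,
  window identity (>= 50%) and physicochemical similarity (>= 70%) rules,
  plus typical / non-typical IGHV usage classification.
- **clonal clustering** (`stereorep.clones`) — partitioning by (V gene,
  J gene, junction length), distance-to-nearest computation, automatic
  threshold detection from the density valley between the two main modes
  of the distance distribution, single-linkage clone families, and
  representative selection by mRNA duplicate count.
- **SHM status** (`stereorep.shm`) — germline identity of the V segment
  (substitution-only, ambiguity-aware) and mutated/unmutated calls at a
  configurable cutoff (default 1%).
- **cohort statistics** (`stereorep.stats`) — exact frequency tables with
  half-away-from-zero rounding, Fisher exact and Monte Carlo Fisher tests,
  Kruskal-Wallis, Dunn post-hoc with Bonferroni correction, and the
  Cochran-Mantel-Haenszel test.
- **synthetic repertoires** (`stereorep.simulate`) — generation of
  annotated repertoires with planted clonal structure (within-clone
  divergence below d1, between-clone above d2), stereotyped spike-ins at
  controlled identity/similarity levels, SHM levels and duplicate counts,
  together with ground truth and recovery metrics.
- **pipeline** (`stereorep.pipeline`, `stereorep.cli`) — a reproducible
  filter → stereotype scan → clustering → collapse → statistics run with
  a manifest; byte-identical outputs for a fixed seed.

## CLI

```bash
# generate a synthetic repertoire (uses the packaged demo configuration)
stereorep simulate --seed 4 --out sim/

# run the pipeline; --germline is optional (annotated v_identity is used
# when present, otherwise identity is recomputed from v_sequence)
stereorep run --input sim/repertoire.tsv --config my_config.yaml \
    --seed 4 --out run/

# score predictions against the simulated ground truth
stereorep evaluate --predicted run/annotated.tsv --truth sim/truth.tsv
```

All configuration lives in one YAML file merged over
`src/stereorep/data/default_config.yaml`: filters, column-name mapping,
similarity classes, clan table, subset definitions, clustering and SHM
parameters, and simulation settings. `src/stereorep/data/subsets_template.yaml`
holds a skeleton for the nine IGHV1-relevant major subsets whose consensus
patterns must be completed from the curated stereotype literature; the
packaged demo subsets are synthetic.

Pipeline outputs (`run/`): `annotated.tsv` (input plus subset, identity /
similarity, typical flag, SHM status, clone id and representative flag),
`clones.tsv`, `frequency_by_subset.tsv`, `frequency_by_population.tsv`,
`stats.json`, `manifest.json` (stage counts, per-group thresholds, input
digests) and `run.log`.

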