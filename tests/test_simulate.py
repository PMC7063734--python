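import dataclasses

import pytest

from stereorep.clones import (
    cluster_clones,
    normalized_hamming,
    partition_records,
)
from stereorep.io import translate_junction, write_rearrangements
from stereorep.shm import germline_identity
from stereorep.simulate import (
    GroundTruth,
    SimulationConfig,
    SpikeConfig,
    evaluate_recovery,
    generate_germline_reference,
    generate_repertoire,
)
from stereorep.stereotypes import assign_subset


@pytest.fixture
def small_config(demo_subsets):
    return SimulationConfig(
        seed=11,
        n_background_clones=60,
        spikes=(
            SpikeConfig("#A", n_clones=5, typical_fraction=1.0),
            SpikeConfig("#B", n_clones=4, typical_fraction=0.5),
        ),
    )


class TestGenerate:
    def test_no_spikes_all_none(self):
        cfg = SimulationConfig(seed=1, n_background_clones=20)
        _, truth = generate_repertoire(cfg)
        assert (truth.per_sequence["true_subset_id"] == "").all()

    def test_exact_spike_matches_consensus(self, demo_subsets):
        cfg = SimulationConfig(
            seed=2,
            n_background_clones=5,
            spikes=(SpikeConfig("#A", n_clones=3, identity_level=1.0,
                                similarity_level=1.0),),
        )
        records, truth = generate_repertoire(cfg, demo_subsets)
        sd = demo_subsets[0]
        spiked = set(
            truth.per_sequence.loc[
                truth.per_sequence["true_subset_id"] == "#A", "sequence_id"
            ]
        )
        assert spiked
        for rec in records:
            if rec.sequence_id in spiked:
                assert rec.cdr3_aa[sd.window] == sd.pattern

    def test_determinism_byte_identical(self, tmp_path, small_config,
                                        demo_subsets):
        paths = []
        for name in ("a.tsv", "b.tsv"):
            records, _ = generate_repertoire(
                dataclasses.replace(small_config), demo_subsets
            )
            path = tmp_path / name
            write_rearrangements(records, path)
            paths.append(path)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_junctions_translate_without_stops(self, small_config,
                                               demo_subsets):
        records, _ = generate_repertoire(small_config, demo_subsets)
        for rec in records:
            aa = translate_junction(rec.junction_nt)
            assert "*" not in aa
            assert aa[0] == "C" and aa[-1] == "W"
            assert aa[1:-1] == rec.cdr3_aa

    def test_junction_lengths_from_support(self):
        cfg = SimulationConfig(
            seed=3, n_background_clones=50,
            junction_length_weights={39: 0.5, 45: 0.5},
        )
        records, _ = generate_repertoire(cfg)
        assert {len(r.junction_nt) for r in records} <= {39, 45}

    def test_unknown_spike_subset_rejected(self, demo_subsets):
        cfg = SimulationConfig(
            seed=1, n_background_clones=1,
            spikes=(SpikeConfig("#missing", n_clones=1),),
        )
        with pytest.raises(ValueError, match="#missing"):
            generate_repertoire(cfg, demo_subsets)

    def test_duplicate_counts_positive(self, small_config, demo_subsets):
        records, _ = generate_repertoire(small_config, demo_subsets)
        assert all(r.duplicate_count >= 1 for r in records)
        assert all(r.productive for r in records)

    def test_invalid_divergence_order(self):
        with pytest.raises(ValueError):
            SimulationConfig(within_clone_divergence=0.5,
                             between_clone_min_divergence=0.4)


class TestPlantedStructure:
    def test_within_below_between_above(self, demo_subsets):
        cfg = SimulationConfig(seed=4, n_background_clones=80)
        records, truth = generate_repertoire(cfg, demo_subsets)
        d1, d2 = truth.threshold_window
        by_id = {r.sequence_id: r for r in records}
        clones = truth.per_sequence.groupby("true_clone_id")["sequence_id"]
        junction_of = {
            cid: [by_id[s].junction_nt for s in members]
            for cid, members in clones
        }
        for cid, juncs in junction_of.items():
            for i in range(len(juncs)):
                for j in range(i + 1, len(juncs)):
                    assert normalized_hamming(juncs[i], juncs[j]) <= d1
        # between clones, within a partition
        parts = partition_records(records)
        clone_of = dict(
            zip(truth.per_sequence["sequence_id"],
                truth.per_sequence["true_clone_id"])
        )
        for members in parts.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    a, b = members[i], members[j]
                    if clone_of[a.sequence_id] != clone_of[b.sequence_id]:
                        assert (
                            normalized_hamming(a.junction_nt, b.junction_nt)
                            > d2
                        )

    def test_any_threshold_in_window_recovers_clones(self, demo_subsets):
        cfg = SimulationConfig(seed=5, n_background_clones=80)
        records, truth = generate_repertoire(cfg, demo_subsets)
        parts = partition_records(records)
        d1, d2 = truth.threshold_window
        for t in (d1 + 0.01, 0.2, d2 - 0.01):
            fams = cluster_clones(parts, t)
            metrics = evaluate_recovery(
                {r.sequence_id: None for r in records}, fams, truth,
                threshold=t,
            )
            assert metrics["clone_ari"] == 1.0
            assert metrics["threshold_in_window"] is True


class TestSpikeScoring:
    def test_identity_within_discretization(self, demo_subsets, groups,
                                            clans):
        sd = demo_subsets[1]  # pattern length 7
        level = 0.8
        cfg = SimulationConfig(
            seed=6, n_background_clones=1,
            spikes=(SpikeConfig("#B", n_clones=6, identity_level=level,
                                similarity_level=1.0),),
        )
        records, truth = generate_repertoire(cfg, demo_subsets)
        spiked = set(
            truth.per_sequence.loc[
                truth.per_sequence["true_subset_id"] == "#B", "sequence_id"
            ]
        )
        w = len(sd.pattern)
        for rec in records:
            if rec.sequence_id not in spiked:
                continue
            res = assign_subset(rec.cdr3_aa, rec.v_gene, demo_subsets,
                                clans, groups)
            assert res.subset_id == "#B"
            assert abs(res.identity - level) <= 1.0 / w + 1e-9
            assert res.similarity == 1.0


class TestShmEmission:
    def test_v_sequences_match_planted_counts(self):
        cfg = SimulationConfig(
            seed=7, n_background_clones=30, emit_v_sequences=True,
            v_length=300,
        )
        germ = generate_germline_reference(cfg.v_gene_usage, 300, seed=7)
        records, truth = generate_repertoire(cfg, germline_v=germ)
        subs = dict(
            zip(truth.per_sequence["sequence_id"],
                truth.per_sequence["v_substitutions"])
        )
        for rec in records:
            k = int(subs[rec.sequence_id])
            ident = germline_identity(rec.v_sequence, germ[rec.v_gene])
            assert ident == pytest.approx(100.0 * (1 - k / 300))
            assert rec.v_identity_pct == pytest.approx(ident)


class TestEvaluateRecovery:
    def _perfect(self, demo_subsets):
        cfg = SimulationConfig(
            seed=8, n_background_clones=30,
            spikes=(SpikeConfig("#A", n_clones=4),),
        )
        records, truth = generate_repertoire(cfg, demo_subsets)
        tdf = truth.per_sequence
        subset = {
            s: (sub or None)
            for s, sub in zip(tdf["sequence_id"], tdf["true_subset_id"])
        }
        clone = dict(zip(tdf["sequence_id"], tdf["true_clone_id"]))
        return subset, clone, truth

    def test_perfect_predictions(self, demo_subsets):
        subset, clone, truth = self._perfect(demo_subsets)
        m = evaluate_recovery(subset, clone, truth)
        assert m["stereotype_sensitivity"] == 1.0
        assert m["stereotype_specificity"] == 1.0
        assert m["clone_ari"] == 1.0

    def test_all_none_gives_zero_sensitivity(self, demo_subsets):
        subset, clone, truth = self._perfect(demo_subsets)
        m = evaluate_recovery({s: None for s in subset}, clone, truth)
        assert m["stereotype_sensitivity"] == 0.0
        assert m["stereotype_specificity"] == 1.0

    def test_ari_label_invariance(self, demo_subsets):
        subset, clone, truth = self._perfect(demo_subsets)
        renamed = {s: f"relabeled-{c}" for s, c in clone.items()}
        m = evaluate_recovery(subset, renamed, truth)
        assert m["clone_ari"] == 1.0

    def test_id_mismatch_rejected(self, demo_subsets):
        subset, clone, truth = self._perfect(demo_subsets)
        subset.pop(next(iter(subset)))
        with pytest.raises(ValueError, match="sequence_id"):
            evaluate_recovery(subset, clone, truth)


class TestGroundTruthIO:
    def test_round_trip(self, tmp_path, demo_subsets):
        cfg = SimulationConfig(
            seed=9, n_background_clones=10,
            spikes=(SpikeConfig("#A", n_clones=2),),
        )
        _, truth = generate_repertoire(cfg, demo_subsets)
        path = tmp_path / "truth.tsv"
        truth.write(path)
        back = GroundTruth.read(path, truth.threshold_window)
        assert list(back.per_sequence["sequence_id"]) == list(
            truth.per_sequence["sequence_id"]
        )
        assert list(back.per_sequence["true_subset_id"]) == list(
            truth.per_sequence["true_subset_id"]
        )
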