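"""End-to-end orchestration.

Stage order mirrors the analysis workflow: record filtering, stereotype
scan over all kept records, clonal clustering with per-group thresholds,
collapse to clone representatives, then representative-level SHM calls,
frequency tables and statistics. A run is a pure function of
(inputs, config, seed): outputs are byte-stable across invocations.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from stereorep.clones import (
    DistanceThreshold,
    cluster_clones,
    find_threshold,
    nearest_neighbor_distances,
    partition_records,
    select_representative,
)
from stereorep.config import PipelineConfig
from stereorep.io import (
    RearrangementRecord,
    filter_records,
    read_rearrangements,
    records_to_frame,
)
from stereorep.shm import germline_identity, mutation_status
from stereorep.simulate import read_germline_fasta
from stereorep.stats import (
    compare_subset_distributions,
    fisher_exact_2x2,
    frequency_table,
)
from stereorep.stereotypes import assign_subset

logger = logging.getLogger(__name__)

_LOG_FORMAT = "%(levelname)s %(name)s: %(message)s"  # timestamp-free: runs must be byte-reproducible


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    inputs: dict[str, str]
    stage_counts: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, dict] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "inputs": self.inputs,
            "stage_counts": self.stage_counts,
            "thresholds": self.thresholds,
            "outputs": self.outputs,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _shm_identity(
    rec: RearrangementRecord, germlines: dict[str, str] | None
) -> float | None:
    """Annotated v_identity takes precedence over recomputation."""
    if rec.v_identity_pct is not None:
        return rec.v_identity_pct
    if germlines and rec.v_sequence and rec.v_gene in germlines:
        germ = germlines[rec.v_gene]
        if len(germ) == len(rec.v_sequence):
            return germline_identity(rec.v_sequence, germ)
    return None


def run_pipeline(
    input_path: str | Path,
    germline_path: str | Path | None,
    config: PipelineConfig,
    out_dir: str | Path,
    seed: int = 0,
) -> RunManifest:
    """Run filter -> stereotype scan -> clonal clustering -> collapse ->
    representative-level reports; write all outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from stereorep import __version__

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter(_LOG_FORMAT))
    root = logging.getLogger("stereorep")
    root.addHandler(handler)
    try:
        return _run(input_path, germline_path, config, out, seed, __version__)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(
    input_path: str | Path,
    germline_path: str | Path | None,
    config: PipelineConfig,
    out: Path,
    seed: int,
    version: str,
) -> RunManifest:
    manifest = RunManifest(
        version=version,
        seed=seed,
        config_hash=config.digest(),
        inputs={Path(input_path).name: _sha256(input_path)},
    )
    if germline_path is not None:
        manifest.inputs[Path(germline_path).name] = _sha256(germline_path)
    germlines = (
        read_germline_fasta(germline_path) if germline_path else None
    )

    # -- stage: read --------------------------------------------------------
    logger.info("stage read: %s", Path(input_path).name)
    result = read_rearrangements(input_path, config.column_map)
    manifest.stage_counts["read"] = len(result.records)
    manifest.stage_counts["rejected_rows"] = len(result.rejected)
    if result.rejected:
        pd.DataFrame(
            [
                {"row_index": r.row_index, "sequence_id": r.sequence_id,
                 "reason": r.reason}
                for r in result.rejected
            ]
        ).to_csv(out / "rejected.tsv", sep="\t", index=False)
        manifest.outputs.append("rejected.tsv")

    # -- stage: filter ------------------------------------------------------
    kept, tally = filter_records(result.records, config.filter)
    logger.info("stage filter: kept %d, rejected %s", len(kept), dict(tally))
    manifest.stage_counts["filtered"] = len(kept)
    for reason, n in sorted(tally.items()):
        manifest.stage_counts[f"filter_rejected_{reason}"] = n

    if not kept:
        logger.warning("no records after filtering; writing empty reports")
        _write_empty(out, manifest)
        manifest.write(out / "manifest.json")
        return manifest

    # -- stage: stereotype scan ---------------------------------------------
    assignments: dict[str, object] = {}
    if config.subsets and not config.scan.representatives_only:
        for rec in kept:
            assignments[rec.sequence_id] = assign_subset(
                rec.cdr3_aa, rec.v_gene, config.subsets,
                clans=config.clans, groups=config.groups,
                full_cdr3=config.scan.full_cdr3,
                sequence_id=rec.sequence_id,
            )
    manifest.stage_counts["scanned"] = len(assignments)

    # -- stage: clonal clustering ------------------------------------------
    groups_of_records: dict[str, list[RearrangementRecord]] = {}
    if config.clustering.mode == "per_group":
        for rec in kept:
            key = f"{rec.sample_id}|{rec.population_label}"
            groups_of_records.setdefault(key, []).append(rec)
    else:
        groups_of_records["global"] = list(kept)

    records_by_id = {r.sequence_id: r for r in kept}
    families = []
    for gname in sorted(groups_of_records):
        grecs = groups_of_records[gname]
        parts = partition_records(grecs)
        if config.clustering.fixed_threshold is not None:
            thr = DistanceThreshold(
                config.clustering.fixed_threshold, "fixed"
            )
        else:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                dists = nearest_neighbor_distances(parts)
            try:
                thr = find_threshold(
                    dists,
                    bandwidth=config.clustering.bandwidth,
                    grid_size=config.clustering.grid_size,
                    fallback=config.clustering.fallback_threshold,
                    min_distances=config.clustering.min_distances,
                )
            except ValueError:
                logger.info(
                    "group %s: too few distances, using fallback", gname
                )
                thr = DistanceThreshold(
                    config.clustering.fallback_threshold, "fixed"
                )
        logger.info(
            "group %s: threshold %.4f (%s)", gname, thr.value, thr.method
        )
        manifest.thresholds[gname] = {
            "value": thr.value, "method": thr.method,
        }
        for fam in cluster_clones(parts, thr):
            rep = select_representative(fam, records_by_id)
            families.append(
                fam.__class__(
                    clone_id=f"{gname}|{fam.clone_id}",
                    key=fam.key,
                    member_ids=fam.member_ids,
                    representative_id=rep,
                )
            )
    families.sort(key=lambda f: f.clone_id)
    manifest.stage_counts["clone_families"] = len(families)
    manifest.stage_counts["representatives"] = len(families)

    clone_of = {
        sid: fam.clone_id for fam in families for sid in fam.member_ids
    }
    rep_ids = {fam.representative_id for fam in families}

    # representatives-only scan mode
    if config.subsets and config.scan.representatives_only:
        for sid in sorted(rep_ids):
            rec = records_by_id[sid]
            assignments[sid] = assign_subset(
                rec.cdr3_aa, rec.v_gene, config.subsets,
                clans=config.clans, groups=config.groups,
                full_cdr3=config.scan.full_cdr3, sequence_id=sid,
            )
        manifest.stage_counts["scanned"] = len(assignments)

    # -- stage: annotate ----------------------------------------------------
    frame = records_to_frame(kept)
    cutoff = config.shm_cutoff_pct
    shm_by_id = {}
    for rec in kept:
        ident = _shm_identity(rec, germlines)
        shm_by_id[rec.sequence_id] = (
            "" if ident is None else mutation_status(ident, cutoff).value
        )
    frame["subset_id"] = [
        (assignments[s].subset_id or "") if s in assignments else ""
        for s in frame["sequence_id"]
    ]
    frame["stereo_identity"] = [
        _fmt(assignments[s].identity) if s in assignments else ""
        for s in frame["sequence_id"]
    ]
    frame["stereo_similarity"] = [
        _fmt(assignments[s].similarity) if s in assignments else ""
        for s in frame["sequence_id"]
    ]
    frame["stereo_typical"] = [
        _fmt_bool(assignments[s].typical) if s in assignments else ""
        for s in frame["sequence_id"]
    ]
    frame["shm_status"] = [shm_by_id[s] for s in frame["sequence_id"]]
    frame["shm_cutoff"] = format(cutoff, "g")
    frame["clone_id"] = [clone_of[s] for s in frame["sequence_id"]]
    frame["is_representative"] = [
        "T" if s in rep_ids else "F" for s in frame["sequence_id"]
    ]
    frame.to_csv(out / "annotated.tsv", sep="\t", index=False)
    manifest.outputs.append("annotated.tsv")

    clone_frame = pd.DataFrame(
        [
            {
                "clone_id": fam.clone_id,
                "v_gene": fam.key.v_gene,
                "j_gene": fam.key.j_gene,
                "junction_length_nt": fam.key.junction_length_nt,
                "size": len(fam.member_ids),
                "representative_id": fam.representative_id,
            }
            for fam in families
        ]
    )
    clone_frame.to_csv(out / "clones.tsv", sep="\t", index=False)
    manifest.outputs.append("clones.tsv")

    # -- stage: representative-level reports --------------------------------
    rep_rows = frame[frame["is_representative"] == "T"]
    total_clones = len(families)
    subset_counts = {
        sd.subset_id: int((rep_rows["subset_id"] == sd.subset_id).sum())
        for sd in config.subsets
    }
    reports: dict[str, object] = {}
    if subset_counts:
        freq = frequency_table(
            subset_counts, total_clones,
            decimals=config.report_decimals, grouping="by_subset",
        )
        freq.to_frame().to_csv(
            out / "frequency_by_subset.tsv", sep="\t", index=False
        )
        manifest.outputs.append("frequency_by_subset.tsv")
        reports["cbs_total"] = int(sum(subset_counts.values()))
        reports["total_clones"] = total_clones

    pop_table = (
        rep_rows.assign(is_cbs=rep_rows["subset_id"] != "")
        .groupby(["population_label", "is_cbs"])
        .size()
        .unstack(fill_value=0)
    )
    pop_table.to_csv(out / "frequency_by_population.tsv", sep="\t")
    manifest.outputs.append("frequency_by_population.tsv")

    stats_results = _run_stats(rep_rows, config, seed)
    (out / "stats.json").write_text(
        json.dumps(stats_results, indent=2, sort_keys=True, default=str)
        + "\n"
    )
    manifest.outputs.append("stats.json")

    manifest.outputs.append("manifest.json")
    manifest.outputs.sort()
    manifest.write(out / "manifest.json")
    logger.info("run complete: %d clone families", total_clones)
    return manifest


def _run_stats(rep_rows: pd.DataFrame, config: PipelineConfig, seed: int) -> dict:
    """Representative-level statistics; degenerate tables are reported as
    skipped rather than failing the run."""
    results: dict[str, object] = {}
    is_cbs = rep_rows["subset_id"] != ""
    shm_known = rep_rows["shm_status"] != ""
    try:
        table = [
            [
                int((is_cbs & (rep_rows["shm_status"] == "unmutated")).sum()),
                int((is_cbs & (rep_rows["shm_status"] == "mutated")).sum()),
            ],
            [
                int((~is_cbs & shm_known
                     & (rep_rows["shm_status"] == "unmutated")).sum()),
                int((~is_cbs & shm_known
                     & (rep_rows["shm_status"] == "mutated")).sum()),
            ],
        ]
        results["cbs_vs_shm_fisher"] = fisher_exact_2x2(table).to_dict()
    except ValueError as exc:
        results["cbs_vs_shm_fisher"] = {"skipped": str(exc)}

    pops = sorted(rep_rows["population_label"].unique())
    subsets = sorted(s for s in rep_rows["subset_id"].unique() if s)
    if len(pops) >= 2 and len(subsets) >= 2:
        try:
            a, b = pops[0], pops[1]
            counts_a = {
                s: int(((rep_rows["population_label"] == a)
                        & (rep_rows["subset_id"] == s)).sum())
                for s in subsets
            }
            counts_b = {
                s: int(((rep_rows["population_label"] == b)
                        & (rep_rows["subset_id"] == s)).sum())
                for s in subsets
            }
            results["subset_distribution_fisher_mc"] = (
                compare_subset_distributions(
                    counts_a, counts_b,
                    iterations=max(1000, config.stats_mc_iterations),
                    seed=seed,
                ).to_dict()
            )
        except ValueError as exc:
            results["subset_distribution_fisher_mc"] = {"skipped": str(exc)}
    return results


def _fmt(value: float | None) -> str:
    return "" if value is None else format(value, ".6g")


def _fmt_bool(value: bool | None) -> str:
    if value is None:
        return ""
    return "T" if value else "F"


def _write_empty(out: Path, manifest: RunManifest) -> None:
    empty_cols = {
        "annotated.tsv": ["sequence_id"],
        "clones.tsv": ["clone_id"],
    }
    for name, cols in empty_cols.items():
        pd.DataFrame(columns=cols).to_csv(out / name, sep="\t", index=False)
        manifest.outputs.append(name)
    (out / "stats.json").write_text("{}\n")
    manifest.outputs.append("stats.json")
    manifest.outputs.append("manifest.json")
    manifest.outputs.sort()
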