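"""YAML configuration: filters, column map, similarity classes, clan
table, subset definitions, clustering/scan/SHM parameters and simulation
settings, merged over packaged defaults."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from stereorep.io import FilterCriteria
from stereorep.simulate import SimulationConfig, SpikeConfig
from stereorep.stereotypes import ClanTable, SimilarityGroups, SubsetDefinition


@dataclass(frozen=True)
class ClusteringParams:
    mode: str = "per_group"  # "per_group" or "global"
    bandwidth: float = 0.02
    grid_size: int = 512
    fallback_threshold: float = 0.15
    min_distances: int = 50
    fixed_threshold: float | None = None

    def __post_init__(self):
        if self.mode not in {"per_group", "global"}:
            raise ValueError(f"unknown clustering mode {self.mode!r}")


@dataclass(frozen=True)
class ScanParams:
    full_cdr3: bool = False
    representatives_only: bool = False


@dataclass
class PipelineConfig:
    filter: FilterCriteria = field(default_factory=FilterCriteria)
    column_map: dict[str, str] = field(default_factory=dict)
    groups: SimilarityGroups = field(default_factory=SimilarityGroups)
    clans: ClanTable = field(default_factory=ClanTable)
    subsets: list[SubsetDefinition] = field(default_factory=list)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)
    scan: ScanParams = field(default_factory=ScanParams)
    shm_cutoff_pct: float = 1.0
    stats_mc_iterations: int = 10_000
    report_decimals: int = 2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    raw: dict = field(default_factory=dict, repr=False)

    def digest(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _default_raw() -> dict:
    text = (
        resources.files("stereorep")
        .joinpath("data/default_config.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def _merge(base: dict, override: Mapping[str, Any]) -> dict:
    out = dict(base)
    for key, value in override.items():
        if (
            key in out
            and isinstance(out[key], dict)
            and isinstance(value, Mapping)
        ):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def parse_subset(entry: Mapping[str, Any]) -> SubsetDefinition:
    return SubsetDefinition(
        subset_id=str(entry["subset_id"]),
        cdr3_length_aa=int(entry["cdr3_length_aa"]),
        pattern=str(entry["pattern"]),
        pattern_offset=int(entry["pattern_offset"]),
        clan=str(entry["clan"]),
        typical_v_genes=frozenset(entry["typical_v_genes"]),
        min_identity=float(entry.get("min_identity", 0.5)),
        min_similarity=float(entry.get("min_similarity", 0.7)),
    )


def _parse_simulation(raw: Mapping[str, Any]) -> SimulationConfig:
    kwargs: dict[str, Any] = {}
    simple = (
        "seed", "n_background_clones", "clone_size_geometric_p",
        "within_clone_divergence", "between_clone_min_divergence",
        "shm_mutated_fraction", "sample_id", "duplicate_zipf_a",
        "duplicate_max", "emit_v_sequences", "v_length",
        "max_rejection_tries",
    )
    for key in simple:
        if key in raw:
            kwargs[key] = raw[key]
    for key in ("v_gene_usage", "j_gene_usage", "isotype_weights",
                "population_weights"):
        if key in raw:
            kwargs[key] = dict(raw[key])
    if "junction_length_weights" in raw:
        kwargs["junction_length_weights"] = {
            int(k): float(v) for k, v in raw["junction_length_weights"].items()
        }
    if "shm_identity_range_mutated" in raw:
        lo, hi = raw["shm_identity_range_mutated"]
        kwargs["shm_identity_range_mutated"] = (float(lo), float(hi))
    if "spikes" in raw:
        kwargs["spikes"] = tuple(
            SpikeConfig(
                subset_id=str(s["subset_id"]),
                n_clones=int(s["n_clones"]),
                typical_fraction=float(s.get("typical_fraction", 1.0)),
                identity_level=float(s.get("identity_level", 1.0)),
                similarity_level=float(s.get("similarity_level", 1.0)),
            )
            for s in raw["spikes"]
        )
    return SimulationConfig(**kwargs)


def build_config(raw: Mapping[str, Any]) -> PipelineConfig:
    raw = _merge(_default_raw(), raw)
    filt_raw = raw.get("filter", {})
    filt = FilterCriteria(
        require_productive=bool(filt_raw.get("require_productive", True)),
        allowed_v_families=frozenset(
            filt_raw.get("allowed_v_families", ["IGHV1"])
        ),
        allowed_isotypes=frozenset(
            filt_raw.get("allowed_isotypes", ["IGHM", "IGHG"])
        ),
    )
    groups = SimilarityGroups(dict(raw.get("similarity_groups", {})))
    clans = ClanTable(
        families=dict(raw.get("clan_families", {})),
        gene_overrides=dict(raw.get("clan_gene_overrides", {}) or {}),
    )
    subsets = []
    for entry in raw.get("subsets", []) or []:
        if entry.get("pattern") in (None, ""):
            continue  # template placeholder awaiting completion
        subsets.append(parse_subset(entry))
    clus_raw = raw.get("clustering", {})
    clustering = ClusteringParams(
        mode=clus_raw.get("mode", "per_group"),
        bandwidth=float(clus_raw.get("bandwidth", 0.02)),
        grid_size=int(clus_raw.get("grid_size", 512)),
        fallback_threshold=float(clus_raw.get("fallback_threshold", 0.15)),
        min_distances=int(clus_raw.get("min_distances", 50)),
        fixed_threshold=(
            None if clus_raw.get("fixed_threshold") is None
            else float(clus_raw["fixed_threshold"])
        ),
    )
    scan_raw = raw.get("stereotype_scan", {})
    scan = ScanParams(
        full_cdr3=bool(scan_raw.get("full_cdr3", False)),
        representatives_only=bool(
            scan_raw.get("representatives_only", False)
        ),
    )
    stats_raw = raw.get("stats", {})
    return PipelineConfig(
        filter=filt,
        column_map=dict(raw.get("column_map", {}) or {}),
        groups=groups,
        clans=clans,
        subsets=subsets,
        clustering=clustering,
        scan=scan,
        shm_cutoff_pct=float(raw.get("shm", {}).get("cutoff_pct", 1.0)),
        stats_mc_iterations=int(stats_raw.get("mc_iterations", 10_000)),
        report_decimals=int(stats_raw.get("decimals", 2)),
        simulation=_parse_simulation(raw.get("simulation", {}) or {}),
        raw=dict(raw),
    )


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML configuration merged over the packaged defaults."""
    if path is None:
        return build_config({})
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return build_config(user)
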