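"""Synthetic annotated repertoires with planted ground truth.

Generates AIRR-dialect rearrangement records with (a) multinomial V/J
usage, (b) a junction-length distribution, (c) clonal lineages whose
within-clone junction divergence sits below a planted threshold d1 while
between-clone divergence sits above d2, (d) stereotyped spike-in clones
built from subset consensus patterns at controlled identity/similarity,
(e) per-sequence SHM levels, and (f) mRNA duplicate counts. Everything is
reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import unambiguous_dna_by_id
from sklearn.metrics import adjusted_rand_score

from stereorep.io import RearrangementRecord, cdr3_from_junction
from stereorep.stereotypes import (
    ClanTable,
    SimilarityGroups,
    StereotypeAssignment,
    SubsetDefinition,
)
from stereorep.clones import CloneFamily

_STANDARD_TABLE = unambiguous_dna_by_id[1]
# aa -> sorted list of codons (deterministic ordering matters for replay)
_CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD_TABLE.forward_table.items()):
    _CODONS_FOR_AA.setdefault(aa, []).append(codon)
_STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)
_NT = "ACGT"

DEFAULT_V_USAGE = {
    "IGHV1-2": 0.18, "IGHV1-3": 0.08, "IGHV1-8": 0.10, "IGHV1-18": 0.14,
    "IGHV1-24": 0.06, "IGHV1-46": 0.10, "IGHV1-58": 0.04, "IGHV1-69": 0.22,
    "IGHV1-69-2": 0.03, "IGHV1-45": 0.05,
}
DEFAULT_J_USAGE = {"IGHJ4": 0.45, "IGHJ6": 0.30, "IGHJ3": 0.15, "IGHJ5": 0.10}
DEFAULT_JUNCTION_LENGTH_WEIGHTS = {39: 0.2, 45: 0.3, 51: 0.3, 57: 0.2}


@dataclass(frozen=True)
class SpikeConfig:
    """A batch of planted stereotyped clones for one subset."""

    subset_id: str
    n_clones: int
    typical_fraction: float = 1.0
    identity_level: float = 1.0
    similarity_level: float = 1.0

    def __post_init__(self):
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if not (0.0 <= self.typical_fraction <= 1.0):
            raise ValueError("typical_fraction out of [0, 1]")
        if not (0.0 <= self.identity_level <= self.similarity_level <= 1.0):
            raise ValueError(
                "need 0 <= identity_level <= similarity_level <= 1"
            )


@dataclass
class SimulationConfig:
    seed: int = 0
    n_background_clones: int = 300
    clone_size_geometric_p: float = 2.0 / 3.0  # mean 1.5
    v_gene_usage: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_V_USAGE)
    )
    j_gene_usage: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_J_USAGE)
    )
    junction_length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_JUNCTION_LENGTH_WEIGHTS)
    )
    within_clone_divergence: float = 0.05
    between_clone_min_divergence: float = 0.40
    shm_mutated_fraction: float = 0.3
    shm_identity_range_mutated: tuple[float, float] = (92.0, 98.9)
    spikes: Sequence[SpikeConfig] = ()
    isotype_weights: Mapping[str, float] = field(
        default_factory=lambda: {"IGHM": 0.9, "IGHG": 0.1}
    )
    population_weights: Mapping[str, float] = field(
        default_factory=lambda: {"FM": 1.0}
    )
    sample_id: str = "SIM1"
    duplicate_zipf_a: float = 2.0
    duplicate_max: int = 1000
    emit_v_sequences: bool = False
    v_length: int = 300
    max_rejection_tries: int = 5000

    def __post_init__(self):
        if not (0.0 <= self.within_clone_divergence
                < self.between_clone_min_divergence <= 1.0):
            raise ValueError("need 0 <= d1 < d2 <= 1")
        for name, weights in (
            ("v_gene_usage", self.v_gene_usage),
            ("j_gene_usage", self.j_gene_usage),
            ("junction_length_weights", self.junction_length_weights),
            ("isotype_weights", self.isotype_weights),
            ("population_weights", self.population_weights),
        ):
            total = sum(weights.values())
            if not weights or abs(total - 1.0) > 1e-6:
                raise ValueError(f"{name} weights must sum to 1, got {total}")
        for length in self.junction_length_weights:
            if length % 3 != 0 or length < 9:
                raise ValueError(
                    f"junction length {length} must be a multiple of 3, >= 9"
                )
        lo, hi = self.shm_identity_range_mutated
        if not (0.0 <= lo <= hi <= 100.0):
            raise ValueError("shm_identity_range_mutated out of order")


@dataclass
class GroundTruth:
    """Planted per-sequence labels and the dataset threshold window."""

    per_sequence: pd.DataFrame
    threshold_window: tuple[float, float]

    def write(self, path: str | Path) -> None:
        self.per_sequence.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(
        cls, path: str | Path, threshold_window: tuple[float, float]
    ) -> "GroundTruth":
        df = pd.read_csv(path, sep="\t", dtype={"true_subset_id": str})
        df["true_subset_id"] = df["true_subset_id"].fillna("")
        return cls(df, threshold_window)


class RejectionBudgetError(RuntimeError):
    """Founder placement failed; advise larger junctions or fewer clones."""


def _choice(rng: np.random.Generator, weights: Mapping) -> object:
    keys = list(weights)
    probs = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def _random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(_NT[i] for i in rng.integers(0, 4, 3))
        if codon not in _STOP_CODONS:
            return codon


def _codon_for(rng: np.random.Generator, aa: str) -> str:
    codons = _CODONS_FOR_AA[aa]
    return codons[rng.integers(0, len(codons))]


def _random_junction(rng: np.random.Generator, length_nt: int) -> str:
    """In-frame junction: 2nd-CYS codon + random non-stop codons + J-TRP."""
    n_mid = length_nt // 3 - 2
    first = "TGT" if rng.integers(0, 2) == 0 else "TGC"
    mid = "".join(_random_codon(rng) for _ in range(n_mid))
    return first + mid + "TGG"


def _mutate_junction(
    rng: np.random.Generator,
    junction: str,
    n_subs: int,
    frozen_codons: frozenset[int] = frozenset(),
) -> str:
    """Apply ``n_subs`` substitutions to middle codons (never the flanking
    conserved codons or ``frozen_codons``), avoiding stop codons."""
    n_codons = len(junction) // 3
    editable = [
        c for c in range(1, n_codons - 1) if c not in frozen_codons
    ]
    if n_subs > 0 and not editable:
        raise RejectionBudgetError("no editable codons for substitutions")
    seq = list(junction)
    mutated_positions: set[int] = set()
    tries = 0
    while len(mutated_positions) < n_subs:
        tries += 1
        if tries > 1000 * (n_subs + 1):
            raise RejectionBudgetError("cannot place junction substitutions")
        codon_idx = editable[rng.integers(0, len(editable))]
        pos = codon_idx * 3 + int(rng.integers(0, 3))
        if pos in mutated_positions:
            continue
        old = seq[pos]
        new = _NT[rng.integers(0, 4)]
        if new == old:
            continue
        codon = seq[codon_idx * 3 : codon_idx * 3 + 3]
        codon[pos % 3] = new
        if "".join(codon) in _STOP_CODONS:
            continue
        seq[pos] = new
        mutated_positions.add(pos)
    return "".join(seq)


def _hamming_nt(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _spike_cdr3(
    rng: np.random.Generator,
    subset: SubsetDefinition,
    spike: SpikeConfig,
    groups: SimilarityGroups,
) -> str:
    """CDR3 whose pattern window hits the configured identity/similarity
    levels exactly (up to 1/len(pattern) discretization)."""
    aa_pool = sorted("ACDEFGHIKLMNPQRSTVWY")
    cdr3 = [aa_pool[i] for i in rng.integers(0, 20, subset.cdr3_length_aa)]
    window = list(subset.pattern)
    w = len(window)
    n_match = round(spike.identity_level * w)
    n_similar = round(spike.similarity_level * w)
    n_same_group = n_similar - n_match  # changed residue, same class
    n_diff_group = w - n_similar
    changeable = [
        i for i in range(w)
        if len(_group_members(groups, window[i])) > 1
    ]
    if n_same_group > len(changeable):
        raise ValueError(
            f"subset {subset.subset_id}: pattern cannot host "
            f"{n_same_group} same-group changes"
        )
    rng.shuffle(changeable)
    same_pos = changeable[:n_same_group]
    remaining = [i for i in range(w) if i not in same_pos]
    rng.shuffle(remaining)
    diff_pos = remaining[:n_diff_group]
    for i in same_pos:
        members = [m for m in _group_members(groups, window[i])
                   if m != window[i]]
        window[i] = members[rng.integers(0, len(members))]
    for i in diff_pos:
        own = groups.group_of(subset.pattern[i])
        others = [a for a in aa_pool if groups.group_of(a) != own]
        window[i] = others[rng.integers(0, len(others))]
    cdr3[subset.window] = window
    return "".join(cdr3)


def _group_members(groups: SimilarityGroups, residue: str) -> str:
    return groups.classes[groups.group_of(residue)]


def _junction_for_cdr3(rng: np.random.Generator, cdr3: str) -> str:
    first = "TGT" if rng.integers(0, 2) == 0 else "TGC"
    body = "".join(_codon_for(rng, aa) for aa in cdr3)
    return first + body + "TGG"


def generate_germline_reference(
    v_genes: Sequence[str], length: int = 300, seed: int = 0
) -> dict[str, str]:
    """Deterministic random germline V reference, one sequence per gene."""
    rng = np.random.default_rng(seed)
    return {
        gene: "".join(_NT[i] for i in rng.integers(0, 4, length))
        for gene in sorted(v_genes)
    }


def write_germline_fasta(germlines: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(germlines):
            fh.write(f">{gene}\n{germlines[gene]}\n")


def read_germline_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def generate_repertoire(
    config: SimulationConfig,
    subset_defs: Sequence[SubsetDefinition] = (),
    germline_v: Mapping[str, str] | None = None,
    groups: SimilarityGroups | None = None,
    clans: ClanTable | None = None,
) -> tuple[list[RearrangementRecord], GroundTruth]:
    """Emit records plus planted ground truth.

    Background clone founders within a (V, J, length) partition are kept
    pairwise farther apart than d2 (with slack for member mutations) by
    rejection sampling; clone members carry at most floor(d1*L/2) junction
    substitutions so within-clone pairwise divergence stays below d1.
    """
    rng = np.random.default_rng(config.seed)
    groups = groups or SimilarityGroups()
    clans = clans or ClanTable()
    defs_by_id = {sd.subset_id: sd for sd in subset_defs}
    for spike in config.spikes:
        if spike.subset_id not in defs_by_id:
            raise ValueError(
                f"spike subset {spike.subset_id!r} has no definition"
            )
    if config.emit_v_sequences and germline_v is None:
        germline_v = generate_germline_reference(
            config.v_gene_usage, config.v_length, seed=config.seed
        )

    d1 = config.within_clone_divergence
    d2 = config.between_clone_min_divergence
    founders: dict[tuple[str, str, int], list[str]] = {}
    records: list[RearrangementRecord] = []
    truth_rows: list[dict] = []
    counter = 0

    def _place_founder(v: str, j: str, junction_maker) -> str | None:
        nonlocal founders
        length = None
        for attempt in range(config.max_rejection_tries):
            junction = junction_maker()
            length = len(junction)
            m = int(math.floor(d1 * length / 2))
            min_sep = int(math.ceil(d2 * length)) + 2 * m + 1
            key = (v, j, length)
            existing = founders.setdefault(key, [])
            if all(_hamming_nt(junction, f) >= min_sep for f in existing):
                existing.append(junction)
                return junction
        raise RejectionBudgetError(
            f"could not place a founder in partition ({v}, {j}, {length}) "
            f"after {config.max_rejection_tries} tries; use longer junctions "
            "or fewer clones"
        )

    def _emit_clone(
        founder: str, v_call: str, j_call: str,
        subset_id: str, typical: bool | None,
    ) -> None:
        nonlocal counter
        length = len(founder)
        m = int(math.floor(d1 * length / 2))
        size = int(
            min(rng.geometric(config.clone_size_geometric_p), 50)
        )
        clone_label = f"true-{len(founders)}-{counter}"
        frozen = frozenset()
        if subset_id:
            sd = defs_by_id[subset_id]
            # +1 for the junction's leading conserved codon
            frozen = frozenset(
                range(sd.pattern_offset + 1,
                      sd.pattern_offset + 1 + len(sd.pattern))
            )
        for _ in range(size):
            n_subs = int(rng.integers(0, m + 1)) if m > 0 else 0
            junction = (
                _mutate_junction(rng, founder, n_subs, frozen)
                if n_subs else founder
            )
            counter += 1
            sid = f"sim-{counter:06d}"
            mutated = rng.random() < config.shm_mutated_fraction
            if config.emit_v_sequences:
                germ = germline_v[v_call.split("*")[0]]
                lv = len(germ)
                if mutated:
                    lo, hi = config.shm_identity_range_mutated
                    target = rng.uniform(lo, hi)
                else:
                    target = rng.uniform(99.0, 100.0)
                k = int(round((100.0 - target) / 100.0 * lv))
                v_seq = _substitute(rng, germ, k)
                v_identity = 100.0 * (1.0 - k / lv)
                v_subs = k
            else:
                if mutated:
                    lo, hi = config.shm_identity_range_mutated
                    v_identity = round(float(rng.uniform(lo, hi)), 2)
                else:
                    v_identity = round(float(rng.uniform(99.0, 100.0)), 2)
                v_seq = None
                v_subs = None
            dup = int(min(rng.zipf(config.duplicate_zipf_a),
                          config.duplicate_max))
            rec = RearrangementRecord(
                sequence_id=sid,
                v_call=v_call,
                j_call=j_call,
                junction_nt=junction,
                cdr3_aa=cdr3_from_junction(junction),
                duplicate_count=dup,
                productive=True,
                sample_id=config.sample_id,
                population_label=str(_choice(rng, config.population_weights)),
                isotype=str(_choice(rng, config.isotype_weights)),
                v_identity_pct=v_identity,
                v_sequence=v_seq,
            )
            rec.validate()
            records.append(rec)
            truth_rows.append(
                {
                    "sequence_id": sid,
                    "true_clone_id": clone_label,
                    "true_subset_id": subset_id,
                    "true_typical": "" if typical is None else typical,
                    "junction_substitutions": n_subs,
                    "v_substitutions": "" if v_subs is None else v_subs,
                }
            )

    # -- background clones --------------------------------------------------
    for _ in range(config.n_background_clones):
        v = str(_choice(rng, config.v_gene_usage))
        j = str(_choice(rng, config.j_gene_usage))
        length = int(_choice(rng, config.junction_length_weights))
        founder = _place_founder(v, j, lambda: _random_junction(rng, length))
        _emit_clone(founder, v, j, subset_id="", typical=None)

    # -- stereotyped spikes -------------------------------------------------
    for spike in config.spikes:
        sd = defs_by_id[spike.subset_id]
        typical_sorted = sorted(sd.typical_v_genes)
        non_typical = sorted(
            g for g in config.v_gene_usage
            if g not in sd.typical_v_genes and clans.clan_of(g) == sd.clan
        )
        for _ in range(spike.n_clones):
            typical = bool(rng.random() < spike.typical_fraction)
            pool = typical_sorted if typical or not non_typical else non_typical
            if not typical and not non_typical:
                typical = True
            v = pool[rng.integers(0, len(pool))]
            j = str(_choice(rng, config.j_gene_usage))
            # redraw the non-window CDR3 residues on every placement
            # attempt: spike founders share the consensus window, so the
            # mutable region must carry all the between-clone separation
            founder = _place_founder(
                v, j,
                lambda: _junction_for_cdr3(
                    rng, _spike_cdr3(rng, sd, spike, groups)
                ),
            )
            _emit_clone(founder, v, j, spike.subset_id, typical)

    truth = GroundTruth(
        per_sequence=pd.DataFrame(
            truth_rows,
            columns=[
                "sequence_id", "true_clone_id", "true_subset_id",
                "true_typical", "junction_substitutions", "v_substitutions",
            ],
        ),
        threshold_window=(d1, d2),
    )
    return records, truth


def _substitute(rng: np.random.Generator, seq: str, k: int) -> str:
    positions = rng.choice(len(seq), size=k, replace=False)
    out = list(seq)
    for pos in positions:
        old = out[pos]
        choices = [n for n in _NT if n != old]
        out[pos] = choices[rng.integers(0, 3)]
    return "".join(out)


def evaluate_recovery(
    assignments: Sequence[StereotypeAssignment] | Mapping[str, str | None],
    clone_families: Sequence[CloneFamily] | Mapping[str, str],
    truth: GroundTruth,
    threshold: float | None = None,
) -> dict[str, object]:
    """Compare predictions with planted truth.

    Returns stereotype sensitivity (truth-stereotyped sequences assigned
    their true subset) and specificity (truth-background assigned NONE),
    the adjusted Rand index of the clone partitions, and — when a threshold
    is supplied — whether it falls inside the planted (d1, d2) window.
    """
    if isinstance(assignments, Mapping):
        predicted_subset = dict(assignments)
    else:
        predicted_subset = {a.sequence_id: a.subset_id for a in assignments}
    if isinstance(clone_families, Mapping):
        predicted_clone = dict(clone_families)
    else:
        predicted_clone = {
            sid: fam.clone_id
            for fam in clone_families
            for sid in fam.member_ids
        }
    tdf = truth.per_sequence
    truth_ids = set(tdf["sequence_id"])
    if truth_ids != set(predicted_subset) or truth_ids != set(predicted_clone):
        raise ValueError("sequence_id spaces of predictions and truth differ")

    true_subset = dict(zip(tdf["sequence_id"], tdf["true_subset_id"]))
    spiked = [s for s, sub in true_subset.items() if sub]
    background = [s for s, sub in true_subset.items() if not sub]
    sensitivity = (
        sum(predicted_subset[s] == true_subset[s] for s in spiked)
        / len(spiked)
        if spiked else float("nan")
    )
    specificity = (
        sum(predicted_subset[s] is None for s in background) / len(background)
        if background else float("nan")
    )
    order = sorted(truth_ids)
    ari = adjusted_rand_score(
        [dict(zip(tdf["sequence_id"], tdf["true_clone_id"]))[s] for s in order],
        [predicted_clone[s] for s in order],
    )
    metrics: dict[str, object] = {
        "stereotype_sensitivity": sensitivity,
        "stereotype_specificity": specificity,
        "clone_ari": float(ari),
    }
    if threshold is not None:
        d1, d2 = truth.threshold_window
        metrics["threshold_in_window"] = bool(d1 < threshold < d2)
    return metrics
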