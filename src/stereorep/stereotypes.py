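"""VH CDR3 stereotype subset assignment.

A CDR3 is assigned to a configured stereotyped subset when it has the
subset's exact CDR3 length, its V gene belongs to the subset's phylogenetic
clan, and the pattern window (anchored at the subset's offset) reaches the
identity and similarity thresholds against the subset consensus. V-gene
usage is further classified as typical or non-typical of the subset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from stereorep.io import strip_allele, v_family

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Standard physicochemical partition of the 20 amino acids; configurable
#: because published stereotypy pipelines do not all agree on the classes.
DEFAULT_SIMILARITY_CLASSES: dict[str, str] = {
    "aliphatic": "GAVLI",
    "aromatic": "FYW",
    "sulfur": "CM",
    "hydroxyl": "ST",
    "basic": "KRH",
    "acid_amide": "DENQ",
    "proline": "P",
}

#: Standard immunogenetics clan assignment of the IGHV families.
DEFAULT_CLAN_FAMILIES: dict[str, str] = {
    "IGHV1": "I",
    "IGHV5": "I",
    "IGHV7": "I",
    "IGHV2": "II",
    "IGHV4": "II",
    "IGHV6": "II",
    "IGHV3": "III",
}


class SequenceComparisonError(ValueError):
    """Sequences are not comparable (length mismatch or invalid residue)."""


def _check_pair(a: str, b: str) -> None:
    if len(a) != len(b):
        raise SequenceComparisonError(
            f"length mismatch: {len(a)} vs {len(b)} (non-comparable CDR3s)"
        )
    if not a:
        raise SequenceComparisonError("empty sequences")
    for seq in (a, b):
        for i, res in enumerate(seq):
            if res not in AA_ALPHABET:
                raise SequenceComparisonError(
                    f"invalid residue {res!r} at position {i}"
                )


def aa_identity(a: str, b: str) -> float:
    """Fraction of positions with identical residues, in [0, 1]."""
    _check_pair(a, b)
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass(frozen=True)
class SimilarityGroups:
    """A named partition of the 20 standard amino acids."""

    classes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SIMILARITY_CLASSES)
    )

    def __post_init__(self):
        seen: dict[str, str] = {}
        for name, members in self.classes.items():
            for res in members:
                if res in seen:
                    raise ValueError(
                        f"residue {res!r} in both {seen[res]!r} and {name!r}"
                    )
                seen[res] = name
        missing = AA_ALPHABET - seen.keys()
        if missing:
            raise ValueError(f"residues not covered: {sorted(missing)}")
        extra = seen.keys() - AA_ALPHABET
        if extra:
            raise ValueError(f"non-standard residues: {sorted(extra)}")
        object.__setattr__(self, "_group_of", seen)

    def group_of(self, residue: str) -> str:
        return self._group_of[residue]

    def same_group(self, a: str, b: str) -> bool:
        return self._group_of[a] == self._group_of[b]

    @classmethod
    def singletons(cls) -> "SimilarityGroups":
        """Degenerate grouping under which similarity equals identity."""
        return cls({res: res for res in sorted(AA_ALPHABET)})


def aa_similarity(a: str, b: str, groups: SimilarityGroups) -> float:
    """Fraction of positions that are identical or in the same
    physicochemical class; always >= ``aa_identity(a, b)``."""
    _check_pair(a, b)
    return (
        sum(x == y or groups.same_group(x, y) for x, y in zip(a, b)) / len(a)
    )


@dataclass(frozen=True)
class ClanTable:
    """Mapping of IGHV families (and optional per-gene overrides) to
    phylogenetic clans I/II/III."""

    families: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLAN_FAMILIES)
    )
    gene_overrides: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for fam, clan in {**self.families, **self.gene_overrides}.items():
            if clan not in {"I", "II", "III"}:
                raise ValueError(f"unknown clan {clan!r} for {fam!r}")

    def clan_of(self, v_gene: str) -> str:
        gene = strip_allele(v_gene)
        if gene in self.gene_overrides:
            return self.gene_overrides[gene]
        fam = v_family(gene)
        try:
            return self.families[fam]
        except KeyError:
            raise KeyError(
                f"V gene {v_gene!r} (family {fam!r}) absent from clan table"
            ) from None


_SUBSET_ID_RE = re.compile(r"^#?[\w\-]+$")


@dataclass(frozen=True)
class SubsetDefinition:
    """One CLL major stereotyped subset definition."""

    subset_id: str
    cdr3_length_aa: int
    pattern: str
    pattern_offset: int
    clan: str
    typical_v_genes: frozenset[str]
    min_identity: float = 0.5
    min_similarity: float = 0.7

    def __post_init__(self):
        if not _SUBSET_ID_RE.match(self.subset_id):
            raise ValueError(f"malformed subset_id {self.subset_id!r}")
        if self.cdr3_length_aa <= 0:
            raise ValueError("cdr3_length_aa must be positive")
        if not self.pattern or set(self.pattern) - AA_ALPHABET:
            raise ValueError(f"invalid pattern {self.pattern!r}")
        if self.pattern_offset < 0:
            raise ValueError("pattern_offset must be >= 0")
        if self.pattern_offset + len(self.pattern) > self.cdr3_length_aa:
            raise ValueError(
                f"pattern window [{self.pattern_offset}, "
                f"{self.pattern_offset + len(self.pattern)}) exceeds CDR3 "
                f"length {self.cdr3_length_aa}"
            )
        if self.clan not in {"I", "II", "III"}:
            raise ValueError(f"unknown clan {self.clan!r}")
        if not (0.0 <= self.min_identity <= 1.0):
            raise ValueError("min_identity out of [0, 1]")
        if not (0.0 <= self.min_similarity <= 1.0):
            raise ValueError("min_similarity out of [0, 1]")
        if self.min_identity > self.min_similarity:
            raise ValueError("min_identity must be <= min_similarity")
        object.__setattr__(
            self, "typical_v_genes", frozenset(self.typical_v_genes)
        )

    @property
    def window(self) -> slice:
        return slice(self.pattern_offset, self.pattern_offset + len(self.pattern))


@dataclass(frozen=True)
class StereotypeAssignment:
    """Per-sequence verdict of the subset scan."""

    sequence_id: str
    subset_id: str | None
    identity: float | None = None
    similarity: float | None = None
    typical: bool | None = None
    ambiguous_candidates: tuple[str, ...] = ()

    def __post_init__(self):
        if self.subset_id is None and self.typical is not None:
            raise ValueError("typical must be None when no subset is assigned")
        if (
            self.identity is not None
            and self.similarity is not None
            and self.identity > self.similarity + 1e-12
        ):
            raise ValueError("identity cannot exceed similarity")


def classify_typical(v_gene: str, subset: SubsetDefinition) -> bool:
    """Whether ``v_gene`` is one the subset's CLL clones typically use."""
    if not subset.typical_v_genes:
        raise ValueError(
            f"subset {subset.subset_id} has an empty typical gene set"
        )
    return strip_allele(v_gene) in subset.typical_v_genes


def assign_subset(
    cdr3_aa: str,
    v_gene: str,
    defs: Sequence[SubsetDefinition],
    clans: ClanTable | None = None,
    groups: SimilarityGroups | None = None,
    full_cdr3: bool = False,
    sequence_id: str = "",
) -> StereotypeAssignment:
    """Scan one CDR3 against the configured subset definitions.

    A subset is a candidate iff the CDR3 length matches exactly, the V gene
    belongs to the subset's clan, and the pattern window reaches both the
    identity and similarity thresholds. Ties between multiple candidates are
    broken by highest similarity, then highest identity, then smallest
    subset_id; all candidates are recorded.

    With ``full_cdr3`` the scores are computed over the whole CDR3 against
    the pattern embedded in an identity-scored frame (window-anchored
    comparison remains the default).
    """
    if not defs:
        raise ValueError("no subset definitions provided")
    clans = clans or ClanTable()
    groups = groups or SimilarityGroups()
    gene = strip_allele(v_gene)
    gene_clan = clans.clan_of(gene)

    candidates: list[tuple[float, float, str, SubsetDefinition]] = []
    for sd in defs:
        if len(cdr3_aa) != sd.cdr3_length_aa:
            continue
        if gene_clan != sd.clan:
            continue
        window_seq = cdr3_aa[sd.window]
        ident = aa_identity(window_seq, sd.pattern)
        simil = aa_similarity(window_seq, sd.pattern, groups)
        if full_cdr3:
            # Positions outside the window count as matches for both scores.
            w, n = len(sd.pattern), sd.cdr3_length_aa
            ident = (ident * w + (n - w)) / n
            simil = (simil * w + (n - w)) / n
        if ident >= sd.min_identity and simil >= sd.min_similarity:
            candidates.append((simil, ident, sd.subset_id, sd))

    if not candidates:
        return StereotypeAssignment(sequence_id=sequence_id, subset_id=None)

    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    simil, ident, subset_id, best = candidates[0]
    return StereotypeAssignment(
        sequence_id=sequence_id,
        subset_id=subset_id,
        identity=ident,
        similarity=simil,
        typical=classify_typical(gene, best),
        ambiguous_candidates=tuple(c[2] for c in candidates),
    )
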