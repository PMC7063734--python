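"""Somatic-hypermutation status from germline identity of the V segment."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

_UNAMBIGUOUS = frozenset("ACGT")


class MutationStatus(str, Enum):
    MUTATED = "mutated"
    UNMUTATED = "unmutated"


def germline_identity(observed_v: str, germline_v: str) -> float:
    """Percent identity of the rearranged V segment to its germline.

    Substitution-only model: the sequences must align position by position
    (equal length). Positions where either sequence carries an ambiguity
    character (anything outside ACGT) are excluded from both numerator and
    denominator.
    """
    if len(observed_v) != len(germline_v):
        raise ValueError(
            f"length mismatch {len(observed_v)} vs {len(germline_v)}: "
            "indel-containing input is unsupported"
        )
    if not observed_v:
        raise ValueError("empty sequences")
    matches = 0
    informative = 0
    for x, y in zip(observed_v.upper(), germline_v.upper()):
        if x not in _UNAMBIGUOUS or y not in _UNAMBIGUOUS:
            continue
        informative += 1
        if x == y:
            matches += 1
    if informative == 0:
        raise ValueError("no informative (unambiguous) positions")
    return 100.0 * matches / informative


def mutation_status(
    v_identity_pct: float, cutoff_pct: float = 1.0
) -> MutationStatus:
    """Unmutated iff germline identity >= 100 - cutoff (boundary
    inclusive: identity exactly at the cutoff counts as unmutated)."""
    if not (0.0 <= v_identity_pct <= 100.0):
        raise ValueError(f"v_identity_pct out of [0, 100]: {v_identity_pct}")
    if cutoff_pct <= 0:
        raise ValueError("cutoff_pct must be positive")
    if v_identity_pct >= 100.0 - cutoff_pct:
        return MutationStatus.UNMUTATED
    return MutationStatus.MUTATED


@dataclass(frozen=True, slots=True)
class MutationCall:
    sequence_id: str
    v_identity_pct: float
    status: MutationStatus
    cutoff_pct: float = 1.0

    def __post_init__(self):
        expected = mutation_status(self.v_identity_pct, self.cutoff_pct)
        if expected is not self.status:
            raise ValueError(
                f"status {self.status} inconsistent with identity "
                f"{self.v_identity_pct} at cutoff {self.cutoff_pct}"
            )
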