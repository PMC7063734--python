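"""Reading, writing and filtering of AIRR-dialect rearrangement tables.

The on-disk format is the AIRR Rearrangement TSV (tab-separated, header
row) with the standard column names plus extension columns for sample,
population and isotype metadata. Rows that fail type coercion or violate
record invariants are collected into a rejection report rather than being
silently dropped.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

POPULATION_LABELS = frozenset(
    {"FM", "GC", "MZ", "MZ27pos", "MZ27neg", "SM", "MO", "DN", "TR",
     "CD5pos", "CD5neg", "OTHER"}
)
ISOTYPES = frozenset({"IGHM", "IGHG", "OTHER"})

#: Default mapping from record fields to AIRR Rearrangement column names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "sequence_id": "sequence_id",
    "sample_id": "sample_id",
    "population_label": "population_label",
    "isotype": "isotype",
    "v_call": "v_call",
    "d_call": "d_call",
    "j_call": "j_call",
    "junction_nt": "junction",
    "cdr3_aa": "junction_aa",
    "v_identity_pct": "v_identity",
    "duplicate_count": "duplicate_count",
    "productive": "productive",
    "v_sequence": "v_sequence",
}

MANDATORY_FIELDS = (
    "sequence_id", "v_call", "j_call", "junction_nt", "duplicate_count",
    "productive",
)

_TRUE = {"t", "true", "1", "yes", "y"}
_FALSE = {"f", "false", "0", "no", "n"}


class ConfigurationError(ValueError):
    """A mandatory column cannot be resolved from the input file."""


def strip_allele(call: str) -> str:
    """Return the gene-level part of an IMGT allele call.

    ``"IGHV1-69*01" -> "IGHV1-69"``; calls without an allele suffix are
    returned unchanged. Comma-separated multi-assignments are resolved to
    the first listed call.
    """
    if not call:
        raise ValueError("empty gene call")
    first = call.split(",")[0].strip()
    return first.split("*")[0]


def v_family(call: str) -> str:
    """Gene family of an IGHV call, e.g. ``"IGHV1"`` from ``"IGHV1-69*01"``."""
    gene = strip_allele(call)
    head = gene.split("-")[0].split("/")[0]
    return head


def translate_junction(junction_nt: str) -> str:
    """Translate an in-frame junction; no stop-codon masking."""
    if len(junction_nt) % 3 != 0:
        raise ValueError(
            f"junction length {len(junction_nt)} is not a multiple of 3"
        )
    return str(Seq(junction_nt).translate())


def cdr3_from_junction(junction_nt: str) -> str:
    """CDR3 amino acids: the translated junction minus the flanking
    conserved residues (IMGT junction = 2nd-CYS + CDR3 + J-TRP/PHE)."""
    aa = translate_junction(junction_nt)
    if len(aa) < 3:
        raise ValueError("junction too short to contain a CDR3")
    return aa[1:-1]


@dataclass(frozen=True, slots=True)
class RearrangementRecord:
    """One annotated IGH VDJ rearrangement with sample metadata."""

    sequence_id: str
    v_call: str
    j_call: str
    junction_nt: str
    cdr3_aa: str
    duplicate_count: int
    productive: bool
    sample_id: str = "S1"
    population_label: str = "OTHER"
    isotype: str = "OTHER"
    d_call: str | None = None
    v_identity_pct: float | None = None
    v_sequence: str | None = None

    @property
    def v_gene(self) -> str:
        return strip_allele(self.v_call)

    @property
    def j_gene(self) -> str:
        return strip_allele(self.j_call)

    @property
    def v_family(self) -> str:
        return v_family(self.v_call)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated record invariant."""
        if not self.sequence_id:
            raise ValueError("sequence_id is empty")
        if len(self.junction_nt) % 3 != 0:
            raise ValueError(
                f"junction length {len(self.junction_nt)} not a multiple of 3"
            )
        derived = cdr3_from_junction(self.junction_nt)
        if derived != self.cdr3_aa:
            raise ValueError(
                f"cdr3_aa {self.cdr3_aa!r} inconsistent with junction "
                f"translation {derived!r}"
            )
        if self.duplicate_count < 1:
            raise ValueError(
                f"duplicate_count must be >= 1, got {self.duplicate_count}"
            )
        if self.v_identity_pct is not None and not (
            0.0 <= self.v_identity_pct <= 100.0
        ):
            raise ValueError(
                f"v_identity_pct out of [0, 100]: {self.v_identity_pct}"
            )
        if self.population_label not in POPULATION_LABELS:
            raise ValueError(
                f"unknown population label {self.population_label!r}"
            )
        if self.isotype not in ISOTYPES:
            raise ValueError(f"unknown isotype {self.isotype!r}")


@dataclass(frozen=True, slots=True)
class RejectedRow:
    """A row that failed ingestion, with its 0-based data-row index."""

    row_index: int
    sequence_id: str | None
    reason: str


@dataclass(slots=True)
class ReadResult:
    records: list[RearrangementRecord] = field(default_factory=list)
    rejected: list[RejectedRow] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True, slots=True)
class FilterCriteria:
    """Record-level filters applied before any downstream analysis."""

    require_productive: bool = True
    allowed_v_families: frozenset[str] = frozenset({"IGHV1"})
    allowed_isotypes: frozenset[str] = frozenset({"IGHM", "IGHG"})

    def __post_init__(self):
        if not self.allowed_v_families:
            raise ValueError("allowed_v_families must be non-empty")
        if not self.allowed_isotypes:
            raise ValueError("allowed_isotypes must be non-empty")
        object.__setattr__(
            self, "allowed_v_families", frozenset(self.allowed_v_families)
        )
        object.__setattr__(
            self, "allowed_isotypes", frozenset(self.allowed_isotypes)
        )


def _parse_bool(value: str) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _opt(row: Mapping[str, object], col: str | None) -> str | None:
    if col is None or col not in row:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return None
    s = str(v).strip()
    return s or None


def record_from_row(
    row: Mapping[str, object], column_map: Mapping[str, str]
) -> RearrangementRecord:
    """Coerce one table row into a validated :class:`RearrangementRecord`."""
    def get(fieldname: str, required: bool = False) -> str | None:
        col = column_map.get(fieldname)
        val = _opt(row, col)
        if required and val is None:
            raise ValueError(f"missing value for {fieldname!r}")
        return val

    junction = get("junction_nt", required=True)
    full_aa = translate_junction(junction)
    cdr3 = get("cdr3_aa")
    if cdr3 is None or cdr3 == full_aa:
        # AIRR junction_aa holds the full junction translation; the CDR3
        # proper drops the flanking conserved residues.
        cdr3 = full_aa[1:-1]
    v_id = get("v_identity_pct")
    rec = RearrangementRecord(
        sequence_id=get("sequence_id", required=True),
        v_call=get("v_call", required=True),
        j_call=get("j_call", required=True),
        junction_nt=junction,
        cdr3_aa=cdr3,
        duplicate_count=int(get("duplicate_count", required=True)),
        productive=_parse_bool(get("productive", required=True)),
        sample_id=get("sample_id") or "S1",
        population_label=get("population_label") or "OTHER",
        isotype=get("isotype") or "OTHER",
        d_call=get("d_call"),
        v_identity_pct=float(v_id) if v_id is not None else None,
        v_sequence=get("v_sequence"),
    )
    rec.validate()
    return rec


def read_rearrangements(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> ReadResult:
    """Read an AIRR-dialect rearrangement TSV.

    Returns records in file order; rows that fail coercion or violate a
    record invariant appear in ``result.rejected`` with a reason. Duplicate
    ``sequence_id`` values are rejected (first occurrence wins).

    Raises
    ------
    ConfigurationError
        If a mandatory column cannot be resolved via ``column_map``.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return ReadResult()
    for fieldname in MANDATORY_FIELDS:
        col = cmap.get(fieldname)
        if col is None or col not in df.columns:
            raise ConfigurationError(
                f"mandatory column for field {fieldname!r} "
                f"(mapped to {col!r}) not found in {path}"
            )
    result = ReadResult()
    seen: set[str] = set()
    for idx, row in enumerate(df.to_dict(orient="records")):
        sid = _opt(row, cmap["sequence_id"])
        try:
            rec = record_from_row(row, cmap)
            if rec.sequence_id in seen:
                raise ValueError(f"duplicate sequence_id {rec.sequence_id!r}")
            seen.add(rec.sequence_id)
            result.records.append(rec)
        except (ValueError, TypeError) as exc:
            result.rejected.append(RejectedRow(idx, sid, str(exc)))
    if result.rejected:
        logger.warning(
            "%s: rejected %d of %d rows", path, len(result.rejected), len(df)
        )
    return result


def records_to_frame(records: Iterable[RearrangementRecord]) -> pd.DataFrame:
    """Records as a DataFrame in the AIRR column dialect."""
    rows = []
    for r in records:
        rows.append(
            {
                "sequence_id": r.sequence_id,
                "sample_id": r.sample_id,
                "population_label": r.population_label,
                "isotype": r.isotype,
                "v_call": r.v_call,
                "d_call": r.d_call or "",
                "j_call": r.j_call,
                "junction": r.junction_nt,
                "junction_aa": translate_junction(r.junction_nt),
                "v_identity": (
                    "" if r.v_identity_pct is None
                    else format(r.v_identity_pct, "g")
                ),
                "duplicate_count": r.duplicate_count,
                "productive": "T" if r.productive else "F",
                "v_sequence": r.v_sequence or "",
            }
        )
    cols = list(DEFAULT_COLUMN_MAP.values())
    return pd.DataFrame(rows, columns=cols)


def write_rearrangements(
    records: Iterable[RearrangementRecord], path: str | Path
) -> None:
    """Write records as an AIRR-dialect TSV (round-trips with
    :func:`read_rearrangements`)."""
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def filter_records(
    records: Sequence[RearrangementRecord], criteria: FilterCriteria
) -> tuple[list[RearrangementRecord], Counter]:
    """Apply productivity / V-family / isotype filters.

    Returns the kept records plus a per-reason rejection tally; a record
    failing several criteria is tallied once under the first failing one
    (order: productive, family, isotype), so kept + tally sums conserve the
    input size.
    """
    kept: list[RearrangementRecord] = []
    tally: Counter = Counter()
    for rec in records:
        if criteria.require_productive and not rec.productive:
            tally["productive"] += 1
        elif rec.v_family not in criteria.allowed_v_families:
            tally["family"] += 1
        elif rec.isotype not in criteria.allowed_isotypes:
            tally["isotype"] += 1
        else:
            kept.append(rec)
    return kept, tally


def with_fields(rec: RearrangementRecord, **changes) -> RearrangementRecord:
    """Functional update helper (records are frozen)."""
    return replace(rec, **changes)
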