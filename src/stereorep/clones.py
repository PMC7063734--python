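"""Clonal-family inference.

Records are partitioned by (V gene, J gene, junction length); within each
partition, single-linkage components under a normalized junction Hamming
distance threshold form the clonal families. The threshold is found from
the valley between the two main modes of the distance-to-nearest
distribution (kernel density estimate on [0, 1]), falling back to a fixed
value when the distribution is not bimodal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from stereorep.io import RearrangementRecord

logger = logging.getLogger(__name__)


def normalized_hamming(a: str, b: str) -> float:
    """Mismatching positions / length, in [0, 1] (0 = identical)."""
    if len(a) != len(b):
        raise ValueError(
            f"length mismatch {len(a)} vs {len(b)}: sequences belong to "
            "different partitions"
        )
    if not a:
        raise ValueError("empty sequences")
    return sum(x != y for x, y in zip(a, b)) / len(a)


@dataclass(frozen=True, slots=True)
class PartitionKey:
    v_gene: str
    j_gene: str
    junction_length_nt: int


@dataclass(frozen=True, slots=True)
class CloneFamily:
    clone_id: str
    key: PartitionKey
    member_ids: tuple[str, ...]
    representative_id: str | None = None


@dataclass(frozen=True, slots=True)
class DistanceThreshold:
    value: float
    method: str  # "density_valley" or "fixed"
    diagnostics: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"threshold out of [0, 1]: {self.value}")
        if self.method not in {"density_valley", "fixed"}:
            raise ValueError(f"unknown method {self.method!r}")


def partition_records(
    records: Iterable[RearrangementRecord],
) -> dict[PartitionKey, list[RearrangementRecord]]:
    """Group records by gene-level V/J calls and junction length."""
    parts: dict[PartitionKey, list[RearrangementRecord]] = {}
    for rec in records:
        key = PartitionKey(rec.v_gene, rec.j_gene, len(rec.junction_nt))
        parts.setdefault(key, []).append(rec)
    return parts


def _encode(seqs: Sequence[str]) -> np.ndarray:
    return np.frombuffer(
        "".join(seqs).encode("ascii"), dtype=np.uint8
    ).reshape(len(seqs), -1)


def _pairwise_distances(seqs: Sequence[str]) -> np.ndarray:
    """Full n x n normalized Hamming distance matrix."""
    mat = _encode(seqs)
    diff = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    return diff / mat.shape[1]


def nearest_neighbor_distances(
    partitions: Mapping[PartitionKey, Sequence[RearrangementRecord]],
) -> list[float]:
    """Per-record minimum junction distance to any other record in its
    partition; singleton partitions contribute nothing."""
    out: list[float] = []
    for members in partitions.values():
        if len(members) < 2:
            continue
        dmat = _pairwise_distances([m.junction_nt for m in members])
        np.fill_diagonal(dmat, np.inf)
        out.extend(dmat.min(axis=1).tolist())
    if not out:
        warnings.warn(
            "no partition with >= 2 members: empty distance-to-nearest list",
            stacklevel=2,
        )
    return out


def _kde_on_grid(
    distances: np.ndarray, bandwidth: float, grid_size: int
) -> tuple[np.ndarray, np.ndarray]:
    grid = np.linspace(0.0, 1.0, grid_size)
    # Chunked Gaussian KDE; avoids a len(d) x grid_size blow-up.
    dens = np.zeros(grid_size)
    for start in range(0, len(distances), 4096):
        chunk = distances[start : start + 4096]
        z = (grid[None, :] - chunk[:, None]) / bandwidth
        dens += np.exp(-0.5 * z * z).sum(axis=0)
    dens /= len(distances) * bandwidth * np.sqrt(2.0 * np.pi)
    return grid, dens


def _local_maxima(dens: np.ndarray) -> list[int]:
    idx = []
    n = len(dens)
    for i in range(n):
        left = dens[i - 1] if i > 0 else -np.inf
        right = dens[i + 1] if i < n - 1 else -np.inf
        if dens[i] > left and dens[i] >= right and dens[i] > 0:
            idx.append(i)
    return idx


def find_threshold(
    distances: Sequence[float],
    bandwidth: float = 0.02,
    grid_size: int = 512,
    fallback: float = 0.15,
    min_distances: int = 50,
) -> DistanceThreshold:
    """Locate the density valley between the two largest modes of the
    distance-to-nearest distribution.

    Returns the fallback value (``method="fixed"``) when fewer than two
    modes are detected; raises when fewer than ``min_distances`` distances
    are supplied, in which case a fixed threshold should be configured.
    """
    d = np.asarray(distances, dtype=float)
    if len(d) < min_distances:
        raise ValueError(
            f"only {len(d)} distances (< {min_distances}); use a fixed "
            "threshold instead"
        )
    if np.any((d < 0) | (d > 1)):
        raise ValueError("distances must lie in [0, 1]")
    grid, dens = _kde_on_grid(d, bandwidth, grid_size)
    maxima = _local_maxima(dens)
    diagnostics = {
        "n_distances": int(len(d)),
        "bandwidth": bandwidth,
        "grid_size": grid_size,
        "n_modes": len(maxima),
        "histogram": np.histogram(d, bins=20, range=(0.0, 1.0))[0].tolist(),
    }
    if len(maxima) < 2:
        logger.info("distance distribution not bimodal; using fallback")
        return DistanceThreshold(fallback, "fixed", diagnostics)
    top_two = sorted(sorted(maxima, key=lambda i: -dens[i])[:2])
    lo, hi = top_two
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    diagnostics["mode_locations"] = [float(grid[i]) for i in top_two]
    return DistanceThreshold(
        float(grid[valley]), "density_valley", diagnostics
    )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_clones(
    partitions: Mapping[PartitionKey, Sequence[RearrangementRecord]],
    threshold: DistanceThreshold | float,
) -> list[CloneFamily]:
    """Single-linkage clonal families within each V/J/length partition.

    Two records join the same family when connected by a chain of pairs at
    normalized Hamming distance <= threshold. Clone ids derive from the
    partition key plus the lexicographically smallest member sequence_id,
    so they do not depend on input order.
    """
    t = threshold.value if isinstance(threshold, DistanceThreshold) else float(threshold)
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"threshold out of [0, 1]: {t}")
    families: list[CloneFamily] = []
    for key, members in partitions.items():
        n = len(members)
        if n == 0:
            continue
        uf = _UnionFind(n)
        if n > 1:
            dmat = _pairwise_distances([m.junction_nt for m in members])
            ii, jj = np.nonzero(np.triu(dmat <= t + 1e-12, k=1))
            for a, b in zip(ii.tolist(), jj.tolist()):
                uf.union(a, b)
        comps: dict[int, list[str]] = {}
        for i, rec in enumerate(members):
            comps.setdefault(uf.find(i), []).append(rec.sequence_id)
        for ids in comps.values():
            ids.sort()
            clone_id = (
                f"{key.v_gene}_{key.j_gene}_{key.junction_length_nt}_{ids[0]}"
            )
            families.append(CloneFamily(clone_id, key, tuple(ids)))
    families.sort(key=lambda f: f.clone_id)
    return families


def select_representative(
    family: CloneFamily,
    records: Mapping[str, RearrangementRecord],
) -> str:
    """Member with the highest duplicate count (most sequenced mRNA
    molecules); ties broken by smallest sequence_id."""
    if not family.member_ids:
        raise ValueError("empty clone family")
    return min(
        family.member_ids,
        key=lambda sid: (-records[sid].duplicate_count, sid),
    )
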