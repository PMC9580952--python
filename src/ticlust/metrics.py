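"""Cluster-quality metrics against a ground-truth labelling.

Purity, Adjusted Rand Index and Normalized Mutual Information are computed
from a shared contingency table; ``count_mixed_clusters`` tallies clusters
whose members carry conflicting true names at a given rank.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np

from .seqsim import Cluster
from .taxonomy import TaxonomicPath

__all__ = [
    "ContingencyTable",
    "MetricsError",
    "purity",
    "adjusted_rand_index",
    "normalized_mutual_information",
    "count_mixed_clusters",
]


class MetricsError(ValueError):
    """Raised for inconsistent metric inputs."""


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation n_ij = |cluster i ∩ class j| with marginals."""

    matrix: np.ndarray
    row_labels: tuple
    col_labels: tuple

    @classmethod
    def from_labelings(cls, a: Mapping, b: Mapping) -> "ContingencyTable":
        if set(a) != set(b):
            raise MetricsError("labelings cover different id universes")
        if not a:
            raise MetricsError("empty labelings")
        rows = sorted({str(v) for v in a.values()})
        cols = sorted({str(v) for v in b.values()})
        ri = {lab: i for i, lab in enumerate(rows)}
        ci = {lab: j for j, lab in enumerate(cols)}
        matrix = np.zeros((len(rows), len(cols)), dtype=np.int64)
        for key in a:
            matrix[ri[str(a[key])], ci[str(b[key])]] += 1
        return cls(matrix=matrix, row_labels=tuple(rows), col_labels=tuple(cols))

    @property
    def a(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def b(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.matrix.sum())


def _as_partition(clusters) -> dict[str, list]:
    """Accept a mapping cluster-id -> members, a list of member collections,
    or a list of species-level Cluster objects."""
    if isinstance(clusters, Mapping):
        return {str(k): list(v) for k, v in clusters.items()}
    out: dict[str, list] = {}
    for i, item in enumerate(clusters):
        if isinstance(item, Cluster):
            out[item.id] = list(item.member_ids)
        else:
            out[f"cluster_{i + 1}"] = list(item)
    return out


def _labeling_from_partition(clusters) -> dict:
    part = _as_partition(clusters)
    labeling: dict = {}
    for cid, members in part.items():
        for member in members:
            if member in labeling:
                raise MetricsError(f"id {member!r} appears in multiple clusters")
            labeling[member] = cid
    return labeling


def purity(clusters, truth: Mapping, macro: bool = False) -> float:
    """Pooled majority-label purity: sum over clusters of the majority true
    label count, divided by the total number of clustered ids.

    With ``macro=True`` returns the unweighted mean of per-cluster purities
    instead.  Every clustered id must be present in *truth* (exclude ids
    with unknown true labels before calling).
    """
    part = _as_partition(clusters)
    if not part or all(not v for v in part.values()):
        raise MetricsError("purity of an empty partition is undefined")
    majority_sum = 0
    total = 0
    per_cluster: list[float] = []
    for cid, members in part.items():
        if not members:
            raise MetricsError(f"cluster {cid!r} has no members")
        counts: dict = {}
        for member in members:
            if member not in truth:
                raise MetricsError(f"id {member!r} has no true label")
            label = truth[member]
            counts[label] = counts.get(label, 0) + 1
        top = max(counts.values())
        majority_sum += top
        total += len(members)
        per_cluster.append(top / len(members))
    if macro:
        return float(np.mean(per_cluster))
    return majority_sum / total


def adjusted_rand_index(a, b) -> float:
    """Permutation-model ARI between two partitions of the same id set.

    Accepts labelings (id -> label mappings) or partitions in any of the
    forms :func:`purity` accepts.  A single-element universe yields 1.0.
    """
    la = a if isinstance(a, Mapping) and not _looks_like_partition(a) else _labeling_from_partition(a)
    lb = b if isinstance(b, Mapping) and not _looks_like_partition(b) else _labeling_from_partition(b)
    table = ContingencyTable.from_labelings(la, lb)
    n = table.n
    if n <= 1:
        return 1.0
    sum_ij = sum(math.comb(int(x), 2) for x in table.matrix.ravel())
    sum_a = sum(math.comb(int(x), 2) for x in table.a)
    sum_b = sum(math.comb(int(x), 2) for x in table.b)
    pairs = math.comb(n, 2)
    expected = sum_a * sum_b / pairs
    maximum = (sum_a + sum_b) / 2.0
    if maximum == expected:
        return 1.0
    return (sum_ij - expected) / (maximum - expected)


def normalized_mutual_information(a, b) -> float:
    """NMI with natural-log entropies, normalised by the arithmetic mean of
    the two partition entropies.  Two trivial partitions yield 1.0."""
    la = a if isinstance(a, Mapping) and not _looks_like_partition(a) else _labeling_from_partition(a)
    lb = b if isinstance(b, Mapping) and not _looks_like_partition(b) else _labeling_from_partition(b)
    table = ContingencyTable.from_labelings(la, lb)
    n = table.n
    pa = table.a / n
    pb = table.b / n
    h_a = float(-np.sum(pa * np.log(pa, where=pa > 0, out=np.zeros_like(pa, dtype=float))))
    h_b = float(-np.sum(pb * np.log(pb, where=pb > 0, out=np.zeros_like(pb, dtype=float))))
    if h_a == 0.0 and h_b == 0.0:
        return 1.0
    mi = 0.0
    matrix = table.matrix
    av = table.a
    bv = table.b
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            nij = matrix[i, j]
            if nij:
                mi += (nij / n) * math.log(n * nij / (av[i] * bv[j]))
    value = mi / ((h_a + h_b) / 2.0)
    return min(1.0, max(0.0, value))


def _looks_like_partition(m: Mapping) -> bool:
    """Heuristic: mapping values that are collections denote cluster->members."""
    for v in m.values():
        return isinstance(v, (list, tuple, set, frozenset))
    return False


def count_mixed_clusters(
    clusters,
    truth: Mapping[str, TaxonomicPath],
    rank: str,
    child_members: Mapping[str, Iterable[str]] | None = None,
) -> int:
    """Number of clusters whose members carry two or more distinct known
    true names at *rank*.  Unknown true labels are ignored.

    *clusters* may be species-level clusters (members are sequence ids) or
    any partition form; for genus/family clusters whose members are child
    cluster ids, pass *child_members* mapping cluster id -> sequence ids.
    """
    if rank not in ("genus", "family"):
        raise MetricsError(f"mixing is evaluated at genus or family, not {rank!r}")
    part = _as_partition(clusters)
    mixed = 0
    for members in part.values():
        seq_ids: list[str] = []
        for member in members:
            if child_members is not None and member in child_members:
                seq_ids.extend(child_members[member])
            else:
                seq_ids.append(member)
        names = set()
        for sid in seq_ids:
            path = truth.get(sid)
            if path is None:
                continue
            name = path.name(rank)
            if name is not None:
                names.add(name)
        if len(names) >= 2:
            mixed += 1
    return mixed
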