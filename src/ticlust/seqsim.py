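"""Pairwise global identity and the greedy centroid clustering engine.

Identity is defined as matching columns over alignment columns excluding
terminal gaps, under an optimal Needleman-Wunsch global alignment with
match +1 / mismatch -1 / gap -2 (linear).  Ambiguous bases (N and other
IUPAC codes) never count as matches.  Optimal-alignment ties are resolved
by preferring a diagonal (mismatch) step over gaps during traceback, and a
gap in the second sequence over a gap in the first; this pins a single
deterministic alignment per pair.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .taxonomy import TaxonomicPath

__all__ = [
    "AnnotatedSequence",
    "Cluster",
    "Hit",
    "SequenceError",
    "global_identity",
    "top_hits",
    "greedy_cluster",
    "canonical_order",
]

IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

# Base codes: A/C/G/T -> 0..3, every ambiguity code -> 4 (never matches).
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _ENCODE[ord(_ch)] = _i
for _ch in "NRYSWKMBDHV":
    _ENCODE[ord(_ch)] = 4


class SequenceError(ValueError):
    """Raised for invalid sequences or clustering inputs."""


@dataclass
class AnnotatedSequence:
    """A denoised amplicon: id, sequence, taxonomy and per-sample counts."""

    id: str
    seq: str
    taxonomy: TaxonomicPath = field(default_factory=TaxonomicPath.empty)
    counts: dict[str, int] = field(default_factory=dict)
    size: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("sequence id must be non-empty")
        self.seq = self.seq.upper()
        if not self.seq:
            raise SequenceError(f"{self.id}: empty sequence")
        bad = set(self.seq) - IUPAC_DNA
        if bad:
            raise SequenceError(
                f"{self.id}: illegal characters {sorted(bad)} (not IUPAC DNA)"
            )
        for sample, count in self.counts.items():
            if count < 0:
                raise SequenceError(f"{self.id}: negative count for {sample!r}")
        if self.counts:
            total = sum(self.counts.values())
            if self.size and self.size != total:
                raise SequenceError(
                    f"{self.id}: size {self.size} != sum of counts {total}"
                )
            self.size = total
        elif self.size <= 0:
            self.size = 1

    def encoded(self) -> np.ndarray:
        # Sequences are treated as immutable after construction; cache the
        # base-code array since centroids are aligned against repeatedly.
        enc = getattr(self, "_enc", None)
        if enc is None:
            enc = _ENCODE[np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)]
            object.__setattr__(self, "_enc", enc)
        return enc


@dataclass(frozen=True)
class Hit:
    """A search result: reference id plus identity fraction."""

    target_id: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise SequenceError(f"identity outside [0,1]: {self.identity}")


@dataclass
class Cluster:
    """An OTU at one level.  ``member_ids`` are sequence ids at species level
    and child-cluster ids at genus/family level.  ``centroid_seq`` and
    ``size`` are carried so incremental placement can keep searching
    centroids without re-reading the input."""

    id: str
    level: str
    centroid_id: str
    member_ids: tuple[str, ...]
    taxonomy: TaxonomicPath = field(default_factory=TaxonomicPath.empty)
    novel: bool = True
    size: int = 0
    centroid_seq: str | None = None

    def __post_init__(self) -> None:
        if self.level not in ("species", "genus", "family"):
            raise SequenceError(f"invalid cluster level {self.level!r}")
        if not self.member_ids:
            raise SequenceError(f"cluster {self.id}: empty member set")
        if self.level == "species" and self.centroid_id not in self.member_ids:
            raise SequenceError(f"cluster {self.id}: centroid not a member")


@njit(cache=True)
def _nw_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int]:
    """Matches and columns (terminal gaps excluded) of the pinned optimal
    global alignment.  Codes >= 4 never match."""
    n = a.size
    m = b.size
    score = np.empty((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    score[0, 0] = 0
    for i in range(1, n + 1):
        score[i, 0] = -2 * i
        ptr[i, 0] = 1
    for j in range(1, m + 1):
        score[0, j] = -2 * j
        ptr[0, j] = 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = 1 if (ai == b[j - 1] and ai < 4) else -1
            best = score[i - 1, j - 1] + s
            p = 0
            up = score[i - 1, j] - 2
            if up > best:
                best = up
                p = 1
            left = score[i, j - 1] - 2
            if left > best:
                best = left
                p = 2
            score[i, j] = best
            ptr[i, j] = p
    # Traceback, recording per column (reversed order) match/gap status.
    total = n + m
    is_match = np.zeros(total, dtype=np.uint8)
    is_gap = np.zeros(total, dtype=np.uint8)
    i = n
    j = m
    k = 0
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == 0:
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                is_match[k] = 1
            i -= 1
            j -= 1
        elif i > 0 and (p == 1 or j == 0):
            is_gap[k] = 1
            i -= 1
        else:
            is_gap[k] = 1
            j -= 1
        k += 1
    # Trim terminal gap runs (columns are reversed: k-1 is alignment start).
    lo = 0
    hi = k
    while hi > lo and is_gap[hi - 1] == 1:
        hi -= 1
    while lo < hi and is_gap[lo] == 1:
        lo += 1
    matches = 0
    for t in range(lo, hi):
        matches += is_match[t]
    return matches, hi - lo


def global_identity(a: str, b: str) -> float:
    """Fraction of matching columns in the optimal global alignment of *a*
    and *b*, excluding terminal-gap columns from the denominator."""
    if not a or not b:
        raise SequenceError("global_identity requires non-empty sequences")
    ea = _ENCODE[np.frombuffer(a.upper().encode("ascii"), dtype=np.uint8)]
    eb = _ENCODE[np.frombuffer(b.upper().encode("ascii"), dtype=np.uint8)]
    if np.any(ea == 255) or np.any(eb == 255):
        raise SequenceError("sequences must be IUPAC DNA")
    matches, columns = _nw_counts(ea, eb)
    if columns == 0:
        return 0.0
    return matches / columns


def _hit_sort_key(identity: float, size: int, ref_id: str):
    return (-identity, -size, ref_id)


def top_hits(
    query: AnnotatedSequence,
    references: Sequence[AnnotatedSequence],
    k: int,
    min_identity: float = 0.0,
) -> list[Hit]:
    """Up to *k* references with identity >= *min_identity*, best first.

    Ties on identity prefer the larger reference ``size``, then the
    lexicographically smaller reference id.  The search is exhaustive.
    """
    if k < 1:
        raise SequenceError("k must be >= 1")
    scored = []
    q = query.encoded()
    for ref in references:
        matches, columns = _nw_counts(q, ref.encoded())
        identity = matches / columns if columns else 0.0
        if identity >= min_identity:
            scored.append((identity, ref.size, ref.id))
    scored.sort(key=lambda t: _hit_sort_key(*t))
    return [Hit(target_id=rid, identity=ident) for ident, _, rid in scored[:k]]


def canonical_order(sequences: Iterable[AnnotatedSequence]) -> list[AnnotatedSequence]:
    """Abundance-first processing order: size descending, ties by sequence
    string, then id.  Makes clustering independent of input file order."""
    return sorted(sequences, key=lambda s: (-s.size, s.seq, s.id))


def greedy_cluster(
    sequences: Sequence[AnnotatedSequence],
    threshold: float,
    level: str = "species",
    id_prefix: str = "cluster",
) -> list[Cluster]:
    """Single-pass abundance-greedy centroid clustering.

    Sequences are processed in :func:`canonical_order`; each joins the best
    existing centroid with identity >= *threshold* (inclusive) or founds a
    new cluster.  Centroids are founders and never re-computed.
    """
    if not sequences:
        raise SequenceError("greedy_cluster requires a non-empty input")
    if not 0.0 < threshold <= 1.0:
        raise SequenceError(f"threshold outside (0,1]: {threshold}")
    ids = [s.id for s in sequences]
    if len(set(ids)) != len(ids):
        raise SequenceError("duplicate sequence ids in clustering input")
    centroids: list[AnnotatedSequence] = []
    members: list[list[str]] = []
    sizes: list[int] = []
    for seq in canonical_order(sequences):
        q = seq.encoded()
        best = None  # (identity, centroid_size, centroid_id, index)
        for idx, centroid in enumerate(centroids):
            matches, columns = _nw_counts(q, centroid.encoded())
            identity = matches / columns if columns else 0.0
            key = (_hit_sort_key(identity, centroid.size, centroid.id), idx)
            if best is None or key < best[0]:
                best = (key, idx, identity)
        if best is not None and best[2] >= threshold:
            members[best[1]].append(seq.id)
            sizes[best[1]] += seq.size
        else:
            centroids.append(seq)
            members.append([seq.id])
            sizes.append(seq.size)
    return [
        Cluster(
            id=f"{id_prefix}_{i + 1}",
            level=level,
            centroid_id=c.id,
            member_ids=tuple(mem),
            taxonomy=c.taxonomy,
            novel=True,
            size=sz,
            centroid_seq=c.seq,
        )
        for i, (c, mem, sz) in enumerate(zip(centroids, members, sizes))
    ]
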