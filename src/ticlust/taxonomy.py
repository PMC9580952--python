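"""Taxonomic path model, parsing/formatting, LCA, and benchmark label pruning.

A :class:`TaxonomicPath` is an ordered assignment of names to the seven
canonical ranks (domain through species).  Unknown ranks are ``None``.
Three placeholder names (``UNKPHYLUM``, ``UNKCLASS``, ``UNKORDER``) stand in
for missing intermediate ranks above novel family-level clusters; no
placeholder exists for family, genus or species, which instead receive novel
``fOTU_n`` / ``gOTU_n`` / ``sOTU_n`` names during clustering.

The two pruning operations (:func:`hard_prune`, :func:`soft_prune`) degrade a
labelled dataset for benchmarking: hard pruning removes whole clades from the
label set, soft pruning removes labels from random individual sequences.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RANKS",
    "PLACEHOLDERS",
    "PLACEHOLDER_NAMES",
    "TaxonomicPath",
    "TaxonomyError",
    "PruneSpec",
    "parse_taxonomy",
    "format_taxonomy",
    "lca",
    "hard_prune",
    "soft_prune",
    "is_placeholder",
    "is_novel_name",
]

#: Canonical ranks, shallowest first.
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
RANK_INDEX: dict[str, int] = {r: i for i, r in enumerate(RANKS)}

#: Single-letter prefixes of the header dialect, aligned with RANKS.
RANK_PREFIXES: tuple[str, ...] = ("d", "p", "c", "o", "f", "g", "s")
_PREFIX_TO_RANK: dict[str, str] = dict(zip(RANK_PREFIXES, RANKS))

#: Placeholder names for missing intermediate ranks.
PLACEHOLDERS: dict[str, str] = {
    "phylum": "UNKPHYLUM",
    "class": "UNKCLASS",
    "order": "UNKORDER",
}
PLACEHOLDER_NAMES: frozenset[str] = frozenset(PLACEHOLDERS.values())

#: Ranks eligible for direct pruning (species is only erased transitively).
PRUNABLE_RANKS: tuple[str, ...] = ("genus", "family", "order", "class")

_NOVEL_PREFIXES: tuple[str, ...] = ("sOTU_", "gOTU_", "fOTU_")


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy annotations or invalid paths."""


def is_placeholder(name: str | None) -> bool:
    """True if *name* is one of the UNKPHYLUM/UNKCLASS/UNKORDER placeholders."""
    return name in PLACEHOLDER_NAMES


def is_novel_name(name: str | None) -> bool:
    """True if *name* is a clustering-assigned novel taxon name."""
    return name is not None and name.startswith(_NOVEL_PREFIXES)


@dataclass(frozen=True)
class TaxonomicPath:
    """An immutable ranked lineage; ``None`` marks an unknown rank."""

    names: tuple[str | None, ...] = (None,) * 7

    def __post_init__(self) -> None:
        if len(self.names) != len(RANKS):
            raise TaxonomyError(
                f"expected {len(RANKS)} rank slots, got {len(self.names)}"
            )
        for name in self.names:
            if name is not None and (not name or any(c in name for c in ";,=")):
                raise TaxonomyError(f"illegal taxon name {name!r}")

    # -- constructors ------------------------------------------------------

    @classmethod
    def empty(cls) -> "TaxonomicPath":
        return cls()

    @classmethod
    def from_names(cls, **by_rank: str | None) -> "TaxonomicPath":
        unknown = set(by_rank) - set(RANKS)
        if unknown:
            raise TaxonomyError(f"unknown rank(s): {sorted(unknown)}")
        return cls(tuple(by_rank.get(r) for r in RANKS))

    # -- accessors ---------------------------------------------------------

    def name(self, rank: str) -> str | None:
        return self.names[RANK_INDEX[rank]]

    def known(self, rank: str) -> bool:
        return self.name(rank) is not None

    def depth(self) -> int | None:
        """Index of the deepest known rank, or None for an empty path."""
        deepest = None
        for i, name in enumerate(self.names):
            if name is not None:
                deepest = i
        return deepest

    def depth_rank(self) -> str | None:
        d = self.depth()
        return None if d is None else RANKS[d]

    def prefix(self, rank: str) -> tuple[str | None, ...]:
        """Names from domain through *rank* inclusive (a hashable clade key)."""
        return self.names[: RANK_INDEX[rank] + 1]

    def is_prefix_contiguous(self) -> bool:
        """Known ranks form an unbroken chain from the top after placeholder
        substitution.  The domain slot may be unknown only when phylum holds
        the UNKPHYLUM placeholder (fully unclassified novel chains)."""
        d = self.depth()
        if d is None:
            return True
        for i in range(1, d):
            if self.names[i] is None:
                return False
        if self.names[0] is None and d >= 1 and self.names[1] != PLACEHOLDERS["phylum"]:
            return False
        return True

    # -- derivation --------------------------------------------------------

    def with_name(self, rank: str, name: str | None) -> "TaxonomicPath":
        i = RANK_INDEX[rank]
        return TaxonomicPath(self.names[:i] + (name,) + self.names[i + 1 :])

    def erase_from(self, rank: str) -> "TaxonomicPath":
        """Erase *rank* and every deeper rank."""
        i = RANK_INDEX[rank]
        return TaxonomicPath(self.names[:i] + (None,) * (len(RANKS) - i))

    def truncate(self, rank: str) -> "TaxonomicPath":
        """Keep ranks through *rank*, erase everything deeper."""
        i = RANK_INDEX[rank] + 1
        return TaxonomicPath(self.names[:i] + (None,) * (len(RANKS) - i))

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return format_taxonomy(self)


def parse_taxonomy(annotation: str) -> TaxonomicPath:
    """Parse a ``tax=d:...,p:...,...`` annotation into a :class:`TaxonomicPath`.

    The leading ``tax=`` is optional; an empty string yields an all-unknown
    path.  Absent ranks stay unknown.  Duplicate or unrecognised rank
    prefixes raise :class:`TaxonomyError` naming the offending token.
    """
    text = annotation.strip()
    if not text:
        return TaxonomicPath.empty()
    if text.startswith("tax="):
        text = text[4:]
    if not text:
        return TaxonomicPath.empty()
    names: list[str | None] = [None] * len(RANKS)
    for token in text.split(","):
        token = token.strip()
        if ":" not in token:
            raise TaxonomyError(f"malformed taxonomy token {token!r}")
        prefix, name = token.split(":", 1)
        rank = _PREFIX_TO_RANK.get(prefix)
        if rank is None:
            raise TaxonomyError(f"unknown rank prefix in token {token!r}")
        if not name:
            raise TaxonomyError(f"empty name in token {token!r}")
        i = RANK_INDEX[rank]
        if names[i] is not None:
            raise TaxonomyError(f"duplicate rank {rank!r} in token {token!r}")
        names[i] = name
    return TaxonomicPath(tuple(names))


def format_taxonomy(path: TaxonomicPath) -> str:
    """Canonical string form; inverse of :func:`parse_taxonomy`.

    All-unknown paths format as the empty string.
    """
    parts = [
        f"{prefix}:{name}"
        for prefix, name in zip(RANK_PREFIXES, path.names)
        if name is not None
    ]
    if not parts:
        return ""
    return "tax=" + ",".join(parts)


def lca(paths: Sequence[TaxonomicPath]) -> TaxonomicPath:
    """Deepest path on which every input agrees at all known ranks.

    Agreement is rank-wise from domain downward; the first rank at which any
    input is unknown or names disagree stops the walk, and everything deeper
    is unknown.
    """
    if not paths:
        raise TaxonomyError("lca of an empty path list is undefined")
    names: list[str | None] = []
    for i in range(len(RANKS)):
        here = {p.names[i] for p in paths}
        if len(here) == 1 and None not in here:
            names.append(next(iter(here)))
        else:
            break
    names.extend([None] * (len(RANKS) - len(names)))
    return TaxonomicPath(tuple(names))


@dataclass(frozen=True)
class PruneSpec:
    """Benchmark pruning parameters: per-rank removal rates, mode, seed.

    Default rates follow the benchmark convention of removing roughly
    10 / 5 / 2.5 / 1 % at genus / family / order / class.
    """

    rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "genus": 0.10,
            "family": 0.05,
            "order": 0.025,
            "class": 0.01,
        }
    )
    mode: str = "soft"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("hard", "soft"):
            raise TaxonomyError(f"unknown prune mode {self.mode!r}")
        extra = set(self.rates) - set(PRUNABLE_RANKS)
        if extra:
            raise TaxonomyError(f"unprunable rank(s): {sorted(extra)}")
        for rank, rate in self.rates.items():
            if not 0.0 <= rate <= 1.0:
                raise TaxonomyError(f"rate for {rank} outside [0,1]: {rate}")

    def rate(self, rank: str) -> float:
        return float(self.rates.get(rank, 0.0))


def hard_prune(
    paths: Mapping[str, TaxonomicPath], spec: PruneSpec
) -> dict[str, TaxonomicPath]:
    """Erase whole clades: per prunable rank, sample ``ceil(rate * n_clades)``
    distinct clades (without replacement, seeded) and erase that rank and all
    deeper ranks for every member sequence.

    Sampling per rank is independent and based on the input clades; when a
    sequence falls in several selected clades the shallowest erasure wins.
    """
    if spec.mode != "hard":
        raise TaxonomyError("hard_prune requires a PruneSpec with mode='hard'")
    rng = np.random.default_rng(spec.seed)
    selected: dict[str, set[tuple[str | None, ...]]] = {}
    for rank in PRUNABLE_RANKS:  # genus, family, order, class
        rate = spec.rate(rank)
        clades = sorted(
            {p.prefix(rank) for p in paths.values() if p.known(rank)},
            key=lambda t: tuple("" if n is None else n for n in t),
        )
        if rate <= 0.0 or not clades:
            selected[rank] = set()
            continue
        n_pick = min(len(clades), math.ceil(rate * len(clades)))
        picks = rng.choice(len(clades), size=n_pick, replace=False)
        selected[rank] = {clades[i] for i in sorted(picks)}
    out: dict[str, TaxonomicPath] = {}
    for seq_id in paths:
        path = paths[seq_id]
        for rank in ("class", "order", "family", "genus"):  # shallow first
            if path.known(rank) and path.prefix(rank) in selected[rank]:
                path = path.erase_from(rank)
                break
        out[seq_id] = path
    return out


def soft_prune(
    paths: Mapping[str, TaxonomicPath], spec: PruneSpec
) -> dict[str, TaxonomicPath]:
    """Erase labels stochastically per sequence: independently per prunable
    rank, with the rank's rate, erase that rank and all deeper ranks.
    Erasure at a shallow rank dominates deeper draws.
    """
    if spec.mode != "soft":
        raise TaxonomyError("soft_prune requires a PruneSpec with mode='soft'")
    rng = np.random.default_rng(spec.seed)
    shallow_first = ("class", "order", "family", "genus")
    out: dict[str, TaxonomicPath] = {}
    for seq_id in sorted(paths):
        path = paths[seq_id]
        draws = rng.random(len(shallow_first))  # always 4 draws: stable stream
        for rank, draw in zip(shallow_first, draws):
            if draw < spec.rate(rank):
                path = path.erase_from(rank)
                break
        out[seq_id] = path
    return out
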