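"""Taxonomy-informed incremental clustering.

Sequences are split by the depth of their classifier-assigned taxonomy and
processed in four stages, each working inside its taxonomic subset so that
sequences from different known lineages are never merged:

1. genus-known sequences are greedy-clustered per genus into molecular
   species (sOTUs) at the species cutoff;
2. family-known sequences are matched against the sOTU centroids of their
   family — joining (and adopting the match's taxonomy), founding a novel
   sOTU inside the matched genus, or deferring to batch clustering into
   novel sOTUs and novel gOTUs within the family;
3. order-known sequences do the same with an added family layer (novel
   fOTUs);
4. sequences of unknown order cascade against sOTUs sharing their known
   prefix, with missing intermediate ranks of unmatched chains filled by
   UNKORDER / UNKCLASS / UNKPHYLUM placeholders.

Novel names are global, sequential and deterministic: ``sOTU_n`` /
``gOTU_n`` / ``fOTU_n`` in processing order.
"""

from __future__ import annotations

import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

from .seqsim import (
    AnnotatedSequence,
    Cluster,
    SequenceError,
    _hit_sort_key,
    _nw_counts,
    canonical_order,
    greedy_cluster,
)
from .taxonomy import (
    PLACEHOLDERS,
    RANK_INDEX,
    RANKS,
    TaxonomicPath,
    is_novel_name,
)

__all__ = [
    "Cutoffs",
    "TicResult",
    "TicError",
    "cluster_known_genera",
    "place_family_level",
    "place_order_level",
    "place_unranked",
    "run_tic",
    "validate_result",
]


class TicError(ValueError):
    """Raised for invalid clustering inputs or inconsistent state."""


@dataclass(frozen=True)
class Cutoffs:
    """Identity cutoffs for the three cluster levels (species > genus > family)."""

    species: float = 0.97
    genus: float = 0.95
    family: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 < self.family < self.genus < self.species <= 1.0:
            raise TicError(
                "cutoffs must satisfy 0 < family < genus < species <= 1, got "
                f"{self.family}/{self.genus}/{self.species}"
            )


@dataclass
class TicResult:
    """Nested cluster layers plus the mappings and updated taxonomies."""

    sotus: list[Cluster] = field(default_factory=list)
    gotus: list[Cluster] = field(default_factory=list)
    fotus: list[Cluster] = field(default_factory=list)
    seq_to_sotu: dict[str, str] = field(default_factory=dict)
    sotu_to_gotu: dict[str, str] = field(default_factory=dict)
    gotu_to_fotu: dict[str, str] = field(default_factory=dict)
    updated_taxonomy: dict[str, TaxonomicPath] = field(default_factory=dict)

    @classmethod
    def empty(cls) -> "TicResult":
        return cls()

    def sequence_members(self, level: str) -> dict[str, list[str]]:
        """Cluster id -> member sequence ids, resolved through the hierarchy."""
        species = {c.id: list(c.member_ids) for c in self.sotus}
        if level == "species":
            return species
        genus = {c.id: [] for c in self.gotus}
        for sid, gid in self.sotu_to_gotu.items():
            genus[gid].extend(species[sid])
        if level == "genus":
            return genus
        if level == "family":
            family = {c.id: [] for c in self.fotus}
            for gid, fid in self.gotu_to_fotu.items():
                family[fid].extend(genus[gid])
            return family
        raise TicError(f"unknown level {level!r}")


class _Sotu:
    """Mutable sOTU record used while clustering is in progress."""

    __slots__ = ("id", "centroid", "members", "size", "tax")

    def __init__(self, sid: str, centroid: AnnotatedSequence, tax: TaxonomicPath):
        self.id = sid
        self.centroid = centroid
        self.members: list[str] = [centroid.id]
        self.size = centroid.size
        self.tax = tax


_NOVEL_RE = re.compile(r"^([sgf])OTU_(\d+)$")


class _Builder:
    def __init__(self, cutoffs: Cutoffs):
        self.cutoffs = cutoffs
        self.sotus: list[_Sotu] = []
        self.seq_to_sotu: dict[str, str] = {}
        self._counters = {"s": 0, "g": 0, "f": 0}
        # genus/family prefix -> (cluster id, centroid seq id, centroid seq)
        self.novel_gotu: dict[tuple, tuple[str, str, str]] = {}
        self.novel_fotu: dict[tuple, tuple[str, str, str]] = {}

    # -- naming ------------------------------------------------------------

    def _next(self, kind: str) -> str:
        self._counters[kind] += 1
        return f"{kind}OTU_{self._counters[kind]}"

    # -- sOTU bookkeeping --------------------------------------------------

    def _create_sotu(self, centroid: AnnotatedSequence, parent: TaxonomicPath) -> _Sotu:
        name = self._next("s")
        rec = _Sotu(name, centroid, parent.with_name("species", name))
        self.sotus.append(rec)
        self.seq_to_sotu[centroid.id] = name
        return rec

    def _join(self, rec: _Sotu, seq: AnnotatedSequence) -> None:
        rec.members.append(seq.id)
        rec.size += seq.size
        self.seq_to_sotu[seq.id] = rec.id

    def _best_hit(self, seq: AnnotatedSequence, pool: Sequence[_Sotu]):
        q = seq.encoded()
        best = None
        best_rec = None
        for rec in pool:
            matches, columns = _nw_counts(q, rec.centroid.encoded())
            identity = matches / columns if columns else 0.0
            key = _hit_sort_key(identity, rec.size, rec.id)
            if best is None or key < best:
                best = key
                best_rec = rec
        if best_rec is None:
            return None, 0.0
        return best_rec, -best[0]

    def _pool(self, rank: str | None, key: tuple | None) -> list[_Sotu]:
        if rank is None:
            return list(self.sotus)
        idx = RANK_INDEX[rank] + 1
        return [s for s in self.sotus if s.tax.names[:idx] == key]

    # -- stage 1: genus-known ----------------------------------------------

    def stage_known_genera(self, gseqs: Sequence[AnnotatedSequence]) -> None:
        groups: dict[tuple, list[AnnotatedSequence]] = {}
        for seq in gseqs:
            if not seq.taxonomy.known("genus"):
                raise TicError(f"{seq.id}: genus unknown in genus-known stage")
            groups.setdefault(seq.taxonomy.prefix("genus"), []).append(seq)
        for key in sorted(groups, key=_key_str):
            group = groups[key]
            parent = TaxonomicPath(key + (None,))
            by_id = {s.id: s for s in group}
            for cluster in greedy_cluster(group, self.cutoffs.species):
                rec = self._create_sotu(by_id[cluster.centroid_id], parent)
                for sid in cluster.member_ids:
                    if sid != cluster.centroid_id:
                        self._join(rec, by_id[sid])

    # -- stages 2-4: placement cascade -------------------------------------

    def stage_place(
        self,
        seqs: Sequence[AnnotatedSequence],
        group_rank: str | None,
        family_layer: bool,
    ) -> None:
        """Shared placement cascade.

        *group_rank* is the deepest known rank the sequences share (family
        for stage 2, order for stage 3, shallower or None for stage 4);
        *family_layer* enables the novel-fOTU tier for deferred sequences.
        """
        c = self.cutoffs
        groups: dict[tuple | None, list[AnnotatedSequence]] = {}
        for seq in seqs:
            key = None if group_rank is None else seq.taxonomy.prefix(group_rank)
            groups.setdefault(key, []).append(seq)
        for key in sorted(groups, key=lambda k: _key_str(k or ())):
            group = groups[key]
            pool = self._pool(group_rank, key)
            deferred: list[AnnotatedSequence] = []
            for seq in canonical_order(group):
                rec, identity = self._best_hit(seq, pool)
                if rec is not None and identity >= c.species:
                    self._join(rec, seq)
                elif rec is not None and identity >= c.genus:
                    new = self._create_sotu(seq, rec.tax.truncate("genus"))
                    pool.append(new)
                elif family_layer and rec is not None and identity >= c.family:
                    gname = self._next("g")
                    parent = rec.tax.truncate("family").with_name("genus", gname)
                    new = self._create_sotu(seq, parent)
                    self.novel_gotu[new.tax.prefix("genus")] = (gname, seq.id, seq.seq)
                    pool.append(new)
                else:
                    deferred.append(seq)
            if deferred:
                base = TaxonomicPath(
                    (key or ()) + (None,) * (len(RANKS) - len(key or ()))
                )
                self._cluster_deferred(deferred, base, family_layer)

    def _cluster_deferred(
        self,
        deferred: list[AnnotatedSequence],
        base: TaxonomicPath,
        family_layer: bool,
    ) -> None:
        """Batch-cluster unmatched sequences: novel sOTUs at the species
        cutoff, their centroids into novel gOTUs at the genus cutoff and,
        with *family_layer*, gOTU centroids into novel fOTUs."""
        c = self.cutoffs
        by_id = {s.id: s for s in deferred}
        new_sotus: list[_Sotu] = []
        for cluster in greedy_cluster(deferred, c.species):
            rec = self._create_sotu(by_id[cluster.centroid_id], base.truncate("genus"))
            for sid in cluster.member_ids:
                if sid != cluster.centroid_id:
                    self._join(rec, by_id[sid])
            new_sotus.append(rec)
        # Novel gOTUs from sOTU centroids.
        pseudo = [
            AnnotatedSequence(id=s.id, seq=s.centroid.seq, size=s.size)
            for s in new_sotus
        ]
        sotu_by_id = {s.id: s for s in new_sotus}
        genus_groups: list[tuple[str, _Sotu, list[_Sotu]]] = []
        for gc in greedy_cluster(pseudo, c.genus):
            gname = self._next("g")
            members = [sotu_by_id[sid] for sid in gc.member_ids]
            for s in members:
                s.tax = s.tax.with_name("genus", gname)
            genus_groups.append((gname, sotu_by_id[gc.centroid_id], members))
        family_groups: list[tuple[str, _Sotu, list[_Sotu]]] = []
        if family_layer and not base.known("family"):
            # Novel fOTUs from gOTU centroids.
            gpseudo = [
                AnnotatedSequence(
                    id=gname,
                    seq=centroid.centroid.seq,
                    size=sum(m.size for m in members),
                )
                for gname, centroid, members in genus_groups
            ]
            group_by_name = {g[0]: g for g in genus_groups}
            for fc in greedy_cluster(gpseudo, c.family):
                fname = self._next("f")
                f_members: list[_Sotu] = []
                for gname in fc.member_ids:
                    for s in group_by_name[gname][2]:
                        s.tax = s.tax.with_name("family", fname)
                        f_members.append(s)
                family_groups.append(
                    (fname, group_by_name[fc.centroid_id][1], f_members)
                )
        # Fill placeholders for ranks above family that remain unknown.
        for s in new_sotus:
            tax = s.tax
            for rank in ("order", "class", "phylum"):
                if tax.known("family") and not tax.known(rank):
                    tax = tax.with_name(rank, PLACEHOLDERS[rank])
            s.tax = tax
        # Register novel gOTUs and fOTUs under their final prefixes.
        for gname, centroid_sotu, members in genus_groups:
            self.novel_gotu[members[0].tax.prefix("genus")] = (
                gname,
                centroid_sotu.centroid.id,
                centroid_sotu.centroid.seq,
            )
        for fname, centroid_sotu, members in family_groups:
            self.novel_fotu[members[0].tax.prefix("family")] = (
                fname,
                centroid_sotu.centroid.id,
                centroid_sotu.centroid.seq,
            )

    # -- finalisation ------------------------------------------------------

    def finalize(self) -> TicResult:
        result = TicResult()
        for s in self.sotus:
            result.sotus.append(
                Cluster(
                    id=s.id,
                    level="species",
                    centroid_id=s.centroid.id,
                    member_ids=tuple(s.members),
                    taxonomy=s.tax,
                    novel=True,
                    size=s.size,
                    centroid_seq=s.centroid.seq,
                )
            )
            for sid in s.members:
                result.updated_taxonomy[sid] = s.tax
        result.seq_to_sotu = dict(self.seq_to_sotu)

        gotu_records: dict[tuple, dict] = {}
        for s in self.sotus:
            key = s.tax.prefix("genus")
            rec = gotu_records.get(key)
            if rec is None:
                if key in self.novel_gotu:
                    gid, cent_id, cent_seq = self.novel_gotu[key]
                    novel = True
                else:
                    gid = self._next("g")
                    cent_id, cent_seq = s.centroid.id, s.centroid.seq
                    novel = is_novel_name(key[-1])
                rec = {
                    "id": gid,
                    "centroid_id": cent_id,
                    "centroid_seq": cent_seq,
                    "members": [],
                    "size": 0,
                    "novel": novel,
                    "tax": TaxonomicPath(key + (None,)),
                }
                gotu_records[key] = rec
            rec["members"].append(s.id)
            rec["size"] += s.size
            result.sotu_to_gotu[s.id] = rec["id"]

        fotu_records: dict[tuple, dict] = {}
        for key, grec in gotu_records.items():
            fkey = key[: RANK_INDEX["family"] + 1]
            frec = fotu_records.get(fkey)
            if frec is None:
                if fkey in self.novel_fotu:
                    fid, cent_id, cent_seq = self.novel_fotu[fkey]
                    novel = True
                else:
                    fid = self._next("f")
                    cent_id, cent_seq = grec["centroid_id"], grec["centroid_seq"]
                    novel = is_novel_name(fkey[-1])
                frec = {
                    "id": fid,
                    "centroid_id": cent_id,
                    "centroid_seq": cent_seq,
                    "members": [],
                    "size": 0,
                    "novel": novel,
                    "tax": TaxonomicPath(fkey + (None,) * 2),
                }
                fotu_records[fkey] = frec
            frec["members"].append(grec["id"])
            frec["size"] += grec["size"]
            result.gotu_to_fotu[grec["id"]] = frec["id"]

        for rec, level in [(gotu_records, "genus"), (fotu_records, "family")]:
            target = result.gotus if level == "genus" else result.fotus
            for r in rec.values():
                target.append(
                    Cluster(
                        id=r["id"],
                        level=level,
                        centroid_id=r["centroid_id"],
                        member_ids=tuple(r["members"]),
                        taxonomy=r["tax"],
                        novel=r["novel"],
                        size=r["size"],
                        centroid_seq=r["centroid_seq"],
                    )
                )
        return result


def _key_str(key: tuple) -> tuple[str, ...]:
    return tuple("" if n is None else n for n in key)


def _builder_from(state: TicResult | None, cutoffs: Cutoffs) -> _Builder:
    builder = _Builder(cutoffs)
    if state is None:
        return builder
    seen_max = {"s": 0, "g": 0, "f": 0}

    def bump(name: str | None) -> None:
        if name is None:
            return
        m = _NOVEL_RE.match(name)
        if m:
            kind, num = m.group(1), int(m.group(2))
            seen_max[kind] = max(seen_max[kind], num)

    for cluster in state.sotus:
        if cluster.centroid_seq is None:
            raise TicError(f"sOTU {cluster.id} lacks a centroid sequence")
        centroid = AnnotatedSequence(
            id=cluster.centroid_id, seq=cluster.centroid_seq, size=1
        )
        rec = _Sotu(cluster.id, centroid, cluster.taxonomy)
        rec.members = list(cluster.member_ids)
        rec.size = cluster.size
        builder.sotus.append(rec)
        bump(cluster.id)
        for name in cluster.taxonomy.names:
            bump(name)
        for sid in cluster.member_ids:
            builder.seq_to_sotu[sid] = cluster.id
    for cluster in state.gotus:
        bump(cluster.id)
        if cluster.novel and cluster.centroid_seq is not None:
            builder.novel_gotu[cluster.taxonomy.prefix("genus")] = (
                cluster.id,
                cluster.centroid_id,
                cluster.centroid_seq,
            )
    for cluster in state.fotus:
        bump(cluster.id)
        if cluster.novel and cluster.centroid_seq is not None:
            builder.novel_fotu[cluster.taxonomy.prefix("family")] = (
                cluster.id,
                cluster.centroid_id,
                cluster.centroid_seq,
            )
    builder._counters.update(seen_max)
    return builder


# -- public operations -----------------------------------------------------


def cluster_known_genera(
    gseqs: Sequence[AnnotatedSequence], cutoffs: Cutoffs = Cutoffs()
) -> list[Cluster]:
    """Greedy-cluster genus-known sequences per genus at the species cutoff."""
    builder = _Builder(cutoffs)
    builder.stage_known_genera(gseqs)
    return builder.finalize().sotus


def place_family_level(
    fseqs: Sequence[AnnotatedSequence],
    state: TicResult | None,
    cutoffs: Cutoffs = Cutoffs(),
) -> TicResult:
    """Place family-known / genus-unknown sequences into the current state."""
    for seq in fseqs:
        if not seq.taxonomy.known("family") or seq.taxonomy.known("genus"):
            raise TicError(
                f"{seq.id}: family-level stage requires known family, unknown genus"
            )
    builder = _builder_from(state, cutoffs)
    builder.stage_place(fseqs, "family", family_layer=False)
    return builder.finalize()


def place_order_level(
    oseqs: Sequence[AnnotatedSequence],
    state: TicResult | None,
    cutoffs: Cutoffs = Cutoffs(),
) -> TicResult:
    """Place order-known / family-unknown sequences into the current state."""
    for seq in oseqs:
        if not seq.taxonomy.known("order") or seq.taxonomy.known("family"):
            raise TicError(
                f"{seq.id}: order-level stage requires known order, unknown family"
            )
    builder = _builder_from(state, cutoffs)
    builder.stage_place(oseqs, "order", family_layer=True)
    return builder.finalize()


def place_unranked(
    useqs: Sequence[AnnotatedSequence],
    state: TicResult | None,
    cutoffs: Cutoffs = Cutoffs(),
) -> TicResult:
    """Place sequences of unknown order, binned by their deepest known rank."""
    builder = _builder_from(state, cutoffs)
    bins: dict[str | None, list[AnnotatedSequence]] = {}
    for seq in useqs:
        if seq.taxonomy.known("order"):
            raise TicError(f"{seq.id}: order known; use place_order_level")
        bins.setdefault(seq.taxonomy.depth_rank(), []).append(seq)
    for rank in ("class", "phylum", "domain", None):
        if rank in bins:
            builder.stage_place(bins[rank], rank, family_layer=True)
    return builder.finalize()


def run_tic(
    dataset: Sequence[AnnotatedSequence], cutoffs: Cutoffs = Cutoffs()
) -> TicResult:
    """Run the full four-stage pipeline over *dataset*.

    Input taxonomies must be prefix-contiguous and ids unique.  Any input
    species rank is ignored: molecular species names are always assigned by
    clustering.
    """
    ids = [s.id for s in dataset]
    if len(set(ids)) != len(ids):
        raise TicError("duplicate sequence ids in dataset")
    staged: dict[str, list[AnnotatedSequence]] = {
        "genus": [],
        "family": [],
        "order": [],
        "unranked": [],
    }
    for seq in dataset:
        tax = seq.taxonomy
        if not tax.is_prefix_contiguous():
            raise TicError(f"{seq.id}: taxonomy is not prefix-contiguous")
        for name in tax.names:
            if is_novel_name(name):
                raise TicError(f"{seq.id}: reserved novel name {name!r} in input")
        if tax.known("species"):
            seq = AnnotatedSequence(
                id=seq.id,
                seq=seq.seq,
                taxonomy=tax.truncate("genus"),
                counts=dict(seq.counts),
                size=seq.size,
            )
        if seq.taxonomy.known("genus"):
            staged["genus"].append(seq)
        elif seq.taxonomy.known("family"):
            staged["family"].append(seq)
        elif seq.taxonomy.known("order"):
            staged["order"].append(seq)
        else:
            staged["unranked"].append(seq)
    builder = _Builder(cutoffs)
    builder.stage_known_genera(staged["genus"])
    builder.stage_place(staged["family"], "family", family_layer=False)
    builder.stage_place(staged["order"], "order", family_layer=True)
    bins: dict[str | None, list[AnnotatedSequence]] = {}
    for seq in staged["unranked"]:
        bins.setdefault(seq.taxonomy.depth_rank(), []).append(seq)
    for rank in ("class", "phylum", "domain", None):
        if rank in bins:
            builder.stage_place(bins[rank], rank, family_layer=True)
    return builder.finalize()


def validate_result(
    result: TicResult, dataset: Sequence[AnnotatedSequence]
) -> None:
    """Assert the structural invariants of a clustering result; raises
    :class:`TicError` on the first violation."""
    input_ids = {s.id for s in dataset}
    clustered = [sid for c in result.sotus for sid in c.member_ids]
    if sorted(clustered) != sorted(input_ids):
        raise TicError("sequences are not conserved through sOTUs")
    if set(result.seq_to_sotu) != input_ids:
        raise TicError("seq_to_sotu does not cover the dataset")
    for mapping, children, parents in (
        (result.sotu_to_gotu, result.sotus, result.gotus),
        (result.gotu_to_fotu, result.gotus, result.fotus),
    ):
        child_ids = {c.id for c in children}
        parent_ids = {c.id for c in parents}
        if set(mapping) != child_ids:
            raise TicError("hierarchy mapping does not cover all clusters")
        if set(mapping.values()) != parent_ids:
            raise TicError("hierarchy mapping is not surjective")
    names = [c.id for c in result.sotus + result.gotus + result.fotus]
    if len(set(names)) != len(names):
        raise TicError("cluster ids are not unique")
    by_id = {s.id: s for s in dataset}
    for level, clusters in (("genus", result.gotus), ("family", result.fotus)):
        members = result.sequence_members(level)
        for cluster in clusters:
            known = {
                by_id[sid].taxonomy.name(level)
                for sid in members[cluster.id]
                if by_id[sid].taxonomy.known(level)
            }
            if len(known) > 1:
                raise TicError(
                    f"{cluster.id} mixes input {level} names: {sorted(known)}"
                )
    for sid, updated in result.updated_taxonomy.items():
        original = by_id[sid].taxonomy
        for rank in RANKS[:-1]:  # input species rank is ignored by design
            if original.known(rank) and updated.name(rank) != original.name(rank):
                raise TicError(
                    f"{sid}: updated taxonomy contradicts input at {rank}"
                )


def taxonomy_blind_baseline(
    dataset: Sequence[AnnotatedSequence], threshold: float
) -> list[Cluster]:
    """Plain greedy clustering of the raw sequences, ignoring taxonomy; the
    naive baseline against which taxonomy-informed clustering is compared."""
    return greedy_cluster(dataset, threshold)
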