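"""k-nearest-neighbour LCA consensus classifier.

A query is placed at the deepest taxonomy shared, rank by rank from domain
downward, by at least ``consensus`` of its ``k`` closest labelled references
(default 7 of 10).  Assignment stops at the first rank without a consensus
name; deeper ranks stay unknown.
"""

from __future__ import annotations

from collections.abc import Sequence

from .seqsim import AnnotatedSequence, SequenceError, top_hits
from .taxonomy import RANKS, TaxonomicPath

__all__ = ["knn_lca_classify", "classify_all"]


def knn_lca_classify(
    query: AnnotatedSequence,
    references: Sequence[AnnotatedSequence],
    k: int = 10,
    consensus: int = 7,
    min_identity: float = 0.5,
) -> TaxonomicPath:
    """Classify *query* against labelled *references*.

    Consensus is counted per rank independently, top-down with early stop;
    references with an unknown name at a rank do not vote there.  When fewer
    than *k* references are available all are used and the consensus
    threshold keeps its absolute count.
    """
    if not 1 <= consensus <= k:
        raise SequenceError(f"need 1 <= consensus <= k, got {consensus}/{k}")
    if not references:
        return TaxonomicPath.empty()
    by_id = {}
    for ref in references:
        if ref.id in by_id:
            raise SequenceError(f"duplicate reference id {ref.id!r}")
        by_id[ref.id] = ref
    hits = top_hits(query, references, k=k, min_identity=min_identity)
    paths = [by_id[h.target_id].taxonomy for h in hits]
    names: list[str | None] = []
    for rank in RANKS:
        votes: dict[str, int] = {}
        for path in paths:
            name = path.name(rank)
            if name is not None:
                votes[name] = votes.get(name, 0) + 1
        if not votes:
            break
        # Highest count wins; ties broken lexicographically for determinism.
        best = min(votes, key=lambda nm: (-votes[nm], nm))
        if votes[best] >= consensus:
            names.append(best)
        else:
            break
    names.extend([None] * (len(RANKS) - len(names)))
    return TaxonomicPath(tuple(names))


def classify_all(
    queries: Sequence[AnnotatedSequence],
    references: Sequence[AnnotatedSequence],
    k: int = 10,
    consensus: int = 7,
    min_identity: float = 0.5,
) -> list[AnnotatedSequence]:
    """Classify every query; returns new sequences with assigned taxonomy."""
    out = []
    for query in queries:
        path = knn_lca_classify(
            query, references, k=k, consensus=consensus, min_identity=min_identity
        )
        out.append(
            AnnotatedSequence(
                id=query.id,
                seq=query.seq,
                taxonomy=path,
                counts=dict(query.counts),
                size=query.size,
            )
        )
    return out
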