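"""Seeded synthetic 16S-fragment communities with planted taxonomy.

Each family evolves from an independent random root; genus, species and
zOTU layers are derived by substituting *disjoint* position sets, so every
within-family pairwise substitution count is exact by construction and the
divergence tiers land strictly inside or outside the species/genus/family
cutoffs with a configurable guard band.  A post-hoc audit verifies the
tiers with the clustering engine's own alignment identity (which can
slightly exceed the substitution-count identity when a gapped alignment
scores better), re-seeding on violation up to a bounded retry count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seqsim import AnnotatedSequence
from .taxonomy import PruneSpec, TaxonomicPath, hard_prune, soft_prune

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "SimulationError",
    "simulate_lineages",
    "evolve_sequences",
    "simulate_counts",
    "make_benchmark",
    "make_adversarial_pair",
    "acceptance_params",
]

_BASES = "ACGT"


class SimulationError(RuntimeError):
    """Raised when a valid community cannot be generated."""


@dataclass(frozen=True)
class SimParams:
    """Shape, divergence tiers and abundance model of a synthetic community.

    Tier values are pairwise substitution fractions between leaf sequences:
    ``within_species`` is an upper bound; the two between-tier intervals are
    inclusive target ranges chosen so the 0.97/0.95/0.90 identity cutoffs
    separate the tiers with at least ``guard`` to spare.  Families evolve
    from independent random roots, so between-family identity is far below
    every cutoff.
    """

    n_families: int = 20
    genera_per_family: int = 5
    species_per_genus: int = 5
    zotus_per_species: int = 3
    seq_length: int = 300
    within_species: float = 0.01
    between_species: tuple[float, float] = (0.035, 0.045)
    between_genera: tuple[float, float] = (0.06, 0.09)
    between_families: tuple[float, float] = (0.12, 0.15)
    guard: float = 0.005
    n_samples: int = 5
    dispersion: float = 1.0
    mean_abundance: float = 50.0
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("n_families", "genera_per_family", "species_per_genus",
                     "zotus_per_species", "seq_length", "n_samples"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        tiers = [
            (0.0, self.within_species),
            self.between_species,
            self.between_genera,
            self.between_families,
        ]
        for lo, hi in tiers:
            if not 0.0 <= lo <= hi < 1.0:
                raise SimulationError(f"invalid tier interval ({lo}, {hi})")
        for (_, hi), (lo, _) in zip(tiers, tiers[1:]):
            if hi >= lo:
                raise SimulationError("divergence tiers must be strictly ordered")

    @property
    def n_genera(self) -> int:
        return self.n_families * self.genera_per_family

    @property
    def n_species(self) -> int:
        return self.n_genera * self.species_per_genus

    @property
    def n_sequences(self) -> int:
        return self.n_species * self.zotus_per_species


def acceptance_params(seed: int = 42, **overrides) -> SimParams:
    """The standard 20 x 5 x 5 x 3 = 1,500 sequence benchmark fixture."""
    return SimParams(seed=seed, **overrides)


@dataclass
class SyntheticTruth:
    """Ground truth: per-sequence full lineage, the generating tree, counts."""

    paths: dict[str, TaxonomicPath] = field(default_factory=dict)
    tree: dict[str, dict[str, dict[str, list[str]]]] = field(default_factory=dict)
    n_families: int = 0
    n_genera: int = 0
    n_species: int = 0


def simulate_lineages(params: SimParams) -> SyntheticTruth:
    """Deterministic tree of named families/genera/species under one
    synthetic domain/phylum/class/order, with one full path per zOTU."""
    truth = SyntheticTruth(
        n_families=params.n_families,
        n_genera=params.n_genera,
        n_species=params.n_species,
    )
    base = {
        "domain": "Bacteria",
        "phylum": "Phylum_1",
        "class": "Class_1",
        "order": "Order_1",
    }
    gi = si = zi = 0
    for fi in range(params.n_families):
        family = f"Family_{fi + 1:03d}"
        truth.tree[family] = {}
        for _ in range(params.genera_per_family):
            gi += 1
            genus = f"Genus_{gi:04d}"
            truth.tree[family][genus] = {}
            for _ in range(params.species_per_genus):
                si += 1
                species = f"Species_{si:05d}"
                leaves: list[str] = []
                for _ in range(params.zotus_per_species):
                    zi += 1
                    zid = f"zotu_{zi:06d}"
                    leaves.append(zid)
                    truth.paths[zid] = TaxonomicPath.from_names(
                        **base, family=family, genus=genus, species=species
                    )
                truth.tree[family][genus][species] = leaves
    return truth


def _edge_counts(params: SimParams) -> tuple[int, int, int, int]:
    """Per-edge substitution counts (zotu, species, genus lo/hi) that place
    leaf-pairwise divergences inside the tiers."""
    length = params.seq_length
    mz = 0 if params.within_species == 0 else max(1, int(params.within_species * length // 2))
    mid_s = sum(params.between_species) / 2.0
    ms = max(mz + 1, round((mid_s * length - 2 * mz) / 2))
    lo_g, hi_g = params.between_genera
    shared = 2 * (ms + mz)
    mg_lo = max(1, math.ceil((lo_g * length - shared) / 2))
    mg_hi = math.floor((hi_g * length - shared) / 2)
    if mg_hi < mg_lo:
        raise SimulationError(
            "between-genera tier too narrow for this seq_length; increase it"
        )
    # Keep to the upper part of the range: cross-genus identities must stay
    # several substitutions below the genus cutoff because an optimal gapped
    # alignment can report slightly higher identity than the substitution
    # count implies (observed inflation up to ~0.007 at 300 nt).
    mg_lo = max(mg_lo, mg_hi - 2)
    return mz, ms, mg_lo, mg_hi


def _mutate(rng: np.random.Generator, seq: np.ndarray, positions: np.ndarray) -> np.ndarray:
    child = seq.copy()
    shift = rng.integers(1, 4, positions.size)
    child[positions] = ((child[positions].astype(np.int64) + shift) % 4).astype(np.int8)
    return child


def _decode(seq: np.ndarray) -> str:
    return "".join(_BASES[b] for b in seq)


def evolve_sequences(
    truth: SyntheticTruth, params: SimParams, _max_retries: int = 3
) -> list[AnnotatedSequence]:
    """Generate one sequence per zOTU leaf of *truth*.

    One random root per family; each genus/species/zOTU edge substitutes a
    drawn number of distinct, family-internally disjoint positions (no back
    mutation), then an exhaustive audit checks every tier against the guard
    bands, re-seeding on violation up to ``_max_retries`` times.
    """
    mz, ms, mg_lo, mg_hi = _edge_counts(params)
    budget = (
        params.genera_per_family * mg_hi
        + params.genera_per_family * params.species_per_genus * ms
        + params.genera_per_family
        * params.species_per_genus
        * params.zotus_per_species
        * mz
    )
    if budget > params.seq_length:
        raise SimulationError(
            f"divergence budget {budget} exceeds seq_length {params.seq_length}; "
            "use a longer seq_length"
        )
    last_error: Exception | None = None
    for attempt in range(_max_retries):
        rng = np.random.default_rng([params.seed, attempt])
        sequences: list[AnnotatedSequence] = []
        for family in truth.tree:
            root = rng.integers(0, 4, params.seq_length, dtype=np.int8)
            free = rng.permutation(params.seq_length)
            cursor = 0

            def take(n: int) -> np.ndarray:
                nonlocal cursor
                pos = free[cursor : cursor + n]
                cursor += n
                return pos

            for genus in truth.tree[family]:
                mg = int(rng.integers(mg_lo, mg_hi + 1))
                genus_seq = _mutate(rng, root, take(mg))
                for species in truth.tree[family][genus]:
                    species_seq = _mutate(rng, genus_seq, take(ms))
                    for zid in truth.tree[family][genus][species]:
                        leaf = (
                            species_seq
                            if mz == 0
                            else _mutate(rng, species_seq, take(mz))
                        )
                        sequences.append(
                            AnnotatedSequence(
                                id=zid,
                                seq=_decode(leaf),
                                taxonomy=truth.paths[zid],
                            )
                        )
        try:
            audit_tiers(sequences, truth, params)
            return sequences
        except SimulationError as err:  # pragma: no cover - needs bad params
            last_error = err
    raise SimulationError(
        f"tier audit failed after {_max_retries} attempts "
        f"({last_error}); use a longer seq_length"
    )


def _identity_matrix(encoded: np.ndarray) -> np.ndarray:
    """All-pairs fraction of equal positions via one-hot matmul."""
    n, length = encoded.shape
    onehot = np.zeros((n, length * 4), dtype=np.float32)
    for b in range(4):
        onehot[:, b * length : (b + 1) * length] = encoded == b
    return (onehot @ onehot.T) / length


def audit_tiers(
    sequences: list[AnnotatedSequence],
    truth: SyntheticTruth,
    params: SimParams,
    cutoffs: tuple[float, float, float] = (0.97, 0.95, 0.90),
) -> dict[str, float]:
    """Verify that realized leaf identities respect the guard bands around
    the cutoffs, measured with the same global-alignment identity the
    clustering engine uses.

    Within-family pairs (the ones near the cutoffs) are checked
    exhaustively; the much more distant cross-family pairs are screened
    exhaustively on positionwise identity (they sit near 25% for
    independent roots) and alignment-checked on one representative pair per
    family pair.  Returns the realized tier extrema; raises
    :class:`SimulationError` on violation.
    """
    from .seqsim import _nw_counts

    species_cut, genus_cut, family_cut = cutoffs
    guard = params.guard
    extrema: dict[str, float] = {}

    def update(name: str, value: float) -> None:
        extrema[f"min_{name}"] = min(extrema.get(f"min_{name}", 1.0), value)
        extrema[f"max_{name}"] = max(extrema.get(f"max_{name}", 0.0), value)

    def require(name: str, lo: float | None, hi: float | None) -> None:
        if f"min_{name}" not in extrema:
            return
        if lo is not None and extrema[f"min_{name}"] <= lo:
            raise SimulationError(
                f"{name}: identity {extrema[f'min_{name}']:.4f} <= guard {lo:.4f}"
            )
        if hi is not None and extrema[f"max_{name}"] >= hi:
            raise SimulationError(
                f"{name}: identity {extrema[f'max_{name}']:.4f} >= guard {hi:.4f}"
            )

    by_family: dict[str, list[AnnotatedSequence]] = {}
    for seq in sequences:
        by_family.setdefault(truth.paths[seq.id].name("family"), []).append(seq)

    for members in by_family.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                matches, columns = _nw_counts(a.encoded(), b.encoded())
                identity = matches / columns if columns else 0.0
                pa, pb = truth.paths[a.id], truth.paths[b.id]
                if pa.name("species") == pb.name("species"):
                    update("within_species", identity)
                elif pa.name("genus") == pb.name("genus"):
                    update("between_species", identity)
                else:
                    update("between_genera", identity)
    require("within_species", species_cut + guard, None)
    require("between_species", genus_cut + guard, species_cut - guard)
    require("between_genera", family_cut + guard, genus_cut - guard)

    families = sorted(by_family)
    if len(families) > 1:
        # coarse positionwise screen over every cross-family pair
        encoded = np.array(
            [[_BASES.index(c) for c in s.seq] for s in sequences], dtype=np.int8
        )
        ident = _identity_matrix(encoded)
        family_idx = {f: i for i, f in enumerate(families)}
        labels = np.array(
            [family_idx[truth.paths[s.id].name("family")] for s in sequences]
        )
        cross = labels[:, None] != labels[None, :]
        screen_max = float(ident[cross].max())
        if screen_max >= 0.70:
            raise SimulationError(
                f"cross-family positionwise identity {screen_max:.4f} "
                "suspiciously high (>= 0.70)"
            )
        # alignment identity on one representative pair per family pair
        for i in range(len(families)):
            for j in range(i + 1, len(families)):
                a = by_family[families[i]][0]
                b = by_family[families[j]][0]
                matches, columns = _nw_counts(a.encoded(), b.encoded())
                update("between_families", matches / columns if columns else 0.0)
        require("between_families", None, family_cut - guard)
    return extrema


def simulate_counts(
    sequences: list[AnnotatedSequence], params: SimParams
) -> pd.DataFrame:
    """Seeded heavy-tailed per-sample abundances (log-normal, integerised,
    minimum 1).  Sets each sequence's ``counts``/``size`` in place and
    returns the table (rows = sequences in input order, columns = samples).
    """
    rng = np.random.default_rng([params.seed, 1000])
    samples = [f"sample_{i + 1}" for i in range(params.n_samples)]
    mu = math.log(params.mean_abundance)
    rows = []
    for seq in sequences:
        if params.dispersion == 0:
            values = np.full(params.n_samples, params.mean_abundance)
        else:
            values = rng.lognormal(mu, params.dispersion, params.n_samples)
        counts = np.maximum(1, np.rint(values)).astype(np.int64)
        seq.counts = dict(zip(samples, (int(c) for c in counts)))
        seq.size = int(counts.sum())
        rows.append(counts)
    return pd.DataFrame(rows, index=[s.id for s in sequences], columns=samples)


def make_benchmark(
    params: SimParams, prune: PruneSpec | None = None
) -> tuple[list[AnnotatedSequence], SyntheticTruth]:
    """Compose the generators into a benchmark dataset.

    The returned sequences carry the *observed* taxonomy — the true lineage
    truncated at genus (classifiers do not assign species) and optionally
    degraded by pruning — while the unpruned truth stays in the
    :class:`SyntheticTruth`.
    """
    truth = simulate_lineages(params)
    sequences = evolve_sequences(truth, params)
    simulate_counts(sequences, params)
    observed = {s.id: truth.paths[s.id].truncate("genus") for s in sequences}
    if prune is not None:
        if prune.mode == "hard":
            observed = hard_prune(observed, prune)
        else:
            observed = soft_prune(observed, prune)
    for seq in sequences:
        seq.taxonomy = observed[seq.id]
    return sequences, truth


def make_adversarial_pair(
    seed: int = 0, zotus_per_species: int = 3, seq_length: int = 300
) -> tuple[list[AnnotatedSequence], SyntheticTruth]:
    """A deliberately hostile fixture: two genera in one family whose
    cross-genus leaf identities sit *above* the 0.95 genus cutoff, so
    taxonomy-blind greedy clustering at that cutoff merges them while
    taxonomy-informed clustering keeps them apart."""
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(n_families=1, n_genera=2, n_species=2)
    base = {
        "domain": "Bacteria",
        "phylum": "Phylum_1",
        "class": "Class_1",
        "order": "Order_1",
        "family": "Family_001",
    }
    root = rng.integers(0, 4, seq_length, dtype=np.int8)
    free = rng.permutation(seq_length)
    # Genus B diverges by only 8 substitutions: cross-genus leaves are
    # ~0.967 identical, above the genus cutoff.
    genus_seqs = {"Genus_0001": root, "Genus_0002": _mutate(rng, root, free[:8])}
    sequences: list[AnnotatedSequence] = []
    truth.tree["Family_001"] = {}
    cursor = 8
    zi = 0
    for gi, (genus, gseq) in enumerate(genus_seqs.items()):
        species = f"Species_{gi + 1:05d}"
        truth.tree["Family_001"][genus] = {species: []}
        for _ in range(zotus_per_species):
            zi += 1
            zid = f"zotu_{zi:06d}"
            leaf = _mutate(rng, gseq, free[cursor : cursor + 1])
            cursor += 1
            path = TaxonomicPath.from_names(**base, genus=genus, species=species)
            truth.paths[zid] = path
            truth.tree["Family_001"][genus][species].append(zid)
            sequences.append(
                AnnotatedSequence(
                    id=zid, seq=_decode(leaf), taxonomy=path.truncate("genus")
                )
            )
    return sequences, truth
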