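"""Readers/writers for the on-disk artifacts plus alignment-region utilities.

Header dialect (bit-exact, SINTAX-style):
``>seqid;size=N;tax=d:...,p:...,c:...,o:...,f:...,g:...,s:...`` —
semicolon-separated key fields; absent ranks omitted; ``size=`` and ``tax=``
both optional.  Alignment coordinates are 1-based and inclusive.  All
writers use fixed ordering, UTF-8 and Unix newlines so reruns are
byte-identical.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .seqsim import AnnotatedSequence, SequenceError
from .taxonomy import TaxonomicPath, format_taxonomy, parse_taxonomy
from .tic_core import TicResult, validate_result

__all__ = [
    "FormatError",
    "CoverageProfile",
    "TrimResult",
    "read_annotated_fasta",
    "write_annotated_fasta",
    "write_result",
    "coverage_profile",
    "trim_to_region",
    "read_config",
    "write_truth_table",
    "read_truth_table",
]

GAP_CHARS = frozenset("-.")


class FormatError(ValueError):
    """Raised for malformed input files."""


def _parse_header(header: str) -> tuple[str, int, TaxonomicPath]:
    fields = header.split(";")
    seq_id = fields[0].strip()
    if not seq_id:
        raise FormatError(f"empty sequence id in header {header!r}")
    size = 1
    tax = TaxonomicPath.empty()
    for token in fields[1:]:
        token = token.strip()
        if not token:
            continue
        if token.startswith("size="):
            try:
                size = int(token[5:])
            except ValueError as err:
                raise FormatError(f"bad size field in header {header!r}") from err
            if size < 1:
                raise FormatError(f"size must be >= 1 in header {header!r}")
        elif token.startswith("tax="):
            tax = parse_taxonomy(token)
    return seq_id, size, tax


def _format_header(seq: AnnotatedSequence) -> str:
    parts = [seq.id, f"size={seq.size}"]
    tax = format_taxonomy(seq.taxonomy)
    if tax:
        parts.append(tax)
    return ";".join(parts)


def read_annotated_fasta(path: str | Path) -> list[AnnotatedSequence]:
    """Read a FASTA file in the annotated-header dialect.

    Sequences are uppercased; a missing ``size=`` field defaults to 1;
    duplicate ids and non-IUPAC characters raise :class:`FormatError`.
    """
    path = Path(path)
    sequences: list[AnnotatedSequence] = []
    seen: set[str] = set()
    with open(path) as handle:
        head = handle.read(1)
        if head not in (">", ""):
            raise FormatError(f"{path}: not FASTA (first byte {head!r})")
        handle.seek(0)
        for header, seq in SimpleFastaParser(handle):
            seq_id, size, tax = _parse_header(header)
            if seq_id in seen:
                raise FormatError(f"{path}: duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            try:
                sequences.append(
                    AnnotatedSequence(id=seq_id, seq=seq, taxonomy=tax, size=size)
                )
            except SequenceError as err:
                raise FormatError(f"{path}: {err}") from err
    return sequences


def write_annotated_fasta(
    sequences: Sequence[AnnotatedSequence], path: str | Path, width: int = 80
) -> None:
    path = Path(path)
    with open(path, "w", newline="\n") as handle:
        for seq in sequences:
            handle.write(f">{_format_header(seq)}\n")
            for i in range(0, len(seq.seq), width):
                handle.write(seq.seq[i : i + width] + "\n")


def write_truth_table(paths: dict[str, TaxonomicPath], path: str | Path) -> None:
    """Two-column TSV: sequence id, taxonomy string (sorted by id)."""
    with open(Path(path), "w", newline="\n") as handle:
        handle.write("seq_id\ttaxonomy\n")
        for sid in sorted(paths):
            handle.write(f"{sid}\t{format_taxonomy(paths[sid])}\n")


def read_truth_table(path: str | Path) -> dict[str, TaxonomicPath]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return {
        row.seq_id: parse_taxonomy(row.taxonomy) for row in frame.itertuples()
    }


def write_result(
    result: TicResult,
    dataset: Sequence[AnnotatedSequence],
    counts: pd.DataFrame | None,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the clustering outputs: annotated FASTA with updated paths, the
    zOTU table (rows = sequences, columns = samples, last column taxonomy),
    and the two hierarchy mapping TSVs.  Consistency is validated before any
    file is written; outputs are byte-stable across reruns.
    """
    validate_result(result, dataset)
    outdir = Path(outdir)
    if counts is not None:
        missing = {s.id for s in dataset} - set(counts.index)
        if missing:
            raise FormatError(f"count table lacks rows for {sorted(missing)[:3]}...")
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    ordered = sorted(dataset, key=lambda s: s.id)
    annotated = [
        AnnotatedSequence(
            id=s.id,
            seq=s.seq,
            taxonomy=result.updated_taxonomy[s.id],
            counts=dict(s.counts),
            size=s.size,
        )
        for s in ordered
    ]
    files["fasta"] = outdir / "zotus_annotated.fasta"
    write_annotated_fasta(annotated, files["fasta"])

    files["table"] = outdir / "zotu_table.tsv"
    with open(files["table"], "w", newline="\n") as handle:
        if counts is not None:
            samples = sorted(counts.columns)
            handle.write("#zOTU\t" + "\t".join(samples) + "\ttaxonomy\n")
            for seq in ordered:
                row = counts.loc[seq.id]
                values = "\t".join(str(int(row[c])) for c in samples)
                handle.write(
                    f"{seq.id}\t{values}\t"
                    f"{format_taxonomy(result.updated_taxonomy[seq.id])}\n"
                )
        else:
            handle.write("#zOTU\tsize\ttaxonomy\n")
            for seq in ordered:
                handle.write(
                    f"{seq.id}\t{seq.size}\t"
                    f"{format_taxonomy(result.updated_taxonomy[seq.id])}\n"
                )

    files["sotu_to_gotu"] = outdir / "sotu_to_gotu.tsv"
    with open(files["sotu_to_gotu"], "w", newline="\n") as handle:
        handle.write("sOTU\tgOTU\n")
        for cluster in result.sotus:
            handle.write(f"{cluster.id}\t{result.sotu_to_gotu[cluster.id]}\n")

    files["gotu_to_fotu"] = outdir / "gotu_to_fotu.tsv"
    with open(files["gotu_to_fotu"], "w", newline="\n") as handle:
        handle.write("gOTU\tfOTU\n")
        for cluster in result.gotus:
            handle.write(f"{cluster.id}\t{result.gotu_to_fotu[cluster.id]}\n")
    return files


@dataclass(frozen=True)
class CoverageProfile:
    """Per-column count of non-gap characters in a multiple alignment."""

    counts: np.ndarray
    alignment_length: int
    n_sequences: int


def _read_alignment(path: str | Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    with open(Path(path)) as handle:
        for header, seq in SimpleFastaParser(handle):
            records.append((header, seq.upper()))
    if not records:
        raise FormatError(f"{path}: empty alignment")
    length = len(records[0][1])
    for header, seq in records:
        if len(seq) != length:
            raise FormatError(
                f"{path}: ragged alignment ({header.split(';')[0]} has length "
                f"{len(seq)}, expected {length})"
            )
    return records


def coverage_profile(aligned_fasta: str | Path) -> CoverageProfile:
    """Count non-gap characters ('-' and '.' are gaps) per alignment column."""
    records = _read_alignment(aligned_fasta)
    length = len(records[0][1])
    counts = np.zeros(length, dtype=np.int64)
    for _, seq in records:
        counts += np.array([c not in GAP_CHARS for c in seq], dtype=np.int64)
    return CoverageProfile(
        counts=counts, alignment_length=length, n_sequences=len(records)
    )


@dataclass
class TrimResult:
    sequences: list[AnnotatedSequence]
    n_kept: int
    n_discarded: int


def trim_to_region(
    aligned_fasta: str | Path,
    start: int,
    end: int,
    min_bases: int = 1,
    dereplicate: bool = False,
) -> TrimResult:
    """Slice alignment columns ``[start, end]`` (1-based, inclusive), drop
    gap characters, and discard sequences with fewer than *min_bases*
    remaining bases.

    With ``dereplicate=True``, identical post-trim sequences are merged:
    sizes summed, the lexicographically smallest id (and its taxonomy) kept.
    """
    records = _read_alignment(aligned_fasta)
    length = len(records[0][1])
    if not 1 <= start <= end <= length:
        raise FormatError(
            f"region {start}..{end} outside alignment of length {length}"
        )
    kept: list[AnnotatedSequence] = []
    discarded = 0
    for header, seq in records:
        seq_id, size, tax = _parse_header(header)
        fragment = "".join(c for c in seq[start - 1 : end] if c not in GAP_CHARS)
        if len(fragment) < min_bases:
            discarded += 1
            continue
        kept.append(
            AnnotatedSequence(id=seq_id, seq=fragment, taxonomy=tax, size=size)
        )
    if dereplicate:
        by_seq: dict[str, AnnotatedSequence] = {}
        for seq in sorted(kept, key=lambda s: s.id):
            prior = by_seq.get(seq.seq)
            if prior is None:
                by_seq[seq.seq] = seq
            else:
                prior.size += seq.size
        kept = sorted(by_seq.values(), key=lambda s: s.id)
    return TrimResult(sequences=kept, n_kept=len(kept), n_discarded=discarded)


def read_config(path: str | Path) -> dict[str, str]:
    """Plain-text ``key=value`` configuration; '#' starts a comment."""
    options: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = line.split("=", 1)
        options[key.strip()] = value.strip()
    return options
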