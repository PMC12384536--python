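"""Competitive zero-mismatch read classification against two parental references.

A read "maps" to a parent iff the read sequence or its reverse complement
is an exact substring of at least one of that parent's transcripts
(zero-mismatch alignment over a transcriptome collapses to exact substring
matching).  Reads are classed competitively:

    PARENT1_SPECIFIC  matches parent 1 only
    PARENT2_SPECIFIC  matches parent 2 only
    SHARED            matches both
    UNMAPPED          matches neither (reads containing N are unmapped by
                      definition: exact matching cannot satisfy ambiguity
                      codes)

The index is a seed-and-verify k-mer position table: every k-mer start
position in every transcript is recorded; a query is located by looking up
its first k-mer and verifying the full sequence at each candidate
position.  Queries shorter than k fall back to a linear scan.  The
semantics are identical to a naive per-transcript substring scan and are
tested against one.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .simulate import ParentalReference, reverse_complement

__all__ = [
    "ExactMatchIndex",
    "ReadClassification",
    "build_index",
    "classify_read",
    "partition_fastq",
    "CLASSES",
]

CLASSES = ("PARENT1_SPECIFIC", "PARENT2_SPECIFIC", "SHARED", "UNMAPPED")

_VALID = frozenset("ACGTN")


@dataclass
class ExactMatchIndex:
    """Exact-substring membership structure over one parent's transcripts."""

    parent_label: str
    k: int
    transcripts: dict[str, str]
    _seeds: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)

    def lookup(self, query: str) -> set[tuple[str, str]]:
        """All (transcript_id, strand) exact hits of the query, both strands."""
        if not query:
            raise ValueError("empty query sequence")
        hits: set[tuple[str, str]] = set()
        for strand, q in (("+", query), ("-", reverse_complement(query))):
            if len(q) >= self.k:
                for tid, pos in self._seeds.get(q[: self.k], ()):
                    if self.transcripts[tid].startswith(q, pos):
                        hits.add((tid, strand))
            else:  # short query: linear scan
                for tid, seq in self.transcripts.items():
                    if q in seq:
                        hits.add((tid, strand))
        return hits

    def __contains__(self, query: str) -> bool:
        return bool(self.lookup(query))


def build_index(ref: ParentalReference, k: int = 31) -> ExactMatchIndex:
    """Build the k-mer seed index for one parental reference.

    ``k`` trades memory for candidate-list length; any value gives the
    same answers.  Raises on an empty reference.
    """
    if not ref.transcripts:
        raise ValueError("cannot index an empty reference")
    seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for tid in sorted(ref.transcripts):
        seq = ref.transcripts[tid]
        for pos in range(len(seq) - k + 1):
            seeds[seq[pos : pos + k]].append((tid, pos))
    return ExactMatchIndex(ref.parent_label, k, dict(ref.transcripts), dict(seeds))


@dataclass
class ReadClassification:
    read_id: str
    klass: str
    hits1: set[tuple[str, str]]
    hits2: set[tuple[str, str]]


def _classify_sequence(seq: str, idx1: ExactMatchIndex, idx2: ExactMatchIndex):
    if not seq:
        raise ValueError("empty read sequence")
    seq = seq.upper()
    if set(seq) - _VALID:
        raise ValueError(f"read contains characters outside ACGTN: {seq!r}")
    if "N" in seq:
        return "UNMAPPED", set(), set()
    h1 = idx1.lookup(seq)
    h2 = idx2.lookup(seq)
    if h1 and h2:
        klass = "SHARED"
    elif h1:
        klass = "PARENT1_SPECIFIC"
    elif h2:
        klass = "PARENT2_SPECIFIC"
    else:
        klass = "UNMAPPED"
    return klass, h1, h2


def classify_read(
    sequence: str, idx1: ExactMatchIndex, idx2: ExactMatchIndex, read_id: str = ""
) -> ReadClassification:
    """Classify one read competitively between the two parental indexes."""
    klass, h1, h2 = _classify_sequence(sequence, idx1, idx2)
    return ReadClassification(read_id, klass, h1, h2)


def _fmt_hits(hits: set[tuple[str, str]]) -> str:
    return ",".join(f"{tid}:{strand}" for tid, strand in sorted(hits)) or "."


def partition_fastq(
    fastq_in: str | Path,
    idx1: ExactMatchIndex,
    idx2: ExactMatchIndex,
    outdir: str | Path,
    prefix: str | None = None,
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Split a FASTQ into parent1 / parent2 / shared / unmapped files.

    Every input record lands in exactly one output file, input order
    preserved.  Returns the four output paths keyed by class and the
    manifest (read_id, class, hits1, hits2) as a DataFrame; the manifest
    TSV is written alongside the FASTQ files.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    fastq_in = Path(fastq_in)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix if prefix is not None else fastq_in.stem
    names = {
        "PARENT1_SPECIFIC": outdir / f"{prefix}.parent1.fastq",
        "PARENT2_SPECIFIC": outdir / f"{prefix}.parent2.fastq",
        "SHARED": outdir / f"{prefix}.shared.fastq",
        "UNMAPPED": outdir / f"{prefix}.unmapped.fastq",
    }
    handles = {klass: open(path, "w") for klass, path in names.items()}
    rows = []
    try:
        with open(fastq_in) as fh:
            it = FastqGeneralIterator(fh)
            i = 0
            while True:
                try:
                    title, seq, qual = next(it)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise ValueError(f"malformed FASTQ record at index {i} in {fastq_in}: {exc}") from exc
                read_id = title.split()[0]
                klass, h1, h2 = _classify_sequence(seq, idx1, idx2)
                handles[klass].write(f"@{title}\n{seq}\n+\n{qual}\n")
                rows.append((read_id, klass, _fmt_hits(h1), _fmt_hits(h2)))
                i += 1
    finally:
        for fh in handles.values():
            fh.close()
    manifest = pd.DataFrame(rows, columns=["read_id", "class", "hits1", "hits2"])
    manifest.to_csv(outdir / f"{prefix}.manifest.tsv", sep="\t", index=False)
    return names, manifest
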