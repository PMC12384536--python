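"""Per-allele gene-level counting and FPKM/TPM normalization.

Only parent-specific reads are quantified: shared reads cannot be
attributed to an allele and are excluded from the allele matrices (their
tally is kept in the per-sample QC ledger).  A parent-specific read
increments its gene iff every transcript it hits in that parent belongs
to one single gene; reads spanning transcripts of two or more genes are
discarded as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AlleleCountMatrix",
    "NormalizedMatrix",
    "count_by_gene",
    "count_matrices_from_manifests",
    "fpkm",
    "tpm",
]

_CLASS_FOR_PARENT = {"parent1": "PARENT1_SPECIFIC", "parent2": "PARENT2_SPECIFIC"}
_HITS_COL = {"parent1": "hits1", "parent2": "hits2"}


@dataclass
class AlleleCountMatrix:
    """Genes x samples integer counts for one parental allele."""

    parent_label: str
    counts: pd.DataFrame  # index: gene ids, columns: sample ids
    library_sizes: pd.Series  # per-sample assigned parent-specific reads

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not (self.counts.sum(axis=0) <= self.library_sizes[self.counts.columns]).all():
            raise ValueError("column sums exceed library sizes")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.rename_axis("gene").to_csv(path, sep="\t")


@dataclass
class NormalizedMatrix:
    mode: str  # "fpkm" or "tpm"
    values: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("gene").to_csv(path, sep="\t", float_format="%.6g")


def count_by_gene(
    manifest: pd.DataFrame,
    transcript_to_gene: dict[str, str],
    parent_label: str,
    genes: list[str] | None = None,
) -> tuple[pd.Series, dict[str, int]]:
    """Count one sample's parent-specific reads per gene.

    Returns the count vector (indexed by gene) and a QC ledger
    ``{assigned, ambiguous, shared, unmapped, other_parent}``.  Raises if
    a manifest hit names a transcript absent from the map.
    """
    if parent_label not in _CLASS_FOR_PARENT:
        raise ValueError(f"parent_label must be parent1 or parent2, got {parent_label!r}")
    want = _CLASS_FOR_PARENT[parent_label]
    hits_col = _HITS_COL[parent_label]
    counts: dict[str, int] = {}
    ledger = {"assigned": 0, "ambiguous": 0, "shared": 0, "unmapped": 0, "other_parent": 0}
    for klass, hits in zip(manifest["class"], manifest[hits_col]):
        if klass == "SHARED":
            ledger["shared"] += 1
        elif klass == "UNMAPPED":
            ledger["unmapped"] += 1
        elif klass != want:
            ledger["other_parent"] += 1
        else:
            hit_genes = set()
            for h in hits.split(","):
                tid = h.rsplit(":", 1)[0]
                if tid not in transcript_to_gene:
                    raise KeyError(
                        f"transcript {tid!r} in manifest is absent from the transcript-to-gene map"
                    )
                hit_genes.add(transcript_to_gene[tid])
            if len(hit_genes) == 1:
                g = hit_genes.pop()
                counts[g] = counts.get(g, 0) + 1
                ledger["assigned"] += 1
            else:
                ledger["ambiguous"] += 1
    index = genes if genes is not None else sorted(set(transcript_to_gene.values()))
    vec = pd.Series(counts, dtype=np.int64).reindex(index, fill_value=0)
    vec.index.name = "gene"
    return vec, ledger


def count_matrices_from_manifests(
    manifests: dict[str, pd.DataFrame],
    transcript_to_gene_1: dict[str, str],
    transcript_to_gene_2: dict[str, str],
) -> tuple[AlleleCountMatrix, AlleleCountMatrix, pd.DataFrame]:
    """Assemble both allele matrices from per-sample manifests.

    Returns (parent1 matrix, parent2 matrix, QC ledger frame with one row
    per sample x parent).
    """
    samples = list(manifests)
    cols1, cols2, ledger_rows = {}, {}, []
    for sample in samples:
        v1, l1 = count_by_gene(manifests[sample], transcript_to_gene_1, "parent1")
        v2, l2 = count_by_gene(manifests[sample], transcript_to_gene_2, "parent2")
        cols1[sample], cols2[sample] = v1, v2
        ledger_rows.append({"sample": sample, "parent": "parent1", **l1})
        ledger_rows.append({"sample": sample, "parent": "parent2", **l2})
    m1 = pd.DataFrame(cols1)
    m2 = pd.DataFrame(cols2)
    lib1 = pd.Series({s: int(cols1[s].sum()) for s in samples})
    lib2 = pd.Series({s: int(cols2[s].sum()) for s in samples})
    return (
        AlleleCountMatrix("parent1", m1, lib1),
        AlleleCountMatrix("parent2", m2, lib2),
        pd.DataFrame(ledger_rows),
    )


def fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series | dict, library_sizes: pd.Series | dict
) -> NormalizedMatrix:
    """Fragments per kilobase of transcript per million mapped reads.

    ``value = count / (length_kb * library_size_millions)``.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    libs = pd.Series(library_sizes).reindex(counts.columns)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every gene needs a positive length")
    if (libs <= 0).any() or libs.isna().any():
        raise ValueError("every sample needs a positive library size")
    vals = counts.div(lengths / 1e3, axis=0).div(libs / 1e6, axis=1)
    return NormalizedMatrix("fpkm", vals.astype(float))


def tpm(counts: pd.DataFrame, gene_lengths: pd.Series | dict) -> NormalizedMatrix:
    """Transcripts per million: length-normalized rates rescaled to 1e6 per sample.

    An all-zero sample stays all-zero.
    """
    if (pd.DataFrame(counts).values < 0).any():
        raise ValueError("counts must be non-negative")
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("every gene needs a positive length")
    rate = counts.div(lengths, axis=0).astype(float)
    denom = rate.sum(axis=0)
    denom = denom.replace(0.0, np.nan)
    vals = (rate.div(denom, axis=1) * 1e6).fillna(0.0)
    return NormalizedMatrix("tpm", vals)
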