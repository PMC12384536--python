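"""Homolog harmonization: align the two allele matrices over one-to-one pairs.

A homolog pair is retained only if (a) both genes are present in their
respective matrices and (b) neither gene participates in any other
candidate pair (many-to-many tangles are dropped entirely rather than
collapsed — the conservative reading of "harmonized or filtered").
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .quantify import AlleleCountMatrix
from .simulate import HomologTable

__all__ = ["JointAlleleMatrix", "harmonize"]


@dataclass
class JointAlleleMatrix:
    """Row-aligned per-allele count matrices over the common homolog pairs."""

    common_genes: list[tuple[str, str]]  # (parent1 gene, parent2 gene), ordered by parent1 gene
    counts1: pd.DataFrame
    counts2: pd.DataFrame
    library_sizes1: pd.Series
    library_sizes2: pd.Series
    report: dict

    @property
    def n_common(self) -> int:
        return len(self.common_genes)

    @property
    def samples(self) -> list[str]:
        return list(self.counts1.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {"parent1_gene": [a for a, _ in self.common_genes], "parent2_gene": [b for _, b in self.common_genes]}
        )
        for s in self.samples:
            out[f"{s}.p1"] = self.counts1[s].to_numpy()
            out[f"{s}.p2"] = self.counts2[s].to_numpy()
        out.to_csv(path, sep="\t", index=False)


def harmonize(
    m1: AlleleCountMatrix, m2: AlleleCountMatrix, homologs: HomologTable
) -> JointAlleleMatrix:
    """Restrict both matrices to the one-to-one homolog pairs present in both.

    Rows are ordered by parent-1 gene id.  Idempotent: harmonizing the
    result again returns it unchanged.
    """
    if list(m1.samples) != list(m2.samples):
        raise ValueError("sample lists of the two allele matrices differ")
    deg1 = Counter(a for a, _ in homologs.pairs)
    deg2 = Counter(b for _, b in homologs.pairs)
    seen1, seen2 = set(m1.genes), set(m2.genes)
    kept, dropped_absent, dropped_tangled = [], 0, 0
    for a, b in homologs.pairs:
        if deg1[a] > 1 or deg2[b] > 1:
            dropped_tangled += 1
        elif a not in seen1 or b not in seen2:
            dropped_absent += 1
        else:
            kept.append((a, b))
    kept.sort(key=lambda p: p[0])
    report = {
        "n_genes_parent1": len(m1.genes),
        "n_genes_parent2": len(m2.genes),
        "n_pairs_input": len(homologs.pairs),
        "n_dropped_absent": dropped_absent,
        "n_dropped_many_to_many": dropped_tangled,
        "n_common": len(kept),
    }
    c1 = m1.counts.loc[[a for a, _ in kept]]
    c2 = m2.counts.loc[[b for _, b in kept]]
    return JointAlleleMatrix(kept, c1, c2, m1.library_sizes, m2.library_sizes, report)
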