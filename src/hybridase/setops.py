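"""Gene-set filtering logic and hypergeometric over-representation analysis.

Two set operations isolate the reprogramming-associated biased genes:
subtracting fibroblast-borne differential alleles from the iPSC contrast
(removing differences inherited from the somatic state), and intersecting
allelically biased genes with differentially expressed genes.  Candidate
pathway sets are then scored by the upper-tail hypergeometric probability
of the observed overlap, with Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "ipsc_specific_deas",
    "bias_de_intersection",
    "hypergeometric_enrichment",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.sets = {name: set(s) & self.universe for name, s in self.sets.items()}


def ipsc_specific_deas(dea_ipsc, dea_fibro) -> list[str]:
    """Differential alleles specific to the iPSC contrast.

    Set difference ``dea_ipsc \\ dea_fibro``, sorted for deterministic
    output: removes differential alleles already present between the
    fibroblast states (inherited interspecies differences), leaving the
    reprogramming-specific set.
    """
    return sorted(set(dea_ipsc) - set(dea_fibro))


def bias_de_intersection(biased, de) -> list[str]:
    """Genes both allelically biased and differentially expressed (sorted)."""
    return sorted(set(biased) & set(de))


def hypergeometric_enrichment(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Over-representation of the query in each collection set.

    Per set: ``p = P[X >= overlap]`` for X hypergeometric drawing
    ``|query|`` genes from the universe with ``|set|`` marked.  Query genes
    outside the universe are dropped (their count is returned in the
    ``n_query_dropped`` frame attribute).  Rows sorted by p then set name.
    """
    query = set(query)
    dropped = len(query - collection.universe)
    query &= collection.universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    M = len(collection.universe)
    N = len(query)
    rows = []
    for name in sorted(collection.sets):
        s = collection.sets[name]
        k = len(s & query)
        p = float(stats.hypergeom.sf(k - 1, M, len(s), N))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(s),
                "query_size": N,
                "universe_size": M,
                "p_value": min(1.0, p),
            }
        )
    out = pd.DataFrame(rows)
    out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    out = out.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    out.attrs["n_query_dropped"] = dropped
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\t{description}\t{genes}\n")
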