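"""Negative-binomial differential testing and allelic-bias calling.

Differential expression between two groups of replicated count samples is
tested with an exact conditional NB test: after equalizing library sizes,
group sums ``A`` and ``B`` are modeled as sums of i.i.d. NB(mu, phi)
variables (so ``A ~ NB(n_a mu, phi/n_a)``); under the null of equal
per-replicate means both group sums share the NB success parameter and

    A | A + B = t  ~  BetaBinomial(t, n_a/phi, n_b/phi),

which degenerates to Binomial(t, n_a/(n_a+n_b)) as phi -> 0.  The
two-sided p-value sums the conditional probabilities of all outcomes no
more likely than the observed one (exact enumeration up to t = 10,000,
normal approximation beyond).  This is the conditional test that
likelihood-based DE tools approximate, derived and implemented here
independently.

Allelic bias within one cell type is tested by pooling the per-sample
allele counts (after scaling the minority library to the majority) and
applying a two-sided exact binomial test against an equal 0.5 split.

Significance calls use raw p-values with the thresholds |log2FC| > 1 and
p < 0.05; BH q-values are reported alongside but never used for flags.
Fold changes add a 0.5 pseudo-count to each group mean so zeros stay
defined.  Tests run on counts with library-size adjustment; FPKM/TPM are
reporting units only — count models on normalized values are invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DispersionEstimate",
    "BiasResult",
    "estimate_common_dispersion",
    "nb_exact_test",
    "call_deas",
    "allelic_bias_test",
    "allelic_bias_table",
]

EXACT_ENUMERATION_LIMIT = 10_000


@dataclass
class DispersionEstimate:
    phi: float
    n_genes_used: int


@dataclass
class BiasResult:
    gene_id: str
    bias_score: float
    binom_p: float
    biased_toward: str  # "parent1" | "parent2" | "none"
    pooled1: int
    pooled2: int


def _geometric_mean(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("library sizes must be positive")
    return float(np.exp(np.mean(np.log(x))))


def estimate_common_dispersion(
    counts: pd.DataFrame | np.ndarray,
    library_sizes,
    groups=None,
) -> DispersionEstimate:
    """Method-of-moments common NB dispersion on library-size-scaled counts.

    Per gene, ``phi_g = max(0, (s2 - m) / m**2)`` where ``s2`` is the
    (within-group pooled, when ``groups`` is given) sample variance of the
    scaled counts and ``m`` their mean; the common estimate is the median
    of ``phi_g`` over genes with ``m > 0``.  At least one group must have
    two or more replicates.
    """
    counts = pd.DataFrame(counts)
    libs = np.asarray(pd.Series(library_sizes).reindex(counts.columns) if isinstance(library_sizes, (pd.Series, dict)) else library_sizes, dtype=float)
    scaled = counts.to_numpy(dtype=float) * (_geometric_mean(libs) / libs)
    if groups is None:
        groups = ["all"] * scaled.shape[1]
    groups = np.asarray(groups)
    labels = [g for g in pd.unique(groups) if (groups == g).sum() >= 2]
    if not labels:
        raise ValueError(
            "no group has >= 2 replicates; dispersion cannot be estimated "
            "(pass a fixed phi to the tests instead)"
        )
    ss = np.zeros(scaled.shape[0])
    df = 0
    means = np.zeros(scaled.shape[0])
    n_used = 0
    for g in labels:
        block = scaled[:, groups == g]
        ss += block.var(axis=1, ddof=1) * (block.shape[1] - 1)
        df += block.shape[1] - 1
        means += block.mean(axis=1) * block.shape[1]
        n_used += block.shape[1]
    s2 = ss / df
    m = means / n_used
    ok = m > 0
    phi_g = np.maximum(0.0, (s2[ok] - m[ok]) / m[ok] ** 2)
    if phi_g.size == 0:
        raise ValueError("no gene with positive mean count")
    return DispersionEstimate(float(np.median(phi_g)), int(phi_g.size))


def _two_sided_from_pmf(pmf: np.ndarray, observed: int) -> float:
    """Sum of probabilities of outcomes no more likely than the observed one."""
    p_obs = pmf[observed]
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    return float(min(1.0, max(p, np.finfo(float).tiny)))


def nb_exact_test(
    counts_a,
    counts_b,
    phi: float,
    library_sizes_a=None,
    library_sizes_b=None,
) -> float:
    """Two-sided exact conditional NB test of equal means between two groups.

    ``phi`` is the per-replicate NB dispersion (variance = mu + phi mu^2).
    Library sizes default to equal; when given, counts are scaled to the
    geometric-mean library size and rounded before summing.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    n_a, n_b = a.size, b.size
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups need at least one sample")
    if library_sizes_a is not None or library_sizes_b is not None:
        la = np.asarray(library_sizes_a, dtype=float)
        lb = np.asarray(library_sizes_b, dtype=float)
        ref = _geometric_mean(np.concatenate([la, lb]))
        a = np.rint(a * ref / la)
        b = np.rint(b * ref / lb)
    sa, sb = int(a.sum()), int(b.sum())
    total = sa + sb
    if total == 0:
        return 1.0
    w = n_a / (n_a + n_b)
    if total <= EXACT_ENUMERATION_LIMIT:
        support = np.arange(total + 1)
        if phi == 0:
            pmf = stats.binom.pmf(support, total, w)
        else:
            pmf = stats.betabinom.pmf(support, total, n_a / phi, n_b / phi)
        return _two_sided_from_pmf(pmf, sa)
    # normal approximation to the conditional distribution
    mean = total * w
    if phi == 0:
        var = total * w * (1 - w)
    else:
        alpha, beta = n_a / phi, n_b / phi
        var = total * w * (1 - w) * (alpha + beta + total) / (alpha + beta + 1)
    z = (abs(sa - mean) - 0.5) / np.sqrt(var)
    return float(min(1.0, max(2 * stats.norm.sf(z), np.finfo(float).tiny)))


def call_deas(
    counts: pd.DataFrame,
    groups,
    library_sizes,
    group_a: str | None = None,
    group_b: str | None = None,
    phi: float | None = None,
    log2fc_threshold: float = 1.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential calls between two groups of samples.

    ``log2fc = log2((mean_a + 0.5) / (mean_b + 0.5))`` on library-size-
    normalized means; ``significant`` iff ``|log2fc| > log2fc_threshold``
    and ``p_value < alpha`` (raw p, no correction — q reported alongside).
    Output sorted by p-value, ties broken by gene id.
    """
    counts = pd.DataFrame(counts)
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    if group_a is None or group_b is None:
        if len(uniq) != 2:
            raise ValueError(f"expected exactly two groups, got {uniq}")
        group_a, group_b = uniq
    mask_a, mask_b = groups == group_a, groups == group_b
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("each group needs at least one sample")
    libs = np.asarray(
        pd.Series(library_sizes).reindex(counts.columns)
        if isinstance(library_sizes, (pd.Series, dict))
        else library_sizes,
        dtype=float,
    )
    if phi is None:
        phi = estimate_common_dispersion(counts, libs, groups).phi
    scaled = counts.to_numpy(dtype=float) * (_geometric_mean(libs) / libs)
    mean_a = scaled[:, mask_a].mean(axis=1)
    mean_b = scaled[:, mask_b].mean(axis=1)
    log2fc = np.log2((mean_a + 0.5) / (mean_b + 0.5))
    raw = counts.to_numpy()
    pvals = np.array(
        [
            nb_exact_test(raw[i, mask_a], raw[i, mask_b], phi, libs[mask_a], libs[mask_b])
            for i in range(raw.shape[0])
        ]
    )
    q = multipletests(pvals, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene": counts.index,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": pvals,
            "q_value": q,
            "significant": (np.abs(log2fc) > log2fc_threshold) & (pvals < alpha),
            "direction": np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none")),
        }
    )
    return out.sort_values(["p_value", "gene"], kind="mergesort").reset_index(drop=True)


def allelic_bias_test(
    counts1,
    counts2,
    library_sizes1=None,
    library_sizes2=None,
    gene_id: str = "",
    alpha: float = 0.05,
) -> BiasResult:
    """Exact binomial test of allelic balance for one gene in one cell type.

    Per sample the minority library's count is scaled up to the majority
    library; the scaled counts are pooled across samples, rounded, and the
    pooled parent-1 count is tested against Binomial(n, 0.5) two-sided.
    ``bias_score = log2((pooled1 + 0.5) / (pooled2 + 0.5))``.
    """
    c1 = np.asarray(counts1, dtype=float)
    c2 = np.asarray(counts2, dtype=float)
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("counts must be non-negative")
    if library_sizes1 is None:
        library_sizes1 = np.ones_like(c1)
    if library_sizes2 is None:
        library_sizes2 = np.ones_like(c2)
    l1 = np.asarray(library_sizes1, dtype=float)
    l2 = np.asarray(library_sizes2, dtype=float)
    up1 = l1 < l2
    f1 = np.where(up1, l2 / l1, 1.0)
    f2 = np.where(up1, 1.0, l1 / l2)
    pooled1 = int(np.rint((c1 * f1).sum()))
    pooled2 = int(np.rint((c2 * f2).sum()))
    n = pooled1 + pooled2
    score = float(np.log2((pooled1 + 0.5) / (pooled2 + 0.5)))
    if n == 0:
        return BiasResult(gene_id, 0.0, 1.0, "none", 0, 0)
    p = float(stats.binomtest(pooled1, n, 0.5).pvalue)
    if p < alpha and score > 0:
        toward = "parent1"
    elif p < alpha and score < 0:
        toward = "parent2"
    else:
        toward = "none"
    return BiasResult(gene_id, score, p, toward, pooled1, pooled2)


def allelic_bias_table(
    counts1: pd.DataFrame,
    counts2: pd.DataFrame,
    library_sizes1,
    library_sizes2,
    gene_ids=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Row-wise :func:`allelic_bias_test` over a row-aligned allele matrix pair."""
    c1 = pd.DataFrame(counts1)
    c2 = pd.DataFrame(counts2)
    if c1.shape != c2.shape:
        raise ValueError("allele matrices must be row-aligned with identical shape")
    l1 = np.asarray(pd.Series(library_sizes1).reindex(c1.columns), dtype=float)
    l2 = np.asarray(pd.Series(library_sizes2).reindex(c2.columns), dtype=float)
    ids = list(gene_ids) if gene_ids is not None else list(c1.index)
    rows = []
    a1, a2 = c1.to_numpy(dtype=float), c2.to_numpy(dtype=float)
    for i, gid in enumerate(ids):
        r = allelic_bias_test(a1[i], a2[i], l1, l2, gene_id=str(gid), alpha=alpha)
        rows.append(
            {
                "gene": r.gene_id,
                "bias_score": r.bias_score,
                "binom_p": r.binom_p,
                "biased_toward": r.biased_toward,
                "pooled1": r.pooled1,
                "pooled2": r.pooled2,
            }
        )
    return pd.DataFrame(rows)
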