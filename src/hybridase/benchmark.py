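"""Simulation-based calibration and truth-recovery evaluation.

These helpers run the pipeline (or individual stages) on synthetic data
with known truth and measure how well the methods recover it: classifier
agreement with a naive-scan oracle, NB-test type-I error, dispersion
recovery, DE recall, and allelic-ratio recovery.  They back both the
test suite and the reproduction script.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .classify import build_index, classify_read
from .config import RunConfig, SimulationConfig
from .differential import nb_exact_test
from .pipeline import run_pipeline
from .simulate import ParentalReference, generate_parental_references, reverse_complement

__all__ = [
    "naive_classify",
    "classifier_agreement",
    "nb_test_type1_error",
    "evaluate_default_run",
]


def naive_classify(seq: str, ref1: ParentalReference, ref2: ParentalReference) -> str:
    """Brute-force double scan oracle: substring on either strand, per parent."""
    if "N" in seq:
        return "UNMAPPED"
    rc = reverse_complement(seq)
    in1 = any(seq in t or rc in t for t in ref1.transcripts.values())
    in2 = any(seq in t or rc in t for t in ref2.transcripts.values())
    if in1 and in2:
        return "SHARED"
    if in1:
        return "PARENT1_SPECIFIC"
    if in2:
        return "PARENT2_SPECIFIC"
    return "UNMAPPED"


def classifier_agreement(
    n_reads: int = 10_000,
    n_genes: int = 20,
    divergence: float = 0.02,
    seed: int = 0,
) -> dict:
    """Fraction of simulated reads on which the indexed classifier and the
    naive-scan oracle agree, plus the class conservation check."""
    cfg = SimulationConfig(
        n_genes=n_genes,
        transcript_length_range=(300, 600),
        divergence_rate=divergence,
        n_conditions=1,
        condition_names=("only",),
        n_replicates_per_condition=1,
        reads_per_sample=n_reads,
        read_length=80,
        seed=seed,
    )
    ref1, ref2, _ = generate_parental_references(cfg)
    idx1, idx2 = build_index(ref1), build_index(ref2)
    rng = np.random.default_rng(seed + 1)
    tids = sorted(ref1.transcripts)
    agree = 0
    counts = {k: 0 for k in ("PARENT1_SPECIFIC", "PARENT2_SPECIFIC", "SHARED", "UNMAPPED")}
    for i in range(n_reads):
        ref = ref1 if rng.random() < 0.5 else ref2
        tid = rng.choice(sorted(ref.transcripts))
        seq = ref.transcripts[tid]
        start = rng.integers(0, len(seq) - cfg.read_length + 1)
        read = seq[start : start + cfg.read_length]
        if rng.random() < 0.5:
            read = reverse_complement(read)
        got = classify_read(read, idx1, idx2).klass
        counts[got] += 1
        if got == naive_classify(read, ref1, ref2):
            agree += 1
    counts["conserved"] = sum(counts[k] for k in ("PARENT1_SPECIFIC", "PARENT2_SPECIFIC", "SHARED", "UNMAPPED")) == n_reads
    return {"agreement": agree / n_reads, "n": n_reads, **counts}


def nb_test_type1_error(
    n_genes: int = 2000,
    phi: float = 0.1,
    mu: float = 100.0,
    n_per_group: int = 3,
    alpha: float = 0.05,
    seed: int = 12345,
) -> dict:
    """Empirical rejection rate of the NB exact test on null NB genes."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_genes):
        if phi > 0:
            lam = rng.gamma(1.0 / phi, phi * mu, size=2 * n_per_group)
        else:
            lam = np.full(2 * n_per_group, mu)
        c = rng.poisson(lam)
        if nb_exact_test(c[:n_per_group], c[n_per_group:], phi) < alpha:
            rej += 1
    return {"type1_error": rej / n_genes, "n": n_genes}


def evaluate_default_run(outdir: str | Path, seed: int = 0, sim: SimulationConfig | None = None) -> dict:
    """Run the default synthetic pipeline and score truth recovery.

    Returns dispersion estimate vs truth, DE recall on well-expressed true
    DE genes, allelic-ratio CI coverage and direction recall on biased
    genes with enough specific reads, and the read-class fractions.
    """
    sim = sim if sim is not None else SimulationConfig(seed=seed)
    cfg = RunConfig(outdir=str(outdir), seed=seed, simulation=sim)
    report = run_pipeline(cfg)
    outdir = Path(outdir)
    truth = pd.read_csv(outdir / "sim" / "truth_genes.tsv", sep="\t")
    cond_fib, cond_ipsc = sim.condition_names[:2]

    # read-class fractions averaged over samples
    frac = {k: float(np.mean([v["fractions"][k] for v in report["stages"]["classify"].values()]))
            for k in ("PARENT1_SPECIFIC", "PARENT2_SPECIFIC", "SHARED", "UNMAPPED")}

    # DE recall per allele lineage: true DE genes with mean specific counts >= 50
    recalls = []
    phis = []
    for tag in ("parent1", "parent2"):
        dea = pd.read_csv(outdir / f"dea_{tag}_{cond_ipsc}_vs_{cond_fib}.tsv", sep="\t")
        phis.append(report["stages"]["differential"][tag]["phi"])
        merged = dea.merge(truth, on="gene")
        well = merged[(merged["de_flag"] == 1) & ((merged["mean_a"] + merged["mean_b"]) / 2 >= 50)]
        if len(well):
            recalls.append(float(well["significant"].mean()))
    de_recall = float(np.mean(recalls)) if recalls else float("nan")

    # allelic-ratio recovery in the iPSC-like condition
    bias = pd.read_csv(outdir / f"bias_{cond_ipsc}.tsv", sep="\t").merge(truth, on="gene")
    biased = bias[(bias["bias_ratio"] != 0.5) & (bias["pooled1"] + bias["pooled2"] >= 100)]
    if len(biased):
        n = (biased["pooled1"] + biased["pooled2"]).to_numpy()
        k = biased["pooled1"].to_numpy()
        p0 = float(biased["bias_ratio"].iloc[0])
        lo = stats.binom.ppf(0.025, n, p0)
        hi = stats.binom.ppf(0.975, n, p0)
        coverage = float(((k >= lo) & (k <= hi)).mean())
        direction = float((biased["biased_toward"] == "parent1").mean())
    else:
        coverage = direction = float("nan")

    return {
        "report": report,
        "class_fractions": frac,
        "phi_estimate": float(np.mean(phis)) if phis else float("nan"),
        "phi_truth": sim.nb_dispersion,
        "de_recall": de_recall,
        "n_de_eval": int(sum(1 for _ in recalls)),
        "bias_ci_coverage": coverage,
        "bias_direction_recall": direction,
        "n_biased_eval": int(len(biased)),
    }
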