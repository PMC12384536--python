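"""Synthetic hybrid transcriptome generator with ground truth.

Emulates the data an F1 interspecies hybrid (horse x donkey-like) RNA-seq
experiment produces: two parental transcript sets diverged by point
substitutions, per-gene negative-binomial expression across two cell
conditions, per-gene allelic ratios with a biased subset, and error-free
short reads sampled from the expressed alleles.  Every quantity a
downstream stage should recover is recorded in a :class:`TruthTable`.

Count model
-----------
For gene *g* in condition *c* the expected total (both alleles) is
``mu_gc = 2 ** (baseline + s_g * de_log2fc * 1[c == iPSC])`` where
``s_g in {-1, 0, +1}`` is the signed DE status.  Per sample, gene weights
are ``mu_gc * G_gs`` with ``G_gs ~ Gamma(1/phi, phi)`` (mean 1), gene
totals are multinomial over ``reads_per_sample`` fragments, and each
gene total is split between the parental alleles binomially at the
gene's true parent-1 ratio.  Marginally each allele count is negative
binomial with mean ``p * mu`` and dispersion ``phi`` (variance
``m + phi * m**2``); conditional on a gene's total, the allele split is
exactly binomial, and each sample's counts sum to ``reads_per_sample``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig, substream_seed

__all__ = [
    "ParentalReference",
    "HomologTable",
    "TruthTable",
    "generate_parental_references",
    "simulate_counts",
    "simulate_reads",
    "simulate_all",
    "write_reference_fasta",
    "read_reference_fasta",
    "reverse_complement",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.encode()[::-1].translate(_COMPLEMENT).decode()


@dataclass
class ParentalReference:
    """One parent's transcript sequences plus the transcript-to-gene map."""

    parent_label: str
    transcripts: dict[str, str]
    transcript_to_gene: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.transcripts) != set(self.transcript_to_gene):
            raise ConfigError("transcripts and transcript_to_gene must cover the same transcript ids")
        for tid, seq in self.transcripts.items():
            if not seq:
                raise ConfigError(f"transcript {tid} has an empty sequence")
            if set(seq) - set("ACGT"):
                raise ConfigError(f"transcript {tid} contains characters outside ACGT")

    @property
    def gene_ids(self) -> list[str]:
        return sorted(set(self.transcript_to_gene.values()))

    def transcript_lengths(self) -> dict[str, int]:
        return {tid: len(s) for tid, s in self.transcripts.items()}

    def gene_lengths(self) -> dict[str, int]:
        """Per-gene length: the maximum transcript length of the gene."""
        out: dict[str, int] = {}
        for tid, gene in self.transcript_to_gene.items():
            out[gene] = max(out.get(gene, 0), len(self.transcripts[tid]))
        return out


@dataclass
class HomologTable:
    """Candidate homologous gene pairs between the two parents."""

    pairs: list[tuple[str, str]]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#parent1_gene\tparent2_gene\n")
            for a, b in self.pairs:
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HomologTable":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                a, b = line.split("\t")[:2]
                pairs.append((a, b))
        return cls(pairs)


@dataclass
class TruthTable:
    """Simulation ground truth used for parameter-recovery tests.

    ``count_truth`` is a genes x samples x 2 integer tensor (allele axis:
    parent1, parent2); ``read_truth`` maps read id -> (parent label,
    transcript id, 0-based start).
    """

    genes: list[str]
    samples: list[str]
    conditions: list[str]
    count_truth: np.ndarray
    de_flag: np.ndarray  # bool per gene
    de_log2fc: np.ndarray  # signed, 0 for non-DE genes
    bias_truth: np.ndarray  # true parent1 ratio per gene, in (0,1)
    read_truth: dict[str, tuple[str, str, int]] = field(default_factory=dict)

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": self.genes,
                "de_flag": self.de_flag.astype(int),
                "de_log2fc": self.de_log2fc,
                "bias_ratio": self.bias_truth,
            }
        )

    def write_gene_tsv(self, path: str | Path) -> None:
        self.gene_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_read_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\torigin_parent\ttranscript_id\tstart\n")
            for rid in sorted(self.read_truth):
                parent, tid, start = self.read_truth[rid]
                fh.write(f"{rid}\t{parent}\t{tid}\t{start}\n")


def _draw_sequences(rng: np.random.Generator, config: SimulationConfig) -> list[str]:
    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    return ["".join(rng.choice(["A", "C", "G", "T"], size=n)) for n in lengths]


def generate_parental_references(
    config: SimulationConfig,
) -> tuple[ParentalReference, ParentalReference, HomologTable]:
    """Generate the two diverged parental transcript sets.

    Parent-2 transcripts are copies of parent-1 transcripts with i.i.d.
    per-base substitution at ``divergence_rate``; the substituted base is
    drawn uniformly from the three alternatives.  One transcript per gene;
    gene ids are paired one-to-one in the homolog table.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(substream_seed(config.seed, "references"))
    t1: dict[str, str] = {}
    t2: dict[str, str] = {}
    map1: dict[str, str] = {}
    map2: dict[str, str] = {}
    pairs: list[tuple[str, str]] = []
    width = max(4, len(str(config.n_genes)))
    for i, seq in enumerate(_draw_sequences(rng, config)):
        g1 = f"H{i:0{width}d}"
        g2 = f"D{i:0{width}d}"
        tid1, tid2 = g1 + ".t1", g2 + ".t1"
        arr = np.frombuffer(seq.encode(), dtype="S1").copy()
        hit = rng.random(arr.size) < config.divergence_rate
        if hit.any():
            # uniform over the 3 non-identical bases: shift by 1..3 in A<C<G<T order
            idx = np.searchsorted(BASES, arr[hit])
            arr[hit] = BASES[(idx + rng.integers(1, 4, size=int(hit.sum()))) % 4]
        t1[tid1] = seq
        t2[tid2] = arr.tobytes().decode()
        map1[tid1] = g1
        map2[tid2] = g2
        pairs.append((g1, g2))
    ref1 = ParentalReference("parent1", t1, map1)
    ref2 = ParentalReference("parent2", t2, map2)
    return ref1, ref2, HomologTable(pairs)


def simulate_counts(config: SimulationConfig, seed: int | None = None) -> TruthTable:
    """Draw the true per-allele count tensor and per-gene truth labels.

    ``seed`` overrides ``config.seed`` for the counts substream.
    """
    config.validate()
    rng = np.random.default_rng(substream_seed(config.seed if seed is None else seed, "counts"))
    G = config.n_genes
    width = max(4, len(str(G)))
    genes = [f"H{i:0{width}d}" for i in range(G)]

    de_flag = rng.random(G) < config.de_fraction
    sign = rng.choice([-1.0, 1.0], size=G)
    de_lfc = np.where(de_flag, sign * config.de_log2fc, 0.0)
    biased = rng.random(G) < config.bias_fraction
    bias = np.where(biased, config.biased_allelic_ratio, 0.5)

    samples = config.sample_ids
    conditions = config.sample_conditions
    count = np.zeros((G, len(samples), 2), dtype=np.int64)
    for s, cond in enumerate(conditions):
        is_ipsc = cond != config.condition_names[0]
        mu = 2.0 ** (config.baseline_mean_log2 + (de_lfc if is_ipsc else 0.0))
        if config.nb_dispersion > 0:
            noise = rng.gamma(1.0 / config.nb_dispersion, config.nb_dispersion, size=G)
        else:
            noise = np.ones(G)
        w = mu * noise
        totals = rng.multinomial(config.reads_per_sample, w / w.sum())
        p1 = rng.binomial(totals, bias)
        count[:, s, 0] = p1
        count[:, s, 1] = totals - p1
    return TruthTable(genes, samples, list(conditions), count, de_flag, de_lfc, bias)


def simulate_reads(
    ref1: ParentalReference,
    ref2: ParentalReference,
    truth: TruthTable,
    config: SimulationConfig,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write one FASTQ per sample, filling ``truth.read_truth`` in place.

    Each counted fragment becomes one read of ``read_length`` bases taken
    at a uniform start on the origin allele's transcript, on a uniform
    strand, with per-base substitution errors at ``error_rate``.  Read ids
    are opaque (sample tag + shuffled sequential integer); ground truth
    lives only in the truth table.  Returns sample id -> FASTQ path.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(substream_seed(config.seed, "reads"))
    refs = {"parent1": ref1, "parent2": ref2}
    gene_to_tid = {
        label: {g: t for t, g in ref.transcript_to_gene.items()} for label, ref in refs.items()
    }
    # parent2 gene ids differ from the parent1-style ids used in the truth
    # table rows; map via homolog position (same row order by construction)
    p2_genes = sorted(gene_to_tid["parent2"])
    if len(p2_genes) != len(truth.genes):
        raise ConfigError("reference and truth table gene sets differ in size")
    L = config.read_length
    qual = "I" * L
    paths: dict[str, Path] = {}
    for s, sample in enumerate(truth.samples):
        entries: list[tuple[str, str, int, str]] = []  # (parent, tid, start, seq)
        for allele, parent in enumerate(("parent1", "parent2")):
            ref = refs[parent]
            for g in range(len(truth.genes)):
                n = int(truth.count_truth[g, s, allele])
                if n == 0:
                    continue
                gene = truth.genes[g] if parent == "parent1" else p2_genes[g]
                tid = gene_to_tid[parent][gene]
                seq = ref.transcripts[tid]
                if len(seq) < L:
                    raise ConfigError(f"read_length {L} exceeds transcript {tid} length {len(seq)}")
                starts = rng.integers(0, len(seq) - L + 1, size=n)
                flip = rng.random(n) < 0.5
                for start, rc in zip(starts, flip):
                    read = seq[start : start + L]
                    if rc:
                        read = reverse_complement(read)
                    if config.error_rate > 0:
                        arr = np.frombuffer(read.encode(), dtype="S1").copy()
                        hit = rng.random(L) < config.error_rate
                        if hit.any():
                            idx = np.searchsorted(BASES, arr[hit])
                            arr[hit] = BASES[(idx + rng.integers(1, 4, size=int(hit.sum()))) % 4]
                            read = arr.tobytes().decode()
                    entries.append((parent, tid, int(start), read))
        order = rng.permutation(len(entries))
        path = outdir / f"sample_{sample}.fastq"
        with open(path, "w") as fh:
            for i, j in enumerate(order):
                parent, tid, start, read = entries[j]
                rid = f"{sample}:r{i:07d}"
                truth.read_truth[rid] = (parent, tid, start)
                fh.write(f"@{rid}\n{read}\n+\n{qual}\n")
        paths[sample] = path
    return paths


def write_reference_fasta(ref: ParentalReference, path: str | Path) -> None:
    """One record per transcript, header ``transcript_id gene=GENEID``."""
    with open(path, "w") as fh:
        for tid in sorted(ref.transcripts):
            fh.write(f">{tid} gene={ref.transcript_to_gene[tid]}\n{ref.transcripts[tid]}\n")


def read_reference_fasta(path: str | Path, parent_label: str) -> ParentalReference:
    from Bio import SeqIO

    transcripts: dict[str, str] = {}
    t2g: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        transcripts[rec.id] = str(rec.seq).upper()
        gene = rec.id
        for token in rec.description.split():
            if token.startswith("gene="):
                gene = token[5:]
        t2g[rec.id] = gene
    if not transcripts:
        raise ConfigError(f"no FASTA records in {path}")
    return ParentalReference(parent_label, transcripts, t2g)


def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate references, counts and reads; write every artifact to disk.

    Returns a manifest dict of written paths plus the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref1, ref2, homologs = generate_parental_references(config)
    truth = simulate_counts(config)
    fastqs = simulate_reads(ref1, ref2, truth, config, outdir)
    write_reference_fasta(ref1, outdir / "parent1.fa")
    write_reference_fasta(ref2, outdir / "parent2.fa")
    homologs.to_tsv(outdir / "homologs.tsv")
    truth.write_gene_tsv(outdir / "truth_genes.tsv")
    truth.write_read_tsv(outdir / "truth_reads.tsv")
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "ref1": ref1,
        "ref2": ref2,
        "homologs": homologs,
        "truth": truth,
        "fastqs": fastqs,
        "paths": {
            "parent1_fasta": outdir / "parent1.fa",
            "parent2_fasta": outdir / "parent2.fa",
            "homologs": outdir / "homologs.tsv",
        },
    }
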