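"""End-to-end orchestration: simulate -> classify -> quantify -> harmonize
-> differential / bias -> set filtering -> enrichment -> report.

Every stage writes its tabular outputs under the run directory; the run
report (``report.json``) collects per-stage record counts, the config
echo and the seed.  Re-running with the same config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import build_index, partition_fastq
from .config import RunConfig, substream_seed
from .differential import allelic_bias_table, call_deas, estimate_common_dispersion
from .harmonize import harmonize
from .quantify import count_matrices_from_manifests, fpkm, tpm
from .setops import GeneSetCollection, bias_de_intersection, hypergeometric_enrichment, ipsc_specific_deas, write_gmt
from .simulate import HomologTable, read_reference_fasta, simulate_all

__all__ = ["run_pipeline"]

log = logging.getLogger("hybridase")


def _stage(name):
    log.info("stage %s", name)
    return time.monotonic()


def _done(name, t0):
    log.info("stage %s done in %.1fs", name, time.monotonic() - t0)


def _synthetic_gmt(universe: list[str], spike: list[str], seed, n_sets: int = 10, set_size: int = 20):
    """Random gene sets over the universe plus one set spiked with the query
    genes, so the enrichment stage has a positive control."""
    rng = np.random.default_rng(seed)
    sets: dict[str, set[str]] = {}
    for i in range(n_sets - 1):
        sets[f"SET_{i:02d}"] = set(rng.choice(universe, size=min(set_size, len(universe)), replace=False))
    spiked = list(spike)[: set_size // 2]
    pad = [g for g in universe if g not in spiked]
    extra = list(rng.choice(pad, size=max(0, set_size - len(spiked)), replace=False))
    sets["SET_SPIKED"] = set(spiked) | set(extra)
    return sets


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(levelname)s %(message)s")

    report: dict = {
        "software": {"name": "hybridase", "version": __version__},
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }

    # ---- inputs -----------------------------------------------------------
    t0 = _stage("simulate" if not config.real_mode else "load")
    if config.real_mode:
        ref1 = read_reference_fasta(config.ref1, "parent1")
        ref2 = read_reference_fasta(config.ref2, "parent2")
        homologs = HomologTable.from_tsv(config.homologs)
        fastqs = {s: Path(p) for s, p in config.reads.items()}
        conditions = dict(config.conditions)
        truth = None
        cond_names = list(dict.fromkeys(conditions.values()))
    else:
        sim = simulate_all(config.simulation, outdir / "sim")
        ref1, ref2, homologs, truth = sim["ref1"], sim["ref2"], sim["homologs"], sim["truth"]
        fastqs = sim["fastqs"]
        conditions = dict(zip(truth.samples, truth.conditions))
        cond_names = list(config.simulation.condition_names[: config.simulation.n_conditions])
    _done("inputs", t0)

    # ---- classify ---------------------------------------------------------
    t0 = _stage("classify")
    idx1, idx2 = build_index(ref1), build_index(ref2)
    classify_dir = outdir / "classified"
    manifests: dict[str, pd.DataFrame] = {}
    class_counts: dict[str, dict[str, int]] = {}
    for sample in sorted(fastqs):
        _, manifest = partition_fastq(fastqs[sample], idx1, idx2, classify_dir, prefix=sample)
        manifests[sample] = manifest
        vc = manifest["class"].value_counts().to_dict()
        n = int(len(manifest))
        class_counts[sample] = {
            "n_reads": n,
            **{k: int(vc.get(k, 0)) for k in ("PARENT1_SPECIFIC", "PARENT2_SPECIFIC", "SHARED", "UNMAPPED")},
        }
        if n:
            class_counts[sample]["fractions"] = {
                k: vc.get(k, 0) / n for k in ("PARENT1_SPECIFIC", "PARENT2_SPECIFIC", "SHARED", "UNMAPPED")
            }
    report["stages"]["classify"] = class_counts
    _done("classify", t0)

    # ---- quantify ---------------------------------------------------------
    t0 = _stage("quantify")
    m1, m2, qc = count_matrices_from_manifests(manifests, ref1.transcript_to_gene, ref2.transcript_to_gene)
    m1.to_tsv(outdir / "counts_parent1.tsv")
    m2.to_tsv(outdir / "counts_parent2.tsv")
    qc.to_csv(outdir / "qc_ledger.tsv", sep="\t", index=False)
    len1 = pd.Series(ref1.gene_lengths())
    len2 = pd.Series(ref2.gene_lengths())
    for m, lens, tag in ((m1, len1, "parent1"), (m2, len2, "parent2")):
        if (m.library_sizes > 0).all():
            fpkm(m.counts, lens, m.library_sizes).to_tsv(outdir / f"fpkm_{tag}.tsv")
        tpm(m.counts, lens).to_tsv(outdir / f"tpm_{tag}.tsv")
    report["stages"]["quantify"] = {
        "genes_parent1": len(m1.genes),
        "genes_parent2": len(m2.genes),
        "library_sizes_parent1": {k: int(v) for k, v in m1.library_sizes.items()},
        "library_sizes_parent2": {k: int(v) for k, v in m2.library_sizes.items()},
    }
    _done("quantify", t0)

    # ---- harmonize --------------------------------------------------------
    t0 = _stage("harmonize")
    joint = harmonize(m1, m2, homologs)
    joint.to_tsv(outdir / "joint_counts.tsv")
    report["stages"]["harmonize"] = joint.report
    _done("harmonize", t0)

    samples = joint.samples
    cond_of = [conditions[s] for s in samples]
    empty = joint.n_common == 0 or all(
        int(joint.counts1[s].sum()) + int(joint.counts2[s].sum()) == 0 for s in samples
    )

    # ---- differential / bias ---------------------------------------------
    t0 = _stage("differential")
    de_report: dict = {}
    dea_sets: dict[str, list[str]] = {}
    bias_sets: dict[str, list[str]] = {}
    p1_ids = [a for a, _ in joint.common_genes]
    if not empty and len(cond_names) >= 2:
        cond_a, cond_b = cond_names[0], cond_names[1]  # fibroblast-like, iPSC-like
        for tag, mat, libs in (("parent1", joint.counts1, joint.library_sizes1), ("parent2", joint.counts2, joint.library_sizes2)):
            counts = mat.copy()
            counts.index = p1_ids
            phi = estimate_common_dispersion(counts, libs[samples], cond_of).phi
            dea = call_deas(counts, cond_of, libs[samples], group_a=cond_b, group_b=cond_a,
                            phi=phi, log2fc_threshold=config.log2fc_threshold, alpha=config.alpha)
            dea.to_csv(outdir / f"dea_{tag}_{cond_b}_vs_{cond_a}.tsv", sep="\t", index=False, float_format="%.6g")
            dea_sets[tag] = sorted(dea.loc[dea["significant"], "gene"])
            de_report[tag] = {"phi": phi, "n_significant": len(dea_sets[tag])}
        # allele-vs-allele contrast within each condition
        for cond in cond_names[:2]:
            cols = [s for s in samples if conditions[s] == cond]
            both = pd.concat(
                [joint.counts1[cols].set_axis([c + ".p1" for c in cols], axis=1).set_axis(p1_ids),
                 joint.counts2[cols].set_axis([c + ".p2" for c in cols], axis=1).set_axis(p1_ids)],
                axis=1,
            )
            libs = pd.concat([
                joint.library_sizes1[cols].set_axis([c + ".p1" for c in cols]),
                joint.library_sizes2[cols].set_axis([c + ".p2" for c in cols]),
            ])
            grp = ["parent1"] * len(cols) + ["parent2"] * len(cols)
            phi = estimate_common_dispersion(both, libs, grp).phi if len(cols) >= 2 else 0.0
            dea = call_deas(both, grp, libs, group_a="parent1", group_b="parent2",
                            phi=phi, log2fc_threshold=config.log2fc_threshold, alpha=config.alpha)
            dea.to_csv(outdir / f"dea_alleles_{cond}.tsv", sep="\t", index=False, float_format="%.6g")
            dea_sets[f"alleles_{cond}"] = sorted(dea.loc[dea["significant"], "gene"])
            de_report[f"alleles_{cond}"] = {"phi": phi, "n_significant": len(dea_sets[f"alleles_{cond}"])}
        for cond in cond_names[:2]:
            cols = [s for s in samples if conditions[s] == cond]
            # both alleles of a sample come from the same sequencing library,
            # so the within-sample allelic depth ratio is 1: pool raw counts
            ones = pd.Series(1.0, index=cols)
            bias = allelic_bias_table(
                joint.counts1[cols], joint.counts2[cols],
                ones, ones,
                gene_ids=p1_ids, alpha=config.alpha,
            )
            bias.to_csv(outdir / f"bias_{cond}.tsv", sep="\t", index=False, float_format="%.6g")
            bias_sets[cond] = sorted(bias.loc[bias["biased_toward"] != "none", "gene"])
            de_report[f"bias_{cond}"] = {"n_biased": len(bias_sets[cond])}
    report["stages"]["differential"] = de_report
    _done("differential", t0)

    # ---- set filtering + enrichment ---------------------------------------
    t0 = _stage("setops")
    sets_report: dict = {}
    if dea_sets and len(cond_names) >= 2:
        cond_a, cond_b = cond_names[0], cond_names[1]
        ipsc_specific = ipsc_specific_deas(dea_sets.get(f"alleles_{cond_b}", []), dea_sets.get(f"alleles_{cond_a}", []))
        de_union = sorted(set(dea_sets.get("parent1", [])) | set(dea_sets.get("parent2", [])))
        bias_de = bias_de_intersection(bias_sets.get(cond_b, []), de_union)
        (outdir / "ipsc_specific_alleles.txt").write_text("".join(g + "\n" for g in ipsc_specific))
        (outdir / "bias_de_intersection.txt").write_text("".join(g + "\n" for g in bias_de))
        sets_report = {
            "n_ipsc_specific_allele_deas": len(ipsc_specific),
            "n_de_union": len(de_union),
            "n_bias_de_intersection": len(bias_de),
        }
        universe = p1_ids
        if universe:
            gmt = _synthetic_gmt(universe, bias_de, substream_seed(config.seed, "gmt"))
            write_gmt(gmt, outdir / "genesets.gmt")
            query = bias_de if bias_de else de_union
            if query:
                enr = hypergeometric_enrichment(query, GeneSetCollection(gmt, set(universe)))
                enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")
                sets_report["n_enriched_q05"] = int((enr["q_value"] < 0.05).sum())
                sets_report["top_set"] = str(enr.iloc[0]["set_name"])
    report["stages"]["setops"] = sets_report
    _done("setops", t0)

    if truth is not None:
        report["truth"] = {
            "n_true_de": int(truth.de_flag.sum()),
            "n_true_biased": int((truth.bias_truth != 0.5).sum()),
        }

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
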