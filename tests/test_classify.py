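"""Read classifier: exact-substring semantics, oracle equivalence, partitioning."""

import numpy as np
import pytest

from hybridase import SimulationConfig, build_index, classify_read, generate_parental_references
from hybridase.benchmark import naive_classify
from hybridase.classify import partition_fastq
from hybridase.simulate import ParentalReference, reverse_complement, simulate_counts, simulate_reads


def test_index_basic_membership(toy_refs):
    ref1, _ = toy_refs
    idx = build_index(ref1, k=4)
    assert ("t1a", "+") in idx.lookup("CGTACG")
    assert idx.lookup("ACGT" * 10) == set()  # longer than every transcript
    assert "CG" in idx  # short-query fallback path
    assert build_index(ref1, k=64).lookup("CGTACG")  # k longer than query still works


def test_empty_reference_and_empty_query_raise(toy_refs):
    with pytest.raises(ValueError):
        build_index(ParentalReference("p", {}, {}))
    ref1, ref2 = toy_refs
    idx1, idx2 = build_index(ref1, k=4), build_index(ref2, k=4)
    with pytest.raises(ValueError):
        classify_read("", idx1, idx2)


def test_classification_classes_and_n_handling(toy_refs):
    ref1, ref2 = toy_refs
    idx1, idx2 = build_index(ref1, k=4), build_index(ref2, k=4)
    assert classify_read("ACGTACGT", idx1, idx2).klass == "SHARED"
    assert classify_read("TTTTCCCC", idx1, idx2).klass == "PARENT1_SPECIFIC"
    assert classify_read("GGGGTTTT", idx1, idx2).klass == "PARENT2_SPECIFIC"
    assert classify_read("ACGTACGN", idx1, idx2).klass == "UNMAPPED"
    # reverse complement of a parent2-only region still maps to parent2
    assert classify_read(reverse_complement("GGGGTTTTAAAA"), idx1, idx2).klass == "PARENT2_SPECIFIC"


def test_label_symmetry(small_refs):
    ref1, ref2, _ = small_refs
    idx1, idx2 = build_index(ref1), build_index(ref2)
    rng = np.random.default_rng(4)
    tids = sorted(ref1.transcripts)
    swap = {"PARENT1_SPECIFIC": "PARENT2_SPECIFIC", "PARENT2_SPECIFIC": "PARENT1_SPECIFIC",
            "SHARED": "SHARED", "UNMAPPED": "UNMAPPED"}
    for _ in range(200):
        tid = tids[rng.integers(len(tids))]
        s = ref1.transcripts[tid]
        i = rng.integers(0, len(s) - 60)
        read = s[i : i + 60]
        assert classify_read(read, idx2, idx1).klass == swap[classify_read(read, idx1, idx2).klass]


def test_exhaustive_substrings_match_naive_scan_on_toy_reference():
    """Every substring of a 50-base toy pair classifies as the naive double scan."""
    rng = np.random.default_rng(17)
    s1 = "".join(rng.choice(list("ACGT"), size=50))
    arr = list(s1)
    for pos in (5, 20, 41):  # three planted substitutions
        arr[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[pos]]
    s2 = "".join(arr)
    ref1 = ParentalReference("parent1", {"t1": s1}, {"t1": "g"})
    ref2 = ParentalReference("parent2", {"t2": s2}, {"t2": "g"})
    idx1, idx2 = build_index(ref1, k=8), build_index(ref2, k=8)
    for i in range(50):
        for j in range(i + 1, 51):
            q = s1[i:j]
            assert classify_read(q, idx1, idx2).klass == naive_classify(q, ref1, ref2)


def test_random_reads_match_bruteforce_oracle(small_refs):
    """Simulated reads at divergence 0.02: indexed classifier == naive scan."""
    ref1, ref2, _ = small_refs
    idx1, idx2 = build_index(ref1), build_index(ref2)
    rng = np.random.default_rng(8)
    refs = [ref1, ref2]
    for _ in range(300):
        ref = refs[rng.integers(2)]
        tid = sorted(ref.transcripts)[rng.integers(len(ref.transcripts))]
        s = ref.transcripts[tid]
        i = rng.integers(0, len(s) - 70)
        read = s[i : i + 70]
        if rng.random() < 0.5:
            read = reverse_complement(read)
        assert classify_read(read, idx1, idx2).klass == naive_classify(read, ref1, ref2)
    # random garbage absent from both references is unmapped
    garbage = "".join(rng.choice(list("ACGT"), size=300))
    assert naive_classify(garbage, ref1, ref2) == "UNMAPPED"
    assert classify_read(garbage, idx1, idx2).klass == "UNMAPPED"


def test_partition_conservation_and_truth_agreement(small_cfg, small_refs, tmp_path):
    ref1, ref2, _ = small_refs
    truth = simulate_counts(small_cfg)
    paths = simulate_reads(ref1, ref2, truth, small_cfg, tmp_path / "fq")
    idx1, idx2 = build_index(ref1), build_index(ref2)
    sample = small_cfg.sample_ids[0]
    names, manifest = partition_fastq(paths[sample], idx1, idx2, tmp_path / "out")
    # conservation: every record in exactly one file
    n_out = 0
    for p in names.values():
        n_out += sum(1 for line in open(p) if line.startswith("@" + sample))
    assert n_out == small_cfg.reads_per_sample == len(manifest)
    assert (manifest["class"] != "UNMAPPED").all()  # error-free reads always map
    # parent-specific calls agree with simulated origin (100% specificity)
    spec = manifest[manifest["class"].str.endswith("_SPECIFIC")]
    assert len(spec) > 0
    for rid, klass in zip(spec["read_id"], spec["class"]):
        origin = truth.read_truth[rid][0]
        assert klass == f"{origin.upper()}_SPECIFIC"
    # manifest preserves input order
    order = [line[1:].strip() for line in open(paths[sample]) if line.startswith("@" + sample)]
    assert list(manifest["read_id"]) == order


def test_partition_empty_and_malformed(tmp_path, toy_refs):
    ref1, ref2 = toy_refs
    idx1, idx2 = build_index(ref1, k=4), build_index(ref2, k=4)
    empty = tmp_path / "empty.fastq"
    empty.write_text("")
    names, manifest = partition_fastq(empty, idx1, idx2, tmp_path)
    assert manifest.empty and all(p.read_text() == "" for p in names.values())
    bad = tmp_path / "bad.fastq"
    bad.write_text("@r1\nACGT\nBROKEN\nIIII\n")
    with pytest.raises(ValueError, match="index 0"):
        partition_fastq(bad, idx1, idx2, tmp_path)


def test_zero_divergence_reads_all_shared(tmp_path):
    cfg = SimulationConfig(n_genes=10, divergence_rate=0.0, reads_per_sample=500,
                           n_replicates_per_condition=1, seed=6)
    r1, r2, _ = generate_parental_references(cfg)
    truth = simulate_counts(cfg)
    paths = simulate_reads(r1, r2, truth, cfg, tmp_path)
    idx1, idx2 = build_index(r1), build_index(r2)
    _, manifest = partition_fastq(paths[cfg.sample_ids[0]], idx1, idx2, tmp_path / "o")
    assert (manifest["class"] == "SHARED").all()


def test_specific_fraction_increases_with_divergence_in_expectation():
    """Averaged over seeds, more divergence cannot mean fewer specific reads."""
    fracs = {}
    for rate in (0.005, 0.05):
        vals = []
        for seed in (1, 2, 3):
            cfg = SimulationConfig(n_genes=10, transcript_length_range=(300, 400),
                                   divergence_rate=rate, n_conditions=1, condition_names=("only",),
                                   n_replicates_per_condition=1, reads_per_sample=400,
                                   read_length=80, seed=seed)
            r1, r2, _ = generate_parental_references(cfg)
            idx1, idx2 = build_index(r1), build_index(r2)
            rng = np.random.default_rng(seed + 100)
            n_spec = 0
            for _ in range(cfg.reads_per_sample):
                tid = sorted(r1.transcripts)[rng.integers(10)]
                s = r1.transcripts[tid]
                i = rng.integers(0, len(s) - 80)
                if classify_read(s[i : i + 80], idx1, idx2).klass == "PARENT1_SPECIFIC":
                    n_spec += 1
            vals.append(n_spec / cfg.reads_per_sample)
        fracs[rate] = np.mean(vals)
    assert fracs[0.05] >= fracs[0.005]
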