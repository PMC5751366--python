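"""Cleaning cascade: trimming, filtering, collapsing, conservation, base bias."""

from __future__ import annotations

import random

import numpy as np
import pytest

from berrymir import preprocess, synthdata
from conftest import tiny_config

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


class TestTrimAdapter:
    def test_full_adapter_removed(self):
        insert = "ACGTACGTACGTACGTACGTA"
        assert preprocess.trim_adapter(insert + ADAPTER, ADAPTER) == (insert, True)

    def test_adapter_only_read_becomes_empty(self):
        trimmed, found = preprocess.trim_adapter(ADAPTER, ADAPTER)
        assert (trimmed, found) == ("", True)

    def test_partial_adapter_suffix(self):
        insert = "ACGTACGTACGTACGTACGTA"
        read = (insert + ADAPTER)[:36]
        trimmed, found = preprocess.trim_adapter(read, ADAPTER)
        assert (trimmed, found) == (insert, True)

    def test_read_without_adapter_flagged(self):
        rng = random.Random(42)
        for _ in range(20):
            read = "".join(rng.choice("ACGT") for _ in range(36))
            # brute-force: confirm no suffix of length >= 6 is an adapter prefix
            has_overlap = any(
                read.endswith(ADAPTER[:k]) for k in range(6, min(36, len(ADAPTER)) + 1)
            )
            trimmed, found = preprocess.trim_adapter(read, ADAPTER, min_overlap=6)
            assert found == has_overlap
            if not found:
                assert trimmed == read

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            preprocess.trim_adapter("ACGT", "")


class TestFilterAndCollapse:
    def test_identical_reads_collapse_with_per_library_counts(self):
        reads = {"WF": ["ACGTACGTACGTACGTACGTA"] * 5, "BF": []}
        table, stats = preprocess.filter_and_collapse(reads)
        assert len(table.counts) == 1
        tag = table.counts.index[0]
        assert tag == "ACGUACGUACGUACGUACGUA"  # stored as RNA
        assert table.counts.loc[tag, "WF"] == 5
        assert table.counts.loc[tag, "BF"] == 0

    def test_length_boundaries(self):
        reads = {"WF": ["A" * 0 + "ACGTACGTACGTACGTA", "ACGTACGTACGTACGTACGTACGTAC"]}
        # 17-mer and 26-mer: both outside 18..25
        table, stats = preprocess.filter_and_collapse(reads)
        assert len(table.counts) == 0
        assert stats["WF"].length_rejected == 2

    def test_junk_reads_dropped(self):
        reads = {"WF": ["A" * 17 + "CGT", "ACGNACGTACGTACGTACGT"]}
        table, stats = preprocess.filter_and_collapse(reads)
        assert stats["WF"].junk_reads == 2
        assert len(table.counts) == 0

    def test_contaminant_substring_removed(self):
        contam = "GGGTTTCCCAAAGGGTTTCCCAAAGGGTTTCCCAAA"
        reads = {"WF": [contam[3:24], "ACGTACGTACGTACGTACGTA"]}
        table, stats = preprocess.filter_and_collapse(reads, contaminants=[contam])
        assert stats["WF"].contaminant_reads == 1
        assert len(table.counts) == 1

    def test_min_len_gt_max_len_rejected(self):
        with pytest.raises(ValueError):
            preprocess.filter_and_collapse({"WF": []}, min_len=20, max_len=18)

    def test_low_quality_filter_applies_to_fastq(self):
        reads = {"WF": ["ACGTACGTACGTACGTACGTA"] * 2}
        quals = {"WF": ["I" * 21, "#" * 21]}  # Phred 40 vs Phred 2
        table, stats = preprocess.filter_and_collapse(reads, qualities=quals)
        assert stats["WF"].low_quality == 1
        assert int(table.counts.sum().sum()) == 1


def test_conservation_and_collapse_totals(small_truth, small_reads):
    table, stats = preprocess.run_preprocess(
        small_reads, ADAPTER, contaminants=small_truth.contaminants.values()
    )
    for lib, st in stats.items():
        assert st.conservation_holds()
        assert st.raw_reads == len(small_reads[lib])
        assert table.counts[lib].sum() == st.retained_reads
        assert sum(st.length_histogram.values()) <= st.clean_reads


def test_contaminant_fraction_recovered(small_truth, small_reads):
    table, stats = preprocess.run_preprocess(
        small_reads, ADAPTER, contaminants=small_truth.contaminants.values()
    )
    frac = small_truth.config.contaminant_fraction
    for lib, st in stats.items():
        observed = st.contaminant_reads / st.raw_reads
        sd = np.sqrt(frac * (1 - frac) / st.raw_reads)
        assert abs(observed - frac) < 4 * sd + 0.01


def test_order_independence(small_reads):
    rng = random.Random(1)
    shuffled = {lib: list(reads) for lib, reads in small_reads.items()}
    for reads in shuffled.values():
        rng.shuffle(reads)
    t1, _ = preprocess.run_preprocess(small_reads, ADAPTER)
    t2, _ = preprocess.run_preprocess(shuffled, ADAPTER)
    assert t1.counts.equals(t2.counts)


class TestFirstNucleotideBias:
    def test_single_tag(self):
        import pandas as pd

        counts = pd.DataFrame({"WF": [1]}, index=pd.Index(["UUUU"], name="tag"))
        table = preprocess.UniqueTagTable(counts, {"WF": 1})
        freq = preprocess.first_nucleotide_bias(table)
        assert all(freq.loc[pos, "U"] == 1.0 for pos in range(1, 5))

    def test_count_weighting(self):
        import pandas as pd

        counts = pd.DataFrame({"WF": [1, 3]}, index=pd.Index(["AAAA", "UUUU"], name="tag"))
        table = preprocess.UniqueTagTable(counts, {"WF": 4})
        freq = preprocess.first_nucleotide_bias(table)
        assert freq.loc[1, "U"] == 0.75
        assert freq.loc[1, "A"] == 0.25

    def test_empty_table_rejected(self):
        import pandas as pd

        counts = pd.DataFrame({"WF": []}, index=pd.Index([], name="tag"), dtype=int)
        table = preprocess.UniqueTagTable(counts, {"WF": 0})
        with pytest.raises(ValueError):
            preprocess.first_nucleotide_bias(table)

    def test_five_prime_u_bias_measured_on_synthetic_library(self):
        cfg = tiny_config(seed=5)
        cfg.contaminant_fraction = 0.0
        cfg.background_fraction = 0.0
        cfg.abundance_sigma_log = 0.0  # equal locus abundances
        cfg.n_mirna_loci = 40
        cfg.scaffold_length = 60_000
        cfg.five_prime_u_bias = 0.5
        truth = synthdata.generate_truth(cfg)
        reads = {"WF": synthdata.simulate_sra_library(truth, "WF")}
        table, _ = preprocess.run_preprocess(reads, cfg.adapter)
        freq = preprocess.first_nucleotide_bias(table)
        sd = np.sqrt(0.25 / cfg.n_mirna_loci)
        assert abs(freq.loc[1, "U"] - 0.5) < 3 * sd + 0.05


def test_tag_fasta_round_trip(tmp_path, small_truth, small_reads):
    table, _ = preprocess.run_preprocess(small_reads, ADAPTER)
    path = tmp_path / "tags.fasta"
    preprocess.write_tag_fasta(path, table)
    back = preprocess.read_tag_fasta(path, ["WF", "BF"])
    assert back.counts.sort_index().equals(table.counts.sort_index())
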