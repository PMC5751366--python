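"""Shared fixtures: a small synthetic dataset that every stage can consume."""

from __future__ import annotations

import pytest

from berrymir import synthdata


def tiny_config(seed: int = 11) -> synthdata.SyntheticConfig:
    """A dataset small enough for sub-second unit tests."""
    return synthdata.SyntheticConfig(
        n_scaffolds=1,
        scaffold_length=12_000,
        n_mirna_loci=6,
        library_sizes={"WF": 8_000, "BF": 8_000},
        fold_change_set=[4.0, 0.25, 1.0, 1.0, 4.0, 1.0],
        n_target_transcripts=4,
        n_decoy_transcripts=2,
        transcript_length=600,
        degradome_tags_per_transcript=60,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_truth() -> synthdata.SyntheticTruth:
    return synthdata.generate_truth(tiny_config())


@pytest.fixture(scope="session")
def small_reads(small_truth):
    return {
        cond: synthdata.simulate_sra_library(small_truth, cond)
        for cond in ("WF", "BF")
    }
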