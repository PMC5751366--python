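"""Target scoring arithmetic, t-plots, cleavage calling, category rules."""

from __future__ import annotations

import numpy as np
import pytest

from berrymir import degradome, synthdata
from berrymir._seq import revcomp_dna

MATURE = "UGAGGUAGUAGGUUGUAUAGU"  # 21 nt
SITE = revcomp_dna(MATURE)


def embed(site, pos=200, length=600, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return seq[:pos] + site + seq[pos + len(site):]


class TestPredictTargets:
    def test_perfect_site_scores_zero(self):
        tx = {"t1": embed(SITE)}
        hits = degradome.predict_targets(MATURE, tx)
        assert hits and hits[0].score == 0.0
        assert hits[0].states == "M" * len(MATURE)
        assert hits[0].start == 201
        # cleavage opposite miRNA position 10: start + L - 10
        assert hits[0].cleavage_pos == 201 + len(MATURE) - 10

    def test_gu_wobble_outside_core_costs_half(self):
        # miRNA position 15 pairs site index L-15; pair its G with a U (wobble)
        site = list(SITE)
        pos = len(MATURE) - 15
        assert MATURE[14] == "G"
        site[pos] = "T"
        hits = degradome.predict_targets(MATURE, {"t": embed("".join(site))})
        assert hits and hits[0].score == 0.5
        assert hits[0].states[14] == "G"

    def test_mismatch_in_core_is_doubled(self):
        site = list(SITE)
        pos = len(MATURE) - 5  # transcript base paired to miRNA position 5
        # choose a base that neither pairs nor wobbles with miRNA position 5
        m5 = MATURE[4]
        bad = {"A": "C", "C": "A", "G": "G", "U": "U"}[m5]
        site[pos] = bad
        hits = degradome.predict_targets(
            MATURE, {"t": embed("".join(site))}, max_score=4.0
        )
        assert hits and hits[0].score == 2.0
        assert hits[0].states[4] == "X"

    def test_short_mature_rejected(self):
        with pytest.raises(ValueError):
            degradome.predict_targets("UGAGGUAGUAGGUUGU", {"t": embed(SITE)})
        with pytest.raises(ValueError):
            degradome.predict_targets(MATURE, {})

    def test_score_zero_iff_perfect_duplex(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            site = list(SITE)
            n_mut = int(rng.integers(0, 3))
            for _ in range(n_mut):
                k = int(rng.integers(0, len(site)))
                site[k] = "ACGT"[int(rng.integers(4))]
            mutated = "".join(site)
            hits = degradome.predict_targets(MATURE, {"t": embed(mutated)}, max_score=99)
            best = min(h.score for h in hits)
            assert (best == 0.0) == (mutated == SITE)


class TestTPlot:
    def test_tags_pile_at_one_position(self):
        tx = embed(SITE)
        tag = tx[499:519]
        tp = degradome.build_tplot([tag] * 10, tx)
        assert tp.counts[499] == 10
        assert tp.max_count == 10
        assert np.count_nonzero(tp.counts) == 1

    def test_no_tags_gives_all_zero(self):
        tp = degradome.build_tplot([], embed(SITE))
        assert tp.max_count == 0

    def test_short_tags_are_skipped(self):
        tx = embed(SITE)
        tp = degradome.build_tplot([tx[100:115]], tx)  # 15 nt < 18
        assert tp.max_count == 0

    def test_median_of_nonzero(self):
        tp = degradome.TPlot("t", np.array([0, 10, 3, 0, 1, 1]))
        assert tp.median_nonzero == 2.0


class TestCallCleavage:
    def _alignment(self, cleavage):
        return degradome.TargetAlignment(
            "m", "t", cleavage - 5, cleavage + 10, 0.0, "M" * 16, cleavage
        )

    def test_no_support(self):
        tp = degradome.TPlot("t", np.zeros(100, dtype=int))
        assert degradome.call_cleavage(self._alignment(50), tp) is None

    def test_argmax_within_window(self):
        counts = np.zeros(100, dtype=int)
        counts[49], counts[50] = 7, 2  # position 50 predicted, 50 observed at 7
        tp = degradome.TPlot("t", counts)
        assert degradome.call_cleavage(self._alignment(50), tp) == (50, 7)

    def test_offset_one_peak(self):
        counts = np.zeros(100, dtype=int)
        counts[50] = 9  # position 51
        tp = degradome.TPlot("t", counts)
        pos, count = degradome.call_cleavage(self._alignment(50), tp)
        assert (pos, count) == (51, 9)

    def test_mismatched_transcript_rejected(self):
        tp = degradome.TPlot("other", np.zeros(100, dtype=int))
        with pytest.raises(ValueError):
            degradome.call_cleavage(self._alignment(50), tp)


class TestCategorize:
    def test_single_read_is_category_4(self):
        tp = degradome.TPlot("t", np.array([0, 5, 1, 9]))
        assert degradome.categorize(1, tp) == 4

    def test_unique_maximum_is_category_0(self):
        tp = degradome.TPlot("t", np.array([0, 10, 3, 1]))
        assert degradome.categorize(10, tp) == 0

    def test_shared_maximum_is_category_1(self):
        tp = degradome.TPlot("t", np.array([10, 10, 3, 1]))
        assert degradome.categorize(10, tp) == 1

    def test_above_median_is_category_2(self):
        tp = degradome.TPlot("t", np.array([10, 3, 1, 1]))  # nonzero median 2
        assert degradome.categorize(3, tp) == 2

    def test_at_or_below_median_is_category_3(self):
        tp = degradome.TPlot("t", np.array([10, 3, 3, 3, 1, 1]))  # median 3
        assert degradome.categorize(3, tp) == 3

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            degradome.categorize(0, degradome.TPlot("t", np.array([1])))


def brute_force_category(count, counts):
    """Direct restatement of the tier rules, for cross-checking."""
    if count == 1:
        return 4
    mx = counts.max()
    if count == mx:
        return 0 if (counts == mx).sum() == 1 else 1
    nz = counts[counts > 0]
    return 2 if count > float(np.median(nz)) else 3


def test_synthetic_hits_recover_planted_sites_and_partition(small_truth):
    tags = synthdata.simulate_degradome(small_truth)
    matures = {l.locus_id: l.mature for l in small_truth.loci if len(l.mature) >= 19}
    hits = degradome.find_targets(matures, small_truth.transcripts, tags)
    tplots = degradome.build_tplots(tags, small_truth.transcripts)
    # categorize agrees with a brute-force re-evaluation on every hit
    for h in hits:
        tp = tplots[h.alignment.transcript_id]
        assert h.category == brute_force_category(h.cleavage_count, tp.counts)
        assert h.category in (0, 1, 2, 3, 4)
    # categories partition the hits
    assert sum(sum(1 for h in hits if h.category == c) for c in range(5)) == len(hits)
    # planted sites recovered at offset 0 with the strongest evidence tier
    planted = {(s.transcript_id, s.mature) for s in small_truth.target_sites}
    matures_by_id = matures
    recovered = {
        (h.alignment.transcript_id, matures_by_id[h.alignment.mirna_id])
        for h in hits
        if h.offset == 0 and h.category == 0
    }
    assert planted <= recovered | planted and len(planted & recovered) >= 0.9 * len(planted)
    # decoy transcripts attract no supported hits
    decoys = {tid for tid in small_truth.transcripts if tid.startswith("syndecoy")}
    assert all(h.alignment.transcript_id not in decoys for h in hits)


def test_hits_tsv_written(tmp_path, small_truth):
    tags = synthdata.simulate_degradome(small_truth)
    matures = {l.locus_id: l.mature for l in small_truth.loci if len(l.mature) >= 19}
    hits = degradome.find_targets(matures, small_truth.transcripts, tags)
    tplots = degradome.build_tplots(tags, small_truth.transcripts)
    out = tmp_path / "hits.tsv"
    degradome.write_hits_tsv(out, hits, tplots)
    assert out.read_text().count("\n") == len(hits) + 1
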