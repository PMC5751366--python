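"""Homology matching, exact location, precursor windows, hairpin screening."""

from __future__ import annotations

import random

import pytest

from berrymir import discovery, preprocess
from berrymir._seq import revcomp_dna, to_dna
from berrymir.discovery import HairpinEvaluation, Locus

REF = {"ref-miR1": "UGAGGUAGUAGGUUGUAUAGU", "ref-miR2": "UUCCACAGCUUUCUUGAACUU"}


def brute_force_match(tag, ref, max_shift=2, max_mm=1, min_core=16):
    """Independent enumeration over all end-shift placements."""
    best = None
    for offset in range(-max_shift, max_shift + 1):
        overhang = offset + len(tag) - len(ref)
        if abs(overhang) > max_shift:
            continue
        core = [
            (tag[i], ref[i + offset])
            for i in range(len(tag))
            if 0 <= i + offset < len(ref)
        ]
        if len(core) < min_core:
            continue
        mm = sum(a != b for a, b in core)
        if mm <= max_mm:
            cand = (mm, abs(-offset) + abs(overhang), -offset, overhang)
            if best is None or cand[:2] < best[:2]:
                best = cand
    return best


class TestMatchKnown:
    def test_identical_tag(self):
        hits = discovery.match_known(REF["ref-miR1"], REF)
        assert hits[0].reference_id == "ref-miR1"
        assert (hits[0].mismatches, hits[0].shift5, hits[0].shift3) == (0, 0, 0)

    def test_two_internal_substitutions_is_no_hit(self):
        tag = list(REF["ref-miR1"])
        tag[8] = "C" if tag[8] != "C" else "G"
        tag[12] = "C" if tag[12] != "C" else "G"
        hits = discovery.match_known("".join(tag), {"ref-miR1": REF["ref-miR1"]})
        assert hits == []

    def test_shifted_tag_with_one_mismatch(self):
        ref = REF["ref-miR1"]
        tag = list(ref[1:] + "C")  # drop 1 nt at 5', extend 1 nt at 3'
        tag[9] = "C" if tag[9] != "C" else "G"
        hits = discovery.match_known("".join(tag), {"ref-miR1": ref})
        assert len(hits) == 1
        assert (hits[0].mismatches, hits[0].shift5, hits[0].shift3) == (1, -1, 1)

    def test_agrees_with_enumeration_oracle(self):
        rng = random.Random(2024)
        bases = "ACGU"
        for _ in range(60):
            ref = "".join(rng.choice(bases) for _ in range(rng.randint(19, 24)))
            tag = list(ref)
            for _ in range(rng.randint(0, 3)):  # random edits
                tag[rng.randrange(len(tag))] = rng.choice(bases)
            d5, d3 = rng.randint(-2, 2), rng.randint(-2, 2)
            s = "".join(tag)
            s = s[max(d5, 0):] if d5 >= 0 else "A" * (-d5) + s
            s = s + "G" * d3 if d3 >= 0 else s[:d3]
            if len(s) < 16:
                continue
            expect = brute_force_match(s, ref)
            hits = discovery.match_known(s, {"r": ref})
            if expect is None:
                assert hits == []
            else:
                assert hits, (s, ref)
                got = hits[0]
                assert (got.mismatches, abs(got.shift5) + abs(got.shift3)) == expect[:2]

    def test_reference_matched_against_itself_returns_itself_first(self):
        for rid, seq in REF.items():
            hits = discovery.match_known(seq, REF)
            assert hits[0].reference_id == rid
            assert (hits[0].mismatches, hits[0].shift5, hits[0].shift3) == (0, 0, 0)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            discovery.match_known("UGAGGUAGUAGGUUGUAUAGU", {})


class TestLocate:
    def test_planted_tag_found_at_exact_locus(self):
        rng = random.Random(0)
        scaffold = "".join(rng.choice("ACGT") for _ in range(2000))
        tag = "TGAGGTAGTAGGTTGTATAGT"
        seq = scaffold[:1000] + tag + scaffold[1000:]
        loci = discovery.locate_on_reference(tag, {"scaf1": seq})
        assert Locus("scaf1", "+", 1001, 1021) in loci

    def test_reverse_complement_found_on_minus_strand(self):
        rng = random.Random(1)
        scaffold = "".join(rng.choice("ACGT") for _ in range(2000))
        tag = "TGAGGTAGTAGGTTGTATAGT"
        seq = scaffold[:500] + revcomp_dna(tag) + scaffold[500:]
        loci = discovery.locate_on_reference(tag, {"scaf1": seq})
        assert Locus("scaf1", "-", 501, 521) in loci

    def test_multiple_loci_sorted(self):
        tag = "TGAGGTAGTAGGTTGTATAGT"
        filler = "CCCCCAAAAACCCCCAAAAA" * 5
        seq = filler + tag + filler + tag + filler
        loci = discovery.locate_on_reference(tag, {"s": seq})
        assert [l.start for l in loci] == sorted(l.start for l in loci)
        assert len(loci) == 2

    def test_agrees_with_brute_force_scan(self):
        rng = random.Random(3)
        refs = {
            f"s{k}": "".join(rng.choice("ACGT") for _ in range(300)) for k in range(3)
        }
        for _ in range(30):
            acc = rng.choice(list(refs))
            at = rng.randrange(280)
            tag = refs[acc][at : at + 20]
            expected = []
            for a, seq in refs.items():
                for strand, q in (("+", tag), ("-", revcomp_dna(tag))):
                    for i in range(len(seq) - len(q) + 1):
                        if seq[i : i + len(q)] == q:
                            expected.append((a, strand, i + 1, i + len(q)))
            got = {(l.accession, l.strand, l.start, l.end)
                   for l in discovery.locate_on_reference(tag, refs)}
            assert got == set(expected)


class TestPrecursorWindows:
    def test_windows_clipped_at_scaffold_bounds(self):
        seq = "ACGT" * 15  # 60 nt
        locus = Locus("s", "+", 10, 30)
        cands = discovery.extract_precursor_candidates(locus, {"s": seq}, max_flank=50)
        assert all(c.locus.start >= 1 and c.locus.end <= 60 for c in cands)
        assert any(c.locus.start == 1 for c in cands)

    def test_a_window_contains_the_full_planted_precursor(self, small_truth):
        locus0 = small_truth.loci[0]
        mat = Locus(locus0.scaffold, locus0.strand, locus0.mature_start, locus0.mature_end)
        cands = discovery.extract_precursor_candidates(mat, small_truth.scaffolds)
        assert any(
            c.locus.start <= locus0.start and c.locus.end >= locus0.end for c in cands
        )

    def test_max_flank_zero_yields_nothing(self):
        locus = Locus("s", "+", 10, 30)
        cands = discovery.extract_precursor_candidates(
            locus, {"s": "ACGT" * 30}, max_flank=0
        )
        assert cands == []

    def test_minus_strand_window_is_reverse_complemented(self, small_truth):
        minus = [l for l in small_truth.loci if l.strand == "-"]
        if not minus:
            pytest.skip("no minus-strand locus in the small dataset")
        locus = minus[0]
        mat = Locus(locus.scaffold, "-", locus.mature_start, locus.mature_end)
        cands = discovery.extract_precursor_candidates(mat, small_truth.scaffolds)
        for c in cands:
            got = c.sequence[c.mature_offset : c.mature_offset + c.mature_length]
            assert got == locus.mature


class TestMfei:
    @pytest.mark.parametrize(
        "mfe,length,gc,expected",
        [(-50.0, 100, 50.0, 1.0), (-40.0, 100, 40.0, 1.0), (-30.0, 120, 40.0, 0.625)],
    )
    def test_formula(self, mfe, length, gc, expected):
        assert discovery.mfei(mfe, length, gc) == pytest.approx(expected)

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            discovery.mfei(-10.0, 100, 0.0)
        with pytest.raises(ValueError):
            discovery.mfei(5.0, 100, 50.0)
        with pytest.raises(ValueError):
            discovery.mfei(-10.0, 0, 50.0)


def _evaluation(**kw) -> HairpinEvaluation:
    base = dict(
        sequence="", structure="", mfe=-40.0, gc=45.0, amfe=-40.0, mfei=1.4,
        arm="5p", duplex_mismatches=0, has_internal_loop_or_bulge=False,
        loop_span=(30, 40), mature_span=(5, 25), star_span=(45, 65),
    )
    base.update(kw)
    return HairpinEvaluation(**base)


class TestClassifyNovel:
    def test_all_criteria_met(self):
        accepted, reasons = discovery.classify_novel(_evaluation(mfei=1.4))
        assert accepted and reasons == []

    def test_excess_duplex_mismatches(self):
        accepted, reasons = discovery.classify_novel(_evaluation(duplex_mismatches=3))
        assert not accepted and reasons == ["duplex-mismatches"]

    def test_low_mfei_is_mrna_like(self):
        accepted, reasons = discovery.classify_novel(_evaluation(mfei=0.62))
        assert not accepted and reasons == ["low-mfei"]

    def test_mature_spanning_the_loop(self):
        accepted, reasons = discovery.classify_novel(_evaluation(arm=None))
        assert not accepted and "mature-not-on-arm" in reasons


def test_evaluate_hairpin_round_trips_planted_mismatches(small_truth):
    for locus in small_truth.loci[:4]:
        mat = Locus(locus.scaffold, locus.strand, locus.mature_start, locus.mature_end)
        cands = discovery.extract_precursor_candidates(mat, small_truth.scaffolds)
        full = next(
            c for c in cands
            if c.locus.start <= locus.start and c.locus.end >= locus.end
        )
        ev = discovery.evaluate_hairpin(full)
        assert ev.arm == locus.arm
        assert ev.duplex_mismatches == locus.n_duplex_mismatches


def test_catalog_recovers_planted_loci_and_is_coordinate_consistent(
    small_truth, small_reads
):
    table, _ = preprocess.run_preprocess(
        small_reads,
        small_truth.config.adapter,
        contaminants=small_truth.contaminants.values(),
    )
    records = discovery.catalog_mirnas(
        table, small_truth.scaffolds, small_truth.mature_reference
    )
    by_mature = {r.mature: r for r in records}
    recovered = 0
    for locus in small_truth.loci:
        rec = by_mature.get(locus.mature)
        if rec is None:
            continue
        if (
            rec.strand == locus.strand
            and rec.arm == locus.arm
            and rec.mature_start == locus.mature_start
            and rec.mature_end == locus.mature_end
        ):
            recovered += 1
        expect_status = "known" if locus.known else "novel"
        assert rec.status == expect_status, locus.locus_id
    assert recovered >= 0.9 * len(small_truth.loci)
    # no contaminant-derived tag may appear in the catalog
    blob = "#".join(small_truth.contaminants.values())
    assert all(to_dna(r.mature) not in blob for r in records)
    # coordinate consistency: re-extract the mature from the reference
    for rec in records:
        seg = small_truth.scaffolds[rec.accession][rec.mature_start - 1 : rec.mature_end]
        if rec.strand == "-":
            seg = revcomp_dna(seg)
        assert discovery.to_rna(seg) == rec.mature
        assert rec.start <= rec.mature_start <= rec.mature_end <= rec.end
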