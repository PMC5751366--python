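"""Known- and novel-miRNA identification from a unique-tag table.

Known miRNAs are assigned by homology to a mature reference set, allowing up
to 2 nt of length variation at each end and one internal mismatch (the
isomiR convention).  Candidate tags are located exactly on the reference
scaffolds (both strands), precursor windows are extracted around the mature
site, folded, and screened with the four classical plant criteria:

1. the mature lies on one arm of the hairpin;
2. at most 2 unpaired residues between the mature and its star;
3. no internal loop or bulge (>= 2 nt run) inside the mature/star duplex;
4. a steady structure with high minimal folding free energy index
   (MFEI = |MFE/length*100| / GC%; threshold 0.85, which separates genuine
   precursors, typically 1.1-1.7, from the ~0.6 of tRNA/rRNA/mRNA).

The catalog reports, per locus, the best candidate window by MFEI (ties go
to the shorter precursor) in the style of a known/novel miRNA table:
mature sequence, length, arm, scaffold accession, strand, precursor span,
homolog or star-mismatch count, MFEI and per-library abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._seq import revcomp_dna, to_dna, to_rna
from . import folding
from .io import PathLike, atomic_write
from .preprocess import UniqueTagTable

__all__ = [
    "KnownHit",
    "Locus",
    "PrecursorCandidate",
    "HairpinEvaluation",
    "MirnaRecord",
    "match_known",
    "locate_on_reference",
    "extract_precursor_candidates",
    "evaluate_hairpin",
    "mfei",
    "classify_novel",
    "catalog_mirnas",
    "write_catalog_tsv",
]

MFEI_THRESHOLD = 0.85
MAX_END_SHIFT = 2
MAX_INTERNAL_MISMATCHES = 1
MIN_MATCH_CORE = 16


@dataclass(frozen=True)
class KnownHit:
    reference_id: str
    mismatches: int
    shift5: int  # negative = tag truncated at its 5' end relative to the reference
    shift3: int  # positive = tag extended at its 3' end


@dataclass(frozen=True)
class Locus:
    accession: str
    strand: str  # "+" | "-"
    start: int  # 1-based inclusive, forward axis
    end: int


@dataclass(frozen=True)
class PrecursorCandidate:
    locus: Locus  # precursor span on the forward axis
    sequence: str  # RNA, 5'->3' of the transcript (reverse-complemented for "-")
    mature_offset: int  # 0-based offset of the mature within `sequence`
    mature_length: int


@dataclass(frozen=True)
class HairpinEvaluation:
    """Folded precursor candidate with duplex statistics and MFEI."""

    sequence: str
    structure: str
    mfe: float
    gc: float  # percent
    amfe: float  # (MFE / length) * 100
    mfei: float  # |AMFE| / GC%
    arm: Optional[str]  # "5p" | "3p" | None (mature spans the loop / unpaired)
    duplex_mismatches: int
    has_internal_loop_or_bulge: bool
    loop_span: Optional[Tuple[int, int]]  # 0-based inclusive, between the arms
    mature_span: Tuple[int, int]
    star_span: Optional[Tuple[int, int]]


@dataclass
class MirnaRecord:
    """One catalogued miRNA locus (known or novel)."""

    mirna_id: str
    mature: str
    length: int
    arm: str
    accession: str
    strand: str
    start: int  # precursor span, 1-based inclusive
    end: int
    mature_start: int
    mature_end: int
    homolog: Optional[str]  # best reference hit (known), else None
    star_mismatches: Optional[int]  # duplex mismatch count (novel), else None
    mfei_value: float
    structure: str = ""
    status: str = "novel"  # "known" | "novel"
    raw_counts: Dict[str, int] = field(default_factory=dict)
    norm_abundance: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length != len(self.mature):
            raise ValueError("length field must equal mature length")
        if self.start > self.end:
            raise ValueError("start > end")


def match_known(
    tag: str,
    reference: Mapping[str, str],
    max_end_shift: int = MAX_END_SHIFT,
    max_mismatches: int = MAX_INTERNAL_MISMATCHES,
    min_core: int = MIN_MATCH_CORE,
) -> List[KnownHit]:
    """Match a tag against a mature reference set with end-variation tolerance.

    A hit aligns the tag to a reference with at most ``max_end_shift`` nt of
    extension/truncation at each end and at most ``max_mismatches`` internal
    mismatches over an overlap core of at least ``min_core`` nt.  Hits are
    sorted by (mismatches, total absolute shift, reference id).
    """
    if not reference:
        raise ValueError("empty reference set")
    tag_r = to_rna(tag)
    hits: List[KnownHit] = []
    for ref_id, ref_seq in reference.items():
        ref_r = to_rna(ref_seq)
        best: Optional[KnownHit] = None
        for offset in range(-max_end_shift, max_end_shift + 1):
            # tag position i aligns reference position i + offset
            overhang3 = (offset + len(tag_r)) - len(ref_r)
            if abs(overhang3) > max_end_shift:
                continue
            lo = max(0, -offset)
            hi = min(len(tag_r), len(ref_r) - offset)
            core = hi - lo
            if core < min_core:
                continue
            mm = sum(1 for i in range(lo, hi) if tag_r[i] != ref_r[i + offset])
            if mm > max_mismatches:
                continue
            hit = KnownHit(ref_id, mm, -offset, overhang3)
            if best is None or (hit.mismatches, abs(hit.shift5) + abs(hit.shift3)) < (
                best.mismatches,
                abs(best.shift5) + abs(best.shift3),
            ):
                best = hit
        if best is not None:
            hits.append(best)
    hits.sort(key=lambda h: (h.mismatches, abs(h.shift5) + abs(h.shift3), h.reference_id))
    return hits


def locate_on_reference(tag: str, references: Mapping[str, str]) -> List[Locus]:
    """All exact-match loci of a tag on both strands of the references.

    Reverse-strand hits are reported on the forward coordinate axis with
    strand '-'.  Coordinates are 1-based inclusive.
    """
    tag_d = to_dna(tag)
    tag_rc = revcomp_dna(tag_d)
    loci: List[Locus] = []
    for acc, seq in references.items():
        seq_d = to_dna(seq)
        for query, strand in ((tag_d, "+"), (tag_rc, "-")):
            if strand == "-" and tag_rc == tag_d:
                continue  # palindromic tag: avoid double-reporting
            at = seq_d.find(query)
            while at >= 0:
                loci.append(Locus(acc, strand, at + 1, at + len(query)))
                at = seq_d.find(query, at + 1)
    loci.sort(key=lambda l: (l.accession, l.start, l.strand))
    return loci


def extract_precursor_candidates(
    locus: Locus,
    references: Mapping[str, str],
    max_flank: int = 250,
    min_flank: int = 20,
    step: int = 10,
    min_length: int = 55,
) -> List[PrecursorCandidate]:
    """Nested candidate windows around a mature locus.

    Flanks of ``min_flank`` .. ``max_flank`` nt (step ``step``) are added
    symmetrically around the mature site; windows are clipped at scaffold
    bounds and must reach ``min_length`` nt.  Sequences are returned 5'->3'
    in transcript orientation (reverse complement for '-' loci).
    """
    seq = to_dna(references[locus.accession])
    n = len(seq)
    mat_len = locus.end - locus.start + 1
    out: List[PrecursorCandidate] = []
    for flank in range(min_flank, max_flank + 1, step):
        w_start = max(1, locus.start - flank)
        w_end = min(n, locus.end + flank)
        if w_end - w_start + 1 < min_length:
            continue
        window = seq[w_start - 1 : w_end]
        if locus.strand == "+":
            rna = to_rna(window)
            mat_off = locus.start - w_start
        else:
            rna = to_rna(revcomp_dna(window))
            mat_off = w_end - locus.end
        cand = PrecursorCandidate(
            locus=Locus(locus.accession, locus.strand, w_start, w_end),
            sequence=rna,
            mature_offset=mat_off,
            mature_length=mat_len,
        )
        if not out or cand.locus != out[-1].locus:
            out.append(cand)
    return out


def mfei(mfe: float, length: int, gc_percent: float) -> float:
    """Minimal folding free energy index, |AMFE| / GC%, as a positive magnitude."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 < gc_percent <= 100.0:
        raise ValueError("gc_percent must lie in (0, 100]")
    if mfe > 0:
        raise ValueError("MFE must be <= 0")
    amfe = mfe / length * 100.0
    return abs(amfe) / gc_percent


def evaluate_hairpin(
    candidate: PrecursorCandidate,
    engine=None,
) -> HairpinEvaluation:
    """Fold a candidate window and measure the mature/star duplex.

    The arm is the side of the terminal loop holding the mature; the star
    span is the set of positions paired to the mature (2-nt offset convention
    applies to annotation, not to the pairing itself).  A mature that spans
    the loop (overlapping its own partner region) has ``arm=None`` and is
    rejected downstream.
    """
    lo = candidate.mature_offset
    hi = lo + candidate.mature_length - 1
    if hi >= len(candidate.sequence):
        raise ValueError("mature not fully inside the window")
    result = folding.fold(candidate.sequence, engine=engine)
    gc = folding.gc_percent(candidate.sequence)
    amfe = result.energy / len(candidate.sequence) * 100.0
    index = abs(amfe) / gc if gc > 0 else 0.0
    region = folding.duplex_region(result.pair_table, (lo, hi))
    arm: Optional[str] = None
    loop_span: Optional[Tuple[int, int]] = None
    star_span: Optional[Tuple[int, int]] = None
    if region.defined:
        star_span = (region.star_start, region.star_end)
        if region.star_start > hi:
            arm = "5p"
            loop_span = (hi + 1, region.star_start - 1)
        elif region.star_end < lo:
            arm = "3p"
            loop_span = (region.star_end + 1, lo - 1)
        # else: mature overlaps its partner span -> spans the loop, arm=None
    return HairpinEvaluation(
        sequence=candidate.sequence,
        structure=result.structure,
        mfe=result.energy,
        gc=gc,
        amfe=amfe,
        mfei=index,
        arm=arm,
        duplex_mismatches=region.unpaired_count,
        has_internal_loop_or_bulge=region.has_internal_loop_or_bulge,
        loop_span=loop_span,
        mature_span=(lo, hi),
        star_span=star_span,
    )


def classify_novel(
    evaluation: HairpinEvaluation,
    star_detected: bool = False,
    mfei_threshold: float = MFEI_THRESHOLD,
    max_duplex_mismatches: int = 2,
) -> Tuple[bool, List[str]]:
    """Apply the four novel-miRNA criteria; returns (accepted, reason codes).

    Star presence in the read data is recorded by callers but not required
    for acceptance.
    """
    reasons: List[str] = []
    if evaluation.arm is None:
        reasons.append("mature-not-on-arm")
    if evaluation.duplex_mismatches > max_duplex_mismatches:
        reasons.append("duplex-mismatches")
    if evaluation.has_internal_loop_or_bulge:
        reasons.append("internal-loop-or-bulge")
    if evaluation.mfei < mfei_threshold:
        reasons.append("low-mfei")
    return (not reasons, reasons)


def _cluster_tags(
    located: List[Tuple[str, int, List[Locus]]], merge_gap: int = 60
) -> List[List[Tuple[str, int, Locus]]]:
    """Group (tag, count, locus) entries into physical loci.

    Entries on either strand within ``merge_gap`` nt of one another are one
    cluster: the reverse complement of a near-perfect-duplex mature matches
    the star arm across the loop, so the mature-site and star-shadow hits of
    one hairpin must not become two catalog entries.
    """
    entries: List[Tuple[str, int, Locus]] = [
        (tag, count, locus) for tag, count, loci in located for locus in loci
    ]
    entries.sort(key=lambda e: (e[2].accession, e[2].start, e[2].end, e[2].strand, e[0]))
    clusters: List[List[Tuple[str, int, Locus]]] = []
    for entry in entries:
        locus = entry[2]
        if clusters:
            last = clusters[-1][-1][2]
            prev_end = max(e[2].end for e in clusters[-1])
            if locus.accession == last.accession and locus.start <= prev_end + merge_gap:
                clusters[-1].append(entry)
                continue
        clusters.append([entry])
    return clusters


def catalog_mirnas(
    table: UniqueTagTable,
    references: Mapping[str, str],
    mature_reference: Mapping[str, str],
    min_count: int = 2,
    mfei_threshold: float = MFEI_THRESHOLD,
    max_flank: int = 250,
    id_prefix: str = "syn",
    engine=None,
) -> List[MirnaRecord]:
    """Build the known/novel miRNA catalog from a tag table.

    Tags with total count >= ``min_count`` are located exactly on the
    reference; overlapping loci are clustered and the most abundant tag of
    each cluster (ties: lexicographically smallest) is the locus
    representative.  All exact loci are considered and the best-MFEI
    precursor is catalogued.  Known status requires a homology hit; novel
    status requires all four hairpin criteria.
    """
    totals = table.counts.sum(axis=1)
    located: List[Tuple[str, int, List[Locus]]] = []
    for tag, total in totals.items():
        if total < min_count:
            continue
        loci = locate_on_reference(tag, references)
        if loci:
            located.append((tag, int(total), loci))
    records: List[MirnaRecord] = []
    n_novel = 0
    for cluster in _cluster_tags(located):
        # orient the locus by read support: end-variation tags map only in
        # the true orientation, while a perfect-duplex mature maps to both
        support = {"+": 0, "-": 0}
        for _tag, cnt, loc in cluster:
            support[loc.strand] += cnt
        strand = "+" if support["+"] >= support["-"] else "-"
        oriented = [e for e in cluster if e[2].strand == strand]
        tag, count, locus = max(oriented, key=lambda e: (e[1], _neg_lex(e[0])))
        mature = to_rna(tag)
        hits = match_known(mature, mature_reference) if mature_reference else []
        evals = [
            (evaluate_hairpin(cand, engine=engine), cand)
            for cand in extract_precursor_candidates(locus, references, max_flank=max_flank)
        ]
        # best-first by MFEI, ties to the shorter precursor; catalog the first
        # candidate meeting the acceptance rule for its status
        evals.sort(key=lambda ec: (-ec[0].mfei, len(ec[1].sequence)))
        best_eval: Optional[HairpinEvaluation] = None
        best_cand: Optional[PrecursorCandidate] = None
        for ev, cand in evals:
            ok = (
                ev.arm is not None
                if hits
                else classify_novel(ev, mfei_threshold=mfei_threshold)[0]
            )
            if ok:
                best_eval, best_cand = ev, cand
                break
        if best_eval is None:
            continue
        if hits:
            status, homolog = "known", hits[0].reference_id
            mirna_id = f"{id_prefix}-{homolog}"
        else:
            status, homolog = "novel", None
            n_novel += 1
            mirna_id = f"{id_prefix}-miR_n{n_novel:02d}"
        row = table.counts.loc[tag]
        rec = MirnaRecord(
            mirna_id=mirna_id,
            mature=mature,
            length=len(mature),
            arm=best_eval.arm,
            accession=locus.accession,
            strand=locus.strand,
            start=best_cand.locus.start,
            end=best_cand.locus.end,
            mature_start=locus.start,
            mature_end=locus.end,
            homolog=homolog,
            star_mismatches=best_eval.duplex_mismatches if status == "novel" else None,
            mfei_value=best_eval.mfei,
            structure=best_eval.structure,
            status=status,
            raw_counts={lib: int(row[lib]) for lib in table.libraries},
        )
        for lib in table.libraries:
            total = table.library_totals.get(lib, 0)
            rec.norm_abundance[lib] = rec.raw_counts[lib] * 1e6 / total if total else 0.0
        records.append(rec)
    records.sort(key=lambda r: (r.accession, r.start, r.mirna_id))
    return records


def _neg_lex(tag: str):
    """Sort helper: prefer lexicographically smaller tags at equal count."""
    return tuple(-ord(c) for c in tag)


def write_catalog_tsv(path: PathLike, records: Sequence[MirnaRecord], libraries: Sequence[str]) -> None:
    """Catalog table: ID, sequence, LT, TP, accession, strand, span, HOMO/NM, MFEI, abundances."""
    cols = ["ID", "sequence", "LT", "TP", "Accession", "Str", "Start", "End",
            "MatStart", "MatEnd", "HOMO/NM", "MFEI"]
    cols += [f"{lib}(norm)" for lib in libraries] + [f"{lib}(raw)" for lib in libraries]
    rows = []
    for r in records:
        homo_nm = r.homolog if r.status == "known" else str(r.star_mismatches)
        row = [
            r.mirna_id, r.mature, r.length, "5'" if r.arm == "5p" else "3'",
            r.accession, r.strand, r.start, r.end, r.mature_start, r.mature_end,
            homo_nm, f"{r.mfei_value:.2f}",
        ]
        row += [f"{r.norm_abundance.get(lib, 0.0):.2f}" for lib in libraries]
        row += [r.raw_counts.get(lib, 0) for lib in libraries]
        rows.append(row)
    with atomic_write(path) as fh:
        pd.DataFrame(rows, columns=cols).to_csv(fh, sep="\t", index=False)
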