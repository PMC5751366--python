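"""Degradome (PARE) target identification: alignment, t-plots, categories 0-4.

A miRNA-guided slice leaves an uncapped mRNA 5' end opposite miRNA positions
10-11; degradome tags pile up at that position.  Targets are predicted by
complementarity with the TargetFinder-style penalty scheme (mismatch 1.0,
G:U wobble 0.5, gap 1.0; penalties doubled over miRNA positions 2-13;
alignments with score <= 4.0 retained; this package emits ungapped
alignments).  Each transcript's t-plot is the per-position count of
degradome tag 5' ends; the observed cleavage site is the highest-count
position within +/-1 nt of the predicted slice (opposite miRNA position 10),
and hits are tiered CleaveLand-style:

* category 0 - count equals the transcript maximum, unique maximum;
* category 1 - equals the maximum, shared with other positions;
* category 2 - below the maximum but above the median of nonzero counts;
* category 3 - below the maximum and at or below that median;
* category 4 - a single raw read.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from ._seq import to_dna, to_rna
from .io import PathLike, atomic_write

__all__ = [
    "TargetAlignment",
    "TPlot",
    "TargetHit",
    "predict_targets",
    "build_tplot",
    "build_tplots",
    "call_cleavage",
    "categorize",
    "find_targets",
    "write_hits_tsv",
    "write_tplot_tsv",
    "plot_tplot",
]

MAX_TARGET_SCORE = 4.0
SEED_REGION = (2, 13)  # miRNA positions with doubled penalties, inclusive
MIN_TAG_PREFIX = 18

# penalty[mirna_base, transcript_base]; bases as ACG(U/T) codes 0..3
_PENALTY = np.ones((4, 4))
_WC = {(0, 3), (3, 0), (1, 2), (2, 1)}  # A:U, U:A, C:G, G:C
for _m, _t in _WC:
    _PENALTY[_m, _t] = 0.0
_PENALTY[2, 3] = 0.5  # G paired with U in the transcript
_PENALTY[3, 2] = 0.5  # U paired with G


@dataclass(frozen=True)
class TargetAlignment:
    """Ungapped miRNA/transcript alignment with TargetFinder-style score."""

    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive span on the transcript
    end: int
    score: float
    states: str  # per miRNA position 5'->3': M (match), G (G:U), X (mismatch)
    cleavage_pos: int  # transcript base opposite miRNA position 10

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if not self.start <= self.cleavage_pos <= self.end:
            raise ValueError("cleavage position outside alignment span")


@dataclass(frozen=True)
class TPlot:
    """Degradome 5'-end counts along one transcript (1-based positions)."""

    transcript_id: str
    counts: np.ndarray

    @property
    def max_count(self) -> int:
        return int(self.counts.max()) if self.counts.size else 0

    @property
    def median_nonzero(self) -> float:
        nz = self.counts[self.counts > 0]
        return float(np.median(nz)) if nz.size else 0.0


@dataclass(frozen=True)
class TargetHit:
    alignment: TargetAlignment
    cleavage_count: int
    category: int
    offset: int  # observed peak minus predicted cleavage position


def predict_targets(
    mature: str,
    transcripts: Mapping[str, str],
    mirna_id: str = "miRNA",
    max_score: float = MAX_TARGET_SCORE,
) -> List[TargetAlignment]:
    """Score the miRNA against every transcript window; keep score <= cutoff.

    The per-position penalty is 0 for a Watson-Crick pair, 0.5 for a G:U
    wobble and 1.0 for a mismatch, doubled at miRNA positions 2-13; the
    predicted cleavage site is the transcript base paired to miRNA position
    10 (counted from the miRNA 5' end).
    """
    if not transcripts:
        raise ValueError("transcripts must be non-empty")
    mat = to_rna(mature)
    if len(mat) < 19:
        raise ValueError("mature miRNA must be >= 19 nt for target prediction")
    L = len(mat)
    m_codes = np.array([_CODE[c] for c in mat])
    # miRNA position i (1-based) pairs window index L - i
    weights = np.where(
        (np.arange(L, 0, -1) >= SEED_REGION[0]) & (np.arange(L, 0, -1) <= SEED_REGION[1]),
        2.0,
        1.0,
    )
    m_rev = m_codes[::-1]  # m_rev[k] = miRNA base paired at window index k
    out: List[TargetAlignment] = []
    for tid, tseq in transcripts.items():
        t_codes = np.array([_CODE[c] for c in to_rna(tseq)])
        if t_codes.size < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(t_codes, L)
        pens = _PENALTY[m_rev[None, :], windows] * weights[None, :]
        scores = pens.sum(axis=1)
        for p in np.nonzero(scores <= max_score)[0]:
            site_pens = _PENALTY[m_rev, windows[p]]
            # states reported miRNA 5'->3'
            states = "".join(
                "M" if pen == 0.0 else ("G" if pen == 0.5 else "X")
                for pen in site_pens[::-1]
            )
            start = int(p) + 1
            out.append(
                TargetAlignment(
                    mirna_id=mirna_id,
                    transcript_id=tid,
                    start=start,
                    end=start + L - 1,
                    score=float(scores[p]),
                    states=states,
                    cleavage_pos=start + L - 10,
                )
            )
    out.sort(key=lambda a: (a.score, a.transcript_id, a.start))
    return out


_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def build_tplot(tags: Iterable[str], transcript: str, transcript_id: str = "tx") -> TPlot:
    """Count degradome tag 5' ends along one transcript.

    A tag maps by exact match of its first 18 nt; tags shorter than 18 nt
    are skipped, and a prefix occurring at several positions counts at each.
    """
    seq = to_dna(transcript)
    counts = np.zeros(len(seq), dtype=np.int64)
    for tag, n in Counter(to_dna(t) for t in tags).items():
        if len(tag) < MIN_TAG_PREFIX:
            continue
        probe = tag[:MIN_TAG_PREFIX]
        at = seq.find(probe)
        while at >= 0:
            counts[at] += n
            at = seq.find(probe, at + 1)
    return TPlot(transcript_id, counts)


def build_tplots(tags: Sequence[str], transcripts: Mapping[str, str]) -> Dict[str, TPlot]:
    """t-plots for many transcripts via a shared 18-mer prefix index."""
    index: Dict[str, List[Tuple[str, int]]] = {}
    for tid, seq in transcripts.items():
        s = to_dna(seq)
        for i in range(0, len(s) - MIN_TAG_PREFIX + 1):
            index.setdefault(s[i : i + MIN_TAG_PREFIX], []).append((tid, i))
    counts = {tid: np.zeros(len(seq), dtype=np.int64) for tid, seq in transcripts.items()}
    for tag, n in Counter(to_dna(t) for t in tags).items():
        if len(tag) < MIN_TAG_PREFIX:
            continue
        for tid, pos in index.get(tag[:MIN_TAG_PREFIX], ()):
            counts[tid][pos] += n
    return {tid: TPlot(tid, c) for tid, c in counts.items()}


def call_cleavage(
    alignment: TargetAlignment, tplot: TPlot, window: int = 1
) -> Optional[Tuple[int, int]]:
    """Observed peak within +/-window nt of the predicted cleavage position.

    Returns ``(position, count)`` or None when no tag supports the site.
    Ties prefer the position closest to the prediction, then the 5'-most.
    """
    if alignment.transcript_id != tplot.transcript_id:
        raise ValueError("alignment and t-plot refer to different transcripts")
    pred = alignment.cleavage_pos
    candidates = [
        p for p in range(pred - window, pred + window + 1)
        if 1 <= p <= tplot.counts.size
    ]
    if not candidates:
        return None
    best = max(candidates, key=lambda p: (tplot.counts[p - 1], -abs(p - pred), -p))
    count = int(tplot.counts[best - 1])
    return (best, count) if count > 0 else None


def categorize(cleavage_count: int, tplot: TPlot) -> int:
    """CleaveLand-style evidence tier 0-4 for a supported cleavage site."""
    if cleavage_count < 1:
        raise ValueError("cleavage count must be >= 1 (filter unsupported sites first)")
    if cleavage_count == 1:
        return 4
    mx = tplot.max_count
    if cleavage_count == mx:
        n_at_max = int((tplot.counts == mx).sum())
        return 0 if n_at_max == 1 else 1
    return 2 if cleavage_count > tplot.median_nonzero else 3


def find_targets(
    matures: Mapping[str, str],
    transcripts: Mapping[str, str],
    degradome_tags: Sequence[str],
    max_score: float = MAX_TARGET_SCORE,
    window: int = 1,
) -> List[TargetHit]:
    """End-to-end target calling: predict, map tags, call peaks, categorize."""
    tplots = build_tplots(degradome_tags, transcripts)
    hits: List[TargetHit] = []
    for mid, mature in matures.items():
        for aln in predict_targets(mature, transcripts, mirna_id=mid, max_score=max_score):
            called = call_cleavage(aln, tplots[aln.transcript_id], window=window)
            if called is None:
                continue
            pos, count = called
            hits.append(
                TargetHit(
                    alignment=aln,
                    cleavage_count=count,
                    category=categorize(count, tplots[aln.transcript_id]),
                    offset=pos - aln.cleavage_pos,
                )
            )
    hits.sort(key=lambda h: (h.category, -h.cleavage_count, h.alignment.mirna_id,
                             h.alignment.transcript_id, h.alignment.start))
    return hits


def write_hits_tsv(path: PathLike, hits: Sequence[TargetHit], tplots: Mapping[str, TPlot]) -> None:
    with atomic_write(path) as fh:
        fh.write("miRNA\ttranscript\tscore\tcleavage_pos\toffset\tcount\ttranscript_max\tcategory\n")
        for h in hits:
            a = h.alignment
            fh.write(
                f"{a.mirna_id}\t{a.transcript_id}\t{a.score:.1f}\t{a.cleavage_pos + h.offset}\t"
                f"{h.offset}\t{h.cleavage_count}\t{tplots[a.transcript_id].max_count}\t{h.category}\n"
            )


def write_tplot_tsv(path: PathLike, tplot: TPlot) -> None:
    with atomic_write(path) as fh:
        fh.write("position\tcount\n")
        for i, c in enumerate(tplot.counts, start=1):
            if c:
                fh.write(f"{i}\t{int(c)}\n")


def plot_tplot(tplot: TPlot, path: PathLike, highlight: Optional[int] = None) -> None:
    """Optional matplotlib rendering of a t-plot (requires the plot extra)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.vlines(np.arange(1, tplot.counts.size + 1), 0, tplot.counts, color="grey")
    if highlight is not None:
        ax.vlines([highlight], 0, tplot.counts[highlight - 1], color="red")
    ax.set_xlabel("transcript position (nt)")
    ax.set_ylabel("degradome 5' ends")
    ax.set_title(tplot.transcript_id)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
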