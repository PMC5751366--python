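"""Raw-read cleaning, collapsing to unique tags, and library statistics.

The cleaning cascade mirrors standard small-RNA practice: 3' adapter removal,
junk-read removal, exact-match contaminant (rRNA/tRNA/snRNA/snoRNA-like)
filtering, an 18-25 nt length window, then collapsing survivors to unique
tags with per-library counts.  Each raw read lands in exactly one category,
so per-library accounting is conservative:

    raw = retained + adapter_rejected + junk + contaminant + length_rejected

"Clean reads" are the reads surviving adapter and junk removal (the
denominator for the length histogram and the in-range fraction, as such
libraries are conventionally summarized); contaminant and length filtering
then select the tags that enter the table.

Contaminant matching is an exact substring lookup against the provided set,
not an alignment: deterministic, and sufficient when contaminants are known
sequences.  The junk rule (any single base >= 80% of the read, or any
non-ACGT/U symbol) is the standard convention.  Tags are stored as RNA (U);
the low-quality filter drops FASTQ reads with mean Phred quality < 20 and is
a no-op for FASTA input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._seq import to_dna, to_rna
from .io import PathLike, atomic_write, write_json

__all__ = [
    "UniqueTagTable",
    "LibraryStats",
    "trim_adapter",
    "filter_and_collapse",
    "run_preprocess",
    "first_nucleotide_bias",
    "write_tag_fasta",
    "read_tag_fasta",
    "write_stats",
]

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 25
JUNK_BASE_FRACTION = 0.8


@dataclass
class LibraryStats:
    """Per-library cleaning statistics."""

    raw_reads: int = 0
    adapter_rejected: int = 0
    junk_reads: int = 0
    low_quality: int = 0
    clean_reads: int = 0  # raw - adapter_rejected - junk - low_quality
    contaminant_reads: int = 0
    length_rejected: int = 0
    retained_reads: int = 0  # reads collapsed into the tag table
    length_histogram: Dict[int, int] = field(default_factory=dict)  # 18..25, clean reads
    fraction_in_range: float = 0.0

    def conservation_holds(self) -> bool:
        return (
            self.raw_reads
            == self.retained_reads
            + self.adapter_rejected
            + self.junk_reads
            + self.low_quality
            + self.contaminant_reads
            + self.length_rejected
        )

    def as_dict(self) -> Dict[str, object]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class UniqueTagTable:
    """Collapsed unique tags (RNA strings) with per-library raw counts."""

    counts: pd.DataFrame  # index: tag, columns: library names, int counts
    library_totals: Dict[str, int]  # clean-read counts per library

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative tag counts")
        if any(len(t) < 1 for t in self.counts.index):
            raise ValueError("empty tag")
        if not self.counts.index.is_unique:
            raise ValueError("tags must be unique")

    @property
    def libraries(self) -> List[str]:
        return list(self.counts.columns)

    def total(self, library: str) -> int:
        return int(self.counts[library].sum())


def trim_adapter(read: str, adapter: str, min_overlap: int = 6) -> Tuple[str, bool]:
    """Remove the longest read suffix that exactly matches an adapter prefix.

    Returns ``(trimmed_read, adapter_found)``; reads without an adapter
    overlap of at least ``min_overlap`` come back unchanged and flagged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read_u, adapter_u = read.upper(), adapter.upper()
    for k in range(min(len(read_u), len(adapter_u)), min_overlap - 1, -1):
        if read_u.endswith(adapter_u[:k]):
            return read[: len(read) - k], True
    return read, False


def _is_junk(read: str) -> bool:
    n = len(read)
    if n == 0:
        return False
    if any(c not in "ACGTU" for c in read):
        return True
    return max(read.count(b) for b in "ACGTU") >= JUNK_BASE_FRACTION * n


def _mean_quality(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def filter_and_collapse(
    reads: Mapping[str, Sequence[str]],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    contaminants: Iterable[str] = (),
    qualities: Optional[Mapping[str, Sequence[str]]] = None,
    min_mean_quality: float = 20.0,
) -> Tuple[UniqueTagTable, Dict[str, LibraryStats]]:
    """Filter adapter-trimmed reads and collapse survivors to unique tags.

    ``reads`` maps library name -> trimmed read sequences.  ``qualities``
    optionally carries parallel FASTQ quality strings (the placeholder
    low-quality filter).  Returns the tag table (RNA tags) and per-library
    statistics; ``raw_reads``/``adapter_rejected`` of the stats cover only
    what this function saw (use :func:`run_preprocess` for full accounting).
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    contam_blob = "#" + "#".join(to_dna(c) for c in contaminants) + "#" if contaminants else ""
    libraries = list(reads)
    counters: Dict[str, Counter] = {lib: Counter() for lib in libraries}
    stats: Dict[str, LibraryStats] = {}
    contaminant_cache: Dict[str, bool] = {}
    for lib in libraries:
        st = LibraryStats(raw_reads=len(reads[lib]))
        hist: Counter = Counter()
        quals = qualities.get(lib) if qualities else None
        counter = counters[lib]
        for idx, read in enumerate(reads[lib]):
            if quals is not None and _mean_quality(quals[idx]) < min_mean_quality:
                st.low_quality += 1
                continue
            up = read.upper()
            if _is_junk(up):
                st.junk_reads += 1
                continue
            st.clean_reads += 1
            if DEFAULT_MIN_LEN <= len(up) <= DEFAULT_MAX_LEN:
                hist[len(up)] += 1
            if contam_blob:
                hit = contaminant_cache.get(up)
                if hit is None:
                    hit = to_dna(up) in contam_blob
                    contaminant_cache[up] = hit
                if hit:
                    st.contaminant_reads += 1
                    continue
            if not min_len <= len(up) <= max_len:
                st.length_rejected += 1
                continue
            counter[to_rna(up)] += 1
        st.retained_reads = sum(counter.values())
        st.length_histogram = {k: hist.get(k, 0) for k in range(DEFAULT_MIN_LEN, DEFAULT_MAX_LEN + 1)}
        st.fraction_in_range = (
            sum(st.length_histogram.values()) / st.clean_reads if st.clean_reads else 0.0
        )
        stats[lib] = st
    all_tags = sorted(set().union(*(c.keys() for c in counters.values())) if counters else [])
    counts = pd.DataFrame(
        {lib: [counters[lib].get(t, 0) for t in all_tags] for lib in libraries},
        index=pd.Index(all_tags, name="tag"),
        dtype=np.int64,
    )
    totals = {lib: stats[lib].clean_reads for lib in libraries}
    return UniqueTagTable(counts, totals), stats


def run_preprocess(
    raw_reads: Mapping[str, Sequence[str]],
    adapter: str,
    min_overlap: int = 6,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    contaminants: Iterable[str] = (),
    qualities: Optional[Mapping[str, Sequence[str]]] = None,
) -> Tuple[UniqueTagTable, Dict[str, LibraryStats]]:
    """Full cleaning cascade from raw adapter-bearing reads to a tag table."""
    trimmed: Dict[str, List[str]] = {}
    trimmed_quals: Optional[Dict[str, List[str]]] = {} if qualities else None
    rejected: Dict[str, int] = {}
    for lib, lib_reads in raw_reads.items():
        kept: List[str] = []
        kept_quals: List[str] = []
        n_rej = 0
        quals = qualities.get(lib) if qualities else None
        for idx, read in enumerate(lib_reads):
            insert, found = trim_adapter(read, adapter, min_overlap)
            if not found:
                n_rej += 1
                continue
            kept.append(insert)
            if quals is not None:
                kept_quals.append(quals[idx][: len(insert)])
        trimmed[lib] = kept
        rejected[lib] = n_rej
        if trimmed_quals is not None:
            trimmed_quals[lib] = kept_quals
    table, stats = filter_and_collapse(
        trimmed, min_len, max_len, contaminants, qualities=trimmed_quals
    )
    for lib, st in stats.items():
        st.adapter_rejected = rejected[lib]
        st.raw_reads += rejected[lib]
    return table, stats


def first_nucleotide_bias(table: UniqueTagTable, max_position: int = 25) -> pd.DataFrame:
    """Count-weighted base frequencies at tag positions 1..max_position.

    Positions beyond a tag's length contribute nothing; each row with any
    coverage sums to 1 over A/C/G/U.
    """
    if table.counts.empty:
        raise ValueError("empty tag table")
    weights = table.counts.sum(axis=1).to_numpy()
    freq = np.zeros((max_position, 4))
    base_index = {b: k for k, b in enumerate("ACGU")}
    for tag, w in zip(table.counts.index, weights):
        for pos, base in enumerate(tag[:max_position]):
            freq[pos, base_index[base]] += w
    row_tot = freq.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(row_tot > 0, freq / row_tot, 0.0)
    return pd.DataFrame(freq, index=pd.RangeIndex(1, max_position + 1, name="position"),
                        columns=list("ACGU"))


def write_tag_fasta(path: PathLike, table: UniqueTagTable) -> None:
    """Collapsed tags as FASTA with ``tag<N>_x<count_WF>_y<count_BF>`` headers."""
    libs = table.libraries
    with atomic_write(path) as fh:
        for n, tag in enumerate(table.counts.index, start=1):
            row = table.counts.loc[tag]
            parts = [f"tag{n}"] + [
                f"{axis}{int(row[lib])}" for axis, lib in zip("xyzuvw", libs)
            ]
            fh.write(f">{'_'.join(parts)}\n{tag}\n")


def read_tag_fasta(path: PathLike, libraries: Sequence[str]) -> UniqueTagTable:
    """Inverse of :func:`write_tag_fasta` (library totals = column sums)."""
    tags: List[str] = []
    rows: List[List[int]] = []
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                header = line[1:]
            elif line:
                parts = header.split("_")
                rows.append([int(p[1:]) for p in parts[1 : 1 + len(libraries)]])
                tags.append(to_rna(line))
    counts = pd.DataFrame(rows, index=pd.Index(tags, name="tag"), columns=list(libraries))
    totals = {lib: int(counts[lib].sum()) for lib in libraries}
    return UniqueTagTable(counts, totals)


def write_stats(path_tsv: PathLike, path_json: PathLike, stats: Mapping[str, LibraryStats]) -> None:
    df = pd.DataFrame({lib: st.as_dict() for lib, st in stats.items()})
    with atomic_write(path_tsv) as fh:
        df.to_csv(fh, sep="\t")
    write_json(path_json, {lib: st.as_dict() for lib, st in stats.items()})
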