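"""File I/O: FASTA/FASTQ via Biopython, GFF3, flat config files, atomic writes."""

from __future__ import annotations

import json
import os
import tempfile
from contextlib import contextmanager
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

PathLike = Union[str, Path]


@contextmanager
def atomic_write(path: PathLike, mode: str = "w") -> Iterator:
    """Write to a temporary file and rename into place on success.

    Interrupted runs never leave truncated output files behind.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        os.unlink(tmp)
        raise


def read_fasta(path: PathLike) -> Dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: PathLike, records: Mapping[str, str]) -> None:
    with atomic_write(path) as fh:
        SeqIO.write(
            (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
            fh,
            "fasta",
        )


def read_reads(path: PathLike) -> List[str]:
    """Read sequences from FASTQ or FASTA (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".fq", ".fastq"):
        with open(path) as fh:
            return [seq for _, seq, _ in FastqGeneralIterator(fh)]
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(path: PathLike, reads: Sequence[str], prefix: str = "read", quality: str = "I") -> None:
    """Write reads with a fixed placeholder quality symbol."""
    with atomic_write(path) as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i + 1}\n{seq}\n+\n{quality * len(seq)}\n")


GffFeature = Tuple[str, str, int, int, str, Mapping[str, str]]  # seqid, type, start, end, strand, attrs


def write_gff3(path: PathLike, features: Iterable[GffFeature], source: str = "berrymir") -> None:
    """1-based inclusive coordinates, as in the GFF3 specification."""
    with atomic_write(path) as fh:
        fh.write("##gff-version 3\n")
        for seqid, ftype, start, end, strand, attrs in features:
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t{attr_s}\n")


def write_json(path: PathLike, obj) -> None:
    with atomic_write(path) as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_flat_config(path: PathLike, values: Mapping[str, object]) -> None:
    """Flat ``key = value`` file; lists are comma-separated."""
    with atomic_write(path) as fh:
        for key, value in values.items():
            if isinstance(value, (list, tuple)):
                value = ",".join(str(v) for v in value)
            elif isinstance(value, dict):
                value = ",".join(f"{k}:{v}" for k, v in value.items())
            fh.write(f"{key} = {value}\n")


def read_flat_config(path: PathLike) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out
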