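"""Stage orchestration: simulate -> preprocess -> discover -> de -> degradome.

Each stage reads its inputs from disk and writes its outputs to the run
directory, so any stage can be re-run from its predecessor's outputs.  All
table/report writes are atomic (write-then-rename).  A stage failure leaves
partial outputs in place together with a ``FAILED.<stage>`` marker file.
"""

from __future__ import annotations

import json
import time
import sys
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Dict, List, Optional

from . import degradome as dg
from . import discovery, expression, preprocess, synthdata
from .io import (
    atomic_write,
    read_fasta,
    read_flat_config,
    read_reads,
    write_fasta,
    write_fastq,
    write_flat_config,
    write_gff3,
    write_json,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_simulate", "stage_preprocess",
           "stage_discover", "stage_de", "stage_degradome"]

_LIBS = ("WF", "BF")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    Input paths default to the simulate stage's outputs inside ``outdir``,
    so ``run_pipeline`` on a fresh directory simulates and analyses a
    complete synthetic dataset.
    """

    outdir: str = "berrymir-run"
    # inputs (empty string -> the simulate-stage default under outdir)
    reads_wf: str = ""
    reads_bf: str = ""
    scaffolds: str = ""
    mature_reference: str = ""
    contaminants: str = ""
    transcripts: str = ""
    degradome_tags: str = ""
    # thresholds
    min_tag_length: int = 18
    max_tag_length: int = 25
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_adapter_overlap: int = 6
    min_tag_count: int = 2
    mfei_threshold: float = discovery.MFEI_THRESHOLD
    max_flank: int = 250
    fc_up: float = 2.0
    fc_down: float = 0.5
    alpha: float = 0.05
    target_score: float = dg.MAX_TARGET_SCORE
    cleavage_window: int = 1
    seed: int = 1
    simulate: bool = True
    # simulate-stage scale (defaults are the reference study conditions)
    sim_n_scaffolds: int = 3
    sim_scaffold_length: int = 50_000
    sim_n_loci: int = 30
    sim_library_size: int = 200_000
    sim_n_transcripts: int = 20

    def __post_init__(self) -> None:
        if self.min_tag_length > self.max_tag_length:
            raise ValueError("min_tag_length > max_tag_length")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.fc_up <= 1 or not 0 < self.fc_down < 1:
            raise ValueError("fold-change thresholds out of range")
        out = Path(self.outdir)
        defaults = {
            "reads_wf": out / "reads_WF.fastq",
            "reads_bf": out / "reads_BF.fastq",
            "scaffolds": out / "scaffolds.fasta",
            "mature_reference": out / "mature_reference.fasta",
            "contaminants": out / "contaminants.fasta",
            "transcripts": out / "transcripts.fasta",
            "degradome_tags": out / "degradome.fasta",
        }
        for key, default in defaults.items():
            if not getattr(self, key):
                setattr(self, key, str(default))

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        raw = read_flat_config(path)
        kwargs = {}
        for f in fields(cls):
            if f.name in raw:
                value = raw[f.name]
                if f.type in ("int", int):
                    value = int(value)
                elif f.type in ("float", float):
                    value = float(value)
                elif f.type in ("bool", bool):
                    value = value.lower() in ("1", "true", "yes")
                kwargs[f.name] = value
        return cls(**kwargs)

    def to_file(self, path: str) -> None:
        write_flat_config(path, {f.name: getattr(self, f.name) for f in fields(self)})


def _log(msg: str) -> None:
    print(f"[berrymir] {msg}", file=sys.stderr)


def stage_simulate(config: PipelineConfig) -> synthdata.SyntheticTruth:
    """Generate the synthetic dataset and write every pipeline input."""
    out = Path(config.outdir)
    scfg = synthdata.SyntheticConfig(
        seed=config.seed,
        n_scaffolds=config.sim_n_scaffolds,
        scaffold_length=config.sim_scaffold_length,
        n_mirna_loci=config.sim_n_loci,
        library_sizes={"WF": config.sim_library_size, "BF": config.sim_library_size},
        n_target_transcripts=config.sim_n_transcripts,
        adapter=config.adapter,
    )
    truth = synthdata.generate_truth(scfg)
    write_fasta(config.scaffolds, truth.scaffolds)
    write_fasta(config.mature_reference, truth.mature_reference)
    write_fasta(config.contaminants, truth.contaminants)
    write_fasta(config.transcripts, truth.transcripts)
    for cond, path in (("WF", config.reads_wf), ("BF", config.reads_bf)):
        write_fastq(path, synthdata.simulate_sra_library(truth, cond), prefix=f"{cond}_")
    write_fasta(
        config.degradome_tags,
        {f"dtag{i + 1}": t for i, t in enumerate(synthdata.simulate_degradome(truth))},
    )
    write_gff3(
        out / "planted_loci.gff3",
        [
            (l.scaffold, "miRNA_primary_transcript", l.start, l.end, l.strand,
             {"ID": l.locus_id, "arm": l.arm, "known": str(l.known).lower()})
            for l in truth.loci
        ],
    )
    with atomic_write(out / "truth.tsv") as fh:
        fh.write("locus_id\tscaffold\tstart\tend\tstrand\tmature\tstar\tarm\t"
                 "mature_start\tmature_end\tn_duplex_mismatches\tknown\t"
                 "expected_wf\texpected_bf\tfold_change\n")
        for l in truth.loci:
            fh.write(
                f"{l.locus_id}\t{l.scaffold}\t{l.start}\t{l.end}\t{l.strand}\t{l.mature}\t"
                f"{l.star}\t{l.arm}\t{l.mature_start}\t{l.mature_end}\t{l.n_duplex_mismatches}\t"
                f"{l.known}\t{l.expected_counts['WF']:.2f}\t{l.expected_counts['BF']:.2f}\t"
                f"{l.fold_change}\n"
            )
    with atomic_write(out / "truth_sites.tsv") as fh:
        fh.write("transcript_id\tmirna_id\tmature\tsite_start\tsite_end\tcleavage_pos\n")
        for s in truth.target_sites:
            fh.write(f"{s.transcript_id}\t{s.mirna_id}\t{s.mature}\t{s.site_start}\t"
                     f"{s.site_end}\t{s.cleavage_pos}\n")
    write_flat_config(out / "synthetic_config.txt", {
        "seed": scfg.seed, "n_scaffolds": scfg.n_scaffolds,
        "scaffold_length": scfg.scaffold_length, "n_mirna_loci": scfg.n_mirna_loci,
        "library_sizes": scfg.library_sizes, "adapter": scfg.adapter,
        "contaminant_fraction": scfg.contaminant_fraction,
        "background_fraction": scfg.background_fraction,
        "degradome_peak_fraction": scfg.degradome_peak_fraction,
    })
    return truth


def stage_preprocess(config: PipelineConfig) -> preprocess.UniqueTagTable:
    out = Path(config.outdir)
    raw = {"WF": read_reads(config.reads_wf), "BF": read_reads(config.reads_bf)}
    contaminants = read_fasta(config.contaminants) if Path(config.contaminants).exists() else {}
    table, stats = preprocess.run_preprocess(
        raw, config.adapter, config.min_adapter_overlap,
        config.min_tag_length, config.max_tag_length, contaminants.values(),
    )
    preprocess.write_tag_fasta(out / "tags.fasta", table)
    preprocess.write_stats(out / "library_stats.tsv", out / "library_stats.json", stats)
    return table


def stage_discover(config: PipelineConfig) -> List[discovery.MirnaRecord]:
    out = Path(config.outdir)
    table = preprocess.read_tag_fasta(out / "tags.fasta", _LIBS)
    totals = {
        lib: stats["clean_reads"]
        for lib, stats in json.loads((out / "library_stats.json").read_text()).items()
    }
    table.library_totals = totals
    scaffolds = read_fasta(config.scaffolds)
    mature_ref = (
        read_fasta(config.mature_reference) if Path(config.mature_reference).exists() else {}
    )
    records = discovery.catalog_mirnas(
        table, scaffolds, mature_ref,
        min_count=config.min_tag_count,
        mfei_threshold=config.mfei_threshold,
        max_flank=config.max_flank,
    )
    discovery.write_catalog_tsv(out / "catalog.tsv", records, _LIBS)
    write_fasta(out / "precursors.fasta",
                {r.mirna_id: discovery.to_dna(_precursor_seq(r, scaffolds)) for r in records})
    with atomic_write(out / "structures.txt") as fh:
        for r in records:
            fh.write(f">{r.mirna_id}\n{_precursor_seq(r, scaffolds)}\n{r.structure}\n")
    write_gff3(
        out / "catalog.gff3",
        [
            (r.accession, "miRNA", r.mature_start, r.mature_end, r.strand,
             {"ID": r.mirna_id, "status": r.status, "arm": r.arm})
            for r in records
        ],
    )
    return records


def _precursor_seq(record: discovery.MirnaRecord, scaffolds: Dict[str, str]) -> str:
    seg = scaffolds[record.accession][record.start - 1 : record.end]
    if record.strand == "-":
        seg = discovery.revcomp_dna(seg)
    return discovery.to_rna(seg)


def stage_de(config: PipelineConfig,
             records: Optional[List[discovery.MirnaRecord]] = None) -> List[expression.ExpressionRecord]:
    out = Path(config.outdir)
    if records is None:
        records = _read_catalog(out / "catalog.tsv")
    totals = {
        lib: stats["clean_reads"]
        for lib, stats in json.loads((out / "library_stats.json").read_text()).items()
    }
    raw_counts = {r.mirna_id: (r.raw_counts["WF"], r.raw_counts["BF"]) for r in records}
    exprs = expression.build_expression_table(
        raw_counts, totals["WF"], totals["BF"],
        fc_up=config.fc_up, fc_down=config.fc_down, alpha=config.alpha,
    )
    expression.write_de_tsv(out / "differential_expression.tsv", exprs, de_only=False)
    expression.write_de_tsv(out / "differential_expression.de.tsv", exprs, de_only=True)
    return exprs


def _read_catalog(path: Path) -> List[discovery.MirnaRecord]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        known = not str(row["HOMO/NM"]).isdigit()
        records.append(
            discovery.MirnaRecord(
                mirna_id=row["ID"], mature=row["sequence"], length=int(row["LT"]),
                arm="5p" if row["TP"] == "5'" else "3p",
                accession=row["Accession"], strand=row["Str"],
                start=int(row["Start"]), end=int(row["End"]),
                mature_start=int(row["MatStart"]), mature_end=int(row["MatEnd"]),
                homolog=row["HOMO/NM"] if known else None,
                star_mismatches=None if known else int(row["HOMO/NM"]),
                mfei_value=float(row["MFEI"]),
                status="known" if known else "novel",
                raw_counts={lib: int(row[f"{lib}(raw)"]) for lib in _LIBS},
                norm_abundance={lib: float(row[f"{lib}(norm)"]) for lib in _LIBS},
            )
        )
    return records


def stage_degradome(config: PipelineConfig,
                    records: Optional[List[discovery.MirnaRecord]] = None):
    out = Path(config.outdir)
    if not Path(config.degradome_tags).exists() or not Path(config.transcripts).exists():
        return None
    tags = read_reads(config.degradome_tags)
    if not tags:
        return None
    if records is None:
        records = _read_catalog(out / "catalog.tsv")
    transcripts = read_fasta(config.transcripts)
    matures = {r.mirna_id: r.mature for r in records if r.length >= 19}
    hits = dg.find_targets(
        matures, transcripts, tags,
        max_score=config.target_score, window=config.cleavage_window,
    )
    tplots = dg.build_tplots(tags, transcripts)
    dg.write_hits_tsv(out / "target_hits.tsv", hits, tplots)
    tdir = out / "tplots"
    tdir.mkdir(exist_ok=True)
    for tid, tp in tplots.items():
        dg.write_tplot_tsv(tdir / f"{tid}.tsv", tp)
    return hits


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Run all stages in order; returns (and writes) the summary."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.simulate:
        missing = [p for p in (config.reads_wf, config.reads_bf, config.scaffolds)
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")
    summary: Dict[str, object] = {"seed": config.seed}
    stages = [("simulate", stage_simulate)] if config.simulate else []
    stages += [("preprocess", stage_preprocess), ("discover", stage_discover)]
    results: Dict[str, object] = {}
    for name, fn in stages + [("de", stage_de), ("degradome", stage_degradome)]:
        t0 = time.monotonic()
        try:
            if name == "de":
                results[name] = stage_de(config, results.get("discover"))
            elif name == "degradome":
                results[name] = stage_degradome(config, results.get("discover"))
            else:
                results[name] = fn(config)
        except BaseException:
            (out / f"FAILED.{name}").touch()
            raise
        _log(f"stage {name} finished in {time.monotonic() - t0:.1f}s")
    records = results["discover"]
    exprs = results["de"]
    hits = results["degradome"]
    summary["mirnas_total"] = len(records)
    summary["mirnas_known"] = sum(1 for r in records if r.status == "known")
    summary["mirnas_novel"] = sum(1 for r in records if r.status == "novel")
    summary["de_up"] = sum(1 for e in exprs if e.direction == "up")
    summary["de_down"] = sum(1 for e in exprs if e.direction == "down")
    if hits is None:
        summary["degradome"] = "not run"
    else:
        summary["target_hits_total"] = len(hits)
        for cat in range(5):
            summary[f"target_hits_category_{cat}"] = sum(1 for h in hits if h.category == cat)
    write_json(out / "summary.json", summary)
    return summary
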