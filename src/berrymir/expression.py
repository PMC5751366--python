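"""Two-library differential expression: normalization, fold change, Fisher test.

Counts are normalized to reads-per-million of clean reads (fold changes are
scale-invariant to the denominator choice, which is configurable in the
pipeline).  miRNAs with normalized counts below 1 in both libraries are
removed.  Differential expression between the ripe (BF) and onset (WF)
libraries requires |log2(BF/WF)| >= 1 together with a two-sided Fisher exact
p-value <= 0.05; significance labels are ** for p <= 0.01 and * for
0.01 < p <= 0.05.  A fold change against a zero WF abundance is reported as
infinity (no pseudo-counts).

The Fisher test uses the point-probability method: the two-sided p-value
sums hypergeometric probabilities of all tables at least as extreme
(probability <= that of the observed table, with a 1+1e-7 relative slack for
floating-point ties).  No multiple-testing correction is applied in the
significance calls; a Benjamini-Hochberg column is emitted alongside for
users, clearly marked as an extension of the two-library protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .io import PathLike, atomic_write

__all__ = [
    "ExpressionRecord",
    "normalize",
    "low_abundance_filter",
    "fold_change",
    "fisher_test",
    "classify_de",
    "sig_label",
    "build_expression_table",
    "write_de_tsv",
]

_TIE_SLACK = 1.0 + 1e-7


@dataclass
class ExpressionRecord:
    """Per-miRNA differential-expression summary between WF and BF."""

    mirna_id: str
    raw_wf: int
    raw_bf: int
    norm_wf: float
    norm_bf: float
    fold_change: float = math.nan  # BF/WF; may be +inf
    log2_fold_change: float = math.nan
    p_value: float = math.nan
    label: str = "ns"  # "**" | "*" | "ns"
    direction: str = "ns"  # "up" | "down" | "ns"
    bh_q: Optional[float] = None  # Benjamini-Hochberg adjusted p (extension)


def normalize(raw_count: float, library_total: int) -> float:
    """Per-million abundance: raw * 1e6 / library total."""
    if library_total <= 0:
        raise ValueError("library total must be positive")
    return raw_count * 1e6 / library_total


def low_abundance_filter(records: Sequence[ExpressionRecord]) -> List[ExpressionRecord]:
    """Drop records with normalized counts < 1 in *both* libraries."""
    return [r for r in records if not (r.norm_wf < 1.0 and r.norm_bf < 1.0)]


def fold_change(bf_norm: float, wf_norm: float) -> Tuple[float, float]:
    """(BF/WF ratio, log2 ratio); +inf when WF is zero; error when both zero."""
    if bf_norm == 0.0 and wf_norm == 0.0:
        raise ValueError("fold change undefined when both abundances are zero")
    if wf_norm == 0.0:
        return math.inf, math.inf
    ratio = bf_norm / wf_norm
    return ratio, math.log2(ratio)


def fisher_test(wf_count: int, bf_count: int, wf_total: int, bf_total: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table

        [[bf_count, bf_total - bf_count],
         [wf_count, wf_total - wf_count]]

    computed by summing hypergeometric point probabilities <= that of the
    observed table.
    """
    if min(wf_count, bf_count) < 0:
        raise ValueError("negative counts")
    if wf_count > wf_total or bf_count > bf_total or min(wf_total, bf_total) <= 0:
        raise ValueError("counts must not exceed positive totals")
    N = wf_total + bf_total
    K = wf_count + bf_count  # total successes
    n = bf_total  # draws attributed to the BF margin
    support = np.arange(max(0, K - (N - n)), min(K, n) + 1)
    pmf = sps.hypergeom.pmf(support, N, K, n)
    p_obs = sps.hypergeom.pmf(bf_count, N, K, n)
    return float(min(1.0, pmf[pmf <= p_obs * _TIE_SLACK].sum()))


def sig_label(p_value: float) -> str:
    if p_value <= 0.01:
        return "**"
    if p_value <= 0.05:
        return "*"
    return "ns"


def classify_de(
    fc: float,
    p_value: float,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
) -> str:
    """'up' / 'down' / 'ns' by fold change and significance.

    Implemented on the |log2 FC| >= 1 form (with default thresholds this is
    the same criterion as FC > 2 or < 0.5 except at exactly 2-fold, where the
    log form is used).
    """
    if p_value > alpha or math.isnan(fc):
        return "ns"
    if fc == math.inf or fc >= fc_up:
        return "up"
    if fc <= fc_down:
        return "down"
    return "ns"


def build_expression_table(
    raw_counts: Mapping[str, Tuple[int, int]],
    wf_total: int,
    bf_total: int,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    alpha: float = 0.05,
    apply_low_abundance_filter: bool = True,
) -> List[ExpressionRecord]:
    """Full DE table from per-miRNA (WF, BF) raw counts and library totals."""
    records: List[ExpressionRecord] = []
    for mid, (wf, bf) in raw_counts.items():
        records.append(
            ExpressionRecord(
                mirna_id=mid,
                raw_wf=int(wf),
                raw_bf=int(bf),
                norm_wf=normalize(wf, wf_total),
                norm_bf=normalize(bf, bf_total),
            )
        )
    if apply_low_abundance_filter:
        records = low_abundance_filter(records)
    for rec in records:
        rec.fold_change, rec.log2_fold_change = fold_change(rec.norm_bf, rec.norm_wf)
        rec.p_value = fisher_test(rec.raw_wf, rec.raw_bf, wf_total, bf_total)
        rec.label = sig_label(rec.p_value)
        rec.direction = classify_de(rec.fold_change, rec.p_value, fc_up, fc_down, alpha)
    if records:
        pvals = np.array([r.p_value for r in records])
        qvals = sps.false_discovery_control(pvals, method="bh")
        for rec, q in zip(records, qvals):
            rec.bh_q = float(q)
    return records


def _fmt(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return f"{x:.2f}"


def write_de_tsv(path: PathLike, records: Sequence[ExpressionRecord], de_only: bool = True) -> None:
    """DE report: miRNA, BF(norm), WF(norm), FC, log2 FC, p, label, direction.

    Values at 2 decimals with an 'inf' literal for infinite entries; the BH
    column is an extension beyond the two-library protocol.
    """
    rows = [r for r in records if r.direction != "ns"] if de_only else list(records)
    with atomic_write(path) as fh:
        fh.write(
            "miRNA\tBF(norm)\tWF(norm)\tFold Change\tlog2(Fold Change)\t"
            "p-Value (Fisher Test)\tSig-Label\tUp/Down\tBH-q (extension)\n"
        )
        for r in rows:
            fh.write(
                f"{r.mirna_id}\t{r.norm_bf:.2f}\t{r.norm_wf:.2f}\t{_fmt(r.fold_change)}\t"
                f"{_fmt(r.log2_fold_change)}\t{r.p_value:.3g}\t{r.label}\t{r.direction}\t"
                f"{r.bh_q:.3g}\n"
            )
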