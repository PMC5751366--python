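"""Packaged catalog tables and the statistics derivable from them.

Two machine-readable tables ship with the package as a permanent regression
surface for the catalog-level statistics of a two-library blueberry fruit
miRNA study:

* ``table1.tsv`` - the full miRNA catalog: 100 rows (84 known + 16 novel)
  with mature sequence, length (LT), arm (TP), precursor scaffold accession,
  strand, precursor span, closest homolog or star-mismatch count (HOMO/NM),
  MFEI and normalized abundances in the BF (ripe) and WF (ripening-onset)
  libraries.
* ``table2.tsv`` - the 41 differentially expressed miRNAs with normalized
  abundances, fold change, log2 fold change, Fisher p-value, significance
  label and direction.

Values are stored as printed (minus signs, thousands separators and
scientific notation normalized to machine forms; "inf" kept as a literal the
loader converts to ``math.inf``).  The loaders verify a SHA-256 checksum,
row counts and column types on load.
"""

from __future__ import annotations

import hashlib
import re
from importlib import resources
from typing import Dict, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "load_table1",
    "load_table2",
    "presence_counts",
    "novel_set_stats",
    "family_census",
    "family_of",
    "is_novel",
]

_CHECKSUMS = {
    "table1.tsv": "822762119c621b3b3c3c6016273ee9b56c1c67935487c169fc1e94f4be550626",
    "table2.tsv": "ec95974a16b8180f2d592f9659d831ef66c8a5f0383abe30fe2e9d04703e7cf3",
}


def _read(name: str) -> pd.DataFrame:
    raw = resources.files("berrymir.data").joinpath(name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValueError(f"{name} checksum mismatch: {digest}")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), sep="\t")


def is_novel(mirna_id: str) -> bool:
    return "miR_n" in mirna_id


def load_table1() -> pd.DataFrame:
    """The 100-row miRNA catalog (84 known + 16 novel)."""
    df = _read("table1.tsv")
    if len(df) != 100:
        raise ValueError(f"table1 must have 100 rows, got {len(df)}")
    if not (df["LT"] == df["sequence"].str.len()).all():
        raise ValueError("LT column inconsistent with sequence lengths")
    if (df[["bf_norm", "wf_norm"]] < 0).any().any():
        raise ValueError("negative abundances")
    novel = df["ID"].map(is_novel)
    if novel.sum() != 16 or (~novel).sum() != 84:
        raise ValueError("known/novel split must be 84/16")
    return df


def load_table2() -> pd.DataFrame:
    """The 41-row differential-expression table; 'inf' parsed to infinity."""
    df = _read("table2.tsv")
    if len(df) != 41:
        raise ValueError(f"table2 must have 41 rows, got {len(df)}")
    for col in ("fold_change", "log2_fc"):
        df[col] = df[col].replace("inf", np.inf).astype(float)
    if not df["direction"].isin(["up", "down"]).all():
        raise ValueError("directions must be up/down")
    return df


def presence_counts(table1: pd.DataFrame) -> Tuple[int, int, int]:
    """(both, bf_only, wf_only) detection counts over the 84 known rows."""
    known = table1[~table1["ID"].map(is_novel)]
    both = int(((known["wf_norm"] > 0) & (known["bf_norm"] > 0)).sum())
    bf_only = int(((known["wf_norm"] == 0) & (known["bf_norm"] > 0)).sum())
    wf_only = int(((known["bf_norm"] == 0) & (known["wf_norm"] > 0)).sum())
    return both, bf_only, wf_only


def novel_set_stats(table1: pd.DataFrame) -> Dict[str, object]:
    """Length histogram, 5'-U count and mean MFEI of the 16 novel rows."""
    novel = table1[table1["ID"].map(is_novel)]
    if len(novel) != 16:
        raise ValueError("expected 16 novel rows")
    hist = {
        L: int((novel["LT"] == L).sum()) for L in range(19, 25)
    }
    five_prime_u = int(novel["sequence"].str.upper().str.startswith(("U", "T")).sum())
    return {
        "length_histogram": hist,
        "fraction_21nt": hist[21] / len(novel),
        "five_prime_u_count": five_prime_u,
        "mean_mfei": float(novel["mfei"].mean()),
    }


_FAMILY_RE = re.compile(r"miR(\d+)")


def family_of(mirna_id: str) -> str:
    """Family label from a catalog ID: strip the species prefix and letter/arm
    suffixes; miR156 and miR157 are counted as one family."""
    m = _FAMILY_RE.search(mirna_id)
    if not m:
        raise ValueError(f"unparseable miRNA id: {mirna_id}")
    num = m.group(1)
    if num in ("156", "157"):
        return "miR156/157"
    return f"miR{num}"


def family_census(table1: pd.DataFrame) -> Dict[str, int]:
    """Family -> member count over the known rows."""
    known = table1[~table1["ID"].map(is_novel)]
    census: Dict[str, int] = {}
    for mid in known["ID"]:
        fam = family_of(mid)
        census[fam] = census.get(fam, 0) + 1
    return census
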