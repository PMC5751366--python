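"""RNA secondary-structure prediction with a light-weight stacking energy model.

The hairpin screen needs a folder that returns a dot-bracket structure and an
energy score so that MFE / AMFE / MFEI statistics can be computed for
precursor candidates.  This module implements a self-contained
nearest-neighbour-lite model:

* a stack of two adjacent pairs contributes the mean of the two pair
  strengths (GC/CG -3.0, AU/UA -2.0, GU/UG -1.0 kcal/mol-scale);
* every hairpin loop costs +4.0 and every internal loop or bulge +2.0;
* multibranch loops and unpaired external bases are free;
* hairpin loops span at least 3 nt, internal loops/bulges at most 30
  unpaired nt, and pseudoknots are disallowed.

The minimum-energy structure under this model is found exactly by a
Zuker-style dynamic program (numba-compiled) with a deterministic traceback
(prefer pairing, then the 5'-most partner).  Energies are multiples of 0.5 and
therefore exact in floating point, which the traceback relies on.

MFEI magnitudes under this model fall in the same regime as thermodynamic
folders (genuine precursors well above the ~0.6 of tRNA/rRNA/mRNA-like
sequences), but MFEI values are only comparable *within* one model.  An
adapter hook (``fold(seq, engine=...)`` / :func:`viennarna_engine`) lets users
substitute a full thermodynamic folder.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from ._seq import encode, to_rna

__all__ = [
    "FoldResult",
    "DuplexRegion",
    "fold",
    "score_structure",
    "gc_percent",
    "duplex_region",
    "pairs_from_dotbracket",
    "viennarna_engine",
    "HAIRPIN_PENALTY",
    "INTERNAL_PENALTY",
    "MIN_HAIRPIN_LOOP",
    "MAX_INTERNAL_LOOP",
]

HAIRPIN_PENALTY = 4.0
INTERNAL_PENALTY = 2.0
MIN_HAIRPIN_LOOP = 3
MAX_INTERNAL_LOOP = 30
_INF = 1e9

# pair strengths; positive sentinel marks an unpairable combination
_PAIR_E = np.full((4, 4), _INF)
_PAIR_E[2, 1] = _PAIR_E[1, 2] = -3.0  # G:C / C:G
_PAIR_E[0, 3] = _PAIR_E[3, 0] = -2.0  # A:U / U:A
_PAIR_E[2, 3] = _PAIR_E[3, 2] = -1.0  # G:U / U:G


@dataclass(frozen=True)
class FoldResult:
    """Minimum-energy structure of one sequence.

    ``pair_table[i]`` is the 0-based partner of position ``i`` or -1.
    """

    sequence: str
    structure: str
    energy: float
    pair_table: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pt = self.pair_table
        for i, j in enumerate(pt):
            if j >= 0 and pt[j] != i:
                raise ValueError("pair table is not involutive")


@dataclass(frozen=True)
class DuplexRegion:
    """Pairing statistics of a mature span inside a folded precursor."""

    star_start: int  # 0-based inclusive; -1 when undefined
    star_end: int
    unpaired_count: int
    has_internal_loop_or_bulge: bool
    defined: bool


@njit(cache=True)
def _fill_tables(s, pair_e):  # pragma: no cover - exercised via fold()
    n = s.shape[0]
    V = np.full((n, n), _INF)
    WM = np.full((n, n), _INF)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            pv = pair_e[s[i], s[j]]
            if pv < 0.0 and span >= MIN_HAIRPIN_LOOP + 1:
                best = HAIRPIN_PENALTY
                # stack on the directly nested pair
                if pair_e[s[i + 1], s[j - 1]] < 0.0 and V[i + 1, j - 1] < _INF / 2:
                    e = (pv + pair_e[s[i + 1], s[j - 1]]) / 2.0 + V[i + 1, j - 1]
                    if e < best:
                        best = e
                # internal loop / bulge around a single nested pair
                kmax = min(i + 2 + MAX_INTERNAL_LOOP, j - MIN_HAIRPIN_LOOP)
                for k in range(i + 1, kmax):
                    gap5 = k - i - 1
                    lmin = max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - (MAX_INTERNAL_LOOP - gap5))
                    for l in range(lmin, j):
                        if gap5 + (j - l - 1) == 0:
                            continue  # that is the stack case
                        if V[k, l] < _INF / 2:
                            e = INTERNAL_PENALTY + V[k, l]
                            if e < best:
                                best = e
                # multibranch: two or more branches in the interior, no penalty
                for m in range(i + 2, j - 1):
                    if WM[i + 1, m] < _INF / 2 and WM[m + 1, j - 1] < _INF / 2:
                        e = WM[i + 1, m] + WM[m + 1, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: minimum over non-empty structures on i..j
            w = V[i, j]
            if WM[i + 1, j] < w:
                w = WM[i + 1, j]
            if WM[i, j - 1] < w:
                w = WM[i, j - 1]
            for m in range(i, j):
                if WM[i, m] < _INF / 2 and WM[m + 1, j] < _INF / 2:
                    e = WM[i, m] + WM[m + 1, j]
                    if e < w:
                        w = e
            WM[i, j] = w
    return V, WM


def _trace(s: np.ndarray, V: np.ndarray, WM: np.ndarray) -> np.ndarray:
    """Deterministic traceback: prefer pairing, then the 5'-most partner."""
    n = s.shape[0]
    pt = np.full(n, -1, dtype=np.int64)

    def wm_or_zero(a: int, b: int) -> float:
        return 0.0 if a > b else min(0.0, WM[a, b])

    def trace_v(i: int, j: int) -> None:
        pt[i], pt[j] = j, i
        e = V[i, j]
        pv = _PAIR_E[s[i], s[j]]
        if _PAIR_E[s[i + 1], s[j - 1]] < 0.0 and V[i + 1, j - 1] < _INF / 2:
            if (pv + _PAIR_E[s[i + 1], s[j - 1]]) / 2.0 + V[i + 1, j - 1] == e:
                trace_v(i + 1, j - 1)
                return
        kmax = min(i + 2 + MAX_INTERNAL_LOOP, j - MIN_HAIRPIN_LOOP)
        for k in range(i + 1, kmax):
            gap5 = k - i - 1
            lmin = max(k + MIN_HAIRPIN_LOOP + 1, j - 1 - (MAX_INTERNAL_LOOP - gap5))
            for l in range(j - 1, lmin - 1, -1):
                if gap5 + (j - l - 1) == 0:
                    continue
                if V[k, l] < _INF / 2 and INTERNAL_PENALTY + V[k, l] == e:
                    trace_v(k, l)
                    return
        for m in range(i + 2, j - 1):
            if WM[i + 1, m] < _INF / 2 and WM[m + 1, j - 1] < _INF / 2:
                if WM[i + 1, m] + WM[m + 1, j - 1] == e:
                    trace_wm(i + 1, m)
                    trace_wm(m + 1, j - 1)
                    return
        # hairpin: nothing further to trace
        assert e == HAIRPIN_PENALTY

    def trace_wm(i: int, j: int) -> None:
        e = WM[i, j]
        if V[i, j] == e:
            trace_v(i, j)
            return
        for m in range(i, j):
            if WM[i, m] < _INF / 2 and WM[m + 1, j] < _INF / 2:
                if WM[i, m] + WM[m + 1, j] == e:
                    trace_wm(i, m)
                    trace_wm(m + 1, j)
                    return
        if WM[i + 1, j] == e:
            trace_wm(i + 1, j)
            return
        assert WM[i, j - 1] == e
        trace_wm(i, j - 1)

    def trace_segment(i: int, j: int, e: float) -> None:
        """External region: left-to-right, pairing i to its 5'-most viable partner."""
        while i <= j:
            if e == 0.0 and wm_or_zero(i, j) == 0.0 and WM[i, j] > 0.0:
                return  # all remaining positions unpaired
            paired = False
            for jp in range(i + MIN_HAIRPIN_LOOP + 1, j + 1):
                if V[i, jp] < _INF / 2 and V[i, jp] + wm_or_zero(jp + 1, j) == e:
                    trace_v(i, jp)
                    e -= V[i, jp]
                    i = jp + 1
                    paired = True
                    break
            if not paired:
                i += 1
        assert e == 0.0

    total = min(0.0, WM[0, n - 1]) if n > 1 else 0.0
    if WM[0, n - 1] <= 0.0:
        trace_segment(0, n - 1, WM[0, n - 1])
    return pt if total <= 0.0 else np.full(n, -1, dtype=np.int64)


def _dotbracket(pt: np.ndarray) -> str:
    out = []
    for i, j in enumerate(pt):
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


def pairs_from_dotbracket(structure: str) -> np.ndarray:
    """Pair table (0-based partners, -1 unpaired) from a dot-bracket string."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket symbol {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


def fold(sequence: str, engine: Optional[Callable[[str], Tuple[str, float]]] = None) -> FoldResult:
    """Fold an RNA sequence into its minimum-energy secondary structure.

    Parameters
    ----------
    sequence:
        RNA string (T is accepted and read as U), length >= 10.
    engine:
        Optional external folding adapter: a callable mapping the sequence to
        a ``(dot_bracket, mfe)`` tuple (e.g. :func:`viennarna_engine`).  When
        given, its structure and energy are returned verbatim; otherwise the
        internal dynamic program is used.
    """
    seq = to_rna(sequence)
    if len(seq) < 10:
        raise ValueError(f"sequence too short to fold ({len(seq)} < 10 nt)")
    codes = encode(seq)  # raises on invalid alphabet
    if engine is not None:
        structure, energy = engine(seq)
        pt = pairs_from_dotbracket(structure)
        return FoldResult(seq, structure, float(energy), pt)
    V, WM = _fill_tables(codes, _PAIR_E)
    pt = _trace(codes, V, WM)
    energy = min(0.0, float(WM[0, len(seq) - 1]))
    return FoldResult(seq, _dotbracket(pt), energy, pt)


def score_structure(sequence: str, pair_table: Sequence[int]) -> float:
    """Energy of an explicit structure under the module's model.

    Independent of the dynamic program: walks the structure, identifying each
    loop directly.  Raises ``ValueError`` for structures the model disallows
    (crossing pairs, hairpin loop < 3 nt, internal loop > 30 nt, or an
    unpairable base combination).
    """
    seq = to_rna(sequence)
    codes = encode(seq)
    n = len(seq)
    pt = list(pair_table)
    for i, j in enumerate(pt):
        if j < 0:
            continue
        if pt[j] != i or j == i:
            raise ValueError("pair table is not involutive")
        if i < j and _PAIR_E[codes[i], codes[j]] >= 0:
            raise ValueError(f"unpairable bases at {i},{j}")
    pairs = sorted((i, j) for i, j in enumerate(pt) if 0 <= i < j)
    for (i, j), (k, l) in zip(pairs, pairs[1:]):
        if i < k <= j < l:
            raise ValueError("crossing pairs (pseudoknot)")
    energy = 0.0
    for i, j in pairs:
        # children: pairs directly nested under (i, j)
        children = []
        k = i + 1
        while k < j:
            if pt[k] > k:
                children.append((k, pt[k]))
                k = pt[k] + 1
            else:
                k += 1
        if not children:
            if j - i - 1 < MIN_HAIRPIN_LOOP:
                raise ValueError("hairpin loop shorter than 3 nt")
            energy += HAIRPIN_PENALTY
        elif len(children) == 1:
            k, l = children[0]
            gap = (k - i - 1) + (j - l - 1)
            if gap == 0:
                energy += (_PAIR_E[codes[i], codes[j]] + _PAIR_E[codes[k], codes[l]]) / 2.0
            elif gap <= MAX_INTERNAL_LOOP:
                energy += INTERNAL_PENALTY
            else:
                raise ValueError("internal loop longer than 30 nt")
        # multibranch loops are free
    return energy


def gc_percent(sequence: str) -> float:
    """100 * (G+C) / length."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = to_rna(sequence)
    return 100.0 * sum(c in "GC" for c in seq) / len(seq)


def duplex_region(pair_table: Sequence[int], mature_span: Tuple[int, int]) -> DuplexRegion:
    """Pairing statistics for a mature span (0-based inclusive) in a structure.

    The star span is the min..max of the partners of the paired mature
    positions.  ``unpaired_count`` counts mature positions without a partner.
    The loop/bulge flag fires on any run of >= 2 consecutive unpaired
    positions strictly inside the mature span or strictly inside the star
    span; a single-base interruption is a tolerated bulge.
    """
    lo, hi = mature_span
    pt = list(pair_table)
    if lo < 0 or hi >= len(pt) or lo > hi:
        raise ValueError("mature span outside sequence")
    partners = [pt[i] for i in range(lo, hi + 1) if pt[i] >= 0]
    unpaired = sum(1 for i in range(lo, hi + 1) if pt[i] < 0)
    if not partners:
        return DuplexRegion(-1, -1, unpaired, True, False)
    star_lo, star_hi = min(partners), max(partners)

    def has_run(a: int, b: int) -> bool:
        run = 0
        for i in range(a + 1, b):  # strictly inside the span
            run = run + 1 if pt[i] < 0 else 0
            if run >= 2:
                return True
        return False

    flag = has_run(lo, hi) or has_run(star_lo, star_hi)
    return DuplexRegion(star_lo, star_hi, unpaired, flag, True)


def viennarna_engine(command: str = "RNAfold") -> Callable[[str], Tuple[str, float]]:
    """Adapter for an external thermodynamic folder with RNAfold's CLI contract.

    Returns a callable suitable for ``fold(seq, engine=...)``.  Raises
    ``RuntimeError`` at construction if the executable is not on PATH.
    """
    if shutil.which(command) is None:
        raise RuntimeError(f"{command} not found on PATH")

    def run(seq: str) -> Tuple[str, float]:
        out = subprocess.run(
            [command, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
        ).stdout.splitlines()
        structure, _, energy = out[1].partition(" ")
        return structure, float(energy.strip().strip("()"))

    return run
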