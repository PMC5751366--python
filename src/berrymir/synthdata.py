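"""Ground-truth simulator for the two-library miRNA discovery pipeline.

Generates everything the pipeline consumes with known truth: genome
scaffolds carrying planted hairpin loci, a mature-miRNA reference set
covering a subset of the planted matures ("known" loci; the rest are
"novel"), two small-RNA read libraries (WF = ripening onset, BF = ripe) with
planted per-locus abundances and fold changes, adapter-bearing reads,
contaminant (rRNA/tRNA-like) reads, random background, target transcripts and
a degradome 5'-tag library with cleavage peaks opposite miRNA position 10.

Every output is a pure function of ``(config, seed)``; all randomness flows
through ``numpy.random.default_rng`` seeded from the config seed plus a fixed
per-stream offset.

Read sampling model: each library is a multinomial over categories
(locus 1..n, contaminant, background) with per-locus probability
``expected_count / library_size``, so an observed locus count is binomial
around its expected count.  ``background_fraction`` is a floor: when it is
positive, background absorbs the leftover probability mass so the emitted
library has exactly ``library_size`` reads; when it is zero, leftover mass
emits nothing (an all-zero config yields an empty library).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._seq import revcomp_dna, revcomp_rna, to_dna, to_rna

__all__ = [
    "SyntheticConfig",
    "PlantedLocus",
    "TargetSite",
    "SyntheticTruth",
    "default_config",
    "build_hairpin_locus",
    "generate_truth",
    "simulate_sra_library",
    "simulate_degradome",
]

CONDITIONS = ("WF", "BF")

# weakest-first so mismatch substitution can avoid both WC and G:U pairing
_PAIRABLE = {"A": {"U"}, "C": {"G"}, "G": {"C", "U"}, "U": {"A", "G"}}
_BASES = "ACGU"


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    The defaults are the package's reference conditions: 3 scaffolds of
    50 kb, 30 planted loci, 200,000 reads per library, seed 1 — a full
    pipeline run in seconds to minutes on one CPU.
    """

    n_scaffolds: int = 3
    scaffold_length: int = 50_000
    n_mirna_loci: int = 30
    # 21 nt and 24 nt classes in excess, as in fruit sRNA libraries
    mature_length_distribution: Dict[int, float] = field(
        default_factory=lambda: {19: 0.05, 20: 0.10, 21: 0.40, 22: 0.10, 23: 0.05, 24: 0.30}
    )
    # log-normal parameters for per-locus expected WF counts; a None mean
    # scales automatically (median locus ~= 30% of the library / n loci)
    abundance_mean_log: Optional[float] = None
    abundance_sigma_log: float = 0.8
    # true BF/WF ratios, assigned to loci in order (cycled if short)
    fold_change_set: List[float] = field(
        default_factory=lambda: [4.0] * 6 + [0.25] * 4 + [1.0] * 20
    )
    library_sizes: Dict[str, int] = field(
        default_factory=lambda: {"WF": 200_000, "BF": 200_000}
    )
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    contaminant_fraction: float = 0.05
    background_fraction: float = 0.15
    degradome_peak_fraction: float = 0.5
    seed: int = 1
    # secondary knobs
    five_prime_u_bias: float = 0.6
    end_variation_rate: float = 0.10
    known_fraction: float = 0.5
    read_length: int = 36
    n_contaminant_seqs: int = 20
    n_target_transcripts: int = 20
    n_decoy_transcripts: int = 5
    transcript_length: int = 1200
    degradome_tags_per_transcript: int = 100

    def __post_init__(self) -> None:
        total = sum(self.mature_length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mature_length_distribution must sum to 1")
        if any(not 19 <= k <= 24 for k in self.mature_length_distribution):
            raise ValueError("mature lengths must lie in 19..24")
        for name in ("contaminant_fraction", "background_fraction", "degradome_peak_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if any(v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library_sizes must be positive")
        if any(fc <= 0 for fc in self.fold_change_set):
            raise ValueError("fold changes must be positive")


def default_config(seed: int = 1) -> SyntheticConfig:
    return SyntheticConfig(seed=seed)


@dataclass(frozen=True)
class PlantedLocus:
    """One planted hairpin locus; coordinates are 1-based inclusive."""

    locus_id: str
    scaffold: str
    start: int  # precursor span on the forward strand
    end: int
    strand: str
    mature: str  # RNA, 5'->3'
    star: str
    arm: str  # "5p" | "3p"
    mature_start: int  # mature span on the forward strand
    mature_end: int
    star_start: int  # annotated star span (2-nt 3' overhang convention)
    star_end: int
    precursor: str  # RNA, 5'->3' of the hairpin transcript
    mature_offset: int  # 0-based offset of the mature within the precursor
    n_duplex_mismatches: int
    known: bool
    expected_counts: Dict[str, float]
    fold_change: float  # true BF/WF ratio


@dataclass(frozen=True)
class TargetSite:
    transcript_id: str
    mirna_id: str
    mature: str
    site_start: int  # 1-based inclusive span of the complementary site
    site_end: int
    cleavage_pos: int  # 1-based; opposite miRNA position 10 from its 5' end
    alignment: str  # per-position states, miRNA 5'->3'


@dataclass
class SyntheticTruth:
    config: SyntheticConfig
    scaffolds: Dict[str, str]  # DNA
    loci: List[PlantedLocus]
    mature_reference: Dict[str, str]  # reference id -> mature RNA (known loci)
    contaminants: Dict[str, str]  # DNA
    transcripts: Dict[str, str]  # DNA
    target_sites: List[TargetSite]


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = _BASES) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def build_hairpin_locus(
    mature: str,
    loop_length: int,
    n_duplex_mismatches: int,
    rng: np.random.Generator,
    arm: Optional[str] = None,
    flank_lengths: Optional[Tuple[int, int]] = None,
    n_wobbles: int = 0,
) -> Tuple[str, str, str, int, int]:
    """Construct a stem-loop precursor around a mature sequence.

    Returns ``(precursor, star, arm, mature_offset, star_offset)`` where the
    offsets are 0-based positions within the precursor.  The star is
    the reverse complement of the mature with exactly ``n_duplex_mismatches``
    pairing positions broken (isolated single-base mismatches, so the duplex
    stays free of >=2-nt internal loops and bulges).  ``n_wobbles`` interior
    Watson-Crick pairs are additionally converted to G:U wobbles (still
    paired, so the duplex mismatch count is unaffected); the generator plants
    one wobble per locus so that a perfect duplex is never an exact reverse
    complement, which would make the genomic strand of the hairpin
    unidentifiable from the reads.
    """
    mature = to_rna(mature)
    if not 19 <= len(mature) <= 24:
        raise ValueError(f"mature length {len(mature)} outside 19..24")
    if any(c not in _BASES for c in mature):
        raise ValueError("mature contains non-ACGU symbols")
    if not 0 <= n_duplex_mismatches <= 2:
        raise ValueError("duplex mismatch budget is 0..2")
    if loop_length < 3:
        raise ValueError("loop length must be >= 3")
    L = len(mature)
    if arm is None:
        arm = "5p" if rng.random() < 0.5 else "3p"
    if arm not in ("5p", "3p"):
        raise ValueError("arm must be '5p' or '3p'")
    if flank_lengths is None:
        flank_lengths = (int(rng.integers(15, 31)), int(rng.integers(15, 31)))

    from . import folding  # deferred: folding does not depend on this module

    # rejection-sample flanks/loop/mismatch placement until the minimum-energy
    # structure of the construct is the intended duplex (the simulator's
    # contract: planted precursors fold as planted)
    for _attempt in range(60):
        star = list(revcomp_rna(mature))
        positions: List[int] = []
        if n_wobbles:
            # convert WC pairs at mature G/U positions into G:U wobbles
            wobble_candidates = [p for p in range(3, L - 3) if mature[p] in "GU"]
            rng.shuffle(wobble_candidates)
            for p in wobble_candidates[:n_wobbles]:
                star[L - 1 - p] = "U" if mature[p] == "G" else "G"
                positions.append(p)
        if n_duplex_mismatches:
            n_placed = 0
            candidates = list(range(3, L - 3))
            rng.shuffle(candidates)
            for p in candidates:
                if any(abs(p - q) < 4 for q in positions):
                    continue
                # substituted star base must not pair the mature base or its
                # neighbours, or the fold can slip into an equal-energy bulge
                bad = [
                    b
                    for b in _BASES
                    if all(
                        b not in _PAIRABLE[mature[q]]
                        for q in (p - 1, p, p + 1)
                    )
                ]
                if not bad:
                    continue
                positions.append(p)
                star[L - 1 - p] = bad[int(rng.integers(len(bad)))]
                n_placed += 1
                if n_placed == n_duplex_mismatches:
                    break
            if n_placed < n_duplex_mismatches:
                continue
        star_seq = "".join(star)
        # GC clamps just outside and just inside the duplex pin its register
        f5 = _random_seq(rng, max(flank_lengths[0] - 2, 0)) + "GG"
        f3 = "CC" + _random_seq(rng, max(flank_lengths[1] - 2, 0))
        loop = "GG" + _random_seq(rng, loop_length) + "CC"
        if arm == "5p":
            precursor = f5 + mature + loop + star_seq + f3
            mature_offset = len(f5)
            star_offset = len(f5) + L + len(loop)
        else:
            precursor = f5 + star_seq + loop + mature + f3
            mature_offset = len(f5) + L + len(loop)
            star_offset = len(f5)
        if not 55 <= len(precursor) <= 930:
            raise ValueError("precursor length outside 55..930 nt")
        result = folding.fold(precursor)
        region = folding.duplex_region(
            result.pair_table, (mature_offset, mature_offset + L - 1)
        )
        if (
            region.defined
            and region.unpaired_count == n_duplex_mismatches
            and not region.has_internal_loop_or_bulge
        ):
            return precursor, star_seq, arm, mature_offset, star_offset
    raise RuntimeError("could not build a hairpin that folds as planted")


def _sample_mature(rng: np.random.Generator, config: SyntheticConfig) -> str:
    lengths = sorted(config.mature_length_distribution)
    probs = [config.mature_length_distribution[k] for k in lengths]
    L = int(rng.choice(lengths, p=probs))
    first = "U" if rng.random() < config.five_prime_u_bias else _random_seq(rng, 1, "ACG")
    return first + _random_seq(rng, L - 1)


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Generate scaffolds, planted loci, contaminants, transcripts and truth."""
    rng = _rng(config, 0)
    scaffolds = {
        f"synscaf{k + 1:02d}": _random_seq(rng, config.scaffold_length, "ACGT")
        for k in range(config.n_scaffolds)
    }
    scaffold_ids = list(scaffolds)

    # per-locus expected counts and fold changes
    wf_lib = config.library_sizes.get("WF", 0)
    mean_log = config.abundance_mean_log
    if mean_log is None:
        mean_log = np.log(max(0.3 * wf_lib / max(config.n_mirna_loci, 1), 1.0))
    expected_wf = np.exp(
        rng.normal(mean_log, config.abundance_sigma_log, config.n_mirna_loci)
    )
    # guarantee feasibility of the read-sampling model at any scale: rescale
    # a pathological tail draw so expected reads fit the library budget
    budget = 1.0 - config.contaminant_fraction - config.background_fraction
    fc_arr = np.array(
        [
            config.fold_change_set[i % len(config.fold_change_set)]
            if config.fold_change_set
            else 1.0
            for i in range(config.n_mirna_loci)
        ]
    )
    if config.n_mirna_loci and wf_lib:
        worst = max(expected_wf.sum(), (expected_wf * fc_arr).sum())
        cap = 0.95 * budget * min(config.library_sizes.values())
        if worst > cap > 0:
            expected_wf *= cap / worst
    fcs = [
        config.fold_change_set[i % len(config.fold_change_set)] if config.fold_change_set else 1.0
        for i in range(config.n_mirna_loci)
    ]

    loci: List[PlantedLocus] = []
    mature_reference: Dict[str, str] = {}
    used: Dict[str, List[Tuple[int, int]]] = {sid: [] for sid in scaffold_ids}
    seen_matures: set[str] = set()
    for i in range(config.n_mirna_loci):
        mature = _sample_mature(rng, config)
        while mature in seen_matures:
            mature = _sample_mature(rng, config)
        seen_matures.add(mature)
        n_mm = int(rng.integers(0, 3))
        precursor, star, arm, mat_off, star_off = build_hairpin_locus(
            mature, int(rng.integers(6, 13)), n_mm, rng, n_wobbles=1
        )
        # place on a scaffold, non-overlapping, margin away from other loci
        plen = len(precursor)
        for _attempt in range(200):
            sid = scaffold_ids[int(rng.integers(len(scaffold_ids)))]
            strand = "+" if rng.random() < 0.5 else "-"
            start = int(rng.integers(300, config.scaffold_length - plen - 300))
            span = (start - 300, start + plen + 300)
            if all(span[1] < a or span[0] > b for a, b in used[sid]):
                used[sid].append((start, start + plen))
                break
        else:  # pragma: no cover - only under absurdly dense configs
            raise RuntimeError("could not place locus; scaffolds too small")
        insert = to_dna(precursor) if strand == "+" else revcomp_dna(precursor)
        scaffolds[sid] = scaffolds[sid][:start] + insert + scaffolds[sid][start + plen:]
        # forward-axis coordinates, 1-based inclusive
        pre_start, pre_end = start + 1, start + plen
        if strand == "+":
            mat_start = pre_start + mat_off
            mat_end = mat_start + len(mature) - 1
        else:
            mat_end = pre_end - mat_off
            mat_start = mat_end - len(mature) + 1
        # annotated star span carries the canonical 2-nt 3' overhang:
        # the in-structure partner span shifted two positions 3'-ward
        s0, s1 = star_off + 2, star_off + len(star) + 1  # 0-based inclusive
        if strand == "+":
            star_start, star_end = pre_start + s0, pre_start + s1
        else:
            star_end, star_start = pre_end - s0, pre_end - s1
        known = rng.random() < config.known_fraction
        locus_id = f"synloc{i + 1:02d}"
        if known:
            mature_reference[f"ref-miR9{i + 1:02d}"] = mature
        loci.append(
            PlantedLocus(
                locus_id=locus_id,
                scaffold=sid,
                start=pre_start,
                end=pre_end,
                strand=strand,
                mature=mature,
                star=star,
                arm=arm,
                mature_start=mat_start,
                mature_end=mat_end,
                star_start=min(star_start, star_end),
                star_end=max(star_start, star_end),
                precursor=precursor,
                mature_offset=mat_off,
                n_duplex_mismatches=n_mm,
                known=known,
                expected_counts={"WF": float(expected_wf[i]), "BF": float(expected_wf[i] * fcs[i])},
                fold_change=float(fcs[i]),
            )
        )

    contaminants = {
        f"contam{k + 1:02d}": _random_seq(rng, int(rng.integers(80, 301)), "ACGT")
        for k in range(config.n_contaminant_seqs)
    }

    # target transcripts: one planted site per transcript, plus decoys
    transcripts: Dict[str, str] = {}
    target_sites: List[TargetSite] = []
    n_targets = min(config.n_target_transcripts, len(loci))
    order = rng.permutation(len(loci))[:n_targets] if loci else []
    for t, li in enumerate(sorted(int(x) for x in order)):
        locus = loci[li]
        tid = f"syntx{t + 1:03d}"
        tlen = config.transcript_length
        seq = _random_seq(rng, tlen, "ACGT")
        site = revcomp_dna(locus.mature)
        pos = int(rng.integers(50, tlen - len(site) - 50))
        seq = seq[:pos] + site + seq[pos + len(site):]
        transcripts[tid] = seq
        L = len(locus.mature)
        site_start = pos + 1
        target_sites.append(
            TargetSite(
                transcript_id=tid,
                mirna_id=locus.locus_id,
                mature=locus.mature,
                site_start=site_start,
                site_end=site_start + L - 1,
                cleavage_pos=site_start + L - 10,
                alignment="M" * L,
            )
        )
    for d in range(config.n_decoy_transcripts):
        transcripts[f"syndecoy{d + 1:02d}"] = _random_seq(rng, config.transcript_length, "ACGT")

    # feasibility of the read-sampling model
    for cond, lib in config.library_sizes.items():
        p_mirna = sum(l.expected_counts.get(cond, 0.0) for l in loci) / lib
        if p_mirna + config.contaminant_fraction + config.background_fraction > 1.0 + 1e-9:
            raise ValueError(f"expected counts exceed library capacity in {cond}")

    return SyntheticTruth(
        config=config,
        scaffolds=scaffolds,
        loci=loci,
        mature_reference=mature_reference,
        contaminants=contaminants,
        transcripts=transcripts,
        target_sites=target_sites,
    )


def _variant_read(locus: PlantedLocus, rng: np.random.Generator, rate: float) -> str:
    """Mature sequence with optional <=2 nt end variation, from its precursor."""
    lo = locus.mature_offset
    hi = lo + len(locus.mature)
    if rng.random() < rate:
        d5 = int(rng.integers(-2, 3))
        d3 = int(rng.integers(-2, 3))
        lo2 = min(max(lo + d5, 0), hi - 16)
        hi2 = max(min(hi + d3, len(locus.precursor)), lo2 + 16)
        return locus.precursor[lo2:hi2]
    return locus.mature


def simulate_sra_library(
    truth: SyntheticTruth, condition: str, config: Optional[SyntheticConfig] = None
) -> List[str]:
    """Emit one adapter-bearing read library (DNA strings of read_length)."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    config = config or truth.config
    lib = config.library_sizes.get(condition, 0)
    rng = _rng(config, 10 + CONDITIONS.index(condition))
    probs = [l.expected_counts.get(condition, 0.0) / lib for l in truth.loci]
    p_cont = config.contaminant_fraction
    p_back = config.background_fraction
    slack = 1.0 - sum(probs) - p_cont - p_back
    if slack < -1e-9:
        raise ValueError("expected counts exceed library capacity")
    if p_back > 0:
        p_back += max(slack, 0.0)  # background absorbs the remainder
        slack = 0.0
    counts = rng.multinomial(lib, probs + [p_cont, p_back, max(slack, 0.0)])
    adapter = config.adapter
    rlen = config.read_length
    reads: List[str] = []
    for locus, k in zip(truth.loci, counts[: len(truth.loci)]):
        for _ in range(k):
            insert = to_dna(_variant_read(locus, rng, config.end_variation_rate))
            reads.append((insert + adapter)[:rlen])
    contam_ids = list(truth.contaminants)
    for _ in range(counts[len(truth.loci)]):
        src = truth.contaminants[contam_ids[int(rng.integers(len(contam_ids)))]]
        ln = int(rng.integers(18, 26))
        at = int(rng.integers(0, len(src) - ln + 1))
        reads.append((src[at:at + ln] + adapter)[:rlen])
    for _ in range(counts[len(truth.loci) + 1]):
        ln = int(rng.integers(18, 26))
        reads.append((_random_seq(rng, ln, "ACGT") + adapter)[:rlen])
    return reads


def simulate_degradome(
    truth: SyntheticTruth,
    transcripts: Optional[Dict[str, str]] = None,
    config: Optional[SyntheticConfig] = None,
) -> List[str]:
    """Emit one degradome 5'-tag library (DNA strings of 20-21 nt).

    For each planted target site, ``degradome_peak_fraction`` of that
    transcript's tags start exactly at the cleavage position; the rest start
    uniformly at random.  Decoy transcripts receive only uniform tags.
    """
    config = config or truth.config
    transcripts = transcripts if transcripts is not None else truth.transcripts
    rng = _rng(config, 20)
    sites = {s.transcript_id: s for s in truth.target_sites}
    for s in truth.target_sites:
        if s.transcript_id not in transcripts:
            raise ValueError(f"target transcript {s.transcript_id} missing")
        if not 1 <= s.cleavage_pos <= len(transcripts[s.transcript_id]):
            raise ValueError("cleavage position outside transcript bounds")
    tags: List[str] = []
    n_per = config.degradome_tags_per_transcript
    for tid in transcripts:
        seq = transcripts[tid]
        site = sites.get(tid)
        n_peak = int(round(config.degradome_peak_fraction * n_per)) if site else 0
        for _ in range(n_peak):
            ln = 20 + int(rng.integers(0, 2))
            start = site.cleavage_pos - 1
            tags.append(seq[start:start + ln])
        for _ in range(n_per - n_peak):
            ln = 20 + int(rng.integers(0, 2))
            start = int(rng.integers(0, max(1, len(seq) - ln)))
            tags.append(seq[start:start + ln])
    return tags
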