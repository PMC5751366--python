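# Methods

This note documents the models and procedures `berrymir` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer would want written down.

## Read cleaning and tag collapsing

Raw reads pass through a fixed cascade, and every read lands in exactly one
category so the accounting is conservative per library:

```
raw = retained + adapter-rejected + junk + low-quality + contaminant + length-rejected
```

* **Adapter trimming** removes the longest read suffix that exactly matches
  a prefix of the 3′ adapter (minimum overlap 6 nt). Reads with no such
  overlap are flagged and excluded; in a 36 bp single-end small-RNA protocol
  every genuine insert is shorter than the read, so a missing adapter
  indicates an artefact.
* **Junk** is any read with one base making up ≥ 80% of its length, or any
  non-ACGT/U symbol. The threshold is the common convention; nothing in the
  pipeline is sensitive to its exact value.
* **Low quality** is a placeholder filter (mean Phred < 20) applied only
  when FASTQ qualities exist; it is a no-op for FASTA input and for the
  simulator's fixed-quality reads.
* **Contaminants** (rRNA/tRNA/snRNA/snoRNA-like sequences) are removed by
  exact substring lookup against the provided set rather than by alignment.
  This is a deliberate simplification: it is deterministic, fast, and exact
  when the contaminant catalog is known, but it will miss contaminant
  variants that an alignment-based (BLAST/Rfam) screen would catch.
* **Length window** 18–25 nt selects the small-RNA fraction; "clean reads"
  (the denominator for the length histogram and the in-range fraction) are
  the reads surviving adapter/junk/quality removal, before contaminant and
  length selection, which is how such libraries are conventionally
  summarized.

Survivors are collapsed to unique tags (stored as RNA) with per-library
counts; collapsing conserves the retained-read count exactly and is
independent of input order.

## RNA folding model

The hairpin screen needs minimum-energy secondary structures with an energy
score. The module implements a self-contained nearest-neighbour-lite model:

* stack of adjacent pairs: mean of the two pair strengths —
  GC/CG −3.0, AU/UA −2.0, GU/UG −1.0 (kcal/mol scale);
* +4.0 per hairpin loop (minimum 3 unpaired nt);
* +2.0 per internal loop or bulge, up to 30 unpaired nt (the standard cap,
  made part of the model definition);
* multibranch loops and external bases are free; no pseudoknots.

The optimum is found exactly by a Zuker-style O(n³) dynamic program
(numba-compiled) over pair-closed (`V`) and non-empty-segment (`WM`)
tables; since all energies are multiples of 0.5 they are exact in floating
point, and the traceback (prefer pairing, then the 5′-most partner) uses
exact equality. Correctness is verified in the test suite against
exhaustive enumeration of all structures for sequences up to 25 nt.

**Caveat.** This is not the Turner thermodynamic model a folding web server
uses. MFEI magnitudes land in the same regime (genuine precursors score
well above random sequence), but MFEI values are only comparable within one
model. `fold(seq, engine=...)` accepts any adapter returning
`(dot_bracket, mfe)` — `viennarna_engine()` wraps an RNAfold-compatible
executable — for users who need thermodynamic energies; the MFEI threshold
below was chosen for, and validated under, the internal model.

## Hairpin screening and the miRNA catalog

Candidate tags (total count ≥ 2) are located exactly on the reference, both
strands. Entries within 60 nt of one another on a scaffold are clustered
into one physical locus regardless of strand: the reverse complement of a
near-perfect-duplex mature matches the star arm across the loop, and that
star-shadow hit must not become a second catalog entry. The cluster is
oriented by total read support — end-variation tags map only in the true
orientation — and its most abundant tag (ties: lexicographically smallest)
becomes the locus representative.

Precursor windows extend 20–250 nt (step 10) symmetrically around the
mature site, clipped at scaffold bounds, minimum 55 nt. Windows are
evaluated best-first by MFEI (ties to the shorter window) and the first
window satisfying the acceptance rule is catalogued. The four novel-miRNA
criteria are:

1. mature on one arm (its structural partner span must not overlap it);
2. ≤ 2 unpaired mature positions against the star;
3. no ≥ 2-nt run of unpaired bases strictly inside the mature span or its
   partner span (a single-base bulge is tolerated — a literal zero-bulge
   rule would reject most published precursors, whose duplexes report up to
   2 mismatches);
4. MFEI ≥ 0.85.

The 0.85 threshold is a design choice: published MFEI ranges put genuine
precursors at ≈ 1.1–1.7 and tRNA/rRNA/mRNA at ≈ 0.59–0.66, and 0.85 cleanly
separates the two under the internal energy model as well (random-sequence
windows measure ≈ 0.3–0.8 here).

Known miRNAs are assigned by homology: up to 2 nt extension/truncation per
end (the isomiR convention; the matching literature says "length variation"
without a bound), ≤ 1 internal mismatch, overlap core ≥ 16 nt; the best hit
(fewest mismatches, then smallest total shift) names the family. Known
status requires only the mature-on-arm condition beyond homology; star
presence in the reads is recorded but never required. Multi-mapping tags:
all exact loci are reported, and each cluster is catalogued independently.

## Differential expression

Normalization is reads-per-million of clean reads. The catalog column
header "FPKM" in the packaged table behaves as normalized read counts; fold
changes are scale-invariant to the denominator choice, which is therefore a
configuration detail, not a result-changing one. Records below 1 normalized
count in both libraries are dropped. Fold change is BF/WF with
WF = 0 reported as infinity (no pseudo-counts, matching the printed "inf"
convention). The Fisher exact test is two-sided by the point-probability
method on the 2×2 table of (count, library-total − count); ties are
included with a 1 + 1e-7 relative slack, and the implementation is verified
against exact-rational enumeration for all tables with margins ≤ 30. The
up/down call requires |log₂ FC| ≥ 1 (equivalently FC > 2 or < 0.5 except at
exactly 2-fold, where the log form decides) and p ≤ 0.05. No
multiple-testing correction enters the calls — the two-library protocol
applies none — but a Benjamini–Hochberg column is emitted alongside,
marked as an extension.

## Degradome target calling

Complementarity scoring follows TargetFinder's published defaults: mismatch
1.0, G:U wobble 0.5, gap 1.0, all penalties doubled over miRNA positions
2–13, alignments retained at score ≤ 4.0. This package emits **ungapped**
alignments only (the gap penalty exists in the scheme but no gapped
alignment is searched): plant miRNA/target duplexes with bulges are rare,
the simulator plants none, and a gapped search costs an order of magnitude
more for no additional coverage here. The predicted cleavage position is
the transcript base paired to miRNA position 10 from the 5′ end; the
observed site is the highest-count t-plot position within ±1 nt (consistent
with slicing between positions 9 and 11), ties to the closest then 5′-most
position. Tags map to t-plots by exact 18-nt prefix match; a prefix
occurring at several positions counts at each. Categories: 4 for a single
raw read; 0/1 at the transcript maximum (unique/shared); 2/3 below the
maximum, above/at-or-below the median of nonzero counts — the CleaveLand
convention for "a clear peak".

## The synthetic-data generator

The generator defines the package's reference study conditions: 3 scaffolds
× 50 kb, 30 hairpin loci, 200,000 reads per library, 5% contaminant and
≥ 15% background reads, mature lengths concentrated at 21 and 24 nt, 5′-U
probability 0.6, end-variation rate 0.1 (≤ 2 nt per end, matching the
matcher's tolerance so recovery is well-posed), fold-change set
{6 × 4.0, 4 × 0.25, 20 × 1.0}, degradome peak fraction 0.5 with 100 tags
per transcript, seed 1. Per-locus expected counts are log-normal
(σ = 0.8; the median auto-scales to ≈ 30% of the library spread over the
loci, ≈ 2,000 reads at the reference scale — the generating process of real
libraries is unknown, and the log-normal is a stand-in, not an inference).

Reads are drawn as one multinomial per library over (loci, contaminant,
background) with per-locus probability expected/library-size, so observed
counts are binomial around their expectations. `background_fraction` is a
floor: when positive, background absorbs leftover probability so exactly
`library_size` reads are emitted; at zero, leftover mass emits nothing (an
all-zero configuration yields an empty library). All outputs are a pure
function of (config, seed).

Hairpin construction places the mature and its star (reverse complement
with the requested number of isolated mismatches) around a loop, with
single-pair GC clamps pinning the duplex register, and **rejection-samples
flanks/loop/mismatch placement until the construct's minimum-energy
structure is the planted duplex** — the generator's contract is that planted
precursors fold as planted, which the truth round-trip tests rely on. Each
duplex also carries one G:U wobble so that a perfect duplex is never an
exact reverse complement; without it the genomic strand of the hairpin is
genuinely unidentifiable from short reads (both orientations are valid
hairpins with identical k-mer content). The mature/star duplex is blunt in
the structure; the canonical 2-nt 3′ overhang is applied to the annotated
star coordinates in the truth table, not to the pairing.

**What passing the recovery tests does and does not show.** The simulator
emulates locus placement on both strands, isomiR end variation, abundance
noise, contaminants and random background, and degradome peaks over uniform
background. It does not model sequencing error, quality scores, PCR
duplication, repetitive genomes, overlapping/clustered miRNA loci, gapped
target duplexes, or composition bias — full recovery here demonstrates the
pipeline's logic is correct and its conventions self-consistent, not that
real-library recovery would be complete.

## Scale and determinism choices

The reference benchmark (30 loci, 2 × 200k reads, ~720 window folds) runs
in roughly a minute on one CPU; the test suite uses a 6-locus, 2 × 8k-read
dataset for unit-level checks and the reference conditions for the
recovery benchmark. Enumeration oracles run at n ≤ 25 (folding) and margins
≤ 30 (Fisher), the scales at which exhaustive verification stays cheap. All
randomness flows through `numpy.random.default_rng` seeded from the
configuration seed plus fixed stream offsets; outputs are byte-identical
across runs at the same seed, and all table writes are atomic
(write-then-rename).

## Known limitations

* The energy model is deliberately light; absolute MFE values are not
  thermodynamic and MFEI is model-relative (see the folding caveat).
* Contaminant filtering is exact-match only.
* One library per condition: the Fisher test treats counts as fixed totals
  and no biological replication or dispersion modeling is possible.
* Degradome alignments are ungapped and t-plot peaks carry no p-value; the
  categories are evidence tiers, not significance statements.
* The packaged catalog tables store normalized abundances as printed; raw
  counts and library totals are not recoverable from them, so their Fisher
  p-values cannot be recomputed (the fold-change columns can, and are).
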