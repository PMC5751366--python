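"""Fold a precursor candidate and compute its MFE / AMFE / MFEI.

A genuine pre-miRNA hairpin folds into a long stem with a strongly negative
energy for its length and GC content, giving an MFEI well above the ~0.6
typical of tRNA/rRNA/mRNA fragments; the printed dot-bracket shows the
mature/star duplex the screen relies on.
"""

import numpy as np

from berrymir import discovery, folding, synthdata

mature = "UGAGGUAGUAGGUUGUAUAGUU"[:21]
precursor, star, arm, mat_off, star_off = synthdata.build_hairpin_locus(
    mature, loop_length=8, n_duplex_mismatches=1,
    rng=np.random.default_rng(0), arm="5p",
)

result = folding.fold(precursor)
gc = folding.gc_percent(precursor)
amfe = result.energy / len(precursor) * 100
index = discovery.mfei(result.energy, len(precursor), gc)

print(precursor)
print(result.structure)
print(f"\nlength {len(precursor)} nt | MFE {result.energy:.1f} | "
      f"GC {gc:.1f}% | AMFE {amfe:.1f} | MFEI {index:.2f}")

region = folding.duplex_region(result.pair_table, (mat_off, mat_off + len(mature) - 1))
print(f"mature on {arm} arm; unpaired mature positions (planted 1): "
      f"{region.unpaired_count}; internal loop/bulge: {region.has_internal_loop_or_bulge}")
print("a random-sequence MFEI for comparison:",
      round(discovery.mfei(folding.fold('AUGCAUGGAUCCAUAGCUUAGGCCAAUUGGAUCAAUGGAUCGAUUAGCCAUAGGCCAAUAG').energy, 61, 39.3), 2))
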