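"""Two-library differential expression with Fisher exact testing.

Counts are normalized to reads-per-million, fold changes are BF/WF, and a
miRNA is called up/down when |log2 FC| >= 1 with a two-sided Fisher exact
p <= 0.05.  A miRNA absent from WF gets an infinite fold change, as such
tables conventionally print it.
"""

from berrymir import expression

raw_counts = {
    "miR-ripe-up": (120, 540),     # ~4.5-fold induction
    "miR-flat": (300, 310),
    "miR-ripe-down": (480, 110),
    "miR-bf-only": (0, 60),
    "miR-rare": (0, 0),            # below the low-abundance filter
}
records = expression.build_expression_table(raw_counts, wf_total=400_000, bf_total=420_000)

print(f"{'miRNA':<14}{'WF':>8}{'BF':>8}{'FC':>8}{'log2':>7}  {'p':>10}  label  call")
for r in records:
    fc = "inf" if r.fold_change == float("inf") else f"{r.fold_change:.2f}"
    l2 = "inf" if r.log2_fold_change == float("inf") else f"{r.log2_fold_change:.2f}"
    print(f"{r.mirna_id:<14}{r.norm_wf:>8.2f}{r.norm_bf:>8.2f}{fc:>8}{l2:>7}"
          f"  {r.p_value:>10.3g}  {r.label:<5}  {r.direction}")
print("\n(the filtered 'miR-rare' row is absent: normalized counts < 1 in both libraries)")
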