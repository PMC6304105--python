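"""Alignment quality measures: the entropy filter and difference summary.

The per-alignment quality filter keeps an alignment only if some run of
>= 30 columns reaches >= 60% identity AND >= 1.8 bits of sequence entropy
— low-complexity matches (e.g. poly-A) pass the identity bar but fail the
entropy bar.  The difference summary classifies every aligned column and
reports rates over reference bases.
"""

from cneqc.alignments import passes_entropy_quality, shannon_entropy, summarize_differences

# a perfect but low-complexity alignment: 40 matching 'A' columns
low_complexity = [("A", "A")] * 40
# a perfect alignment with balanced composition
balanced = [(b, b) for b in "ACGT" * 10]

print("low-complexity run : identity 100%, "
      f"H = {shannon_entropy([40, 0, 0, 0]):.2f} bits -> "
      f"passes = {passes_entropy_quality(low_complexity)}")
print("balanced run       : identity 100%, "
      f"H = {shannon_entropy([10, 10, 10, 10]):.2f} bits -> "
      f"passes = {passes_entropy_quality(balanced)}")

# pairwise difference summary of a 1,000-column alignment
pairs = [("A", "A")] * 996 + [("A", "G"), ("C", "T"), ("-", "G"), ("T", "-")]
stats, pct = summarize_differences(pairs)
print(f"columns={stats.columns}: {stats.match} match, {stats.mismatch} subst, "
      f"{stats.ins} ins, {stats.dele} del")
print(f"rates over {stats.reference_bases} reference bases: "
      f"{pct['substitution_pct']:.2f}% subst, {pct['insertion_pct']:.2f}% ins, "
      f"{pct['deletion_pct']:.2f}% del")
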