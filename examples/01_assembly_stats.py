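"""Assembly summary statistics on a synthetic fragmented assembly.

Builds a 200 kb genome, breaks it into 11 scaffolds rejoined with 100 bp
N-gaps, and reports gap/contig/N(x) statistics.
"""

from cneqc.assembly import summarize_assembly
from cneqc.simulate import SimulationConfig, fragment_assembly, join_with_gaps, simulate_clade

sim = simulate_clade(SimulationConfig(seed=42))
scaffold = join_with_gaps(
    fragment_assembly(sim.reference, n_breaks=10, seed=42), gap_len=100
)
report = summarize_assembly([scaffold])

print(f"total bases      : {report.total_bases:,}")
print(f"gap bases        : {report.gap_bases:,} "
      f"({100 * report.gap_bases / report.total_bases:.1f}% of the assembly)")
print(f"scaffolds/contigs: {report.n_scaffolds}/{report.n_contigs}")
print(f"scaffold N50/N90 : {report.scaffold_n50:,} / {report.scaffold_nx[90]:,} bp")
print(f"contig   N50/N90 : {report.contig_n50:,} / {report.contig_nx[90]:,} bp")
# N50 = the length L such that sequences >= L cover half the assembly;
# the contig values are always <= the scaffold values because contigs are
# the gap-free scaffold pieces.
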