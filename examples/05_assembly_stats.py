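"""Draft-assembly statistics and the 7-fold coverage filter.

Simulates a contig set with SPAdes-style coverage headers, drops
low-coverage contigs and reports the usual per-genome table columns
(size, %GC, N50, L50, mean coverage).
"""

from myxopan import assembly_stats, filter_by_coverage, simulate_contigs

contigs = simulate_contigs(
    genome_size=1_000_000, n_contigs=120, coverage_range=(3, 120), gc=0.699, seed=9
)
kept = filter_by_coverage(contigs, min_cov=7.0)
print(f"contigs: {len(contigs)} simulated, {len(kept)} kept at >=7-fold coverage")

s = assembly_stats(kept)
print(f"size: {s.size:,} bp   %GC: {s.gc:.1f}   contigs: {s.n_contigs}")
print(f"N50: {s.n50:,} bp   L50: {s.l50}   mean coverage: {s.mean_coverage:.1f}x")
print("\nL50 = smallest number of largest contigs covering more than half")
print("the assembly; N50 = length of the last contig counted.")
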