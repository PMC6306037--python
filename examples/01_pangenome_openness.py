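"""Pan-genome openness: rarefaction, Heaps'-law fit and extrapolation.

Simulates a 24-genome presence/absence matrix with a known open
pan-genome (kappa=8000, gamma=0.55), partitions it into the four
Roary-style tiers, fits the rarefaction medians to kappa*n^gamma and
extrapolates how many new genes later genomes would contribute.
"""

from myxopan import (
    extrapolate_pan,
    fit_core_inverse,
    fit_heaps,
    new_genes,
    novelty_horizon,
    partition,
    rarefy,
    simulate_pangenome,
    summarize,
)

matrix, truth = simulate_pangenome(n_genomes=24, seed=7)
part = partition(matrix)
s = summarize(part)
print(f"pan-genome: {s['pan_size']} orthogroups across {s['n_genomes']} genomes")
print(f"core (hard+soft): {s['core_total']} ({s['core_pct_of_pan']}% of pan); "
      f"cloud: {s['cloud']} ({s['cloud_pct']}%)")
print(f"average % of each genome's genes in the core: {s['avg_pct_genes_in_core']}%")

rare = rarefy(matrix, permutations=100, seed=7)
fit = fit_heaps(rare)
print(f"\nHeaps fit: P(n) = {fit.kappa:.0f} * n^{fit.gamma:.4f} "
      f"(generating values: {truth.heaps_kappa:.0f}, {truth.heaps_gamma})")
print("open pan-genome" if fit.is_open else "closed pan-genome")

for n in (101, 501, 1001):
    print(f"  extrapolated pan at n={n}: {extrapolate_pan(fit, n)} "
          f"(genome {n} adds {new_genes(fit, n)} new genes)")
print(f"  fewer than 100 new genes per genome only after "
      f"~{novelty_horizon(fit, 100)} genomes")

core_fit = fit_core_inverse(rare)
print(f"\ncore at infinitely many genomes (1/n regression): "
      f"{core_fit.intercept:.0f} genes "
      f"({100 * core_fit.intercept / part.core_total:.1f}% of the current core)")
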