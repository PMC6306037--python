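"""Congruence between a taxonomy tree and predation-profile trees.

Generates killing-zone matrices at high and zero congruence to a
reference tree, builds neighbor-joining trees from the standardized
Euclidean profile distances, and compares each against the reference
with a tanglegram (crossing minimization), Robinson-Foulds distance
and a leaf-permutation null test.
"""

from myxopan import (
    distance_from_profile,
    entanglement_null_test,
    neighbor_joining,
    simulate_predation,
    tanglegram,
)
from myxopan.io import read_newick

reference = read_newick(
    "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);"
)

for congruence in (1.0, 0.0):
    predation, _ = simulate_predation(reference, n_prey=30, congruence=congruence, seed=3)
    ptree = neighbor_joining(distance_from_profile(predation))
    res = tanglegram(reference, ptree, seed=0)
    null = entanglement_null_test(reference, ptree, permutations=49, seed=0)
    print(f"congruence={congruence}: crossings={res.crossings} "
          f"entanglement={res.entanglement:.3f} RF={res.rf_distance:.2f} "
          f"permutation p={null['p_value']:.3f}")
print("\nlow entanglement/RF with small p = tree-structured predation;")
print("p > 0.05 = predation indistinguishable from a random relabeling.")
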