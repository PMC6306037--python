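"""Distances, neighbor-joining, bootstrap and tanglegram congruence.

Distance constructors cover the three data types compared in
predator-genomics congruence analysis: Kimura 2-parameter distances
from aligned nucleotide sequences, linear transforms of ANI matrices,
and profile distances (standardized Euclidean for continuous killing-
zone profiles, Jaccard for binary gene/BGC complements).  Trees are
built by neighbor joining with deterministic lexicographic
tie-breaking; topological congruence between two trees on the same
leaves is quantified by a tanglegram (crossing minimization over
subtree rotations) plus normalized Robinson-Foulds distance, with a
leaf-permutation null to judge significance.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: List[str]
    values: np.ndarray
    source: str = "profile"           # k2p | ani | profile
    undefined_pairs: List[Tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("values shape does not match labels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels")
        finite = np.isfinite(v)
        if not self.undefined_pairs and not finite.all():
            raise ValueError("non-finite distances without undefined_pairs record")
        if (v[finite] < 0).any():
            raise ValueError("distances must be non-negative")
        with np.errstate(invalid="ignore"):
            if not np.allclose(v, v.T, equal_nan=True):
                raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


# --------------------------------------------------------------------------
# distance constructors
# --------------------------------------------------------------------------

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_UNAMBIG = {"A", "C", "G", "T"}


def k2p_pair(s1: str, s2: str) -> float:
    """Kimura 2-parameter distance between two aligned sequences.

    d = -1/2 ln((1-2P-Q) * sqrt(1-2Q)) with P and Q the transition and
    transversion proportions over sites where both sequences carry an
    unambiguous base (pairwise deletion).  Returns NaN when the log
    argument is non-positive (distance undefined — too divergent).
    """
    if len(s1) != len(s2):
        raise ValueError("sequences must be aligned to equal length")
    usable = transitions = transversions = 0
    for a, b in zip(s1.upper(), s2.upper()):
        if a not in _UNAMBIG or b not in _UNAMBIG:
            continue
        usable += 1
        if a == b:
            continue
        if (a in _PURINES) == (b in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if usable == 0:
        raise ValueError("no comparable (both unambiguous) sites")
    P = transitions / usable
    Q = transversions / usable
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return float("nan")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(alignment: Dict[str, str]) -> DistanceMatrix:
    """All-pairs K2P distances from a name -> aligned sequence mapping."""
    labels = list(alignment)
    n = len(labels)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    v = np.zeros((n, n))
    undefined: List[Tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = k2p_pair(alignment[labels[i]], alignment[labels[j]])
            if math.isnan(d):
                undefined.append((labels[i], labels[j]))
            v[i, j] = v[j, i] = d
    return DistanceMatrix(labels, v, source="k2p", undefined_pairs=undefined)


def distance_from_identity(matrix) -> DistanceMatrix:
    """Linear ANI-to-distance transform d = (100 - identity) / 100."""
    v = (100.0 - matrix.values()) / 100.0
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(matrix.labels, v, source="ani")


def distance_from_profile(rows: pd.DataFrame, metric: str = "euclidean_standardized") -> DistanceMatrix:
    """Distances between row profiles (strains x features).

    Continuous profiles (killing-zone diameters): per-column
    standardization then Euclidean distance; zero-variance columns are
    dropped with a warning.  Binary profiles (gene/BGC complements):
    Jaccard distance.
    """
    if rows.isna().any().any():
        raise ValueError("profile matrix has missing cells")
    labels = list(rows.index)
    if metric == "euclidean_standardized":
        x = rows.to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance column(s) before standardization"
            )
        if not keep.any():
            v = np.zeros((len(labels), len(labels)))
            return DistanceMatrix(labels, v, source="profile")
        z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
        v = squareform(pdist(z, metric="euclidean"))
    elif metric == "jaccard":
        x = rows.to_numpy(dtype=bool)
        v = squareform(pdist(x, metric="jaccard"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(labels, v, source="profile")


# --------------------------------------------------------------------------
# neighbor joining
# --------------------------------------------------------------------------

def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Joins the pair minimizing the Q criterion; exact ties are broken by
    the lexicographically smallest label pair (labels of the clusters'
    first members).  Negative branch lengths arising from non-additive
    input are clamped to zero.  On an additive matrix the output tree
    reproduces the input distances exactly.
    """
    if d.undefined_pairs:
        raise ValueError("cannot build a tree from undefined distances")
    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 labels")
    if n == 2:
        warnings.warn("fewer than 3 labels: returning trivial 2-leaf tree")
        half = d.values[0, 1] / 2.0
        return TreeNode.read([f"({labels[0]}:{half},{labels[1]}:{half});"])

    dist = d.values.astype(float).copy()
    nodes: List[TreeNode] = [TreeNode(name=lab) for lab in labels]
    # sort key per cluster: smallest leaf label inside it
    keys: List[str] = list(labels)
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sub = dist[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best: Optional[Tuple[str, str, int, int]] = None
        for a in range(r):
            for b in range(a + 1, r):
                if q[a, b] <= qmin + 1e-9 * max(1.0, abs(qmin)):
                    ka, kb = keys[active[a]], keys[active[b]]
                    pair = (min(ka, kb), max(ka, kb), a, b)
                    if best is None or pair[:2] < best[:2]:
                        best = pair
        _, _, a, b = best
        i, j = active[a], active[b]
        dij = dist[i, j]
        li = 0.5 * dij + (row_sums[a] - row_sums[b]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # distances from the new node to every other active cluster
        new_row = np.zeros(dist.shape[0] + 1)
        for c in active:
            if c in (i, j):
                continue
            new_row[c] = 0.5 * (dist[i, c] + dist[j, c] - dij)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :-1] = new_row[:-1]
        dist[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [c for c in active if c not in (i, j)] + [len(nodes) - 1]

    # final three clusters join at an unrooted trifurcation
    i, j, k = active
    dij, dik, djk = dist[i, j], dist[i, k], dist[j, k]
    li = max(0.5 * (dij + dik - djk), 0.0)
    lj = max(0.5 * (dij + djk - dik), 0.0)
    lk = max(0.5 * (dik + djk - dij), 0.0)
    for node, length in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = length
    return TreeNode(children=[nodes[i], nodes[j], nodes[k]])


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances of a tree."""
    skdm = tree.tip_tip_distances()
    labels = list(skdm.ids)
    return DistanceMatrix(labels, np.asarray(skdm.data, dtype=float), source="profile")


# --------------------------------------------------------------------------
# bootstrap
# --------------------------------------------------------------------------

def _bipartitions(tree: TreeNode) -> Set[FrozenSet[str]]:
    """Non-trivial bipartitions, each canonicalized as the side not
    containing the lexicographically smallest leaf."""
    leaves = sorted(t.name for t in tree.tips())
    ref = leaves[0]
    full = frozenset(leaves)
    parts: Set[FrozenSet[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = full - side
        # trivial splits (one leaf on either side) carry no topology
        if 1 < len(side) < len(leaves) - 1:
            parts.add(side)
    return parts


def robinson_foulds(t1: TreeNode, t2: TreeNode, normalized: bool = True) -> float:
    """Symmetric-difference (Robinson-Foulds) distance between two trees
    on the same leaves; normalized by the total bipartition count."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    b1, b2 = _bipartitions(t1), _bipartitions(t2)
    raw = len(b1 ^ b2)
    if not normalized:
        return float(raw)
    denom = len(b1) + len(b2)
    return raw / denom if denom else 0.0


def bootstrap_support(
    alignment: Dict[str, str],
    replicates: int = 500,
    seed: Optional[int] = None,
) -> TreeNode:
    """NJ tree from K2P distances with bootstrap support on internal nodes.

    Alignment columns are resampled with replacement; each replicate is
    rebuilt by NJ and internal edges of the full-data tree receive the
    percentage of usable replicates containing the same bipartition.
    Replicates with undefined distances are discarded (and excluded
    from the denominator).
    """
    base = neighbor_joining(k2p_distance(alignment))
    labels = list(alignment)
    length = len(next(iter(alignment.values())))
    arrays = {k: np.frombuffer(v.upper().encode(), dtype="S1") for k, v in alignment.items()}
    rng = np.random.default_rng(seed)
    counts: Dict[FrozenSet[str], int] = {bp: 0 for bp in _bipartitions(base)}
    used = 0
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        boot = {k: arrays[k][cols].tobytes().decode() for k in labels}
        dm = k2p_distance(boot)
        if dm.undefined_pairs:
            continue
        used += 1
        reps = _bipartitions(neighbor_joining(dm))
        for bp in counts:
            if bp in reps:
                counts[bp] += 1
    denom = max(used, 1)
    full = frozenset(labels)
    ref = min(labels)
    for node in base.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = full - side
        if side in counts:
            node.name = f"{100.0 * counts[side] / denom:.0f}"
    return base


# --------------------------------------------------------------------------
# tanglegram
# --------------------------------------------------------------------------

@dataclass
class TanglegramResult:
    tree1: TreeNode
    tree2: TreeNode
    order1: List[str]
    order2: List[str]
    crossings: int
    entanglement: float
    rf_distance: float


def count_crossings(order1: Sequence[str], order2: Sequence[str]) -> int:
    """Number of crossing connector pairs between two leaf orderings."""
    if set(order1) != set(order2):
        raise ValueError("orders must cover the same labels")
    pos2 = {lab: i for i, lab in enumerate(order2)}
    seq = [pos2[lab] for lab in order1]
    crossings = 0
    for i in range(len(seq)):
        for j in range(i + 1, len(seq)):
            if seq[i] > seq[j]:
                crossings += 1
    return crossings


def _leaf_order(tree: TreeNode) -> List[str]:
    return [t.name for t in tree.tips()]


def _hill_climb(tree: TreeNode, other_order: List[str]) -> Tuple[TreeNode, int]:
    """Greedy subtree-rotation pass: flip any internal node's children
    whenever it reduces crossings against a fixed opposite order."""
    best = count_crossings(_leaf_order(tree), other_order)
    improved = True
    while improved:
        improved = False
        for node in list(tree.non_tips(include_self=True)):
            if len(node.children) < 2:
                continue
            node.children.reverse()
            trial = count_crossings(_leaf_order(tree), other_order)
            if trial < best:
                best = trial
                improved = True
            else:
                node.children.reverse()
    return tree, best


def tanglegram(
    t1: TreeNode,
    t2: TreeNode,
    seed: Optional[int] = 0,
    baselines: int = 100,
) -> TanglegramResult:
    """Untangle two trees on the same leaves and score their congruence.

    Alternating subtree-rotation hill climbs minimize the number of
    crossing connectors; the entanglement score normalizes the final
    crossing count by the maximum over ``baselines`` random leaf-order
    pairings (0 = perfectly congruent after rotation).  Normalized
    Robinson-Foulds distance is reported alongside.
    """
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError(f"leaf sets differ: {sorted(l1 ^ l2)}")
    a = t1.copy()
    b = t2.copy()
    prev = None
    best = count_crossings(_leaf_order(a), _leaf_order(b))
    while prev is None or best < prev:
        prev = best
        a, _ = _hill_climb(a, _leaf_order(b))
        b, best = _hill_climb(b, _leaf_order(a))
    rng = np.random.default_rng(seed)
    labels = sorted(l1)
    worst = 0
    for _ in range(baselines):
        o1 = list(rng.permutation(labels))
        o2 = list(rng.permutation(labels))
        worst = max(worst, count_crossings(o1, o2))
    ent = best / worst if worst else 0.0
    return TanglegramResult(
        tree1=a,
        tree2=b,
        order1=_leaf_order(a),
        order2=_leaf_order(b),
        crossings=best,
        entanglement=ent,
        rf_distance=robinson_foulds(a, b),
    )


def entanglement_null_test(
    t1: TreeNode,
    t2: TreeNode,
    permutations: int = 99,
    seed: Optional[int] = 0,
) -> dict:
    """Permutation test: is the observed entanglement lower than that of
    trees with randomly shuffled leaf labels?

    The null resamples t2 with its leaf labels permuted; the p-value is
    the fraction of null draws (plus one) whose optimized crossing
    count is <= the observed one.  A large p means the two trees are
    statistically indistinguishable from unrelated trees.
    """
    rng = np.random.default_rng(seed)
    observed = tanglegram(t1, t2, seed=seed).crossings
    labels = sorted(t.name for t in t2.tips())
    at_or_below = 0
    for _ in range(permutations):
        shuffled = t2.copy()
        perm = dict(zip(labels, rng.permutation(labels)))
        for tip in shuffled.tips():
            tip.name = perm[tip.name]
        null = tanglegram(t1, shuffled, seed=seed).crossings
        if null <= observed:
            at_or_below += 1
    p = (at_or_below + 1) / (permutations + 1)
    return {"observed_crossings": observed, "p_value": p, "permutations": permutations}
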