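"""Tiered genomospecies delimitation from ANI / dDDH matrices.

Genome-similarity thresholds in conventional use: an ANI of >= 95%
places two genomes in the same species, <= 92% in different species
(< 75% in different genera), and the intermediate 93-94% band marks
separate subspecies of one species.  dDDH cut-offs of > 70 / > 50 /
> 30% are reported side by side.  Grouping is single linkage
(connected components of the "value >= t" graph); values that fall in
the undefined (92, 93) gap or that contradict the transitive grouping
are reported as conflicts rather than silently adjudicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .config import AnalysisConfig, DEFAULT_CONFIG


class IdentityMatrix:
    """Symmetric pairwise percentage matrix (ANI or dDDH), diagonal 100."""

    def __init__(self, data: pd.DataFrame, kind: str = "ANI"):
        if kind not in ("ANI", "dDDH"):
            raise ValueError(f"kind must be 'ANI' or 'dDDH', got {kind!r}")
        if data.shape[0] != data.shape[1]:
            raise ValueError(f"identity matrix must be square, got {data.shape}")
        if list(data.index) != list(data.columns):
            raise ValueError("row and column labels must match (in order)")
        if data.index.duplicated().any():
            raise ValueError("duplicate genome labels")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValueError("identity matrix contains missing values")
        if (values < 0).any() or (values > 100).any():
            raise ValueError("identity values must lie in [0, 100]")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("matrix must be symmetric (use io.read_identity_matrix to average)")
        np.fill_diagonal(values, 100.0)
        self._df = pd.DataFrame(values, index=data.index, columns=data.columns)
        self.kind = kind

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def labels(self) -> List[str]:
        return list(self._df.index)

    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def __repr__(self) -> str:
        return f"IdentityMatrix(kind={self.kind}, n={len(self.labels)})"


@dataclass
class SpeciesGrouping:
    """Result of tiered delimitation on an ANI matrix."""

    genus_ok: bool
    species: List[List[str]]            # clusters after subspecies merging
    subspecies: List[List[List[str]]]   # per species: its >=95% sub-clusters
    species_count_range: Tuple[int, int]  # (after merging, before merging)
    conflicts: List[dict] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.species)


def _components(values: np.ndarray, labels: Sequence[str], mask: np.ndarray) -> List[List[str]]:
    adj = csr_matrix(mask)
    n_comp, assign = connected_components(adj, directed=False)
    comps: List[List[str]] = [[] for _ in range(n_comp)]
    for lab, c in zip(labels, assign):
        comps[c].append(lab)
    # deterministic order: by first member's position in the input
    comps.sort(key=lambda c: labels.index(c[0]) if c else 0)
    return comps


def cluster_at_threshold(matrix: IdentityMatrix, t: float, strict: bool = False) -> List[List[str]]:
    """Single-linkage clusters: connected components of the graph with
    edges where the pairwise value >= t (or > t when ``strict``)."""
    if not 0 < t <= 100:
        raise ValueError("threshold must lie in (0, 100]")
    v = matrix.values()
    mask = (v > t) if strict else (v >= t)
    np.fill_diagonal(mask, True)
    return _components(v, matrix.labels, mask)


def delimit(matrix: IdentityMatrix, config: AnalysisConfig = DEFAULT_CONFIG) -> SpeciesGrouping:
    """Tiered ANI delimitation.

    Definite-species clusters are components at >= ani_species_high
    (95%); clusters any of whose inter-cluster pairs fall in the
    subspecies band [93, 95) are merged into one species whose member
    clusters become subspecies.  genus_ok is true iff every pair is at
    or above the genus floor (75%).  Conflict records cover (a) pairs
    in the unnamed (92, 93) gap and (b) within-species pairs at or
    below the different-species cut-off (92%), which contradict the
    transitive grouping.
    """
    if matrix.kind != "ANI":
        raise ValueError(f"delimit requires an ANI matrix, got kind={matrix.kind!r}")
    labels = matrix.labels
    v = matrix.values()
    n = len(labels)
    genus_ok = bool((v >= config.ani_genus_min).all())

    tight = cluster_at_threshold(matrix, config.ani_species_high)
    n_before = len(tight)

    # merge tight clusters linked by any pair inside the subspecies band
    lo, hi = config.subspecies_band
    idx_of = {lab: i for i, lab in enumerate(labels)}
    k = len(tight)
    link = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(link, True)
    for a in range(k):
        for b in range(a + 1, k):
            ia = [idx_of[x] for x in tight[a]]
            ib = [idx_of[x] for x in tight[b]]
            block = v[np.ix_(ia, ib)]
            if ((block >= lo) & (block < hi)).any():
                link[a, b] = link[b, a] = True
    n_comp, assign = connected_components(csr_matrix(link), directed=False)
    merged: List[List[List[str]]] = [[] for _ in range(n_comp)]
    for ci, comp in zip(assign, tight):
        merged[ci].append(comp)
    merged.sort(key=lambda subs: labels.index(subs[0][0]))
    species = [[g for sub in subs for g in sub] for subs in merged]

    conflicts: List[dict] = []
    sp_of = {g: si for si, sp in enumerate(species) for g in sp}
    for i in range(n):
        for j in range(i + 1, n):
            val = v[i, j]
            if config.ani_species_low < val < lo:
                conflicts.append(
                    {"pair": (labels[i], labels[j]), "value": float(val), "reason": "gap_92_93"}
                )
            elif val <= config.ani_species_low and sp_of[labels[i]] == sp_of[labels[j]]:
                conflicts.append(
                    {"pair": (labels[i], labels[j]), "value": float(val),
                     "reason": "within_species_below_species_cutoff"}
                )

    return SpeciesGrouping(
        genus_ok=genus_ok,
        species=species,
        subspecies=merged,
        species_count_range=(len(species), n_before),
        conflicts=conflicts,
    )


def ddh_groups(
    matrix: IdentityMatrix,
    thresholds: Sequence[float] = (70.0, 50.0, 30.0),
) -> Dict[float, List[List[str]]]:
    """Single-linkage components at each strict-greater dDDH cut-off."""
    if matrix.kind != "dDDH":
        raise ValueError(f"ddh_groups requires a dDDH matrix, got kind={matrix.kind!r}")
    return {float(t): cluster_at_threshold(matrix, t, strict=True) for t in thresholds}


def rand_index(a: Sequence[Sequence[str]], b: Sequence[Sequence[str]]) -> float:
    """Pair-counting agreement between two partitions of one label set."""
    la = {g: i for i, cl in enumerate(a) for g in cl}
    lb = {g: i for i, cl in enumerate(b) for g in cl}
    if set(la) != set(lb):
        raise ValueError("partitions cover different label sets")
    labels = sorted(la)
    agree = 0
    total = 0
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            total += 1
            same_a = la[labels[i]] == la[labels[j]]
            same_b = lb[labels[i]] == lb[labels[j]]
            if same_a == same_b:
                agree += 1
    return 1.0 if total == 0 else agree / total


def compare_groupings(a: Sequence[Sequence[str]], b: Sequence[Sequence[str]]) -> dict:
    """Concordance of two partitions: Rand index plus the genomes whose
    cluster (as a member set) differs between the partitions."""
    cluster_a = {g: frozenset(cl) for cl in a for g in cl}
    cluster_b = {g: frozenset(cl) for cl in b for g in cl}
    if set(cluster_a) != set(cluster_b):
        missing = set(cluster_a) ^ set(cluster_b)
        raise ValueError(f"partitions cover different label sets: {sorted(missing)}")
    differing = sorted(g for g in cluster_a if cluster_a[g] != cluster_b[g])
    return {"rand_index": rand_index(a, b), "differing_genomes": differing}
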