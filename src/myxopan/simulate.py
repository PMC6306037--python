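"""Synthetic inputs with known ground truth for every pipeline stage.

Raw myxobacterial genome collections are large external downloads, so
each analysis stage gets a generator that emulates the relevant input
with planted, recoverable structure:

* ``simulate_pangenome``   — presence/absence matrices whose rarefaction
  follows a Heaps power law with tunable kappa and gamma;
* ``simulate_identity_matrix`` — symmetric ANI/dDDH matrices with planted
  genus/species/subspecies block structure on the conventional tiers;
* ``simulate_annotations`` — per-gene COG letters with planted
  accessory-set enrichment;
* ``simulate_predation``   — killing-zone matrices with tunable
  congruence to a reference tree (Brownian signal on the tree);
* ``simulate_contigs``     — draft-assembly FASTA with SPAdes-style
  coverage headers for the assembly-statistics stage.

All generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .delimit import IdentityMatrix
from .pam import PanPartition, PresenceAbsenceMatrix


@dataclass
class SyntheticTruth:
    """Planted parameters of a synthetic dataset."""

    heaps_kappa: Optional[float] = None
    heaps_gamma: Optional[float] = None
    core_size: Optional[int] = None
    group_labels: Dict[str, Tuple[str, str, str]] = field(default_factory=dict)
    enriched_categories: Dict[str, float] = field(default_factory=dict)
    predation_congruence: Optional[float] = None
    rng_seed: Optional[int] = None

    def n_species(self) -> int:
        return len({(g, s) for g, s, _ in self.group_labels.values()})

    def n_subspecies_groups(self) -> int:
        return len(set(self.group_labels.values()))


# --------------------------------------------------------------------------
# presence/absence
# --------------------------------------------------------------------------

def simulate_pangenome(
    n_genomes: int = 24,
    core_size: int = 2486,
    kappa: float = 8000.0,
    gamma: float = 0.55,
    retention: float = 0.6,
    seed: Optional[int] = None,
) -> Tuple[PresenceAbsenceMatrix, SyntheticTruth]:
    """Open pan-genome presence/absence matrix with Heaps-law growth.

    Core genes are present in every genome.  Genome i (in simulation
    order) contributes Poisson(kappa*gamma*i^(gamma-1)) previously
    unseen accessory genes — the derivative of the Heaps curve, so the
    expected pan-size trajectory follows kappa*n^gamma up to core
    adjustments — and re-samples each previously seen accessory gene
    with probability retention * (its frequency among earlier genomes).
    Retention controls how cloud-heavy the gene frequency spectrum is.
    """
    if n_genomes < 2:
        raise ValueError("n_genomes must be >= 2")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1) for an open pan-genome")
    if not 0 < retention <= 1:
        raise ValueError("retention must lie in (0, 1]")
    if core_size < 0:
        raise ValueError("core_size must be non-negative")

    rng = np.random.default_rng(seed)
    counts = np.zeros(0, dtype=np.int64)          # accessory gene -> #genomes so far
    membership: List[np.ndarray] = []              # per genome: accessory gene indices
    for i in range(1, n_genomes + 1):
        if i == 1:
            resampled = np.empty(0, dtype=np.int64)
        else:
            p = retention * counts / (i - 1)
            resampled = np.nonzero(rng.random(len(counts)) < p)[0]
        n_new = rng.poisson(kappa * gamma * i ** (gamma - 1.0))
        new = np.arange(len(counts), len(counts) + n_new, dtype=np.int64)
        counts = np.concatenate([counts, np.zeros(n_new, dtype=np.int64)])
        present = np.concatenate([resampled, new])
        counts[present] += 1
        membership.append(present)

    n_acc = len(counts)
    genome_names = [f"G{i:02d}" for i in range(1, n_genomes + 1)]
    data = np.zeros((core_size + n_acc, n_genomes), dtype=bool)
    data[:core_size, :] = True
    for j, present in enumerate(membership):
        data[core_size + present, j] = True
    index = [f"core_{i:05d}" for i in range(core_size)] + [
        f"acc_{i:06d}" for i in range(n_acc)
    ]
    matrix = PresenceAbsenceMatrix(pd.DataFrame(data, index=index, columns=genome_names))
    truth = SyntheticTruth(
        heaps_kappa=kappa, heaps_gamma=gamma, core_size=core_size, rng_seed=seed
    )
    return matrix, truth


# --------------------------------------------------------------------------
# identity matrices
# --------------------------------------------------------------------------

def _validate_ranges(ranges: Sequence[Tuple[float, float]], noise_sd: float) -> None:
    for lo, hi in ranges:
        if not 0 <= lo < hi <= 100:
            raise ValueError(f"range ({lo}, {hi}) is not a valid percentage interval")
        if hi - lo <= 6 * noise_sd:
            raise ValueError(
                f"range ({lo}, {hi}) narrower than 6*noise_sd={6 * noise_sd}; "
                "noise could not be kept inside it"
            )
    for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
        if hi1 + 3 * noise_sd >= lo2 - 3 * noise_sd:
            raise ValueError(
                f"ranges ({lo1},{hi1}) and ({lo2},{hi2}) can overlap after +/-3*noise_sd={3*noise_sd}"
            )
    if ranges[-1][1] > 100:
        raise ValueError("top range exceeds 100%")


def simulate_identity_matrix(
    group_sizes: Sequence[int],
    subspecies_splits: Optional[Dict[int, Sequence[int]]] = None,
    genus_groups: Optional[Sequence[str]] = None,
    between_genus: Tuple[float, float] = (80.0, 85.0),
    between_species: Tuple[float, float] = (86.0, 91.5),
    subspecies_band: Tuple[float, float] = (93.0, 94.5),
    within: Tuple[float, float] = (95.5, 99.0),
    noise_sd: float = 0.1,
    kind: str = "ANI",
    seed: Optional[int] = None,
) -> Tuple[IdentityMatrix, SyntheticTruth]:
    """Symmetric identity matrix with planted block structure.

    ``group_sizes[k]`` genomes form species k; ``subspecies_splits``
    optionally divides a species into subspecies whose between-
    subspecies pairs fall in ``subspecies_band``.  ``genus_groups``
    assigns each species to a genus-level group (pairs across groups
    draw from ``between_genus``).  Every pairwise value is uniform in
    the range its true relationship dictates plus Gaussian noise
    truncated at +/-3 sd; range validation guarantees noise can never
    move a pair across a tier boundary, keeping the planted truth
    unambiguous.
    """
    if any(s < 1 for s in group_sizes):
        raise ValueError("species sizes must be >= 1")
    subspecies_splits = subspecies_splits or {}
    for k, split in subspecies_splits.items():
        if sum(split) != group_sizes[k]:
            raise ValueError(f"subspecies split {split} does not sum to species size {group_sizes[k]}")
    genus_groups = list(genus_groups) if genus_groups is not None else ["A"] * len(group_sizes)
    if len(genus_groups) != len(group_sizes):
        raise ValueError("genus_groups must have one entry per species")
    # only validate separation between levels the design actually uses
    used = []
    if len(set(genus_groups)) > 1:
        used.append(between_genus)
    if len(group_sizes) > 1:
        used.append(between_species)
    if subspecies_splits:
        used.append(subspecies_band)
    used.append(within)
    _validate_ranges(used, noise_sd)

    labels: List[str] = []
    truth_labels: Dict[str, Tuple[str, str, str]] = {}
    for k, size in enumerate(group_sizes):
        split = list(subspecies_splits.get(k, [size]))
        member = 0
        for sub_i, sub_size in enumerate(split):
            for _ in range(sub_size):
                member += 1
                name = f"G{len(labels) + 1:02d}"
                labels.append(name)
                truth_labels[name] = (genus_groups[k], f"sp{k + 1}", f"ssp{sub_i + 1}")

    n = len(labels)
    rng = np.random.default_rng(seed)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            gi, si, ui = truth_labels[labels[i]]
            gj, sj, uj = truth_labels[labels[j]]
            if gi != gj:
                lo, hi = between_genus
            elif si != sj:
                lo, hi = between_species
            elif ui != uj:
                lo, hi = subspecies_band
            else:
                lo, hi = within
            # keep base + truncated noise strictly inside the range so a
            # draw can never cross a tier boundary
            base = rng.uniform(lo + 3 * noise_sd, hi - 3 * noise_sd)
            noise = np.clip(rng.normal(0.0, noise_sd), -3 * noise_sd, 3 * noise_sd) if noise_sd > 0 else 0.0
            values[i, j] = values[j, i] = base + noise
    matrix = IdentityMatrix(pd.DataFrame(values, index=labels, columns=labels), kind=kind)
    truth = SyntheticTruth(group_labels=truth_labels, rng_seed=seed)
    return matrix, truth


def nine_species_preset(
    seed: Optional[int] = None, kind: str = "ANI", **kwargs
) -> Tuple[IdentityMatrix, SyntheticTruth]:
    """24-genome preset: nine species across two genus-level groups, two
    of the species split into two subspecies each (11 groups at the
    same-species tier, 9 after subspecies merging)."""
    return simulate_identity_matrix(
        group_sizes=[11, 3, 1, 1, 1, 2, 1, 1, 3],
        subspecies_splits={0: [5, 6], 5: [1, 1]},
        genus_groups=["A", "A", "A", "A", "A", "B", "B", "B", "B"],
        kind=kind,
        seed=seed,
        **kwargs,
    )


# --------------------------------------------------------------------------
# annotations
# --------------------------------------------------------------------------

def simulate_annotations(
    partition: PanPartition,
    base_profile: Dict[str, float],
    planted: Optional[Dict[str, float]] = None,
    annotated_fraction: float = 0.9,
    seed: Optional[int] = None,
) -> Tuple[Dict[str, str], SyntheticTruth]:
    """Per-gene COG letters with planted accessory enrichment.

    Core genes draw their category from ``base_profile`` (percentages,
    renormalized); accessory genes draw from the same profile with
    each planted category's weight multiplied by 2**fold, renormalized.
    A fraction of genes is left unannotated (empty string).
    """
    planted = planted or {}
    if not base_profile:
        raise ValueError("base_profile is empty")
    if sum(base_profile.values()) > 100 + 1e-9:
        raise ValueError("base_profile sums to more than 100%")
    missing = [c for c in planted if c not in base_profile]
    if missing:
        raise ValueError(f"planted categories absent from base_profile: {missing}")
    if not 0 < annotated_fraction <= 1:
        raise ValueError("annotated_fraction must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    cats = sorted(base_profile)
    base = np.array([base_profile[c] for c in cats], dtype=float)
    base = base / base.sum()
    tilted = base * np.array([2.0 ** planted.get(c, 0.0) for c in cats])
    tilted = tilted / tilted.sum()

    table: Dict[str, str] = {}
    for gene_ids, probs in (
        (partition.core_orthogroups, base),
        (partition.accessory_orthogroups, tilted),
    ):
        if not gene_ids:
            continue
        draws = rng.choice(len(cats), size=len(gene_ids), p=probs)
        annotated = rng.random(len(gene_ids)) < annotated_fraction
        for g, d, ok in zip(gene_ids, draws, annotated):
            table[g] = cats[d] if ok else ""
    truth = SyntheticTruth(enriched_categories=dict(planted), rng_seed=seed)
    return table, truth


# --------------------------------------------------------------------------
# predation
# --------------------------------------------------------------------------

def _brownian_tips(tree: TreeNode, rng: np.random.Generator) -> Dict[str, float]:
    """One Brownian-motion draw down the tree; tip name -> trait value."""
    values: Dict[int, float] = {id(tree): 0.0}
    out: Dict[str, float] = {}
    for node in tree.preorder(include_self=False):
        length = node.length if node.length is not None else 0.0
        v = values[id(node.parent)] + rng.normal(0.0, math.sqrt(max(length, 0.0)))
        values[id(node)] = v
        if node.is_tip():
            out[node.name] = v
    return out


def simulate_predation(
    tree: TreeNode,
    n_prey: int = 10,
    congruence: float = 1.0,
    base_mm: float = 10.0,
    scale_mm: float = 4.0,
    seed: Optional[int] = None,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Strain x prey killing-zone diameters (mm) with tunable tree signal.

    Per prey, a Brownian trait on the tree (standardized across
    strains) is mixed with i.i.d. standard normal noise with weight
    ``congruence``; diameters are base + scale * signal, clamped at 0.
    congruence=1 makes predation profiles perfectly tree-structured;
    congruence=0 makes them independent of the tree.
    """
    tips = [t.name for t in tree.tips()]
    if not tips:
        raise ValueError("tree has no leaves")
    if not 0 <= congruence <= 1:
        raise ValueError("congruence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cols = {}
    for p in range(n_prey):
        signal = _brownian_tips(tree, rng)
        z = np.array([signal[t] for t in tips])
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
        noise = rng.standard_normal(len(tips))
        mixed = congruence * z + (1.0 - congruence) * noise
        cols[f"prey{p + 1:02d}"] = np.clip(base_mm + scale_mm * mixed, 0.0, None)
    frame = pd.DataFrame(cols, index=tips)
    truth = SyntheticTruth(predation_congruence=congruence, rng_seed=seed)
    return frame, truth


def random_tree(labels: Sequence[str], seed: Optional[int] = None) -> TreeNode:
    """Random binary tree over ``labels`` with exponential branch lengths."""
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=lab, length=float(rng.exponential(0.1)) + 0.01) for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b], length=float(rng.exponential(0.1)) + 0.01)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# --------------------------------------------------------------------------
# contigs
# --------------------------------------------------------------------------

def simulate_contigs(
    genome_size: int,
    n_contigs: int,
    coverage_range: Tuple[float, float] = (10.0, 150.0),
    gc: float = 0.699,
    seed: Optional[int] = None,
) -> List[SeqRecord]:
    """Draft assembly: contig lengths summing to ``genome_size``, with
    SPAdes-style ``NODE_<i>_length_<L>_cov_<C>`` headers and the
    requested GC composition."""
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if genome_size < n_contigs:
        raise ValueError("cannot split genome_size bp into more contigs than bases")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be a fraction in [0, 1]")
    lo, hi = coverage_range
    if not 0 <= lo <= hi:
        raise ValueError("invalid coverage_range")
    rng = np.random.default_rng(seed)
    # random composition: each contig gets >= 1 bp
    extra = rng.multinomial(genome_size - n_contigs, np.full(n_contigs, 1.0 / n_contigs))
    lengths = extra + 1
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    for i, length in enumerate(lengths, start=1):
        seq = "".join(rng.choice(bases, size=int(length), p=probs))
        cov = rng.uniform(lo, hi)
        name = f"NODE_{i}_length_{length}_cov_{cov:.1f}"
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    return records
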