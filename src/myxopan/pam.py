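"""Gene presence/absence matrices and core/accessory tier partitioning.

The presence/absence matrix (orthogroups x genomes, boolean) is the
central object of pan-genome analysis: one row per orthologous gene
family, one column per genome, cell true iff the genome carries at
least one member of the family.  Tiering follows the Roary convention:
hard core (>=99% of genomes), soft core (95-99%), shell (15-95%) and
cloud (<15%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG

TIERS = ("hard_core", "soft_core", "shell", "cloud")


class PresenceAbsenceMatrix:
    """Boolean incidence of orthogroups (rows) across genomes (columns).

    Wraps a pandas DataFrame with unique orthogroup and genome labels.
    Rows absent from every genome are rejected: an orthogroup observed
    nowhere is not part of the pan-genome.
    """

    def __init__(self, data: pd.DataFrame, *, _allow_single: bool = False):
        if data.shape[1] < 2 and not _allow_single:
            raise ValueError("a presence/absence matrix needs at least 2 genomes")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate genome names: {dups}")
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate orthogroup names: {dups}")
        values = data.to_numpy()
        if values.dtype != bool:
            if not np.isin(values, [0, 1, True, False]).all():
                raise ValueError("presence/absence cells must be 0/1 or boolean")
            data = data.astype(bool)
        empty = ~data.any(axis=1)
        if empty.any():
            raise ValueError(
                f"orthogroups absent from every genome: {data.index[empty].tolist()[:5]}"
            )
        self._df = data

    # -- basic accessors -------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def genomes(self) -> List[str]:
        return list(self._df.columns)

    @property
    def orthogroups(self) -> List[str]:
        return list(self._df.index)

    @property
    def n_genomes(self) -> int:
        return self._df.shape[1]

    @property
    def pan_size(self) -> int:
        return self._df.shape[0]

    def values(self) -> np.ndarray:
        return self._df.to_numpy()

    def __eq__(self, other) -> bool:
        if not isinstance(other, PresenceAbsenceMatrix):
            return NotImplemented
        return self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"PresenceAbsenceMatrix({self.pan_size} orthogroups x {self.n_genomes} genomes)"

    # -- operations ------------------------------------------------------
    def presence_fractions(self) -> pd.Series:
        return self._df.sum(axis=1) / self.n_genomes

    def gene_counts_per_genome(self) -> pd.Series:
        return self._df.sum(axis=0)

    def subset(self, genome_ids: Sequence[str]) -> "PresenceAbsenceMatrix":
        """Restrict to the given genomes, dropping orthogroups absent
        from every retained genome (the pan shrinks accordingly)."""
        unknown = [g for g in genome_ids if g not in self._df.columns]
        if unknown:
            raise KeyError(f"unknown genome ids: {unknown}")
        sub = self._df.loc[:, list(genome_ids)]
        sub = sub.loc[sub.any(axis=1)]
        # a single-genome subset is a legal degenerate pan (its pan size
        # is that genome's gene count), so relax the 2-genome invariant
        return PresenceAbsenceMatrix(sub, _allow_single=sub.shape[1] == 1)


@dataclass
class PanPartition:
    """Tier assignment per orthogroup plus Table-style roll-up counts."""

    tiers: pd.Series                 # orthogroup -> tier name
    tier_counts: Dict[str, int]
    pan_size: int
    n_genomes: int
    mean_genes_per_genome: float
    per_genome_core_fraction: pd.Series   # percent of each genome's genes in the core
    core_orthogroups: List[str]
    accessory_orthogroups: List[str]

    @property
    def core_total(self) -> int:
        return self.tier_counts["hard_core"] + self.tier_counts["soft_core"]

    @property
    def accessory_total(self) -> int:
        return self.tier_counts["shell"] + self.tier_counts["cloud"]


def partition(matrix: PresenceAbsenceMatrix, config: AnalysisConfig = DEFAULT_CONFIG) -> PanPartition:
    """Assign each orthogroup to hard-core/soft-core/shell/cloud.

    With f the fraction of genomes carrying the orthogroup and
    (hard, soft, shell) the configured lower bounds:
    hard core f >= hard; soft core soft <= f < hard;
    shell shell <= f < soft; cloud f < shell.
    """
    hard, soft, shell = config.partition_thresholds
    frac = matrix.presence_fractions()
    tiers = pd.Series(
        np.select(
            [frac >= hard, frac >= soft, frac >= shell],
            ["hard_core", "soft_core", "shell"],
            default="cloud",
        ),
        index=frac.index,
        name="tier",
    )
    counts = {t: int((tiers == t).sum()) for t in TIERS}
    core_mask = tiers.isin(["hard_core", "soft_core"])
    core_ids = tiers.index[core_mask].tolist()
    acc_ids = tiers.index[~core_mask].tolist()

    genes_per_genome = matrix.gene_counts_per_genome()
    core_per_genome = matrix.df.loc[core_mask].sum(axis=0)
    per_genome_core = 100.0 * core_per_genome / genes_per_genome

    return PanPartition(
        tiers=tiers,
        tier_counts=counts,
        pan_size=matrix.pan_size,
        n_genomes=matrix.n_genomes,
        mean_genes_per_genome=float(genes_per_genome.mean()),
        per_genome_core_fraction=per_genome_core,
        core_orthogroups=core_ids,
        accessory_orthogroups=acc_ids,
    )


def summarize(part: PanPartition) -> Dict[str, float]:
    """Roll a partition up into the conventional pan-genome summary.

    Percentages of the pan are computed from the tier counts; the
    "average % of genes in the core" divides the core total by the mean
    genome gene count (core_total / mean_genes_per_genome * 100), which
    is how published pan-genome tables compute that row.
    """
    pan = part.pan_size
    core = part.core_total
    acc = part.accessory_total
    pct = lambda x: round(100.0 * x / pan, 1)
    return {
        "n_genomes": part.n_genomes,
        "pan_size": pan,
        "mean_genes_per_genome": round(part.mean_genes_per_genome, 1),
        "core_total": core,
        "core_pct_of_pan": pct(core),
        "hard_core": part.tier_counts["hard_core"],
        "hard_core_pct": pct(part.tier_counts["hard_core"]),
        "soft_core": part.tier_counts["soft_core"],
        "soft_core_pct": pct(part.tier_counts["soft_core"]),
        "accessory_total": acc,
        "accessory_pct_of_pan": pct(acc),
        "shell": part.tier_counts["shell"],
        "shell_pct": pct(part.tier_counts["shell"]),
        "cloud": part.tier_counts["cloud"],
        "cloud_pct": pct(part.tier_counts["cloud"]),
        "avg_pct_genes_in_core": round(100.0 * core / part.mean_genes_per_genome, 1),
    }
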