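"""Analysis configuration: the thresholds that drive every pipeline stage.

The defaults encode the conventional cut-offs used for bacterial
pan-genome tiering (Roary's hard/soft/shell/cloud percentages), ANI- and
dDDH-based genomospecies delimitation, COG enrichment calling, and the
assembly coverage filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass(frozen=True)
class AnalysisConfig:
    """Bundle of thresholds shared across pipeline stages.

    Attributes
    ----------
    partition_thresholds : (float, float, float)
        Lower presence-fraction bounds for the hard-core, soft-core and
        shell tiers (cloud is everything below the shell bound).
        Defaults: hard >= 0.99, soft >= 0.95, shell >= 0.15.
    ani_genus_min : float
        Pairs below this ANI (%) indicate different genera (default 75).
    ani_species_low : float
        Pairs at or below this ANI (%) indicate different species
        (default 92).
    ani_species_high : float
        Pairs at or above this ANI (%) indicate the same species
        (default 95).
    subspecies_band : (float, float)
        ANI interval [low, high) read as "same species, different
        subspecies" (default [93, 95)).
    ddh_thresholds : (float, float, float)
        dDDH strict-greater cut-offs reported side by side (70, 50, 30).
    enrichment_log2_cutoff : float
        |log2 fold| that must be exceeded for an enrichment call
        (default 1).
    enrichment_abundance_cutoff : float
        Relative abundance (%) the favored set must exceed (default 2).
    rarefaction_permutations : int
        Genome orderings sampled per rarefaction (default 100).
    rng_seed : int
        Seed for all stochastic stages.
    coverage_min : float
        Minimum fold coverage for a contig to be retained (default 7).
    """

    partition_thresholds: Tuple[float, float, float] = (0.99, 0.95, 0.15)
    ani_genus_min: float = 75.0
    ani_species_low: float = 92.0
    ani_species_high: float = 95.0
    subspecies_band: Tuple[float, float] = (93.0, 95.0)
    ddh_thresholds: Tuple[float, float, float] = (70.0, 50.0, 30.0)
    enrichment_log2_cutoff: float = 1.0
    enrichment_abundance_cutoff: float = 2.0
    rarefaction_permutations: int = 100
    rng_seed: int = 0
    coverage_min: float = 7.0

    def __post_init__(self) -> None:
        hard, soft, shell = self.partition_thresholds
        if not (0.0 <= shell < soft < hard <= 1.0):
            raise ValueError(
                "partition_thresholds must satisfy 0 <= shell < soft < hard <= 1, "
                f"got {self.partition_thresholds}"
            )
        for name in ("ani_genus_min", "ani_species_low", "ani_species_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {v}")
        if not self.ani_species_high > self.ani_species_low:
            raise ValueError("ani_species_high must exceed ani_species_low")
        lo, hi = self.subspecies_band
        if not (0.0 <= lo < hi <= 100.0):
            raise ValueError(f"subspecies_band must be an interval in [0, 100], got {self.subspecies_band}")
        if any(not 0.0 <= t <= 100.0 for t in self.ddh_thresholds):
            raise ValueError("ddh_thresholds must lie in [0, 100]")
        if self.rarefaction_permutations < 1:
            raise ValueError("rarefaction_permutations must be >= 1")
        if self.coverage_min < 0:
            raise ValueError("coverage_min must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_CONFIG = AnalysisConfig()
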