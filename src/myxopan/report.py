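"""Aggregated run report: one machine-readable summary of all stages.

The report mirrors the shape of a published pan-genome summary table:
tier counts and percentages, Heaps-fit extrapolations at chosen genome
counts, the 1/n core extrapolation, the tiered species delimitation,
core-vs-accessory COG enrichment and the mean BGC burden.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG
from .delimit import IdentityMatrix, compare_groupings, ddh_groups, delimit
from .enrichment import cog_profile, compare_profiles
from .openness import (
    extrapolate_pan,
    fit_core_inverse,
    fit_heaps,
    new_genes,
    novelty_horizon,
    rarefy,
)
from .pam import PresenceAbsenceMatrix, partition, summarize


def run_report(
    matrix: PresenceAbsenceMatrix,
    ani: Optional[IdentityMatrix] = None,
    ddh: Optional[IdentityMatrix] = None,
    annotations: Optional[Dict[str, str]] = None,
    bgc_counts: Optional[pd.Series] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
    extrapolation_ns: Sequence[int] = (101, 501, 1001),
    novelty_threshold: int = 100,
) -> dict:
    """Run every applicable stage and aggregate the results."""
    report: dict = {}

    part = partition(matrix, config)
    report["partition"] = summarize(part)

    rare = rarefy(matrix, config.rarefaction_permutations, config.rng_seed)
    heaps = fit_heaps(rare)
    core_fit = fit_core_inverse(rare)
    openness = {
        "kappa": heaps.kappa,
        "gamma": heaps.gamma,
        "open": heaps.is_open,
        "permutations": rare.permutations,
        "extrapolated_pan": {
            str(n): {"pan": extrapolate_pan(heaps, n), "new_genes": new_genes(heaps, n)}
            for n in extrapolation_ns
        },
        "novelty_horizon": {
            "threshold": novelty_threshold,
            "n": novelty_horizon(heaps, novelty_threshold),
        },
        "core_at_infinity": core_fit.intercept,
        "core_at_infinity_pct_of_core": (
            round(100.0 * core_fit.intercept / part.core_total, 1) if part.core_total else None
        ),
    }
    if part.core_total:
        openness["core_predicted_accessory_pct"] = round(
            100.0 * (part.core_total - core_fit.intercept) / part.core_total, 1
        )
    report["openness"] = openness

    if ani is not None:
        grouping = delimit(ani, config)
        report["delimitation"] = {
            "genus_ok": grouping.genus_ok,
            "species_count_range": list(grouping.species_count_range),
            "species": grouping.species,
            "n_conflicts": len(grouping.conflicts),
        }
        if ddh is not None:
            groups = ddh_groups(ddh, config.ddh_thresholds)
            report["ddh_groups"] = {str(t): g for t, g in groups.items()}
            # the loosest dDDH tier corresponds to the merged species tier
            loose = min(config.ddh_thresholds)
            report["ani_vs_ddh_rand"] = compare_groupings(
                grouping.species, groups[float(loose)]
            )["rand_index"]

    if annotations is not None:
        core_profile = cog_profile(annotations, part.core_orthogroups)
        acc_profile = cog_profile(annotations, part.accessory_orthogroups)
        result = compare_profiles(acc_profile, core_profile, config)
        report["enrichment"] = {
            "accessory_enriched": result.enriched,
            "core_enriched": result.impoverished,
        }

    if bgc_counts is not None:
        report["bgc"] = {
            "total": int(bgc_counts.sum()),
            "n_genomes": int(len(bgc_counts)),
            "mean_per_genome": round(float(bgc_counts.sum()) / len(bgc_counts)),
        }

    return report
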