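"""COG-category profiles and core-vs-accessory enrichment calls.

A profile gives each single-letter COG functional category its
relative abundance (percent of annotated genes in a gene set;
multi-letter assignments are split fractionally so abundances sum to
100).  Two profiles are compared by log2 ratio of abundances; a
category is called enriched in a set when the ratio exceeds the log2
cutoff (default 1) AND the favored set's abundance exceeds the
abundance gate (default 2%).  This is the descriptive fold/abundance
filter used in pan-proteome comparisons, not a significance test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

from .config import AnalysisConfig, DEFAULT_CONFIG


@dataclass
class COGProfile:
    """Relative COG-category abundances (%) of one gene set."""

    abundances: Dict[str, float]    # category letter -> percent of annotated genes
    set_size: int                   # genes in the set (annotated or not)
    unannotated: int                # genes without any COG letter

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if self.abundances and not math.isclose(total, 100.0, abs_tol=1e-6):
            raise ValueError(f"abundances must sum to 100, got {total}")
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")


@dataclass
class CategoryCall:
    category: str
    log2_ratio: Optional[float]     # None when undefined (absent on one side)
    abundance_a: float
    abundance_b: float
    call: str                       # enriched | impoverished | none | absent


@dataclass
class EnrichmentResult:
    """Per-category comparison of set A (e.g. accessory) vs set B (core)."""

    calls: Dict[str, CategoryCall]

    @property
    def enriched(self) -> list:
        return sorted(c for c, r in self.calls.items() if r.call == "enriched")

    @property
    def impoverished(self) -> list:
        return sorted(c for c, r in self.calls.items() if r.call == "impoverished")


def cog_profile(annotations: Mapping[str, str], gene_set: Iterable[str]) -> COGProfile:
    """Profile of a gene set under a gene -> COG-letters annotation map.

    A gene annotated "EF" contributes half a count to E and half to F;
    genes missing from the map (or mapped to "", "-", "S"-free blanks)
    count as unannotated.  Percentages are over annotated genes only.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene set is empty")
    weights: Dict[str, float] = {}
    annotated = 0
    for g in genes:
        letters = annotations.get(g, "") or ""
        letters = "".join(ch for ch in letters if ch.isalpha())
        if not letters:
            continue
        annotated += 1
        w = 1.0 / len(letters)
        for ch in letters:
            weights[ch] = weights.get(ch, 0.0) + w
    if annotated == 0:
        raise ValueError("no annotated genes in set")
    abundances = {c: 100.0 * w / annotated for c, w in weights.items()}
    return COGProfile(abundances=abundances, set_size=len(genes), unannotated=len(genes) - annotated)


def compare_profiles(
    a: COGProfile,
    b: COGProfile,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> EnrichmentResult:
    """Call categories enriched/impoverished in profile A relative to B.

    log2(a/b) is computed only where both abundances are positive; a
    category present in one profile but absent from the other is
    reported as "absent" (never an infinite fold).  Enriched in A:
    log2 > cutoff and A-abundance > gate; impoverished in A (i.e.
    enriched in B): log2 < -cutoff and B-abundance > gate.
    """
    cats = sorted(set(a.abundances) | set(b.abundances))
    cutoff = config.enrichment_log2_cutoff
    gate = config.enrichment_abundance_cutoff
    calls: Dict[str, CategoryCall] = {}
    for c in cats:
        av = a.abundances.get(c, 0.0)
        bv = b.abundances.get(c, 0.0)
        if av == 0.0 and bv == 0.0:
            continue
        if av == 0.0 or bv == 0.0:
            calls[c] = CategoryCall(c, None, av, bv, "absent")
            continue
        ratio = math.log2(av / bv)
        if ratio > cutoff and av > gate:
            call = "enriched"
        elif ratio < -cutoff and bv > gate:
            call = "impoverished"
        else:
            call = "none"
        calls[c] = CategoryCall(c, ratio, av, bv, call)
    return EnrichmentResult(calls=calls)
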