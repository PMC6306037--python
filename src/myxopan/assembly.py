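"""Per-genome assembly statistics and the contig coverage filter.

N50/L50 follow the cumulative-sum definition: L50 is the smallest X
such that the X largest contigs together exceed half the assembly
("more than half" is strict), and N50 is the length of the X-th
largest contig.  Draft-assembly contigs carry SPAdes-style headers
(``..._length_<L>_cov_<C>``) from which fold coverage is parsed; the
conventional quality filter drops contigs below 7-fold coverage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from Bio.SeqRecord import SeqRecord

_COV_RE = re.compile(r"_cov_([0-9]+(?:\.[0-9]+)?)")


@dataclass
class AssemblyStats:
    size: int
    gc: float
    n_contigs: int
    n50: int
    l50: int
    mean_coverage: Optional[float]


def n50_l50(contig_lengths: Sequence[int]) -> Tuple[int, int]:
    """(N50, L50) of a contig length list by the cumulative-sum rule."""
    if len(contig_lengths) == 0:
        raise ValueError("contig length list is empty")
    if any(l < 1 for l in contig_lengths):
        raise ValueError("all contig lengths must be >= 1")
    ordered = sorted(contig_lengths, reverse=True)
    half = sum(ordered) / 2.0
    running = 0
    for x, length in enumerate(ordered, start=1):
        running += length
        if running > half:
            return length, x
    raise AssertionError("unreachable: cumulative sum must exceed half")


def parse_coverage(header: str) -> float:
    """Fold coverage from a SPAdes-style ``_cov_<C>`` header token."""
    m = _COV_RE.search(header)
    if m is None:
        raise ValueError(f"no _cov_ token in contig header: {header!r}")
    return float(m.group(1))


def _record_coverage(rec: SeqRecord) -> float:
    for token in (rec.id, rec.description):
        m = _COV_RE.search(token or "")
        if m:
            return float(m.group(1))
    raise ValueError(f"contig {rec.id!r}: header has no _cov_ token")


def filter_by_coverage(contigs: Iterable[SeqRecord], min_cov: float = 7.0) -> List[SeqRecord]:
    """Keep contigs whose parsed coverage is >= min_cov, order preserved.

    The threshold is inclusive: a contig at exactly min_cov survives
    ("less than" min_cov is removed).
    """
    return [rec for rec in contigs if _record_coverage(rec) >= min_cov]


def gc_content(sequences: Iterable) -> float:
    """%GC over all sequences: 100*(G+C)/(A+C+G+T), case-insensitive;
    ambiguous bases are excluded from numerator and denominator."""
    gc = 0
    at = 0
    for seq in sequences:
        s = str(seq.seq if isinstance(seq, SeqRecord) else seq).upper()
        gc += s.count("G") + s.count("C")
        at += s.count("A") + s.count("T")
    if gc + at == 0:
        raise ValueError("no unambiguous (ACGT) bases in input")
    return 100.0 * gc / (gc + at)


def assembly_stats(contigs: Sequence[SeqRecord]) -> AssemblyStats:
    """Table-style summary of one draft assembly."""
    if len(contigs) == 0:
        raise ValueError("no contigs")
    lengths = [len(r.seq) for r in contigs]
    n50, l50 = n50_l50(lengths)
    covs = []
    for rec in contigs:
        try:
            covs.append(_record_coverage(rec))
        except ValueError:
            covs = None
            break
    return AssemblyStats(
        size=sum(lengths),
        gc=gc_content(contigs),
        n_contigs=len(contigs),
        n50=n50,
        l50=l50,
        mean_coverage=(sum(covs) / len(covs)) if covs else None,
    )
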