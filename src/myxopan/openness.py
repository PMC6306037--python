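"""Pan-genome openness: rarefaction, Heaps'-law fitting, extrapolation.

Rarefaction samples random genome orderings and records, for each
prefix length n, the pan size (orthogroups in at least one of the
first n genomes) and core size (orthogroups in all of the first n).
The per-n medians are then fitted: pan to the Heaps power law
P(n) = kappa * n^gamma (gamma < 1 with unbounded growth = open
pan-genome), core to a straight line in 1/n whose intercept estimates
the core at infinitely many genomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .pam import PresenceAbsenceMatrix


@dataclass
class RarefactionResult:
    """Pan/core trajectories over sampled genome orderings.

    ``pan_sizes`` and ``core_sizes`` are (permutations x N) integer
    arrays; row p column j holds the size after the first j+1 genomes
    of ordering p.
    """

    pan_sizes: np.ndarray
    core_sizes: np.ndarray
    permutations: int
    seed: Optional[int]

    @property
    def n_genomes(self) -> int:
        return self.pan_sizes.shape[1]

    @property
    def ns(self) -> np.ndarray:
        return np.arange(1, self.n_genomes + 1)

    @property
    def pan_median(self) -> np.ndarray:
        return np.median(self.pan_sizes, axis=0)

    @property
    def core_median(self) -> np.ndarray:
        return np.median(self.core_sizes, axis=0)

    @property
    def pan_sd(self) -> np.ndarray:
        return np.std(self.pan_sizes, axis=0, ddof=0)

    @property
    def core_sd(self) -> np.ndarray:
        return np.std(self.core_sizes, axis=0, ddof=0)

    def validate(self) -> None:
        """Assert the defining monotonicities of rarefaction curves."""
        if np.any(np.diff(self.pan_median) < 0):
            raise AssertionError("pan medians must be non-decreasing in n")
        if np.any(np.diff(self.core_median) > 0):
            raise AssertionError("core medians must be non-increasing in n")


@dataclass
class HeapsFit:
    """Power-law coefficients for the pan curve P(n) = kappa * n^gamma."""

    kappa: float
    gamma: float
    rss: float
    method: str = "nls"

    @property
    def is_open(self) -> bool:
        return 0.0 < self.gamma < 1.0


@dataclass
class CoreExtrapolationFit:
    """OLS of median core size on 1/n; intercept = core at n = infinity."""

    intercept: float
    slope: float
    r_squared: float
    clamped: bool = False


def rarefy(
    matrix: PresenceAbsenceMatrix,
    permutations: int = 100,
    seed: Optional[int] = None,
) -> RarefactionResult:
    """Sample genome orderings and accumulate pan/core prefix sizes.

    For each ordering the pan size is the running union and the core
    size the running intersection of gene sets; pan(1) == core(1) by
    construction.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    values = matrix.values()
    n = matrix.n_genomes
    rng = np.random.default_rng(seed)
    pan = np.empty((permutations, n), dtype=np.int64)
    core = np.empty((permutations, n), dtype=np.int64)
    for p in range(permutations):
        order = rng.permutation(n)
        m = values[:, order]
        # first occurrence (first True) per gene -> pan prefix counts
        first = np.argmax(m, axis=1)            # every row has >=1 True
        pan[p] = np.cumsum(np.bincount(first, minlength=n))
        # first absence per gene -> core prefix counts; genes present
        # everywhere stay core for all prefixes
        anti = ~m
        has_gap = anti.any(axis=1)
        first_gap = np.where(has_gap, np.argmax(anti, axis=1), n)
        gap_hist = np.bincount(first_gap, minlength=n + 1)[:n]
        # core(j) = genes whose first gap is at column >= j (0-based)
        core[p] = matrix.pan_size - np.cumsum(gap_hist)
    result = RarefactionResult(pan, core, permutations, seed)
    result.validate()
    return result


def _loglog_fit(ns: np.ndarray, pans: np.ndarray) -> tuple[float, float]:
    slope, intercept, *_ = linregress(np.log(ns), np.log(pans))
    return math.exp(intercept), slope


def fit_heaps(result: RarefactionResult, method: str = "nls") -> HeapsFit:
    """Least-squares fit of the per-n median pan sizes to kappa * n^gamma.

    ``method="nls"`` fits on the original scale (the default);
    ``method="loglog"`` fits a line to log P vs log n.  A constant
    curve is degenerate: kappa = the constant, gamma = 0 (closed).
    """
    ns = result.ns.astype(float)
    pans = result.pan_median.astype(float)
    if len(np.unique(ns)) < 3:
        raise ValueError("need at least 3 distinct n values to fit")
    if np.allclose(pans, pans[0]):
        return HeapsFit(kappa=float(pans[0]), gamma=0.0, rss=0.0, method=method)
    k0, g0 = _loglog_fit(ns, pans)
    if method == "loglog":
        rss = float(np.sum((pans - k0 * ns**g0) ** 2))
        return HeapsFit(kappa=k0, gamma=g0, rss=rss, method="loglog")
    if method != "nls":
        raise ValueError(f"unknown fit method {method!r}")
    popt, _ = curve_fit(
        lambda n, k, g: k * n**g, ns, pans, p0=[k0, min(max(g0, 0.05), 0.95)], maxfev=20000
    )
    kappa, gamma = float(popt[0]), float(popt[1])
    rss = float(np.sum((pans - kappa * ns**gamma) ** 2))
    return HeapsFit(kappa=kappa, gamma=gamma, rss=rss, method="nls")


def extrapolate_pan(fit: HeapsFit, n: int) -> int:
    """Predicted pan size at n genomes, rounded to the nearest gene."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return round(fit.kappa * n**fit.gamma)


def new_genes(fit: HeapsFit, n: int) -> int:
    """Genes the n-th genome adds: the finite difference P(n) - P(n-1)."""
    if n < 2:
        raise ValueError("n must be >= 2")
    return round(fit.kappa * n**fit.gamma - fit.kappa * (n - 1) ** fit.gamma)


def novelty_horizon(fit: HeapsFit, threshold: int = 100) -> Optional[int]:
    """Smallest n at which the n-th genome adds fewer than ``threshold``
    new genes, or None ("never") when growth is linear or faster.

    Seeded by the closed form kappa*gamma*n^(gamma-1) = threshold, then
    refined by a local scan of the finite difference.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if fit.gamma >= 1.0 or fit.gamma <= 0.0:
        if fit.gamma <= 0.0:
            return 2  # curve flat or shrinking: the second genome already adds < threshold
        return None
    if new_genes(fit, 2) < threshold:
        return 2
    n0 = (fit.kappa * fit.gamma / threshold) ** (1.0 / (1.0 - fit.gamma))
    n = max(2, int(n0 * 0.9))
    while new_genes(fit, n) >= threshold:
        n += 1
    while n > 2 and new_genes(fit, n - 1) < threshold:
        n -= 1
    return n


def fit_core_inverse(result: RarefactionResult) -> CoreExtrapolationFit:
    """Regress median core size on 1/n (n >= 2 only) by OLS.

    n = 1 is excluded because core(1) = pan(1) is an artifact of the
    definitions, not information about the core.  A negative intercept
    is clamped to zero and flagged.
    """
    ns = result.ns
    mask = ns >= 2
    x = 1.0 / ns[mask]
    y = result.core_median[mask]
    if len(np.unique(ns[mask])) < 3:
        raise ValueError("need at least 3 distinct n >= 2 to fit")
    if np.allclose(y, y[0]):
        return CoreExtrapolationFit(intercept=float(y[0]), slope=0.0, r_squared=1.0)
    res = linregress(x, y)
    intercept = float(res.intercept)
    clamped = intercept < 0
    return CoreExtrapolationFit(
        intercept=max(intercept, 0.0),
        slope=float(res.slope),
        r_squared=float(res.rvalue**2),
        clamped=clamped,
    )
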