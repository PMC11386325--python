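"""Windowed population-genomic diversity estimators.

Implements the classical frequency-spectrum summaries on called diploid
genotypes: the folded site frequency spectrum, Watterson's θ (per-site
S / a1 / L_eff), nucleotide diversity π (average pairwise differences
per site), Tajima's D with its mutation–drift equilibrium variance
normalization, individual heterozygosity H, and their population-level
window means.

Per-site estimates are normalized by an "effective number of sites":
by default the callable-mask length inside the window; optionally the
number of sites with genotype data (``sites_with_data=True`` paths).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genomic_io import HET, HOM_ALT, HOM_REF, MISSING, IntervalSet, VariantTable, Window

DEFAULT_CALL_RATE = 0.8


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 coefficients of Tajima's D variance for sample size n."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("Tajima constants require n >= 2 chromosomes")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n, a1, a2, b1, b2, c1, c2, e1, e2)


def harmonic_a1(n: int) -> float:
    """a1(n) = sum_{i=1}^{n-1} 1/i, the Watterson correction factor."""
    if n < 2:
        raise ValueError("need n >= 2 chromosomes")
    return float(np.sum(1.0 / np.arange(1, n)))


@dataclass(frozen=True)
class FoldedSFS:
    """Folded site frequency spectrum: counts indexed by minor-allele count."""

    n_chromosomes: int
    counts: np.ndarray  # length n//2 + 1; index 0 unused (monomorphic dropped)

    @property
    def n_segregating(self) -> int:
        return int(self.counts[1:].sum())


@dataclass(frozen=True)
class WindowStats:
    window: Window
    S: int
    theta_w: float | None
    pi: float | None
    tajimas_d: float | None
    n: int  # chromosomes used (modal over sites; 2 × individuals when complete)


@dataclass(frozen=True)
class HetEstimate:
    sample: str
    het_sites: int
    callable_sites: int

    @property
    def H(self) -> float:
        return self.het_sites / self.callable_sites


@dataclass(frozen=True)
class SpeciesGD:
    """Population-level summary: window means plus per-individual H mean."""

    label: str
    mean_theta_w: float
    mean_pi: float
    mean_H: float
    mean_D: float | None
    f100kb: float | None
    f1mb: float | None
    n_individuals: int
    n_windows: int


def _site_allele_counts(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (alt allele count, called chromosome count) from the matrix."""
    called = genotypes != MISSING
    alt = np.where(genotypes == HET, 1, 0) + np.where(genotypes == HOM_ALT, 2, 0)
    return alt.sum(axis=1), 2 * called.sum(axis=1)


def folded_sfs(
    table: VariantTable,
    region: IntervalSet | None = None,
    call_rate: float = DEFAULT_CALL_RATE,
) -> FoldedSFS:
    """Fold allele counts onto the minor allele by direct genotype counting.

    Sites with call rate below ``call_rate`` are excluded; monomorphic
    sites contribute nothing.
    """
    if table.n_samples < 1:
        raise ValueError("need at least one sample")
    sub = table.subset_region(region) if region is not None else table
    n = 2 * sub.n_samples
    counts = np.zeros(n // 2 + 1, dtype=np.int64)
    if sub.n_sites:
        alt, called = _site_allele_counts(sub.genotypes)
        keep = called >= call_rate * n
        for x, nc in zip(alt[keep], called[keep]):
            if 0 < x < nc:
                counts[min(int(x), int(nc - x))] += 1
    return FoldedSFS(n_chromosomes=n, counts=counts)


def watterson_theta(S: int, n: int, L_eff: float) -> float | None:
    """Per-site Watterson's θ: (S / a1(n)) / L_eff. None when L_eff = 0."""
    if L_eff == 0:
        return None
    if S == 0:
        return 0.0
    return (S / harmonic_a1(n)) / L_eff


def pairwise_diversity_abs(alt_counts: np.ndarray, called_counts: np.ndarray) -> float:
    """Absolute π: Σ_sites 2·x·(n−x)/(n·(n−1)) with per-site minor count x and n."""
    total = 0.0
    for x, n in zip(alt_counts, called_counts):
        if n >= 2 and 0 < x < n:
            total += 2.0 * x * (n - x) / (n * (n - 1.0))
    return total


def nucleotide_diversity(
    table: VariantTable,
    region: IntervalSet | None = None,
    L_eff: float | None = None,
) -> float | None:
    """Per-site nucleotide diversity over a region. None when L_eff = 0."""
    sub = table.subset_region(region) if region is not None else table
    if L_eff is None:
        L_eff = region.total_length() if region is not None else 0
    if L_eff == 0:
        return None
    alt, called = _site_allele_counts(sub.genotypes)
    return pairwise_diversity_abs(alt, called) / L_eff


def tajimas_d(S: int, pi_abs: float, n: int) -> float | None:
    """Tajima's D = (π_abs − S/a1) / sqrt(e1·S + e2·S·(S−1)); None at S = 0."""
    if S == 0:
        return None
    k = TajimaConstants.from_n(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    return (pi_abs - S / k.a1) / math.sqrt(var)


def window_stats(
    table: VariantTable,
    window: Window,
    call_rate: float = DEFAULT_CALL_RATE,
    sites_with_data: bool = False,
) -> WindowStats:
    """Assemble S, per-site θ_W and π, and Tajima's D for one window.

    θ_W and D use the window-modal called chromosome count; sites whose
    call rate falls below ``call_rate`` are dropped. π uses per-site n.
    With ``sites_with_data`` the per-site denominator is the number of
    retained sites rather than the callable-mask length.
    """
    sub = table.subset_window(window.scaffold, window.start, window.end)
    n_full = 2 * table.n_samples
    if sub.n_sites:
        alt, called = _site_allele_counts(sub.genotypes)
        keep = called >= call_rate * n_full
        alt, called = alt[keep], called[keep]
    else:
        alt = called = np.empty(0, dtype=np.int64)
    seg = (alt > 0) & (alt < called)
    S = int(seg.sum())
    n_modal = int(np.bincount(called[seg]).argmax()) if S else n_full
    L_eff = len(alt) if sites_with_data else window.effective_sites
    if L_eff == 0:
        return WindowStats(window, S, None, None, None, n_modal)
    pi_abs = pairwise_diversity_abs(alt, called)
    return WindowStats(
        window=window,
        S=S,
        theta_w=watterson_theta(S, n_modal, L_eff),
        pi=pi_abs / L_eff,
        tajimas_d=tajimas_d(S, pi_abs, n_modal),
        n=n_modal,
    )


def individual_heterozygosity(
    table: VariantTable, sample: str, callable_sites: int
) -> HetEstimate | None:
    """H = het-site count / callable sites for one sample; None if no denominator."""
    if callable_sites == 0:
        return None
    try:
        j = table.samples.index(sample)
    except ValueError:
        raise ValueError(f"sample {sample!r} not in table") from None
    het = int(np.sum(table.genotypes[:, j] == HET))
    return HetEstimate(sample=sample, het_sites=het, callable_sites=callable_sites)


def population_summary(
    stats: Sequence[WindowStats],
    het_estimates: Sequence[HetEstimate],
    froh_summary: tuple[float | None, float | None] | None = None,
    label: str = "population",
    include_partial_windows: bool = True,
) -> SpeciesGD:
    """Arithmetic means over defined windows (θ_W, π, D) and individuals (H)."""
    usable = [
        s for s in stats
        if s.theta_w is not None and (include_partial_windows or not s.window.partial)
    ]
    if not usable:
        raise ValueError("no windows with defined statistics")
    if len(het_estimates) < 2:
        warnings.warn("fewer than 2 individuals: H mean is a single genome", stacklevel=2)
    d_vals = [s.tajimas_d for s in usable if s.tajimas_d is not None]
    f100, f1m = froh_summary if froh_summary is not None else (None, None)
    return SpeciesGD(
        label=label,
        mean_theta_w=float(np.mean([s.theta_w for s in usable])),
        mean_pi=float(np.mean([s.pi for s in usable])),
        mean_H=float(np.mean([h.H for h in het_estimates])) if het_estimates else float("nan"),
        mean_D=float(np.mean(d_vals)) if d_vals else None,
        f100kb=f100,
        f1mb=f1m,
        n_individuals=len(het_estimates),
        n_windows=len(usable),
    )
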