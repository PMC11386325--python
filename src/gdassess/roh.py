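"""Runs-of-homozygosity calling and F_ROH summaries.

A two-state hidden Markov model over per-site genotype observations of
one diploid individual: state AZ (autozygous, inside an ROH) emits
heterozygotes at a small residual rate; state HW (Hardy–Weinberg,
outside) emits heterozygotes at the expected rate 2p(1−p) from the
sample allele frequency at the site. Transition probability scales with
the physical gap between adjacent sites, P(switch over g bp) =
1 − (1 − r)^g, so sparse regions switch more readily. Decoding is
Viterbi in log space.

F_ROH>L is the summed length of called segments at least L bp long,
divided by the assessed (callable) length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genomic_io import HET, MISSING, GenomeIndex, IntervalSet, VariantTable

AZ, HW = 0, 1  # state indices

ROH_MIN_100KB = 100_000
ROH_MIN_1MB = 1_000_000


@dataclass(frozen=True)
class RohHmmParams:
    p_het_in_roh: float = 0.005
    transition_per_bp: float = 5e-7
    use_site_frequencies: bool = True
    p_het_outside: float = 0.25  # HW het emission when frequencies unused

    def __post_init__(self) -> None:
        for name in ("p_het_in_roh", "transition_per_bp", "p_het_outside"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass(frozen=True)
class RohSegment:
    sample: str
    scaffold: str
    start: int
    end: int
    n_sites: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FrohSummary:
    sample: str
    assessed_length: int
    f100kb: float
    f1mb: float | None  # None when no scaffold reaches 1 Mb


def _emission_logs(
    observations: np.ndarray, het_probs_hw: np.ndarray, p_het_az: float
) -> np.ndarray:
    """(n_sites, 2) log emission matrix; missing sites emit 1 in both states."""
    n = len(observations)
    logs = np.zeros((n, 2))
    is_het = observations == HET
    is_hom = (observations != HET) & (observations != MISSING)
    logs[is_het, AZ] = math.log(p_het_az)
    logs[is_hom, AZ] = math.log1p(-p_het_az)
    logs[is_het, HW] = np.log(het_probs_hw[is_het])
    logs[is_hom, HW] = np.log1p(-het_probs_hw[is_hom])
    return logs


def viterbi_roh(
    observations: np.ndarray,
    positions: np.ndarray,
    params: RohHmmParams = RohHmmParams(),
    site_het_freqs: np.ndarray | None = None,
) -> np.ndarray:
    """Most probable AZ/HW state path for one individual on one scaffold.

    observations: per-site genotype codes (HET / hom codes / MISSING);
    site_het_freqs: per-site expected het probability 2p̂(1−p̂) used as
    the HW emission when ``params.use_site_frequencies`` is set.
    Returns an int array of AZ/HW state codes; fewer than two sites
    yield an all-HW path.
    """
    observations = np.asarray(observations)
    positions = np.asarray(positions, dtype=np.int64)
    n = len(observations)
    if n != len(positions):
        raise ValueError("observations and positions differ in length")
    if np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    if n < 2:
        return np.full(n, HW, dtype=np.int8)

    if params.use_site_frequencies and site_het_freqs is not None:
        hw = np.clip(np.asarray(site_het_freqs, dtype=float), 1e-6, 1 - 1e-6)
    else:
        hw = np.full(n, params.p_het_outside)
    emis = _emission_logs(observations, hw, params.p_het_in_roh)

    gaps = np.diff(positions)
    # log P(stay) = g·log(1−r); log P(switch) = log(1 − (1−r)^g)
    log_stay = gaps * math.log1p(-params.transition_per_bp)
    log_switch = np.log(-np.expm1(log_stay))

    score = np.array([math.log(0.5), math.log(0.5)]) + emis[0]
    back = np.zeros((n, 2), dtype=np.int8)
    for t in range(1, n):
        stay, switch = log_stay[t - 1], log_switch[t - 1]
        for s in (AZ, HW):
            cand = (score[AZ] + (stay if s == AZ else switch),
                    score[HW] + (switch if s == AZ else stay))
            best = int(np.argmax(cand))
            back[t, s] = best
            new = cand[best] + emis[t, s]
            if s == AZ:
                new_az = new
            else:
                new_hw = new
        score = np.array([new_az, new_hw])
    path = np.empty(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def call_segments(
    path: np.ndarray, positions: np.ndarray, sample: str, scaffold: str = "."
) -> list[RohSegment]:
    """Maximal AZ runs as segments [first site pos, last site pos + 1)."""
    path = np.asarray(path)
    positions = np.asarray(positions, dtype=np.int64)
    if len(path) != len(positions):
        raise ValueError("path and positions differ in length")
    segs: list[RohSegment] = []
    start_i: int | None = None
    for i, state in enumerate(path):
        if state == AZ and start_i is None:
            start_i = i
        elif state != AZ and start_i is not None:
            segs.append(RohSegment(sample, scaffold, int(positions[start_i]),
                                   int(positions[i - 1]) + 1, i - start_i))
            start_i = None
    if start_i is not None:
        segs.append(RohSegment(sample, scaffold, int(positions[start_i]),
                               int(positions[-1]) + 1, len(path) - start_i))
    return segs


def froh(
    segments: Sequence[RohSegment], assessed_length: int, min_len: int
) -> float | None:
    """Fraction of the assessed genome in ROH at least min_len bp long."""
    if assessed_length == 0:
        return None
    return sum(s.length for s in segments if s.length >= min_len) / assessed_length


def sample_froh(
    segments: Sequence[RohSegment],
    assessed_length: int,
    sample: str,
    any_scaffold_ge_1mb: bool = True,
) -> FrohSummary:
    f100 = froh(segments, assessed_length, ROH_MIN_100KB)
    if f100 is None:
        raise ValueError("assessed_length must be positive")
    f1m = froh(segments, assessed_length, ROH_MIN_1MB) if any_scaffold_ge_1mb else None
    return FrohSummary(sample=sample, assessed_length=assessed_length,
                       f100kb=f100, f1mb=f1m)


def population_froh(
    summaries: Sequence[FrohSummary],
) -> tuple[float, float | None]:
    """Arithmetic means of F_ROH>100kb and F_ROH>1Mb across individuals.

    The 1 Mb mean is None when no individual has a defined value (low
    assembly contiguity).
    """
    if not summaries:
        raise ValueError("no per-sample summaries to average")
    f100 = float(np.mean([s.f100kb for s in summaries]))
    defined = [s.f1mb for s in summaries if s.f1mb is not None]
    return f100, (float(np.mean(defined)) if defined else None)


def call_roh(
    table: VariantTable,
    index: GenomeIndex,
    callable_regions: IntervalSet | None = None,
    params: RohHmmParams = RohHmmParams(),
    use_genome_span: bool = False,
) -> tuple[list[RohSegment], list[FrohSummary]]:
    """Call ROH for every sample over every scaffold of the index.

    The F_ROH denominator defaults to callable length on the indexed
    scaffolds (genome span with ``use_genome_span``); F_ROH>1Mb is
    undefined (None) when no scaffold reaches 1 Mb.
    """
    lengths = index.lengths()
    if callable_regions is None or use_genome_span:
        assessed = sum(lengths.values())
    else:
        assessed = sum(
            end - start
            for chrom, start, end in callable_regions.intervals
            if chrom in lengths
        )
    any_1mb = any(l >= ROH_MIN_1MB for l in lengths.values())

    # per-site expected het probability from sample allele frequencies
    alt = np.where(table.genotypes == HET, 1, 0) + np.where(table.genotypes == 2, 2, 0)
    called = 2 * np.sum(table.genotypes != MISSING, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(called > 0, alt.sum(axis=1) / np.maximum(called, 1), 0.0)
    het_freqs = 2.0 * p * (1.0 - p)

    scaff_arr = np.asarray(table.scaffolds)
    all_segments: list[RohSegment] = []
    summaries: list[FrohSummary] = []
    for j, sample in enumerate(table.samples):
        segs: list[RohSegment] = []
        for chrom in lengths:
            sel = scaff_arr == chrom
            if not sel.any():
                continue
            obs = table.genotypes[sel, j]
            pos = table.positions[sel]
            path = viterbi_roh(obs, pos, params, site_het_freqs=het_freqs[sel])
            segs.extend(call_segments(path, pos, sample, chrom))
        all_segments.extend(segs)
        summaries.append(sample_froh(segs, assessed, sample, any_scaffold_ge_1mb=any_1mb))
    return all_segments, summaries
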