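"""Genome index, interval-set and genotype-table I/O.

All coordinates are 0-based half-open (BED convention); VCF's 1-based
positions are converted on read. Interval sets are kept normalized —
sorted by (scaffold, start), with overlapping or abutting intervals on
one scaffold merged — so set algebra stays a linear sweep.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# genotype alphabet used by every downstream estimator
HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

DEFAULT_MIN_SCAFFOLD = 100_000
DEFAULT_WINDOW_SIZE = 50_000


@dataclass(frozen=True)
class GenomeIndex:
    """Ordered table of (scaffold name, length in bp)."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate scaffold names in genome index")
        if any(length <= 0 for _, length in self.entries):
            raise ValueError("scaffold lengths must be positive")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeIndex":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @classmethod
    def read(cls, path: str | Path) -> "GenomeIndex":
        """Read a 2+ column genome index (name<TAB>length...), e.g. a .fai."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"malformed genome index line: {line!r}")
                pairs.append((parts[0], int(parts[1])))
        return cls.from_pairs(pairs)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self.entries:
                fh.write(f"{name}\t{length}\n")

    def lengths(self) -> dict[str, int]:
        return dict(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def total_length(self) -> int:
        return sum(length for _, length in self.entries)


def filter_scaffolds(index: GenomeIndex, min_len: int = DEFAULT_MIN_SCAFFOLD) -> GenomeIndex:
    """Keep scaffolds of length >= min_len, preserving input order.

    The boundary is inclusive: a scaffold of exactly min_len bp is retained.
    """
    if min_len <= 0:
        raise ValueError("min_len must be positive")
    return GenomeIndex(tuple(e for e in index.entries if e[1] >= min_len))


def _merge_sorted(ivs: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, start, end in ivs:
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            if end > prev[2]:
                out[-1] = (chrom, prev[1], end)
        else:
            out.append((chrom, start, end))
    return out


@dataclass(frozen=True)
class IntervalSet:
    """Normalized set of genomic intervals (sorted, merged, non-abutting)."""

    intervals: tuple[tuple[str, int, int], ...] = field(default=())

    @classmethod
    def from_intervals(cls, ivs: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        clean = []
        for chrom, start, end in ivs:
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(f"empty or inverted interval {chrom}:{start}-{end}")
            if start < 0:
                raise ValueError(f"negative coordinate in {chrom}:{start}-{end}")
            clean.append((str(chrom), start, end))
        clean.sort()
        return cls(tuple(_merge_sorted(clean)))

    @classmethod
    def read_bed(cls, path: str | Path) -> "IntervalSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                ivs.append((parts[0], int(parts[1]), int(parts[2])))
        return cls.from_intervals(ivs)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")

    def total_length(self) -> int:
        return sum(end - start for _, start, end in self.intervals)

    def scaffolds(self) -> list[str]:
        seen: dict[str, None] = {}
        for chrom, _, _ in self.intervals:
            seen.setdefault(chrom)
        return list(seen)

    def by_scaffold(self) -> dict[str, np.ndarray]:
        """Intervals as {scaffold: (k, 2) int array}, convenient for sweeps."""
        out: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            out.setdefault(chrom, []).append((start, end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        arr = self.by_scaffold().get(chrom)
        if arr is None:
            return False
        i = np.searchsorted(arr[:, 0], pos, side="right") - 1
        return i >= 0 and pos < arr[i, 1]


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Exact set intersection of two normalized interval sets."""
    by_a, by_b = a.by_scaffold(), b.by_scaffold()
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(set(by_a) & set(by_b)):
        ia, ib = by_a[chrom], by_b[chrom]
        i = j = 0
        while i < len(ia) and j < len(ib):
            start = max(ia[i, 0], ib[j, 0])
            end = min(ia[i, 1], ib[j, 1])
            if start < end:
                out.append((chrom, int(start), int(end)))
            if ia[i, 1] <= ib[j, 1]:
                i += 1
            else:
                j += 1
    return IntervalSet.from_intervals(out) if out else IntervalSet()


def complement(a: IntervalSet, index: GenomeIndex) -> IntervalSet:
    """Per-scaffold complement of `a` within [0, scaffold length)."""
    lengths = index.lengths()
    by_a = a.by_scaffold()
    for chrom in by_a:
        if chrom not in lengths:
            raise ValueError(f"interval scaffold {chrom!r} absent from genome index")
        if by_a[chrom][-1, 1] > lengths[chrom]:
            raise ValueError(f"interval beyond end of scaffold {chrom!r}")
    out: list[tuple[str, int, int]] = []
    for chrom, length in index.entries:
        cursor = 0
        for start, end in by_a.get(chrom, np.empty((0, 2), dtype=np.int64)):
            if start > cursor:
                out.append((chrom, cursor, int(start)))
            cursor = int(end)
        if cursor < length:
            out.append((chrom, cursor, length))
    return IntervalSet.from_intervals(out) if out else IntervalSet()


@dataclass(frozen=True)
class Window:
    """One analysis window; effective_sites = callable bp under the mask."""

    scaffold: str
    start: int
    end: int
    effective_sites: int
    partial: bool = False

    @property
    def span(self) -> int:
        return self.end - self.start


def make_windows(
    index: GenomeIndex,
    window_size: int = DEFAULT_WINDOW_SIZE,
    mask: IntervalSet | None = None,
) -> list[Window]:
    """Tile each scaffold with non-overlapping windows, left to right.

    The trailing partial window is kept and flagged. effective_sites is
    the number of callable bp the mask contributes inside the window;
    with no mask every position counts.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    by_mask = mask.by_scaffold() if mask is not None else None
    windows: list[Window] = []
    for chrom, length in index.entries:
        arr = None if by_mask is None else by_mask.get(chrom)
        for start in range(0, length, window_size):
            end = min(start + window_size, length)
            if by_mask is None:
                eff = end - start
            elif arr is None:
                eff = 0
            else:
                overlap = np.minimum(arr[:, 1], end) - np.maximum(arr[:, 0], start)
                eff = int(np.clip(overlap, 0, None).sum())
            windows.append(Window(chrom, start, end, eff, partial=(end - start) < window_size))
    return windows


@dataclass
class VariantTable:
    """Biallelic SNP genotypes for one population.

    Genotypes are coded 0 hom-ref / 1 het / 2 hom-alt / -1 missing in a
    (n_sites, n_samples) int8 matrix; positions are 0-based and strictly
    increasing within a scaffold.
    """

    samples: list[str]
    scaffolds: list[str]          # per-site scaffold name
    positions: np.ndarray         # per-site 0-based position, int64
    genotypes: np.ndarray         # (n_sites, n_samples) int8

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.positions), len(self.samples)):
            raise ValueError("genotype matrix shape does not match sites × samples")
        if len(self.scaffolds) != len(self.positions):
            raise ValueError("scaffold column length mismatch")
        prev: dict[str, int] = {}
        for chrom, pos in zip(self.scaffolds, self.positions):
            if chrom in prev and pos <= prev[chrom]:
                raise ValueError(f"positions not strictly increasing on {chrom}")
            prev[chrom] = pos
        if not 2 <= self.n_samples <= 25:
            warnings.warn(
                f"{self.n_samples} samples is outside the recommended 2-25 range",
                stacklevel=2,
            )

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_region(self, region: IntervalSet) -> "VariantTable":
        keep = np.array(
            [region.contains(c, int(p)) for c, p in zip(self.scaffolds, self.positions)],
            dtype=bool,
        )
        return self._take(keep)

    def subset_window(self, scaffold: str, start: int, end: int) -> "VariantTable":
        keep = np.array(
            [c == scaffold and start <= p < end for c, p in zip(self.scaffolds, self.positions)],
            dtype=bool,
        )
        return self._take(keep)

    def _take(self, keep: np.ndarray) -> "VariantTable":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return VariantTable(
                samples=list(self.samples),
                scaffolds=[c for c, k in zip(self.scaffolds, keep) if k],
                positions=self.positions[keep],
                genotypes=self.genotypes[keep],
            )


# cyvcf2 gt_types codes: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
_CYVCF2_MAP = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}


def read_genotype_table(
    vcf_path: str | Path, sample_subset: Sequence[str] | None = None
) -> VariantTable:
    """Read biallelic SNPs from a VCF into a VariantTable.

    Multi-allelic and non-SNP records are skipped (count logged); phase
    and half-calls are collapsed onto the 4-state genotype alphabet.
    """
    from cyvcf2 import VCF

    vcf_path = Path(vcf_path)
    if not vcf_path.exists():
        raise FileNotFoundError(vcf_path)
    vcf = VCF(str(vcf_path))
    if sample_subset is not None:
        missing = set(sample_subset) - set(vcf.samples)
        if missing:
            raise ValueError(f"samples not in VCF: {sorted(missing)}")
        vcf.set_samples(list(sample_subset))
    samples = list(vcf.samples)

    scaffolds: list[str] = []
    positions: list[int] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            n_skipped += 1
            continue
        scaffolds.append(var.CHROM)
        positions.append(var.POS - 1)  # to 0-based
        rows.append(
            np.array([_CYVCF2_MAP[g] for g in var.gt_types], dtype=np.int8)
        )
    vcf.close()
    if n_skipped:
        logger.info("skipped %d multi-allelic or non-SNP records", n_skipped)
    gts = (
        np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return VariantTable(
            samples=samples,
            scaffolds=scaffolds,
            positions=np.asarray(positions, dtype=np.int64),
            genotypes=gts,
        )


def callable_mask(
    repeats: IntervalSet,
    mappability: IntervalSet,
    index: GenomeIndex,
    min_scaffold: int = DEFAULT_MIN_SCAFFOLD,
) -> tuple[IntervalSet, GenomeIndex]:
    """Build the callable mask: non-repeat ∩ mappable ∩ scaffolds >= min_scaffold.

    Returns the mask and the length-filtered genome index.
    """
    kept = filter_scaffolds(index, min_scaffold)
    kept_names = {name for name, _ in kept.entries}
    rep_kept = IntervalSet.from_intervals(
        iv for iv in repeats.intervals if iv[0] in kept_names
    ) if len(repeats) else IntervalSet()
    map_kept = IntervalSet.from_intervals(
        iv for iv in mappability.intervals if iv[0] in kept_names
    ) if len(mappability) else IntervalSet()
    non_repeat = complement(rep_kept, kept)
    return intersect(non_repeat, map_kept), kept
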