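"""Coalescent fixture generation.

Simulates neutral variation at a known θ under the standard Kingman
coalescent with infinite-sites mutation and no intra-window
recombination: waiting times while k lineages remain are exponential
with rate k(k−1)/2 on the coalescent time scale, and mutations fall on
branches as a Poisson process with rate θ/2 per unit branch length.
Windows are independent replicates tiled along one scaffold. Haplotypes
are paired into diploids, autozygous tracts can be injected by forcing
a sample homozygous over an interval, and the result is written as
plain-text VCF + genome index + callable BED + truth JSON so the whole
toolkit is testable without external data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genomic_io import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    GenomeIndex,
    IntervalSet,
    VariantTable,
)

DEFAULT_SCAFFOLD = "chr1"


@dataclass(frozen=True)
class SimConfig:
    n_individuals: int = 10
    theta_per_window: float = 5.0  # absolute θ per window
    window_length: int = 50_000
    n_windows: int = 100
    seed: int = 42
    scaffold: str = DEFAULT_SCAFFOLD
    roh_tracts: tuple[tuple[str, str, int, int], ...] = ()  # (sample, scaffold, start, end)

    @property
    def scaffold_length(self) -> int:
        return self.window_length * self.n_windows


@dataclass(frozen=True)
class HaplotypeSample:
    """Segregating sites of one simulated window.

    positions are unique ints in [0, window_length); each carrier set is
    a proper, non-empty subset of the haplotype indices.
    """

    n_haplotypes: int
    positions: np.ndarray
    carriers: tuple[frozenset[int], ...]


def simulate_coalescent(
    n_haplotypes: int,
    theta: float,
    rng: np.random.Generator,
    window_length: int = 50_000,
) -> HaplotypeSample:
    """One Kingman coalescent genealogy with infinite-sites mutations.

    Mutations are Poisson with mean θ/2 × branch length per lineage
    segment; positions drawn uniformly and de-duplicated by resampling.
    """
    if n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    if theta <= 0:
        raise ValueError("theta must be positive")
    lineages: list[frozenset[int]] = [frozenset([i]) for i in range(n_haplotypes)]
    carriers: list[frozenset[int]] = []
    k = n_haplotypes
    while k > 1:
        t = rng.exponential(1.0 / (k * (k - 1) / 2.0))
        # each of the k lineage segments carries Poisson(θ/2 · t) mutations
        counts = rng.poisson(theta / 2.0 * t, size=k)
        for lin, c in zip(lineages, counts):
            carriers.extend([lin] * int(c))
        i, j = rng.choice(k, size=2, replace=False)
        merged = lineages[i] | lineages[j]
        lineages = [l for m, l in enumerate(lineages) if m not in (i, j)]
        lineages.append(merged)
        k -= 1

    n_mut = len(carriers)
    positions = np.sort(rng.integers(0, window_length, size=n_mut))
    while len(np.unique(positions)) < n_mut:  # infinite sites: resample collisions
        positions = np.sort(rng.integers(0, window_length, size=n_mut))
    order = np.argsort(positions)
    return HaplotypeSample(
        n_haplotypes=n_haplotypes,
        positions=positions[order],
        carriers=tuple(carriers[i] for i in order),
    )


def pairwise_differences(sample: HaplotypeSample) -> float:
    """Mean pairwise Hamming distance among haplotypes (absolute π)."""
    n = sample.n_haplotypes
    total = sum(len(c) * (n - len(c)) for c in sample.carriers)
    return total / (n * (n - 1) / 2.0)


def pair_diploids(
    sample: HaplotypeSample,
    scaffold: str = DEFAULT_SCAFFOLD,
    offset: int = 0,
    sample_names: list[str] | None = None,
) -> VariantTable:
    """Pair haplotypes (2i, 2i+1) into diploid individuals."""
    if sample.n_haplotypes % 2:
        raise ValueError("need an even haplotype count to pair diploids")
    n_ind = sample.n_haplotypes // 2
    names = sample_names or [f"ind{i}" for i in range(n_ind)]
    gts = np.zeros((len(sample.positions), n_ind), dtype=np.int8)
    for s, carrier in enumerate(sample.carriers):
        for i in range(n_ind):
            a = 2 * i in carrier
            b = 2 * i + 1 in carrier
            gts[s, i] = HOM_ALT if (a and b) else (HET if (a or b) else HOM_REF)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return VariantTable(
            samples=names,
            scaffolds=[scaffold] * len(sample.positions),
            positions=sample.positions + offset,
            genotypes=gts,
        )


def simulate_population(config: SimConfig) -> VariantTable:
    """Tile independent coalescent windows along one scaffold."""
    rng = np.random.default_rng(config.seed)
    names = [f"ind{i}" for i in range(config.n_individuals)]
    scaffolds: list[str] = []
    positions: list[np.ndarray] = []
    blocks: list[np.ndarray] = []
    for w in range(config.n_windows):
        hap = simulate_coalescent(
            2 * config.n_individuals,
            config.theta_per_window,
            rng,
            config.window_length,
        )
        tab = pair_diploids(hap, config.scaffold, offset=w * config.window_length,
                            sample_names=names)
        scaffolds.extend(tab.scaffolds)
        positions.append(tab.positions)
        blocks.append(tab.genotypes)
    table = VariantTable(
        samples=names,
        scaffolds=scaffolds,
        positions=np.concatenate(positions) if positions else np.empty(0, dtype=np.int64),
        genotypes=np.vstack(blocks) if blocks else np.empty((0, len(names)), dtype=np.int8),
    )
    if config.roh_tracts:
        table = inject_roh(table, config.roh_tracts)
    return table


def inject_roh(
    table: VariantTable,
    tracts: "tuple[tuple[str, str, int, int], ...] | list[tuple[str, str, int, int]]",
) -> VariantTable:
    """Force autozygosity: within each (sample, scaffold, start, end) tract
    the sample's heterozygous genotypes become hom-ref; everything else is
    untouched. Overlapping tracts for one sample are rejected.
    """
    per_sample: dict[str, list[tuple[str, int, int]]] = {}
    for sample, scaffold, start, end in tracts:
        per_sample.setdefault(sample, []).append((scaffold, int(start), int(end)))
    for sample, ivs in per_sample.items():
        ivs.sort()
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError(f"overlapping ROH tracts for sample {sample!r}")

    gts = table.genotypes.copy()
    scaff = np.asarray(table.scaffolds)
    for sample, ivs in per_sample.items():
        if sample not in table.samples:
            raise ValueError(f"unknown sample {sample!r} in tract list")
        j = table.samples.index(sample)
        for scaffold, start, end in ivs:
            in_tract = (scaff == scaffold) & (table.positions >= start) & (
                table.positions < end
            )
            col = gts[:, j]
            col[in_tract & (col == HET)] = HOM_REF
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return VariantTable(
            samples=list(table.samples),
            scaffolds=list(table.scaffolds),
            positions=table.positions.copy(),
            genotypes=gts,
        )


_GT_STR = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, index: GenomeIndex, path: str | Path) -> None:
    """Write the table as minimal plain-text VCFv4.2 (A→T biallelic SNPs)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in index.entries:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for s in range(table.n_sites):
            gts = "\t".join(_GT_STR[int(g)] for g in table.genotypes[s])
            fh.write(
                f"{table.scaffolds[s]}\t{table.positions[s] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_fixture(
    table: VariantTable, config: SimConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Emit VCF + genome index + all-callable BED + truth JSON for tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = GenomeIndex.from_pairs([(config.scaffold, config.scaffold_length)])
    paths = {
        "vcf": out / "population.vcf",
        "index": out / "genome.idx",
        "callable": out / "callable.bed",
        "truth": out / "truth.json",
    }
    write_vcf(table, index, paths["vcf"])
    index.write(paths["index"])
    IntervalSet.from_intervals(
        [(config.scaffold, 0, config.scaffold_length)]
    ).write_bed(paths["callable"])
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "theta_per_window": config.theta_per_window,
                "window_length": config.window_length,
                "n_windows": config.n_windows,
                "n_individuals": config.n_individuals,
                "seed": config.seed,
                "roh_tracts": [list(t) for t in config.roh_tracts],
            },
            fh,
            indent=1,
        )
    return paths
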