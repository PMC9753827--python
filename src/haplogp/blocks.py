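"""Pairwise LD and haploblock partitioning.

Two partitioners are provided.  The LD-based rule groups consecutive SNPs on
a chromosome into a block when the r² between every two consecutive SNPs in
the group is at or above a threshold (greedy left-to-right chain scan;
blocks never span chromosomes; a block has at least two SNPs, singletons are
"nonblocked").  The fixed-SNP rule chunks the map into runs of exactly k
markers, either genome-wide (default; the final run may be short) or
restarting at each chromosome boundary.

r² for two biallelic loci is D²/(pA1·pA2·pB1·pB2) with
D = pA1B1·pA2B2 − pA1B2·pA2B1, all frequencies counted over the 2n phased
haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genio import HaplotypePanel

__all__ = [
    "LDStat",
    "BlockPartition",
    "BlockSummary",
    "pairwise_r2",
    "adjacent_r2",
    "ld_partition",
    "fixed_partition",
    "block_summary",
    "write_block_table",
]


class MonomorphicMarkerError(ValueError):
    """LD is undefined when a marker has allele frequency 0 or 1."""


@dataclass
class LDStat:
    D: float
    r2: float
    hap_freqs: tuple  # (pA1B1, pA1B2, pA2B1, pA2B2)
    allele_freqs: tuple  # (pA1, pA2, pB1, pB2)


@dataclass
class BlockPartition:
    """Ordered disjoint marker-index blocks plus the nonblocked markers.

    ``blocks`` are 0-based half-open ``(start, stop)`` intervals of
    consecutive map indices; ``nonblocked`` is a sorted index array.
    """

    blocks: list
    nonblocked: np.ndarray
    method: str  # {"ld", "fixed"}
    threshold: float
    chunking_mode: Optional[str] = None  # fixed mode only
    n_markers: int = 0

    def __post_init__(self) -> None:
        self.nonblocked = np.asarray(self.nonblocked, dtype=int)
        self.validate()

    def validate(self) -> None:
        covered = np.zeros(self.n_markers, dtype=bool)
        last_stop = -1
        for start, stop in self.blocks:
            if not (0 <= start < stop <= self.n_markers):
                raise ValueError(f"invalid block interval ({start}, {stop})")
            if self.method == "ld" and stop - start < 2:
                raise ValueError("LD blocks must contain at least 2 markers")
            if covered[start:stop].any():
                raise ValueError("overlapping blocks")
            covered[start:stop] = True
            if start < last_stop:
                raise ValueError("blocks must be ordered")
            last_stop = stop
        if covered[self.nonblocked].any():
            raise ValueError("nonblocked marker inside a block")
        covered[self.nonblocked] = True
        if not covered.all():
            raise ValueError("partition does not cover all markers")
        if len(self.nonblocked) != len(set(self.nonblocked.tolist())):
            raise ValueError("duplicate nonblocked indices")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_sizes(self) -> np.ndarray:
        return np.array([stop - start for start, stop in self.blocks], dtype=int)


@dataclass
class BlockSummary:
    n_blocks: int
    n_snps_in_blocks: int
    n_snps_out_of_blocks: int
    mean_snps_per_block: float
    max_snps_per_block: int
    n_alleles_total: Optional[int] = None


def pairwise_r2(panel: HaplotypePanel, i: int, j: int) -> LDStat:
    """LD between markers ``i`` and ``j`` by haplotype-frequency counting.

    Allele A1/B1 is the reference (0) allele.  Raises
    :class:`MonomorphicMarkerError` when either marker is monomorphic.
    """
    h = panel.haplotypes
    if (h[:, [i, j]] < 0).any():
        raise ValueError("LD requires missing-free markers")
    xi = h[:, i].astype(float)
    xj = h[:, j].astype(float)
    n = xi.size
    pA2 = xi.mean()  # freq of '1' at locus A
    pB2 = xj.mean()
    if pA2 in (0.0, 1.0) or pB2 in (0.0, 1.0):
        raise MonomorphicMarkerError(f"marker {i if pA2 in (0, 1) else j} is monomorphic")
    # all four classes counted directly, and the denominator grouped per
    # locus, so that r2(i, j) == r2(j, i) bit-exactly
    p22 = float((xi * xj).sum()) / n  # A2B2
    p21 = float((xi * (1 - xj)).sum()) / n  # A2B1
    p12 = float(((1 - xi) * xj).sum()) / n  # A1B2
    p11 = float(((1 - xi) * (1 - xj)).sum()) / n  # A1B1
    D = p11 * p22 - p12 * p21
    r2 = D * D / (((1 - pA2) * pA2) * ((1 - pB2) * pB2))
    return LDStat(
        D=float(D),
        r2=float(min(r2, 1.0)),
        hap_freqs=(p11, p12, p21, p22),
        allele_freqs=(1 - pA2, pA2, 1 - pB2, pB2),
    )


def adjacent_r2(panel: HaplotypePanel) -> np.ndarray:
    """Vectorised r² for every adjacent map pair (NaN across chromosome
    boundaries or when a marker is monomorphic)."""
    h = panel.haplotypes.astype(float)
    n = h.shape[0]
    p = h.mean(axis=0)
    p22 = (h[:, :-1] * h[:, 1:]).sum(axis=0) / n
    D = p22 - p[:-1] * p[1:]
    denom = p[:-1] * (1 - p[:-1]) * p[1:] * (1 - p[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, D * D / denom, np.nan)
    chrom = panel.marker_map["chrom"].to_numpy()
    r2[chrom[:-1] != chrom[1:]] = np.nan
    return np.minimum(r2, 1.0)


def ld_partition(panel: HaplotypePanel, r2_threshold: float) -> BlockPartition:
    """Greedy left-to-right LD-threshold partition (chain rule per block).

    A candidate block opens at the current marker and extends while the r²
    between the block's last marker and the next marker is ≥ the threshold;
    when the test fails (or the chromosome ends) the candidate closes and
    becomes a block if it holds ≥ 2 markers, otherwise its marker is
    nonblocked.  Monomorphic markers are sent directly to the nonblocked set
    and never open or extend a block.
    """
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0, 1]")
    if panel.has_missing:
        raise ValueError("LD partitioning requires a missing-free panel")

    p = panel.haplotypes.astype(float).mean(axis=0)
    poly = (p > 0) & (p < 1)
    adj = adjacent_r2(panel)

    blocks: list = []
    nonblocked: list = []
    for _, start, stop in panel.chromosome_spans():
        j = start
        while j < stop:
            if not poly[j]:
                nonblocked.append(j)
                j += 1
                continue
            b0 = j
            # extend while next marker is on-chromosome, polymorphic, and linked
            while j + 1 < stop and poly[j + 1] and adj[j] >= r2_threshold:
                j += 1
            if j > b0:
                blocks.append((b0, j + 1))
            else:
                nonblocked.append(b0)
            j += 1
    return BlockPartition(
        blocks=blocks,
        nonblocked=np.array(sorted(nonblocked), dtype=int),
        method="ld",
        threshold=float(r2_threshold),
        n_markers=panel.n_markers,
    )


def fixed_partition(marker_map: pd.DataFrame, k: int, chunking_mode: str = "genome_wide") -> BlockPartition:
    """Fixed-SNP-count partition: consecutive runs of exactly ``k`` markers.

    ``genome_wide`` chunks the global map order (final run possibly smaller);
    ``per_chromosome`` restarts the chunking at each chromosome boundary.
    Every marker lands in a block, so the nonblocked set is empty.
    """
    if k < 1:
        raise ValueError("block size k must be >= 1")
    if chunking_mode not in ("genome_wide", "per_chromosome"):
        raise ValueError(f"unknown chunking_mode {chunking_mode!r}")
    m = len(marker_map)
    blocks = []
    if chunking_mode == "genome_wide":
        spans = [(0, m)]
    else:
        chrom = marker_map["chrom"].to_numpy()
        bnd = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1 if m else np.array([], dtype=int)
        starts = np.concatenate(([0], bnd)) if m else []
        stops = np.concatenate((bnd, [m])) if m else []
        spans = list(zip(starts, stops))
    for s, t in spans:
        for b in range(int(s), int(t), k):
            blocks.append((b, min(b + k, int(t))))
    return BlockPartition(
        blocks=blocks,
        nonblocked=np.array([], dtype=int),
        method="fixed",
        threshold=float(k),
        chunking_mode=chunking_mode,
        n_markers=m,
    )


def block_summary(partition: BlockPartition, design=None) -> BlockSummary:
    """Block accounting; with a design, also the total allele-column count
    (haplotype alleles for blocked markers plus one column per nonblocked
    SNP)."""
    sizes = partition.block_sizes()
    n_in = int(sizes.sum())
    n_alleles = None
    if design is not None:
        n_alleles = int(design.m_H + design.m_nb)
    return BlockSummary(
        n_blocks=partition.n_blocks,
        n_snps_in_blocks=n_in,
        n_snps_out_of_blocks=int(partition.n_markers - n_in),
        mean_snps_per_block=float(sizes.mean()) if sizes.size else 0.0,
        max_snps_per_block=int(sizes.max()) if sizes.size else 0,
        n_alleles_total=n_alleles,
    )


def write_block_table(partition: BlockPartition, marker_map: pd.DataFrame, path) -> None:
    """Export blocks as TSV (1-based inclusive bp coordinates)."""
    with open(path, "w") as fh:
        fh.write(
            f"# method={partition.method} threshold={partition.threshold} "
            f"chunking_mode={partition.chunking_mode} coordinates=1-based-inclusive\n"
        )
        fh.write("chrom\tstart_bp\tend_bp\tn_snps\tfirst_marker_id\tlast_marker_id\n")
        for start, stop in partition.blocks:
            first = marker_map.iloc[start]
            last = marker_map.iloc[stop - 1]
            fh.write(
                f"{first.chrom}\t{first.pos}\t{last.pos}\t{stop - start}\t{first.id}\t{last.id}\n"
            )
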