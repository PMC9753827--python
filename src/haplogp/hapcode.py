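"""Haplotype-allele enumeration, dosage design matrices and MHAF filtering.

Within each haploblock the phased SNP alleles are read as one string per
haplotype; the distinct strings are the block's haplotype alleles.  Each
individual carries 0, 1 or 2 copies of each allele, giving the pseudo-marker
dosage matrix M_H (entries {0,1,2}); before any frequency filtering the
dosages of one individual within one block sum to 2.

Rare alleles are removed by the minor-haplotype-allele-frequency (MHAF)
rule: a column whose allele frequency (over the 2n haplotypes) is strictly
below the threshold is discarded.  A block left with at most one surviving
allele column is dropped entirely (its markers are not returned to the
nonblocked set), and nonblocked SNPs are themselves MAF-filtered at the same
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .blocks import BlockPartition
from .genio import HaplotypePanel

__all__ = ["AlleleCatalog", "HaplotypeDesign", "enumerate_alleles", "build_design", "design_summary", "write_catalog"]


@dataclass
class BlockAlleles:
    """Distinct haplotype strings of one block, ordered by descending
    frequency (ties broken lexicographically by string)."""

    block_index: int
    interval: tuple  # (start, stop) marker indices
    strings: list  # e.g. ["01", "00", ...]
    freqs: np.ndarray  # over the 2n haplotypes, sums to 1
    dosages: np.ndarray  # individuals × alleles, entries {0,1,2}


@dataclass
class AlleleCatalog:
    blocks: list  # list[BlockAlleles], in partition order
    n_haplotypes: int

    def n_alleles_per_block(self) -> np.ndarray:
        return np.array([len(b.strings) for b in self.blocks], dtype=int)


@dataclass
class HaplotypeDesign:
    """Dosage design: haplotype-allele columns plus nonblocked-SNP columns.

    ``p_H``/``p_nb`` are the pre-filter observed column frequencies used for
    centering (P = 2p) and for the VanRaden denominator.  ``M_snp`` carries
    the all-SNP dosages (polymorphic markers only) so the plain SNP
    relationship matrix can be built from the same object.
    """

    M_H: np.ndarray
    p_H: np.ndarray
    col_ids: list
    col_block: np.ndarray  # block index per M_H column
    M_nb: np.ndarray
    p_nb: np.ndarray
    nb_ids: list
    M_snp: np.ndarray
    p_snp: np.ndarray
    snp_ids: list
    mhaf: float
    partition: Optional[BlockPartition] = None
    surviving_blocks: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def m_H(self) -> int:
        return self.M_H.shape[1]

    @property
    def m_nb(self) -> int:
        return self.M_nb.shape[1]

    @property
    def P_H(self) -> np.ndarray:
        return 2.0 * self.p_H

    @property
    def P_nb(self) -> np.ndarray:
        return 2.0 * self.p_nb

    @property
    def n_blocks_surviving(self) -> int:
        return int(np.unique(self.col_block).size)


def enumerate_alleles(panel: HaplotypePanel, partition: BlockPartition) -> AlleleCatalog:
    """Observed haplotype alleles per block with frequencies and dosages."""
    if panel.has_missing:
        raise ValueError("allele enumeration requires a missing-free panel")
    h = panel.haplotypes
    n = panel.n_individuals
    out = []
    for bi, (start, stop) in enumerate(partition.blocks):
        sub = h[:, start:stop]
        uniq, inverse, counts = np.unique(sub, axis=0, return_inverse=True, return_counts=True)
        strings = ["".join(map(str, row)) for row in uniq]
        freqs = counts / (2.0 * n)
        # order: descending frequency, ties lexicographic by string
        order = sorted(range(len(strings)), key=lambda a: (-freqs[a], strings[a]))
        rank = np.empty(len(order), dtype=int)
        for newpos, old in enumerate(order):
            rank[old] = newpos
        dos = np.zeros((n, len(strings)), dtype=np.int8)
        alle = rank[np.ravel(inverse)]  # one allele index per haplotype row
        np.add.at(dos, (np.repeat(np.arange(n), 2), alle), 1)
        out.append(
            BlockAlleles(
                block_index=bi,
                interval=(start, stop),
                strings=[strings[o] for o in order],
                freqs=freqs[order],
                dosages=dos,
            )
        )
    return AlleleCatalog(blocks=out, n_haplotypes=2 * n)


def build_design(
    panel: HaplotypePanel,
    partition: BlockPartition,
    catalog: AlleleCatalog,
    mhaf: float = 0.0,
) -> HaplotypeDesign:
    """Assemble M_H / M_nb under the strict-< MHAF rule.

    Columns with allele frequency < ``mhaf`` are removed; blocks reduced to
    ≤ 1 surviving column are dropped; nonblocked SNPs with MAF < ``mhaf``
    are removed.  Recorded frequencies are the pre-filter observed values.
    """
    if mhaf < 0:
        raise ValueError("mhaf must be non-negative")
    if mhaf >= 0.5:
        raise ValueError("mhaf must be below 0.5")
    if len(catalog.blocks) != len(partition.blocks):
        raise ValueError("catalog inconsistent with partition")

    n = panel.n_individuals
    cols, ids, freqs, blk_idx = [], [], [], []
    kept_blocks = []
    for b in catalog.blocks:
        keep = np.flatnonzero(b.freqs >= mhaf)  # strict <: freq == mhaf survives
        if keep.size <= 1:
            continue  # block dropped entirely
        kept_blocks.append(b.block_index)
        for a in keep:
            cols.append(b.dosages[:, a])
            ids.append(f"b{b.block_index}:{b.strings[a]}")
            freqs.append(b.freqs[a])
            blk_idx.append(b.block_index)
    M_H = np.column_stack(cols).astype(np.int8) if cols else np.empty((n, 0), dtype=np.int8)

    geno = panel.genotypes().astype(np.int8)
    p_all = panel.alt_freq()

    nb = partition.nonblocked
    nb_maf = np.minimum(p_all[nb], 1 - p_all[nb]) if nb.size else np.array([])
    nb_keep = nb[(nb_maf >= mhaf) & (nb_maf > 0)] if nb.size else nb
    M_nb = geno[:, nb_keep] if nb_keep.size else np.empty((n, 0), dtype=np.int8)

    poly = (p_all > 0) & (p_all < 1)
    snp_cols = np.flatnonzero(poly)

    mm_id = panel.marker_map["id"]
    return HaplotypeDesign(
        M_H=M_H,
        p_H=np.asarray(freqs, dtype=float),
        col_ids=ids,
        col_block=np.asarray(blk_idx, dtype=int),
        M_nb=M_nb,
        p_nb=p_all[nb_keep] if nb_keep.size else np.array([]),
        nb_ids=[mm_id.iat[int(j)] for j in nb_keep],
        M_snp=geno[:, snp_cols],
        p_snp=p_all[snp_cols],
        snp_ids=[mm_id.iat[int(j)] for j in snp_cols],
        mhaf=float(mhaf),
        partition=partition,
        surviving_blocks=np.asarray(kept_blocks, dtype=int),
    )


def design_summary(design: HaplotypeDesign) -> pd.DataFrame:
    """Audit counts: haplotype alleles, nonblocked SNPs, surviving blocks,
    and the total allele-column count."""
    return pd.DataFrame(
        {
            "quantity": [
                "n_haplotype_alleles",
                "n_nonblocked_snps",
                "n_blocks_surviving",
                "n_alleles_total",
            ],
            "value": [
                design.m_H,
                design.m_nb,
                len(design.surviving_blocks),
                design.m_H + design.m_nb,
            ],
        }
    )


def write_catalog(catalog: AlleleCatalog, path, mhaf: float = 0.0) -> None:
    """Allele catalog TSV: block id, haplotype string, frequency, kept flag."""
    with open(path, "w") as fh:
        fh.write("block\thaplotype\tfrequency\tkept\n")
        for b in catalog.blocks:
            keep = b.freqs >= mhaf
            n_keep = int(keep.sum())
            for s, f, k in zip(b.strings, b.freqs, keep):
                kept = bool(k) and n_keep > 1
                fh.write(f"{b.block_index}\t{s}\t{f:.8g}\t{int(kept)}\n")
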