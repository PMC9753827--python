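"""Genotype and phenotype I/O plus chip-style quality control.

The central container is :class:`HaplotypePanel`: a phased, biallelic allele
matrix with two rows per individual (maternal/paternal order arbitrary but
fixed) and one column per marker, together with the marker map.  Raw input
may carry missing alleles (coded ``-1``); every analysis stage downstream of
:func:`qc_filter` requires a missing-free panel (inputs are assumed
pre-imputed and phased — phasing/imputation itself is out of scope).

QC applies the standard chip filters in a fixed order: individual call rate,
then per-SNP call rate, minor allele frequency, and a Hardy–Weinberg exact
test (mid-p, full enumeration over heterozygote counts).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypePanel",
    "PhenotypeTable",
    "QCReport",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_plink_map",
    "hwe_midp_exact",
    "qc_filter",
]

MAP_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes: (2·n_individuals) × n_markers.

    Parameters
    ----------
    haplotypes
        int8 matrix with entries in {0, 1} (−1 marks a missing allele in raw
        input).  Rows ``2i`` and ``2i+1`` are the two haplotypes of
        individual ``i``.
    sample_ids
        Individual identifiers, one per pair of rows.
    marker_map
        DataFrame with columns ``chrom, pos, id, ref, alt``; markers must be
        sorted with strictly increasing position within each chromosome and
        chromosomes contiguous.
    """

    haplotypes: np.ndarray
    sample_ids: list
    marker_map: pd.DataFrame

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        if self.haplotypes.shape[0] != 2 * len(self.sample_ids):
            raise ValueError(
                f"haplotype rows ({self.haplotypes.shape[0]}) must equal "
                f"2 × samples ({len(self.sample_ids)})"
            )
        if self.haplotypes.shape[1] != len(self.marker_map):
            raise ValueError("marker_map length must match haplotype columns")
        bad = ~np.isin(self.haplotypes, (-1, 0, 1))
        if bad.any():
            raise ValueError("haplotype entries must be in {-1, 0, 1}")
        self._check_map_order()

    def _check_map_order(self) -> None:
        mm = self.marker_map
        if list(mm.columns[:2]) != ["chrom", "pos"] and not set(
            MAP_COLUMNS[:2]
        ).issubset(mm.columns):
            raise ValueError(f"marker_map needs columns {MAP_COLUMNS[:2]}")
        chrom = mm["chrom"].to_numpy()
        pos = mm["pos"].to_numpy()
        if len(chrom) == 0:
            return
        # contiguity + strictly increasing position per chromosome
        boundaries = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [len(chrom)]))
        labels = [chrom[s] for s in starts]
        if len(set(labels)) != len(labels):
            raise ValueError("chromosome blocks must be contiguous in the map")
        for s, t in zip(starts, stops):
            if np.any(np.diff(pos[s:t]) <= 0):
                raise ValueError("positions must be strictly increasing per chromosome")

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.haplotypes < 0).any())

    def genotypes(self) -> np.ndarray:
        """n × m diploid alt-allele dosages; −1 where either allele missing."""
        h0 = self.haplotypes[0::2].astype(np.int16)
        h1 = self.haplotypes[1::2].astype(np.int16)
        g = h0 + h1
        g[(h0 < 0) | (h1 < 0)] = -1
        return g

    def alt_freq(self) -> np.ndarray:
        """Per-marker alternate-allele frequency over non-missing haplotypes."""
        h = self.haplotypes
        obs = h >= 0
        with np.errstate(invalid="ignore"):
            return np.where(obs.sum(0) > 0, np.where(obs, h, 0).sum(0), np.nan) / np.maximum(
                obs.sum(0), 1
            )

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def chromosome_spans(self) -> list:
        """[(chrom_label, start_col, stop_col)] in map order (half-open)."""
        chrom = self.marker_map["chrom"].to_numpy()
        if len(chrom) == 0:
            return []
        boundaries = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1
        starts = np.concatenate(([0], boundaries))
        stops = np.concatenate((boundaries, [len(chrom)]))
        return [(chrom[s], int(s), int(t)) for s, t in zip(starts, stops)]

    def subset(
        self,
        individuals: Optional[Sequence[int]] = None,
        markers: Optional[Sequence[int]] = None,
    ) -> "HaplotypePanel":
        ind = np.arange(self.n_individuals) if individuals is None else np.asarray(individuals, dtype=int)
        mk = np.arange(self.n_markers) if markers is None else np.asarray(markers, dtype=int)
        rows = np.empty(2 * len(ind), dtype=int)
        rows[0::2] = 2 * ind
        rows[1::2] = 2 * ind + 1
        return HaplotypePanel(
            self.haplotypes[np.ix_(rows, mk)],
            [self.sample_ids[i] for i in ind],
            self.marker_map.iloc[mk].reset_index(drop=True),
        )


@dataclass
class PhenotypeTable:
    """One-record-per-individual phenotypes with fixed-effect columns.

    ``data`` holds a ``sample_id`` column, one or more trait columns, and any
    number of categorical factor / real covariate columns (declared in
    ``factors`` / ``covariates``).
    """

    data: pd.DataFrame
    traits: list
    factors: list = field(default_factory=list)
    covariates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if "sample_id" not in self.data.columns:
            raise ValueError("phenotype table needs a sample_id column")
        if self.data["sample_id"].duplicated().any():
            raise ValueError("duplicated sample ids in phenotype table")
        for t in self.traits:
            vals = self.data[t].dropna()
            if not np.isfinite(vals.to_numpy(dtype=float)).all():
                raise ValueError(f"non-finite values in trait {t!r}")

    @property
    def sample_ids(self) -> list:
        return self.data["sample_id"].tolist()

    def trait_values(self, trait: Optional[str] = None) -> np.ndarray:
        trait = trait or self.traits[0]
        return self.data[trait].to_numpy(dtype=float)


@dataclass
class QCReport:
    n_individuals_in: int
    n_individuals_out: int
    n_markers_in: int
    n_markers_out: int
    removed_individual_call_rate: int
    removed_snp_call_rate: int
    removed_maf: int
    removed_hwe: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"criterion": list(dataclasses.asdict(self)), "count": list(dataclasses.asdict(self).values())}
        )


# ----------------------------------------------------------------------
# VCF I/O
# ----------------------------------------------------------------------

def read_phased_vcf(path) -> HaplotypePanel:
    """Read a phased, biallelic VCF into a :class:`HaplotypePanel`.

    Every called genotype must use the ``|`` separator; an unphased ``/``
    record or a multiallelic site raises ``ValueError`` naming the first
    offending record.  Fully missing genotypes (``./.``) are tolerated and
    stored as −1 (QC input only).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = []
    rows_map = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic site at {var.CHROM}:{var.POS} ({var.ID or '.'}); "
                "only biallelic markers are supported"
            )
        g = np.array(var.genotypes, dtype=object)  # rows: [a0, a1, phased]
        alleles = np.array([[row[0], row[1]] for row in g], dtype=np.int8)
        phased = np.array([bool(row[2]) for row in g])
        called = (alleles >= 0).any(axis=1)
        if np.any(called & ~phased):
            bad = samples[int(np.flatnonzero(called & ~phased)[0])]
            raise ValueError(
                f"unphased genotype at {var.CHROM}:{var.POS} sample {bad}: "
                "all GT fields must use '|'"
            )
        col = np.empty(2 * len(samples), dtype=np.int8)
        col[0::2] = alleles[:, 0]
        col[1::2] = alleles[:, 1]
        cols.append(col)
        rows_map.append(
            (var.CHROM, var.POS, var.ID or f"{var.CHROM}:{var.POS}", var.REF, var.ALT[0])
        )
    vcf.close()
    hap = np.column_stack(cols) if cols else np.empty((2 * len(samples), 0), dtype=np.int8)
    mm = pd.DataFrame(rows_map, columns=MAP_COLUMNS)
    return HaplotypePanel(hap, samples, mm)


def write_phased_vcf(panel: HaplotypePanel, path) -> None:
    """Write a panel as an uncompressed VCFv4.2 with phased GT fields."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=haplogp\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, _s, _t in panel.chromosome_spans():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in panel.sample_ids)
            + "\n"
        )
        h = panel.haplotypes
        mm = panel.marker_map
        for j in range(panel.n_markers):
            a = h[0::2, j]
            b = h[1::2, j]
            gts = "\t".join(
                ("." if x < 0 else str(x)) + "|" + ("." if y < 0 else str(y))
                for x, y in zip(a, b)
            )
            fh.write(
                f"{mm.chrom.iat[j]}\t{mm.pos.iat[j]}\t{mm.id.iat[j]}\t"
                f"{mm.ref.iat[j]}\t{mm.alt.iat[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.data.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, traits, factors=(), covariates=()) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return PhenotypeTable(df, list(traits), list(factors), list(covariates))


def read_plink_map(path) -> pd.DataFrame:
    """PLINK ``.map`` dialect: chrom, id, cM (ignored), bp."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "id", "cm", "pos"])
    out = df[["chrom", "pos", "id"]].copy()
    out["ref"] = "A"
    out["alt"] = "B"
    return out[MAP_COLUMNS]


# ----------------------------------------------------------------------
# Hardy–Weinberg mid-p exact test
# ----------------------------------------------------------------------

def hwe_midp_exact(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Mid-p exact Hardy–Weinberg test (enumeration over heterozygote counts).

    The conditional distribution of the heterozygote count given the minor
    allele count (Wigginton, Cutler & Abecasis 2005) is enumerated exactly;
    mid-p sums all outcomes strictly less probable than the observed one plus
    half the probability of outcomes equally probable.
    """
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n - n_minor
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    # feasible heterozygote counts share the parity of the minor-allele count
    het_min = n_minor % 2
    hets = np.arange(het_min, n_minor + 1, 2)
    # log unnormalised probabilities (gammaln-based for stability)
    from scipy.special import gammaln

    hom_min = (n_minor - hets) // 2
    hom_maj = n - hets - hom_min
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(hom_min + 1)
        - gammaln(hom_maj + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[np.flatnonzero(hets == n_het)[0]]
    less = prob[prob < obs * (1 - 1e-12)].sum()
    equal = prob[np.abs(prob - obs) <= obs * 1e-12].sum()
    return float(less + 0.5 * equal)


# ----------------------------------------------------------------------
# Quality control
# ----------------------------------------------------------------------

def qc_filter(
    panel: HaplotypePanel,
    snp_call_rate: float = 0.90,
    maf_min: float = 0.01,
    hwe_p: float = 1e-5,
    ind_call_rate: float = 0.90,
):
    """Chip QC: individuals by call rate, then SNPs by call rate / MAF / HWE.

    Returns ``(filtered_panel, QCReport)``.  SNP removal is attributed to the
    first failing criterion in the order call rate → MAF → HWE, so the
    report's per-criterion counts sum to the number of removed markers.
    Genotypes for MAF/HWE are the sums of the two phased rows.  The filter is
    idempotent: a panel that passes is returned unchanged.
    """
    n_ind_in, n_mark_in = panel.n_individuals, panel.n_markers
    geno = panel.genotypes()

    ind_cr = (geno >= 0).mean(axis=1) if n_mark_in else np.ones(n_ind_in)
    keep_ind = np.flatnonzero(ind_cr >= ind_call_rate)
    removed_ind = n_ind_in - keep_ind.size
    panel = panel.subset(individuals=keep_ind)
    geno = geno[keep_ind]

    n = panel.n_individuals
    removed_cr = removed_maf = removed_hwe = 0
    keep_mark = []
    for j in range(panel.n_markers):
        g = geno[:, j]
        called = g >= 0
        if n and called.mean() < snp_call_rate:
            removed_cr += 1
            continue
        gc = g[called]
        if gc.size == 0:
            removed_cr += 1
            continue
        p = gc.mean() / 2.0
        if min(p, 1 - p) < maf_min:
            removed_maf += 1
            continue
        n_het = int((gc == 1).sum())
        n_hom_alt = int((gc == 2).sum())
        n_hom_ref = int((gc == 0).sum())
        if hwe_midp_exact(n_het, n_hom_alt, n_hom_ref) < hwe_p:
            removed_hwe += 1
            continue
        keep_mark.append(j)

    out = panel.subset(markers=keep_mark)
    report = QCReport(
        n_individuals_in=n_ind_in,
        n_individuals_out=out.n_individuals,
        n_markers_in=n_mark_in,
        n_markers_out=out.n_markers,
        removed_individual_call_rate=removed_ind,
        removed_snp_call_rate=removed_cr,
        removed_maf=removed_maf,
        removed_hwe=removed_hwe,
    )
    return out, report
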