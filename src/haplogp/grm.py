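"""VanRaden-form genomic relationship matrices.

G = (M − P)(M − P)ᵀ / Σᵢ 2pᵢ(1−pᵢ), where M holds 0/1/2 dosages, P has
columns 2pᵢ, and pᵢ is the observed frequency of the counted allele.  The
same construction serves the SNP matrix G (SNP columns), the haplotype
matrix G_H (haplotype-allele columns, possibly multiallelic per block), and
the nonblocked-SNP matrix of the two-component model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hapcode import HaplotypeDesign

__all__ = ["GRM", "vanraden_grm", "grm_for_model", "write_grm_tsv", "read_grm_tsv"]

PSD_TOL = 1e-8


@dataclass
class GRM:
    matrix: np.ndarray
    sample_ids: list
    source: str  # {"snp", "haplotype", "nonblocked_snp"}
    denominator: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.validate()

    def validate(self) -> None:
        A = self.matrix
        if A.shape[0] != A.shape[1] or A.shape[0] != len(self.sample_ids):
            raise ValueError("GRM must be square and match sample_ids")
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if A.shape[0] <= 2000:
            w = np.linalg.eigvalsh(A)
            if w.min() < -PSD_TOL * max(1.0, abs(w.max())):
                raise ValueError(f"GRM not PSD within tolerance (min eig {w.min():.3g})")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def align(self, ids) -> np.ndarray:
        """Row/col indices of ``ids`` in this GRM's ordering."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)


def vanraden_grm(M: np.ndarray, p: np.ndarray, sample_ids=None, source: str = "snp") -> GRM:
    """G = (M−P)(M−P)ᵀ / Σ 2p(1−p) with P's columns equal to 2p."""
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be 2-D (individuals × columns)")
    if M.shape[1] != p.size:
        raise ValueError(f"dimension mismatch: M has {M.shape[1]} columns, p has {p.size}")
    if not np.isin(np.unique(M), (0.0, 1.0, 2.0)).all():
        raise ValueError("dosage entries must be in {0, 1, 2}")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("column frequencies must be in (0, 1); filter fixed columns first")
    W = M - 2.0 * p[None, :]
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)
    ids = list(sample_ids) if sample_ids is not None else [f"ind{i}" for i in range(M.shape[0])]
    return GRM(matrix=G, sample_ids=ids, source=source, denominator=denom)


def grm_for_model(design: HaplotypeDesign, which: str, sample_ids=None) -> GRM:
    """Dispatch the VanRaden construction on a design component.

    ``which``: ``"G"`` (all SNPs), ``"G_H"`` (haplotype-allele columns) or
    ``"G_nonblocked"`` (SNPs outside every block).
    """
    if which == "G":
        M, p, src = design.M_snp, design.p_snp, "snp"
    elif which == "G_H":
        M, p, src = design.M_H, design.p_H, "haplotype"
    elif which == "G_nonblocked":
        M, p, src = design.M_nb, design.p_nb, "nonblocked_snp"
    else:
        raise ValueError(f"unknown GRM request {which!r}")
    if M.shape[1] == 0:
        raise ValueError(
            f"cannot build {which}: no columns available"
            + (" (model must degrade to G_H_BLUP)" if which == "G_nonblocked" else "")
        )
    return vanraden_grm(M, p, sample_ids=sample_ids, source=src)


def write_grm_tsv(grm: GRM, path) -> None:
    """Lower-triangle TSV export: id_i, id_j, value."""
    with open(path, "w") as fh:
        fh.write(f"# source={grm.source} denominator={grm.denominator:.10g}\n")
        fh.write("id1\tid2\tvalue\n")
        for i in range(grm.n):
            for j in range(i + 1):
                fh.write(f"{grm.sample_ids[i]}\t{grm.sample_ids[j]}\t{grm.matrix[i, j]:.10g}\n")


def read_grm_tsv(path) -> GRM:
    import pandas as pd

    with open(path) as fh:
        header = fh.readline()
    meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
    df = pd.read_csv(path, sep="\t", comment="#")
    ids = list(dict.fromkeys(df["id1"]))
    lookup = {s: i for i, s in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    for a, b, v in zip(df["id1"], df["id2"], df["value"]):
        i, j = lookup[a], lookup[b]
        A[i, j] = A[j, i] = v
    return GRM(matrix=A, sample_ids=ids, source=meta.get("source", "snp"), denominator=float(meta.get("denominator", 1.0)))
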