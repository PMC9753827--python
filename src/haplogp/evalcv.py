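"""Cross-validated evaluation of genomic prediction.

k-fold plans (default 5 folds × 5 repeats) are balanced random partitions of
the individuals; within a run the same plan is shared by every model so that
per-fold comparisons are paired.  Per validation fold the metrics are

    accuracy  r = cor(y_adj, gebv)
    bias      b = cov(gebv, y_adj) / var(gebv)

with b = 1 unbiased, b > 1 deflated and b < 1 inflated predictions.  Model
comparisons use the one-sided paired t-test over (repeat, fold) pairs, and
the haplotype-vs-SNP improvement is reported as the per-fold percent change
100·(r_hap − r_snp)/r_snp, mean ± SE.

Block construction and allele frequencies are computed once on the full
panel; only model fitting (REML+BLUP or the Bayesian sampler) is
fold-specific, so no validation phenotype can influence its own GEBV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bayesb import BayesB, BayesBConfig
from .mixedmodel import GBLUP

__all__ = [
    "FoldPlan",
    "CVResult",
    "kfold_split",
    "accuracy",
    "bias",
    "paired_onesided_ttest",
    "percent_change",
    "run_cv",
]


@dataclass
class FoldPlan:
    k: int
    repeats: int
    assignments: list  # per repeat: list of k disjoint id arrays
    seed: int

    def validate(self, ids=None) -> None:
        for groups in self.assignments:
            allids = np.concatenate([np.asarray(g) for g in groups])
            if len(set(allids.tolist())) != allids.size:
                raise ValueError("folds within a repeat must be disjoint")
            sizes = [len(g) for g in groups]
            if max(sizes) - min(sizes) > 1:
                raise ValueError("fold sizes must differ by at most 1")
            if ids is not None and set(allids.tolist()) != set(ids):
                raise ValueError("folds must exhaust the id set")


@dataclass
class CVResult:
    records: pd.DataFrame  # model, repeat, fold, n_validation, accuracy, bias, failed
    model_tag: str

    def summary(self) -> dict:
        ok = self.records[~self.records["failed"]]
        acc = ok["accuracy"].dropna()
        b = ok["bias"].dropna()
        return {
            "model": self.model_tag,
            "mean_accuracy": float(acc.mean()) if len(acc) else np.nan,
            "sd_accuracy": float(acc.std(ddof=1)) if len(acc) > 1 else np.nan,
            "mean_bias": float(b.mean()) if len(b) else np.nan,
            "n_folds": int(len(ok)),
            "n_failed": int(self.records["failed"].sum()),
        }

    def export(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def kfold_split(ids: Sequence, k: int = 5, repeats: int = 5, seed: int = 0) -> FoldPlan:
    """Balanced random k-fold partitions, repeated; deterministic by seed."""
    ids = np.asarray(list(ids))
    if k > ids.size:
        raise ValueError(f"k={k} exceeds the {ids.size} available ids")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    assignments = []
    for _ in range(repeats):
        perm = rng.permutation(ids)
        assignments.append([np.sort(g) for g in np.array_split(perm, k)])
    plan = FoldPlan(k=k, repeats=repeats, assignments=assignments, seed=seed)
    plan.validate(ids=ids.tolist())
    return plan


def accuracy(y_adj_val: np.ndarray, gebv_val: np.ndarray) -> float:
    """Pearson correlation between adjusted phenotypes and GEBVs;
    NaN (flagged undefined) when either vector is constant."""
    y = np.asarray(y_adj_val, dtype=float)
    g = np.asarray(gebv_val, dtype=float)
    if y.size < 3:
        raise ValueError("accuracy needs at least 3 pairs")
    if np.std(y) == 0 or np.std(g) == 0:
        return np.nan
    return float(np.corrcoef(y, g)[0, 1])


def bias(y_adj_val: np.ndarray, gebv_val: np.ndarray) -> float:
    """Regression coefficient of the adjusted phenotype on the GEBV:
    cov(gebv, y)/var(gebv); NaN when the GEBVs are constant."""
    y = np.asarray(y_adj_val, dtype=float)
    g = np.asarray(gebv_val, dtype=float)
    vg = np.var(g)
    if vg == 0:
        return np.nan
    return float(np.cov(g, y, ddof=1)[0, 1] / np.var(g, ddof=1))


def paired_onesided_ttest(acc_model_A: np.ndarray, acc_model_B: np.ndarray):
    """One-sided paired t-test of H1: mean(A − B) > 0.

    Returns ``(t, df, p)``.  All-zero differences give (0, df, 0.5); a
    degenerate nonzero-mean, zero-variance difference vector gives p = 0
    (mean > 0) or p = 1 (mean < 0).
    """
    a = np.asarray(acc_model_A, dtype=float)
    b = np.asarray(acc_model_B, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("paired vectors of equal length >= 2 required")
    d = a - b
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return 0.0, df, 0.5
        warnings.warn("zero-variance nonzero differences: degenerate t", stacklevel=2)
        return (np.inf, df, 0.0) if d.mean() > 0 else (-np.inf, df, 1.0)
    t = d.mean() / (sd / np.sqrt(d.size))
    p = float(stats.t.sf(t, df))
    return float(t), df, p


def percent_change(acc_hap: np.ndarray, acc_snp: np.ndarray):
    """Per-fold 100·(r_hap − r_snp)/r_snp, mean ± SE over folds/repeats.

    Folds with r_snp ≤ 0 are excluded with a warning.
    """
    h = np.asarray(acc_hap, dtype=float)
    s = np.asarray(acc_snp, dtype=float)
    ok = s > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} folds with non-positive SNP accuracy excluded", stacklevel=2)
    h, s = h[ok], s[ok]
    if h.size == 0:
        return np.nan, np.nan
    pc = 100.0 * (h - s) / s
    se = pc.std(ddof=1) / np.sqrt(pc.size) if pc.size > 1 else 0.0
    return float(pc.mean()), float(se)


BLUP_TAGS = {"GBLUP": ["G"], "G_H_BLUP": ["G_H"], "G_H_BLUP+GBLUP": ["G_H", "G_nonblocked"]}
BAYES_TAGS = ("BayesB", "BayesBH", "BayesBH+BayesB")


def run_cv(
    y_adj: np.ndarray,
    sample_ids: Sequence,
    model_tag: str,
    plan: FoldPlan,
    grms: Optional[list] = None,
    design_columns: Optional[tuple] = None,  # (M raw dosages, p) for Bayes models
    bayes_cfg: Optional[BayesBConfig] = None,
) -> CVResult:
    """Fit the requested model per (repeat, fold) on training ids only and
    score validation accuracy and bias.

    For BLUP-family tags supply ``grms`` (over all individuals, in
    ``sample_ids`` order); for Bayes-family tags supply ``design_columns``.
    A failed fold is recorded and the run continues.
    """
    y_adj = np.asarray(y_adj, dtype=float)
    ids = list(sample_ids)
    pos = {s: i for i, s in enumerate(ids)}
    rows = []
    is_blup = model_tag in BLUP_TAGS
    if is_blup and not grms:
        raise ValueError(f"{model_tag} needs relationship matrices")
    if not is_blup and model_tag not in BAYES_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}")
    if not is_blup and design_columns is None:
        raise ValueError(f"{model_tag} needs design columns")

    for rep, groups in enumerate(plan.assignments):
        for fold, val_ids in enumerate(groups):
            val_idx = np.array([pos[s] for s in val_ids], dtype=int)
            train_mask = np.ones(len(ids), dtype=bool)
            train_mask[val_idx] = False
            train_idx = np.flatnonzero(train_mask)
            try:
                if is_blup:
                    model = GBLUP(
                        y_adj[train_idx], grms,
                        train_ids=[ids[i] for i in train_idx], model_tag=model_tag,
                    )
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = model.fit()
                    gebv_val = res.gebv.to_numpy()[val_idx]
                else:
                    M, p = design_columns
                    cfg = bayes_cfg or BayesBConfig()
                    cfg = BayesBConfig(**{**cfg.__dict__, "seed": cfg.seed + 1000 * rep + fold})
                    bm = BayesB(y_adj[train_idx], M[train_idx], p=p, config=cfg)
                    bres = bm.fit()
                    gebv_val = bres.predict(M[val_idx])
                r = accuracy(y_adj[val_idx], gebv_val)
                b = bias(y_adj[val_idx], gebv_val)
                rows.append((model_tag, rep, fold, val_idx.size, r, b, False))
            except Exception as exc:  # fold failure is recorded, run continues
                warnings.warn(f"fold ({rep},{fold}) failed: {exc}", stacklevel=2)
                rows.append((model_tag, rep, fold, val_idx.size, np.nan, np.nan, True))
    records = pd.DataFrame(
        rows, columns=["model", "repeat", "fold", "n_validation", "accuracy", "bias", "failed"]
    )
    return CVResult(records=records, model_tag=model_tag)
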