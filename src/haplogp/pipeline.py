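"""End-to-end pipeline: simulate/load → QC → blocks → encode → GRM → fit → CV.

A run is described by one YAML config (see :class:`RunConfig`); every stage
writes plain-text outputs into the run directory plus a manifest recording
the package version, the master seed and a hash of the config, so any output
is regenerable from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import child_seed
from .bayesb import BayesBConfig, columns_for_model
from .blocks import block_summary, fixed_partition, ld_partition, write_block_table
from .evalcv import BLUP_TAGS, kfold_split, paired_onesided_ttest, percent_change, run_cv
from .genio import (
    PhenotypeTable,
    read_phased_vcf,
    read_phenotypes,
    write_phased_vcf,
    write_phenotypes,
)
from .grm import grm_for_model
from .hapcode import build_design, design_summary, enumerate_alleles, write_catalog
from .mixedmodel import adjust_phenotypes
from .simdata import SimConfig, simulate_panel, simulate_phenotypes, write_truth

ALL_MODELS = ("GBLUP", "G_H_BLUP", "G_H_BLUP+GBLUP", "BayesB", "BayesBH", "BayesBH+BayesB")


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "haplogp_run"
    simulate: dict | None = None  # SimConfig fields
    input: dict | None = None  # {vcf, phenotypes, traits, factors, covariates}
    qc: dict = field(default_factory=dict)
    ld_thresholds: list = field(default_factory=lambda: [0.3])
    fixed_k: list = field(default_factory=list)
    chunking_mode: str = "genome_wide"
    mhaf: list = field(default_factory=lambda: [0.01])
    models: list = field(default_factory=lambda: ["GBLUP", "G_H_BLUP"])
    bayesb: dict = field(default_factory=dict)
    cv: dict = field(default_factory=lambda: {"k": 5, "repeats": 5})
    adjust_alpha: float = 0.05

    def validate(self) -> None:
        if not self.models:
            raise ValueError("config error: at least one model is required")
        for m in self.models:
            if m not in ALL_MODELS:
                raise ValueError(f"config error: unknown model {m!r} (choose from {ALL_MODELS})")
        if not self.ld_thresholds and not self.fixed_k:
            raise ValueError("config error: block grid is empty (ld_thresholds and fixed_k)")
        if (self.simulate is None) == (self.input is None):
            raise ValueError("config error: exactly one of 'simulate' or 'input' must be given")
        if not self.mhaf:
            raise ValueError("config error: mhaf grid is empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"config error: unknown keys {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        canon = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _block_settings(cfg: RunConfig):
    for thr in cfg.ld_thresholds:
        yield ("ld", float(thr), f"ld{thr}")
    for k in cfg.fixed_k:
        yield ("fixed", int(k), f"fixed{k}")


def run(cfg: RunConfig, resume: bool = False) -> dict:
    """Execute the configured grid; returns the manifest dict."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": [],
        "results": [],
    }

    # --- stage: genotypes + phenotypes -------------------------------
    panel_path = out / "panel.vcf"
    pheno_path = out / "phenotypes.tsv"
    if cfg.simulate is not None:
        sim = SimConfig(**{**cfg.simulate, "seed": child_seed(cfg.seed, "simulate")})
        if resume and panel_path.exists() and pheno_path.exists():
            panel = read_phased_vcf(panel_path)
            pheno = read_phenotypes(pheno_path, traits=["trait"],
                                    factors=[f[0] for f in (sim.fixed_effect_spec or [])])
        else:
            panel = simulate_panel(sim)
            pheno, truth = simulate_phenotypes(panel, sim)
            write_phased_vcf(panel, panel_path)
            write_phenotypes(pheno, pheno_path)
            write_truth(truth, out / "truth.tsv")
        manifest["stages"].append("simulate")
    else:
        panel = read_phased_vcf(cfg.input["vcf"])
        pheno = read_phenotypes(
            cfg.input["phenotypes"],
            traits=cfg.input.get("traits", ["trait"]),
            factors=cfg.input.get("factors", []),
            covariates=cfg.input.get("covariates", []),
        )
        manifest["stages"].append("load")

    # --- stage: QC ----------------------------------------------------
    from .genio import qc_filter

    panel, report = qc_filter(panel, **cfg.qc)
    report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    manifest["stages"].append("qc")

    # align phenotypes to surviving individuals
    keep = pheno.data["sample_id"].isin(panel.sample_ids)
    pheno = PhenotypeTable(pheno.data[keep].reset_index(drop=True),
                           pheno.traits, pheno.factors, pheno.covariates)

    adj = adjust_phenotypes(pheno, alpha=cfg.adjust_alpha)
    pd.DataFrame({"sample_id": adj.sample_ids, "y_adj": adj.y_adj}).to_csv(
        out / "adjusted.tsv", sep="\t", index=False
    )
    manifest["stages"].append("adjust")

    # reorder y to panel id order
    y_lookup = dict(zip(adj.sample_ids, adj.y_adj))
    y = np.array([y_lookup[s] for s in panel.sample_ids])

    plan = kfold_split(panel.sample_ids, k=cfg.cv.get("k", 5),
                       repeats=cfg.cv.get("repeats", 5), seed=child_seed(cfg.seed, "cv"))

    comparison_rows = []
    for method, thr, tag in _block_settings(cfg):
        if method == "ld":
            part = ld_partition(panel, thr)
        else:
            part = fixed_partition(panel.marker_map, thr, cfg.chunking_mode)
        write_block_table(part, panel.marker_map, out / f"blocks_{tag}.tsv")
        catalog = enumerate_alleles(panel, part)
        write_catalog(catalog, out / f"catalog_{tag}.tsv")
        for mhaf in cfg.mhaf:
            design = build_design(panel, part, catalog, mhaf=mhaf)
            gtag = f"{tag}_mhaf{mhaf}"
            design_summary(design).to_csv(out / f"design_{gtag}.tsv", sep="\t", index=False)
            bs = block_summary(part, design)
            print(f"[haplogp] {gtag}: {bs.n_blocks} blocks, "
                  f"{bs.n_snps_in_blocks} SNPs in / {bs.n_snps_out_of_blocks} out, "
                  f"{bs.n_alleles_total} allele columns")

            grms_cache: dict = {}

            def get_grm(which):
                if which not in grms_cache:
                    grms_cache[which] = grm_for_model(design, which, sample_ids=panel.sample_ids)
                return grms_cache[which]

            cv_acc: dict = {}
            for model in cfg.models:
                seed_m = child_seed(cfg.seed, f"cv:{gtag}:{model}")
                if model in BLUP_TAGS:
                    try:
                        grms = [get_grm(w) for w in BLUP_TAGS[model]]
                    except ValueError as exc:
                        print(f"[haplogp] {model} skipped for {gtag}: {exc}")
                        continue
                    cvres = run_cv(y, panel.sample_ids, model, plan, grms=grms)
                else:
                    M, p, _ids, _cls = columns_for_model(design, model)
                    bb = BayesBConfig(**{**cfg.bayesb, "seed": seed_m})
                    cvres = run_cv(y, panel.sample_ids, model, plan,
                                   design_columns=(M, p), bayes_cfg=bb)
                cvres.export(out / f"cv_{gtag}_{model.replace('+', 'p')}.tsv")
                summ = cvres.summary()
                summ.update({"setting": gtag})
                manifest["results"].append(summ)
                cv_acc[model] = cvres.records["accuracy"].to_numpy()

            # paired haplotype-vs-SNP comparisons where both sides ran
            for hap, snp in (("G_H_BLUP", "GBLUP"), ("BayesBH", "BayesB"),
                             ("G_H_BLUP+GBLUP", "GBLUP"), ("BayesBH+BayesB", "BayesB")):
                if hap in cv_acc and snp in cv_acc:
                    pc, se = percent_change(cv_acc[hap], cv_acc[snp])
                    t, df, pval = paired_onesided_ttest(cv_acc[hap], cv_acc[snp])
                    stars = "**" if pval < 0.01 else ("*" if pval < 0.05 else "")
                    comparison_rows.append((gtag, hap, snp, pc, se, t, df, pval, stars))

    if comparison_rows:
        pd.DataFrame(
            comparison_rows,
            columns=["setting", "model", "baseline", "percent_change", "se",
                     "t", "df", "p_one_sided", "significance"],
        ).to_csv(out / "comparison.tsv", sep="\t", index=False)
    manifest["stages"].append("cv")

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
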