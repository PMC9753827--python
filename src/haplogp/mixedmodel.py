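"""Phenotype adjustment, REML variance components, and (G)BLUP prediction.

The workflow mirrors standard animal-model practice: raw records are first
adjusted for significant fixed effects and covariates by ordinary least
squares (adjusted phenotype = residual + grand mean); variance components of

    y = 1μ + a (+ a_u) + e,    a ~ N(0, σa² K1),  a_u ~ N(0, σau² K2),
    e ~ N(0, σe² I)

are then estimated by average-information REML with EM fallback steps, and
genomic values for unphenotyped individuals come from the mixed-model
equations through the train–validation blocks of the relationship matrices.
Each individual contributes one adjusted record, so the incidence matrices
are identities.

The statsmodels-style entry point is :class:`GBLUP` → :class:`GBLUPResults`;
the functional layer (:func:`reml_fit`, :func:`blup_predict`,
:func:`heritability`) is what the class drives underneath.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .genio import PhenotypeTable
from .grm import GRM

__all__ = [
    "AdjustedPhenotype",
    "VarianceComponents",
    "FitResult",
    "adjust_phenotypes",
    "reml_fit",
    "blup_predict",
    "heritability",
    "GBLUP",
    "GBLUPResults",
]


@dataclass
class AdjustedPhenotype:
    sample_ids: list
    y_adj: np.ndarray
    retained_factors: list
    model_p_values: dict


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    sigma_au2: Optional[float] = None
    h2: float = np.nan
    se_h2: float = np.nan
    loglik: float = np.nan
    converged: bool = False
    n_iter: int = 0
    h2_components: dict = field(default_factory=dict)
    cov_theta: Optional[np.ndarray] = None

    @property
    def variances(self) -> np.ndarray:
        if self.sigma_au2 is None:
            return np.array([self.sigma_a2, self.sigma_e2])
        return np.array([self.sigma_a2, self.sigma_au2, self.sigma_e2])


@dataclass
class FitResult:
    vc: VarianceComponents
    mu: float
    gebv: pd.Series  # indexed by sample id, train + validation
    model_tag: str


# ----------------------------------------------------------------------
# Fixed-effect pre-adjustment
# ----------------------------------------------------------------------

def adjust_phenotypes(pheno: PhenotypeTable, trait: Optional[str] = None, alpha: float = 0.05) -> AdjustedPhenotype:
    """OLS screening of candidate fixed effects; keep terms with F-test
    p < alpha, refit, and return residual + grand mean."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    trait = trait or pheno.traits[0]
    df = pheno.data.copy()
    y = df[trait].to_numpy(dtype=float)
    terms = [f"C({f})" for f in pheno.factors] + list(pheno.covariates)
    pvals: dict = {}
    retained: list = []
    if terms:
        model = smf.ols(f"{trait} ~ {' + '.join(terms)}", data=df).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                tbl = anova_lm(model, typ=2)
            except Exception:
                tbl = anova_lm(model, typ=1)
        for term in terms:
            if term in tbl.index:
                p = float(tbl.loc[term, "PR(>F)"])
                pvals[term] = p
                if np.isnan(p) or p < alpha:
                    if not np.isnan(p):
                        retained.append(term)
    if retained:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            refit = smf.ols(f"{trait} ~ {' + '.join(retained)}", data=df).fit()
        y_adj = refit.resid.to_numpy() + y.mean()
    else:
        y_adj = y.copy()
    return AdjustedPhenotype(
        sample_ids=df["sample_id"].tolist(),
        y_adj=y_adj,
        retained_factors=retained,
        model_p_values=pvals,
    )


# ----------------------------------------------------------------------
# AI-REML
# ----------------------------------------------------------------------

def _as_matrix(g) -> np.ndarray:
    return g.matrix if isinstance(g, GRM) else np.asarray(g, dtype=float)


def _reml_quantities(y: np.ndarray, Ks: list, theta: np.ndarray):
    """Restricted loglik, score, AI matrix and P-projections at theta.

    Ks are the K+1 covariance bases (GRMs then I); theta the variances.
    """
    n = y.size
    V = sum(t * K for t, K in zip(theta, Ks))
    c, low = cho_factor(V, lower=True)
    Vinv = cho_solve((c, low), np.eye(n))
    logdetV = 2.0 * np.sum(np.log(np.diag(c)))
    one = np.ones(n)
    Vi1 = Vinv @ one
    s = float(one @ Vi1)
    Viy = Vinv @ y
    Py = Viy - Vi1 * (float(one @ Viy) / s)
    yPy = float(y @ Py)
    ll = -0.5 * (logdetV + np.log(s) + yPy)

    K1 = len(Ks)
    u = [K @ Py for K in Ks]
    score = np.empty(K1)
    AI = np.empty((K1, K1))
    Pu = []
    for k in range(K1):
        trPK = float(np.sum(Vinv * Ks[k])) - float(Vi1 @ Ks[k] @ Vi1) / s
        score[k] = -0.5 * (trPK - float(Py @ u[k]))
        Puk = Vinv @ u[k] - Vi1 * (float(Vi1 @ u[k]) / s)
        Pu.append(Puk)
    for k in range(K1):
        for l in range(k, K1):
            AI[k, l] = AI[l, k] = 0.5 * float(u[k] @ Pu[l])
    yPVP = np.array([float(Py @ uk) for uk in u])
    trPV = np.array([-2.0 * score[k] + yPVP[k] for k in range(K1)])
    return ll, score, AI, yPVP, trPV


def reml_fit(
    y_adj: np.ndarray,
    grms: Sequence,
    tol: float = 1e-8,
    max_iter: int = 200,
    verbose: bool = False,
) -> VarianceComponents:
    """Average-information REML for one or two genomic variance components.

    EM-form fallback steps replace an AI update that proposes a negative
    component or decreases the restricted likelihood; accepted iterations
    therefore never decrease the restricted log-likelihood.  Components are
    floored at 1e-10·var(y).
    """
    y = np.asarray(y_adj, dtype=float)
    n = y.size
    if n < 30:
        warnings.warn(f"REML with n={n} < 30 records is fragile", stacklevel=2)
    if not 1 <= len(grms) <= 2:
        raise ValueError("reml_fit supports one or two GRMs")
    Ks = [_as_matrix(g) for g in grms] + [np.eye(n)]
    for K in Ks[:-1]:
        if K.shape != (n, n):
            raise ValueError("GRM dimensions must match the phenotype vector")
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-6 * max(1.0, w.max()):
            raise ValueError("GRM is not PSD within tolerance; consider grm_ridge")

    vy = float(np.var(y))
    floor = 1e-10 * vy
    K1 = len(Ks)
    theta = np.full(K1, vy / K1)
    ll, score, AI, yPVP, trPV = _reml_quantities(y, Ks, theta)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # AI proposal
        try:
            step = np.linalg.solve(AI + 1e-12 * np.eye(K1), score)
        except np.linalg.LinAlgError:
            step = score / np.maximum(np.diag(AI), 1e-12)
        prop = theta + step
        if np.any(prop < floor):
            # EM-form fallback: theta_k + theta_k^2 (y'PV_kPy - tr(PV_k)) / n
            prop = theta + theta**2 * (yPVP - trPV) / n
        prop = np.maximum(prop, floor)

        ll_new, score_new, AI_new, yPVP_new, trPV_new = _reml_quantities(y, Ks, prop)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            prop = theta + 0.5 * (prop - theta)
            ll_new, score_new, AI_new, yPVP_new, trPV_new = _reml_quantities(y, Ks, prop)
            halvings += 1
        if ll_new < ll - 1e-12:
            converged = True  # cannot improve: treat current point as optimum
            break
        delta = ll_new - ll
        theta, ll, score, AI, yPVP, trPV = prop, ll_new, score_new, AI_new, yPVP_new, trPV_new
        if verbose:
            print(f"iter {it}: ll={ll:.8f} theta={theta}")
        if abs(delta) < tol:
            converged = True
            break

    try:
        cov_theta = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov_theta = np.full((K1, K1), np.nan)

    if K1 == 2:
        sa2, se2 = theta
        sau2 = None
        tot = sa2 + se2
        h2 = sa2 / tot if tot > 0 else 0.0
        g = np.array([se2, -sa2]) / tot**2
        comps = {"h2": h2}
    else:
        sa2, sau2, se2 = theta
        tot = sa2 + sau2 + se2
        h2 = (sa2 + sau2) / tot if tot > 0 else 0.0
        g = np.array([se2, se2, -(sa2 + sau2)]) / tot**2
        comps = {
            "h2_total": h2,
            "h2_first": sa2 / tot if tot > 0 else 0.0,
            "h2_second": sau2 / tot if tot > 0 else 0.0,
        }
    se_h2 = float(np.sqrt(max(g @ cov_theta @ g, 0.0))) if np.isfinite(cov_theta).all() else np.nan

    return VarianceComponents(
        sigma_a2=float(sa2),
        sigma_au2=None if sau2 is None else float(sau2),
        sigma_e2=float(se2),
        h2=float(np.clip(h2, 0.0, 1.0)),
        se_h2=se_h2,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
        h2_components=comps,
        cov_theta=cov_theta,
    )


def blup_predict(
    y_adj_train: np.ndarray,
    grms: Sequence,
    vc: VarianceComponents,
    train_idx: np.ndarray,
    sample_ids: Optional[list] = None,
    model_tag: str = "GBLUP",
) -> FitResult:
    """BLUP of genomic values for all individuals from training records.

    ``grms`` cover train + validation individuals; ``train_idx`` indexes the
    training records (aligned with ``y_adj_train``).  Validation GEBVs come
    from the conditional expectation through the train–validation GRM
    cross-blocks; with two components the GEBV is the per-individual sum.
    """
    Ks = [_as_matrix(g) for g in grms]
    n_all = Ks[0].shape[0]
    train_idx = np.asarray(train_idx, dtype=int)
    y = np.asarray(y_adj_train, dtype=float)
    if y.size != train_idx.size:
        raise ValueError("y_adj_train and train_idx lengths differ")
    sig = vc.variances
    if sig.size != len(Ks) + 1:
        raise ValueError("variance components do not match the number of GRMs")

    nt = train_idx.size
    V = sum(s * K[np.ix_(train_idx, train_idx)] for s, K in zip(sig[:-1], Ks))
    V = V + sig[-1] * np.eye(nt)
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular mixed-model coefficient matrix; consider grm_ridge") from exc
    one = np.ones(nt)
    Vi1 = cho_solve((c, low), one)
    Viy = cho_solve((c, low), y)
    mu = float(one @ Viy) / float(one @ Vi1)
    alpha = cho_solve((c, low), y - mu)

    gebv = np.zeros(n_all)
    for s, K in zip(sig[:-1], Ks):
        gebv += s * (K[:, train_idx] @ alpha)

    ids = list(sample_ids) if sample_ids is not None else (
        grms[0].sample_ids if isinstance(grms[0], GRM) else [f"ind{i}" for i in range(n_all)]
    )
    return FitResult(vc=vc, mu=mu, gebv=pd.Series(gebv, index=ids), model_tag=model_tag)


def heritability(vc: VarianceComponents):
    """(h², SE) — σa²/(σa²+σe²) for the one-component model; for the
    two-component model the summed proportion, as recorded at fit time."""
    return vc.h2, vc.se_h2


# ----------------------------------------------------------------------
# statsmodels-style front end
# ----------------------------------------------------------------------

class GBLUP:
    """GBLUP-family model: adjusted phenotypes plus 1–2 relationship matrices.

    Parameters
    ----------
    y_adj
        Adjusted phenotype records for the training individuals.
    grms
        One GRM (GBLUP or G_H_BLUP) or two (G_H_BLUP+GBLUP), covering all
        individuals for which GEBVs are wanted.
    train_ids
        Ids of the phenotyped individuals (default: all GRM ids, in order).
    model_tag
        Optional label; inferred from the GRM sources when omitted.

    Examples
    --------
    >>> res = GBLUP(y, [g]).fit()
    >>> res.vc.h2, res.gebv
    """

    def __init__(self, y_adj, grms, train_ids=None, model_tag: Optional[str] = None):
        self.grms = list(grms) if isinstance(grms, (list, tuple)) else [grms]
        if not 1 <= len(self.grms) <= 2:
            raise ValueError("GBLUP takes one or two GRMs")
        first = self.grms[0]
        self.sample_ids = first.sample_ids if isinstance(first, GRM) else [
            f"ind{i}" for i in range(_as_matrix(first).shape[0])
        ]
        if train_ids is None:
            self.train_idx = np.arange(len(self.sample_ids))
        else:
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            self.train_idx = np.array([lookup[s] for s in train_ids], dtype=int)
        self.y_adj = np.asarray(y_adj, dtype=float)
        if self.y_adj.size != self.train_idx.size:
            raise ValueError("y_adj length must match the training ids")
        if model_tag is None:
            srcs = [g.source if isinstance(g, GRM) else "snp" for g in self.grms]
            if len(srcs) == 2:
                model_tag = "G_H_BLUP+GBLUP"
            elif srcs[0] == "haplotype":
                model_tag = "G_H_BLUP"
            else:
                model_tag = "GBLUP"
        self.model_tag = model_tag

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, grms, trait: str = "trait", id_col: str = "sample_id", **kw):
        return cls(df[trait].to_numpy(dtype=float), grms, train_ids=df[id_col].tolist(), **kw)

    def fit(self, tol: float = 1e-8, max_iter: int = 200, verbose: bool = False) -> "GBLUPResults":
        sub = [_as_matrix(g)[np.ix_(self.train_idx, self.train_idx)] for g in self.grms]
        vc = reml_fit(self.y_adj, sub, tol=tol, max_iter=max_iter, verbose=verbose)
        fr = blup_predict(
            self.y_adj, self.grms, vc, self.train_idx,
            sample_ids=self.sample_ids, model_tag=self.model_tag,
        )
        return GBLUPResults(self, vc, fr)


class GBLUPResults:
    """REML estimates, heritability and GEBVs for a fitted GBLUP model."""

    def __init__(self, model: GBLUP, vc: VarianceComponents, fr: FitResult):
        self.model = model
        self.vc = vc
        self.mu = fr.mu
        self.gebv = fr.gebv
        self.model_tag = fr.model_tag

    @property
    def h2(self) -> float:
        return self.vc.h2

    def predict(self, ids=None) -> pd.Series:
        """Full predictions μ + GEBV (correlation metrics are shift-invariant)."""
        out = self.mu + self.gebv
        return out if ids is None else out.loc[list(ids)]

    def summary(self) -> str:
        vc = self.vc
        lines = [
            f"{self.model_tag} fit (AI-REML)",
            "=" * 34,
            f"records            {self.model.y_adj.size}",
            f"individuals        {len(self.model.sample_ids)}",
            f"sigma_a2           {vc.sigma_a2:.6g}",
        ]
        if vc.sigma_au2 is not None:
            lines.append(f"sigma_au2          {vc.sigma_au2:.6g}")
        lines += [
            f"sigma_e2           {vc.sigma_e2:.6g}",
            f"h2                 {vc.h2:.4f} (SE {vc.se_h2:.4f})",
            f"mu                 {self.mu:.6g}",
            f"restricted loglik  {vc.loglik:.6f}",
            f"converged          {vc.converged} ({vc.n_iter} iterations)",
        ]
        return "\n".join(lines)

    def export(self, path) -> None:
        self.gebv.rename("gebv").to_csv(path, sep="\t", index_label="sample_id")
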