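"""Gene-level rare-variant association: CMC and SKAT.

Variants enter a gene set when they are protein-altering and have sample
MAF < 0.05 (strict).  CMC collapses the set to a per-sample carrier
indicator (any minor allele across the set) tested by covariate-adjusted
logistic regression; with the MAF filter the multivariate common-variant
component of CMC is empty, so the collapsed form is the whole test.

SKAT is the variance-component score test: with null fitted probabilities
mu from a covariates-only logistic model,

    Q = (y - mu)' G W^2 G' (y - mu)

where G is the gene's dosage submatrix and W the diagonal of Beta(1, 25)
density weights at each variant's MAF (the canonical SKAT default).  The
null distribution of Q is the weighted mixture sum_i lambda_i chi2_1 with
lambda_i the eigenvalues of W G' P0 G W, P0 the projected null variance
operator.  P-values come from characteristic-function inversion (Imhof's
integral) with a Liu moment-matching fallback, recorded in the metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, stats

from .core import MISSING, CohortBundle
from .assoc import _prepare_outcome, _resolve_covariates, _fit_one


@dataclass
class GeneSet:
    gene: str
    variant_ids: list
    n_carriers: int | None = None


def skat_weights(maf: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(a, b) density evaluated at the MAF (SKAT default a=1, b=25,
    i.e. w = 25 (1 - maf)^24)."""
    return stats.beta.pdf(np.asarray(maf, dtype=float), a, b)


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def build_gene_sets(bundle: CohortBundle, annotation: pd.DataFrame | None = None,
                    maf_max: float = 0.05,
                    protein_altering_only: bool = True) -> list[GeneSet]:
    """One GeneSet per annotated gene from qualifying variants.

    ``annotation`` maps variant_id -> gene (long format, one row per
    assignment; a variant annotated to two genes joins both sets).  When
    omitted, the bundle's own ``gene``/``protein_altering`` columns are used.
    MAF is computed on the bundle sample; the ``maf_max`` bound is strict.
    Genes whose sets end up empty are still returned (flagged untestable by
    the tests themselves).
    """
    maf = pd.Series(bundle.maf(), index=bundle.variants.index)
    if annotation is None:
        ann = bundle.variants.reset_index()[["variant_id", "gene"]].copy()
        if protein_altering_only and "protein_altering" in bundle.variants:
            pa = bundle.variants["protein_altering"].reindex(ann["variant_id"]).to_numpy()
            ann = ann[pa]
    else:
        ann = annotation.copy()
        if protein_altering_only and "protein_altering" in ann:
            ann = ann[ann["protein_altering"]]
    ann = ann[ann["variant_id"].isin(maf.index)]
    qualifies = ann["variant_id"].map(maf) < maf_max
    carriers = _minor_dosage_matrix(bundle) > 0

    sets = []
    for gene, grp in ann.groupby("gene", sort=True):
        vids = list(grp.loc[qualifies[grp.index], "variant_id"])
        n_car = None
        if vids:
            cols = [bundle.variants.index.get_loc(v) for v in vids]
            n_car = int(carriers[:, cols].any(axis=1).sum())
        sets.append(GeneSet(gene=str(gene), variant_ids=vids, n_carriers=n_car))
    return sets


def _minor_dosage_matrix(bundle: CohortBundle, cols=None) -> np.ndarray:
    """Minor-allele dosage with missing treated as zero copies."""
    g = bundle.genotypes if cols is None else bundle.genotypes[:, cols]
    called = g != MISSING
    n2 = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n2 > 0, np.where(called, g, 0).sum(axis=0) / n2, np.nan)
    flip = np.nan_to_num(p) > 0.5
    d = np.where(flip[None, :], 2 - g, g)
    return np.where(g == MISSING, 0, d)


# ---------------------------------------------------------------------------
# Null model (fit once per outcome, shared by both tests)
# ---------------------------------------------------------------------------

class NullModel:
    """Covariates-only logistic null fit with the projected variance operator."""

    def __init__(self, bundle: CohortBundle, outcome, covariates=None):
        rows, y = _prepare_outcome(bundle, outcome)
        covars = _resolve_covariates(bundle, covariates)
        X = np.ones((rows.size, 1))
        if covars is not None:
            X = np.column_stack([X, covars[rows]])
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        self.rows = rows
        self.y = y
        self.X = X
        self.mu = np.asarray(fit.fittedvalues)
        self.resid = y - self.mu
        self.v = self.mu * (1 - self.mu)
        VX = X * self.v[:, None]
        self.VX = VX
        self.XVX_inv = np.linalg.inv(X.T @ VX)
        self.covars = covars[rows] if covars is not None else None

    def project_quad(self, Gw: np.ndarray) -> np.ndarray:
        """W G' P0 G W for a weighted dosage matrix Gw (n x m)."""
        A = Gw.T @ (Gw * self.v[:, None])
        B = Gw.T @ self.VX
        return A - B @ self.XVX_inv @ B.T


# ---------------------------------------------------------------------------
# Mixture-of-chi-squared p-values
# ---------------------------------------------------------------------------

def mixture_chi2_sf(q: float, lambdas: np.ndarray) -> tuple[float, str]:
    """P(sum_i lambda_i chi2_1 > q) by Imhof characteristic-function
    inversion, falling back to Liu moment matching.  Returns (p, method)."""
    lam = np.asarray(lambdas, dtype=float)
    lam = lam[lam > 1e-12 * max(lam.max(initial=0.0), 1.0)]
    if lam.size == 0 or q <= 0:
        return 1.0, "degenerate"
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1)), "exact-chi2"

    # Imhof: p = 1/2 + (1/pi) int_0^inf sin(phi(u) - qu/2) / (u rho(u)) du.
    # The head [0, a] is integrated directly; the oscillatory tail uses
    # QUADPACK's sin/cos weights at frequency q/2 (sin(phi - qu/2) expanded).
    def phi_rho(u):
        return (0.5 * np.sum(np.arctan(lam * u)),
                np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2))))

    def head(u):
        p_, r_ = phi_rho(u)
        return np.sin(p_ - 0.5 * q * u) / (u * r_)

    def tail_sin(u):
        p_, r_ = phi_rho(u)
        return np.sin(p_) / (u * r_)

    def tail_cos(u):
        p_, r_ = phi_rho(u)
        return np.cos(p_) / (u * r_)

    a = 1.0 if q >= 2 * np.pi else 2 * np.pi / q
    a = min(a, 64.0)  # cap the directly integrated head; QAWF owns the tail
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            v0, e0 = integrate.quad(head, 0, a, limit=200)
            v1, e1 = integrate.quad(tail_sin, a, np.inf, weight="cos",
                                    wvar=q / 2, limit=200)
            v2, e2 = integrate.quad(tail_cos, a, np.inf, weight="sin",
                                    wvar=q / 2, limit=200)
        p = 0.5 + (v0 + v1 - v2) / np.pi
        if np.isfinite(p) and e0 + e1 + e2 < 1e-6 and -1e-8 <= p <= 1 + 1e-8:
            return float(min(max(p, 1e-14), 1.0)), "imhof"
    except Exception:
        pass
    return _liu_sf(q, lam), "liu"


def _liu_sf(q: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matched non-central chi-squared approximation."""
    c = [np.sum(lam ** k) for k in (1, 2, 3, 4)]
    s1 = c[2] / c[1] ** 1.5
    s2 = c[3] / c[1] ** 2
    if s1 ** 2 > s2:
        a = 1 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = 1 / s2
    mu_q, sigma_q = c[0], np.sqrt(2 * c[1])
    mu_x, sigma_x = df + delta, np.sqrt(2 * (df + 2 * delta))
    t = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(min(max(stats.ncx2.sf(t, df, delta), 1e-14), 1.0))


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------

def cmc_test(bundle: CohortBundle, gene_set: GeneSet, outcome,
             covariates=None, null: NullModel | None = None) -> dict:
    """Collapsed carrier-indicator logistic test; 1-df Wald p.

    Returns a dict with ``p``, ``or``, ``n_carriers`` and ``status``
    ('untestable' when no sample, or every sample, carries a minor allele).
    """
    if not gene_set.variant_ids:
        return {"p": np.nan, "or": np.nan, "n_carriers": 0, "status": "untestable"}
    null = null or NullModel(bundle, outcome, covariates)
    cols = [bundle.variants.index.get_loc(v) for v in gene_set.variant_ids]
    carrier = (_minor_dosage_matrix(bundle, cols)[null.rows] > 0).astype(float)
    carrier = carrier.any(axis=1).astype(float) if carrier.ndim > 1 else carrier
    n_car = int(carrier.sum())
    if n_car == 0 or n_car == carrier.size:
        return {"p": np.nan, "or": np.nan, "n_carriers": n_car, "status": "untestable"}
    res = _fit_one(null.y, null.covars, carrier)
    return {"p": res["p"], "or": res["or"], "n_carriers": n_car,
            "status": res["status"]}


def skat_test(bundle: CohortBundle, gene_set: GeneSet, outcome,
              covariates=None, weight_beta: tuple = (1.0, 25.0),
              null: NullModel | None = None) -> dict:
    """SKAT variance-component score test for one gene set.

    Returns ``Q``, ``p``, the p-value algorithm used (``imhof`` or the
    moment-matching fallback ``liu``) and the weight specification.
    """
    if not gene_set.variant_ids:
        return {"Q": np.nan, "p": np.nan, "method": "untestable",
                "weights": f"beta{weight_beta}", "status": "untestable"}
    null = null or NullModel(bundle, outcome, covariates)
    cols = [bundle.variants.index.get_loc(v) for v in gene_set.variant_ids]
    G = _minor_dosage_matrix(bundle, cols)[null.rows].astype(float)
    maf = G.sum(axis=0) / (2.0 * G.shape[0])
    keep = (maf > 0) & (maf < 1)
    if not keep.any():
        return {"Q": np.nan, "p": np.nan, "method": "untestable",
                "weights": f"beta{weight_beta}", "status": "untestable"}
    G = G[:, keep]
    w = skat_weights(maf[keep], *weight_beta)
    Gw = G * w[None, :]
    Q = float(np.sum((Gw.T @ null.resid) ** 2))
    M = null.project_quad(Gw)
    try:
        lam = np.linalg.eigvalsh(M)
    except np.linalg.LinAlgError:
        return {"Q": Q, "p": _liu_sf(Q, np.diag(M)), "method": "liu-fallback",
                "weights": f"beta{weight_beta}", "status": "eig-failed"}
    p, method = mixture_chi2_sf(Q, lam)
    return {"Q": Q, "p": p, "method": method,
            "weights": f"beta{weight_beta}", "status": "ok"}


def gene_scan(bundle: CohortBundle, outcome, covariates=None,
              annotation: pd.DataFrame | None = None, alpha: float = 0.05,
              n_genes: int | None = None, maf_max: float = 0.05) -> pd.DataFrame:
    """CMC and SKAT for every gene set; Bonferroni threshold alpha/n_genes
    (``n_genes`` defaults to the number of testable genes)."""
    sets = build_gene_sets(bundle, annotation, maf_max=maf_max)
    null = NullModel(bundle, outcome, covariates)
    rows = []
    for gs in sets:
        if not gs.variant_ids:
            continue
        cmc = cmc_test(bundle, gs, outcome, covariates, null=null)
        skat = skat_test(bundle, gs, outcome, covariates, null=null)
        rows.append({
            "gene": gs.gene, "n_variants": len(gs.variant_ids),
            "n_carriers": cmc["n_carriers"],
            "cmc_p": cmc["p"], "cmc_or": cmc["or"], "cmc_status": cmc["status"],
            "skat_q": skat["Q"], "skat_p": skat["p"],
            "skat_method": skat["method"], "skat_status": skat["status"],
        })
    out = pd.DataFrame.from_records(rows)
    if out.empty:
        return out
    out = out.set_index("gene")
    denom = n_genes if n_genes is not None else len(out)
    threshold = alpha / max(denom, 1)
    out["bonferroni_threshold"] = threshold
    out["cmc_significant"] = out["cmc_p"] < threshold
    out["skat_significant"] = out["skat_p"] < threshold
    return out
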