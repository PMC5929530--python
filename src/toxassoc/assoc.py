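"""Single-variant case-control association and diagnostics.

Per-variant additive-dosage logistic regression (Wald test) with ancestry
principal components as covariates, the 2x2 allelic chi-squared test, the
genomic inflation factor lambda, a scan over imputed binary HLA markers, and
plot-ready QQ/Manhattan exports.  Fitting is done with statsmodels; variants
with separation or non-convergence are flagged, never silently dropped, and
are excluded from the lambda computation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import MISSING, CohortBundle

logger = logging.getLogger("toxassoc.assoc")

#: Median of the 1-df chi-squared distribution, the lambda denominator.
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, 1))


def _fit_one(y: np.ndarray, covars: np.ndarray | None, g: np.ndarray) -> dict:
    """Wald logistic fit of y on [intercept, covariates, dosage]."""
    X = np.column_stack([np.ones_like(g)] +
                        ([covars] if covars is not None else []) + [g])
    out = {"beta": np.nan, "se": np.nan, "or": np.nan, "chi2": np.nan,
           "p": np.nan, "status": "ok"}
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        beta, se = fit.params[-1], fit.bse[-1]
        if (not fit.mle_retvals.get("converged", False) or not np.isfinite(se)
                or se > 50 or abs(beta) > 15):
            out["status"] = "separation"
            return out
        chi2 = (beta / se) ** 2
        out.update(beta=float(beta), se=float(se), or_=np.exp(beta),
                   chi2=float(chi2), p=float(stats.chi2.sf(chi2, 1)))
        out["or"] = float(np.exp(beta))
    except Exception:
        out["status"] = "failed"
    return out


def _prepare_outcome(bundle: CohortBundle, outcome) -> tuple[np.ndarray, np.ndarray]:
    """Align a binary outcome (series or column name) to the bundle; returns
    (sample positions used, 0/1 outcome)."""
    if isinstance(outcome, str):
        outcome = bundle.samples[outcome]
    y = outcome.reindex(bundle.samples.index)
    use = y.isin([0, 1]).to_numpy()
    return np.flatnonzero(use), y.to_numpy(dtype=float)[use]


def logistic_assoc(bundle: CohortBundle, outcome, covariates=None,
                   variant_idx=None) -> pd.DataFrame:
    """Per-variant logistic Wald association.

    Parameters
    ----------
    outcome
        Binary 0/1 series (indexed by sample id) or name of a sample column.
        Values other than 0/1 (excluded / missing) drop the sample.
    covariates
        Array-like (n_samples x c) aligned to the bundle, or list of sample
        column names; typically the first two ancestry PCs.
    """
    rows_idx, y = _prepare_outcome(bundle, outcome)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("outcome needs at least one case and one control")
    covars = _resolve_covariates(bundle, covariates)
    if covars is not None:
        covars = covars[rows_idx]
        if not np.isfinite(covars).all():
            raise ValueError("covariate scores missing for analysed samples")

    vidx = (np.arange(bundle.n_variants) if variant_idx is None
            else np.asarray(variant_idx))
    records = []
    for j in vidx:
        g = bundle.genotypes[rows_idx, j].astype(float)
        called = g != MISSING
        gj, yj = g[called], y[called]
        cj = covars[called] if covars is not None else None
        n_used = int(called.sum())
        freq = gj.mean() / 2.0 if n_used else np.nan
        if n_used == 0 or gj.min() == gj.max() or yj.sum() in (0, yj.size):
            res = {"beta": np.nan, "se": np.nan, "or": np.nan, "chi2": np.nan,
                   "p": np.nan, "status": "monomorphic"}
        else:
            res = _fit_one(yj, cj, gj)
        records.append({
            "variant_id": bundle.variants.index[j], "a1_freq": freq,
            "n": n_used, "n_cases": int(yj.sum()),
            "beta": res["beta"], "se": res["se"], "or": res["or"],
            "chi2": res["chi2"], "p": res["p"], "status": res["status"],
            "test": "logistic-wald",
        })
    out = pd.DataFrame.from_records(records).set_index("variant_id")
    out["chrom"] = bundle.variants["chrom"].reindex(out.index).to_numpy()
    out["pos"] = bundle.variants["pos"].reindex(out.index).to_numpy()
    return out


def _resolve_covariates(bundle: CohortBundle, covariates):
    if covariates is None:
        return None
    if isinstance(covariates, (list, tuple)) and all(isinstance(c, str) for c in covariates):
        return bundle.samples[list(covariates)].to_numpy(dtype=float)
    return np.asarray(covariates, dtype=float)


# ---------------------------------------------------------------------------
# Allelic chi-squared
# ---------------------------------------------------------------------------

def allelic_chi2(case_counts, control_counts) -> tuple[float, float]:
    """Pearson 1-df chi-squared on a 2x2 allele-count table.

    ``case_counts`` and ``control_counts`` are (allele-1 count, allele-2
    count).  A zero margin (monomorphic) returns (nan, nan).
    """
    table = np.array([case_counts, control_counts], dtype=float)
    if table.min() < 0:
        raise ValueError("allele counts must be non-negative")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows <= 0).any() or (cols <= 0).any():
        return (np.nan, np.nan)
    expected = np.outer(rows, cols) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


def allelic_scan(genotypes: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized allelic chi-squared across variant columns.

    ``genotypes``: (n x m) dosage matrix with :data:`MISSING` sentinels;
    ``y``: 0/1 vector (or (n x P) matrix of P phenotype labellings, e.g.
    permutations, returning an (m x P) statistic matrix).  Monomorphic or
    empty-margin variants get NaN.
    """
    g = genotypes
    called = (g != MISSING)
    gz = np.where(called, g, 0).astype(np.float64)
    Y = np.atleast_2d(np.asarray(y, dtype=np.float64).T).T  # (n x P)
    case_a1 = gz.T @ Y                    # (m x P)
    case_n2 = 2.0 * (called.astype(np.float64).T @ Y)
    tot_a1 = gz.sum(axis=0)[:, None]
    tot_n2 = 2.0 * called.sum(axis=0)[:, None]
    ctrl_a1 = tot_a1 - case_a1
    ctrl_n2 = tot_n2 - case_n2
    pbar = np.divide(tot_a1, tot_n2, out=np.full_like(case_a1, np.nan),
                     where=tot_n2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = case_a1 / case_n2
        p0 = ctrl_a1 / ctrl_n2
        denom = pbar * (1 - pbar) * (1 / case_n2 + 1 / ctrl_n2)
        chi2 = (p1 - p0) ** 2 / denom
    bad = (~np.isfinite(chi2)) | (pbar <= 0) | (pbar >= 1)
    chi2 = np.where(bad, np.nan, chi2)
    return chi2 if np.asarray(y).ndim > 1 else chi2[:, 0]


# ---------------------------------------------------------------------------
# Genomic inflation
# ---------------------------------------------------------------------------

def genomic_inflation(results, min_stats: int = 100) -> float | None:
    """lambda = median(1-df chi-squared) / 0.4549...

    Accepts an association result table (uses converged rows' ``chi2``) or a
    raw array of statistics.  Returns None with a warning when fewer than
    ``min_stats`` valid statistics are available.
    """
    if isinstance(results, pd.DataFrame):
        ok = results["status"] == "ok" if "status" in results else slice(None)
        chi2 = results.loc[ok, "chi2"].to_numpy(dtype=float)
    else:
        chi2 = np.asarray(results, dtype=float)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size < min_stats:
        warnings.warn(f"only {chi2.size} valid statistics; lambda omitted")
        return None
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


# ---------------------------------------------------------------------------
# Imputed-marker scan (HLA alleles / amino acids / SNP dosages)
# ---------------------------------------------------------------------------

def marker_scan(markers: pd.DataFrame, outcome: pd.Series, covariates=None,
                family_alpha: float = 0.05) -> pd.DataFrame:
    """Logistic association for each imputed marker (markers x samples,
    dosages in [0, 2]); the significance flag is Bonferroni-corrected for the
    number of markers actually tested."""
    y_all = outcome.reindex(markers.columns)
    use = y_all.isin([0, 1]).to_numpy()
    y = y_all.to_numpy(dtype=float)[use]
    covars = None
    if covariates is not None:
        covars = np.asarray(covariates, dtype=float)[use]

    records = []
    for mid, row in markers.iterrows():
        d = row.to_numpy(dtype=float)[use]
        called = np.isfinite(d)
        dj, yj = d[called], y[called]
        cj = covars[called] if covars is not None else None
        if dj.size == 0 or dj.min() == dj.max():
            logger.info("marker %s constant; skipped", mid)
            continue
        res = _fit_one(yj, cj, dj)
        records.append({"marker_id": mid, "freq": dj.mean() / 2.0,
                        "n": int(called.sum()), **{k: res[k] for k in
                        ("beta", "se", "or", "chi2", "p", "status")}})
    out = pd.DataFrame.from_records(records)
    if out.empty:
        out = pd.DataFrame(columns=["marker_id", "freq", "n", "beta", "se",
                                    "or", "chi2", "p", "status", "significant"])
        return out.set_index("marker_id")
    out = out.set_index("marker_id")
    threshold = family_alpha / len(out)
    out["bonferroni_threshold"] = threshold
    out["significant"] = out["p"] < threshold
    return out


# ---------------------------------------------------------------------------
# Plot-ready exports
# ---------------------------------------------------------------------------

def export_plot_data(results: pd.DataFrame) -> dict:
    """QQ and Manhattan tables from an association result frame.

    QQ: sorted observed vs expected -log10(p), expected quantile for rank i
    of n being -log10((i - 0.5)/n).  Manhattan: per-chromosome cumulative
    x-coordinates with -log10(p).
    """
    valid = results[np.isfinite(results.get("p", pd.Series(dtype=float)))].copy() \
        if len(results) else results.copy()
    n = len(valid)
    if n == 0:
        return {"qq": pd.DataFrame(columns=["expected", "observed"]),
                "manhattan": pd.DataFrame(columns=["x", "chrom", "pos", "neglog10p"])}
    obs = np.sort(-np.log10(valid["p"].to_numpy()))[::-1]
    exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    qq = pd.DataFrame({"expected": exp, "observed": obs})

    man = valid.sort_values(["chrom", "pos"]).copy()
    offset = 0.0
    xs = np.empty(len(man))
    for chrom, grp in man.groupby("chrom", sort=True):
        loc = man["chrom"] == chrom
        xs[loc.to_numpy()] = offset + man.loc[loc, "pos"].to_numpy(dtype=float)
        offset += float(man.loc[loc, "pos"].max())
    man["x"] = xs
    man["neglog10p"] = -np.log10(man["p"])
    return {"qq": qq, "manhattan": man[["x", "chrom", "pos", "neglog10p"]]}
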