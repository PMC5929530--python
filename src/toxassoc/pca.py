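"""Ancestry principal components with iterative outlier removal.

EIGENSTRAT-style PCA: genotypes are mean-centred per variant and scaled by
the binomial standard deviation sqrt(p(1-p)) at the sample allele frequency;
missing genotypes are imputed to the variant mean before scaling.  Scores are
eigenvectors of the sample-sample covariance of the standardized matrix.

The outlier loop recomputes PCs on the retained samples each iteration and
removes any sample lying more than ``sd_limit`` standard deviations from the
median on any of the first ``k_outlier`` components, until none is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING, CohortBundle


@dataclass
class PCAResult:
    scores: pd.DataFrame           # retained samples x K components (PC1..PCK)
    eigenvalues: np.ndarray        # non-increasing
    variant_ids: list
    iterations: int = 1
    removed_per_iteration: list = field(default_factory=list)

    @property
    def removed_ids(self) -> list:
        return [sid for it in self.removed_per_iteration for sid in it]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def ld_prune(bundle: CohortBundle, maf_min: float = 0.01, window: int = 50,
             step: int = 5, r2_max: float = 0.5) -> np.ndarray:
    """Greedy sliding-window LD pruning on autosomal variants.

    Variants with MAF <= ``maf_min`` are excluded before pruning (retained
    variants all have MAF > ``maf_min``).  Within each window of ``window``
    SNPs (advanced by ``step``), the later member of any pair with genotype
    r^2 > ``r2_max`` is dropped.  Returns positions (column indices) of the
    retained variants in the original bundle.
    """
    maf = np.nan_to_num(bundle.maf())
    autosomal = bundle.variants["chrom"].astype(int).between(1, 22).to_numpy()
    candidates = np.flatnonzero((maf > maf_min) & autosomal)
    if candidates.size == 0:
        return candidates

    g = bundle.genotypes[:, candidates].astype(float)
    g[g == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    inds = np.where(np.isnan(g))
    g[inds] = np.take(col_mean, inds[1])
    g -= g.mean(axis=0)
    norms = np.sqrt((g**2).sum(axis=0))
    norms[norms == 0] = np.inf

    chroms = bundle.variants["chrom"].to_numpy()[candidates]
    order = np.lexsort((bundle.variants["pos"].to_numpy()[candidates], chroms))
    keep = np.ones(candidates.size, dtype=bool)
    for chrom in np.unique(chroms):
        block = order[chroms[order] == chrom]
        for start in range(0, block.size, step):
            win = block[start:start + window]
            win = win[keep[win]]
            if win.size < 2:
                continue
            gw = g[:, win] / norms[win]
            r2 = (gw.T @ gw) ** 2
            for a in range(win.size):
                if not keep[win[a]]:
                    continue
                hits = np.flatnonzero(r2[a, a + 1:] > r2_max) + a + 1
                keep[win[hits]] = False
    return candidates[keep]


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------

def _standardize(bundle: CohortBundle, variant_idx) -> tuple[np.ndarray, list]:
    g = bundle.genotypes[:, variant_idx].astype(float)
    g[g == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    sd = np.sqrt(p * (1 - p))
    nonzero = sd > 0
    if not nonzero.all():
        warnings.warn(f"{(~nonzero).sum()} zero-variance variants dropped from PCA")
    g = g[:, nonzero]
    p = p[nonzero]
    sd = sd[nonzero]
    mean = 2 * p
    inds = np.where(np.isnan(g))
    g[inds] = np.take(mean, inds[1])
    z = (g - mean) / sd
    kept_ids = list(np.asarray(bundle.variants.index[variant_idx])[nonzero])
    return z, kept_ids


def compute_pcs(bundle: CohortBundle, variant_idx, k: int = 10) -> PCAResult:
    """Top-``k`` ancestry principal components on the given variant subset.

    Deterministic: the eigendecomposition is followed by a sign convention
    (largest-magnitude loading positive) so repeated runs agree exactly.
    """
    variant_idx = np.asarray(variant_idx)
    if variant_idx.size == 0:
        raise ValueError("PCA requires a non-empty variant subset")
    if bundle.n_samples < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} components")
    z, kept_ids = _standardize(bundle, variant_idx)
    m = z.shape[1]
    cov = (z @ z.T) / m
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1][:k]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        i_max = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i_max, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores = pd.DataFrame(
        eigvecs, index=bundle.samples.index,
        columns=[f"PC{j + 1}" for j in range(eigvecs.shape[1])],
    )
    return PCAResult(scores=scores, eigenvalues=eigvals, variant_ids=kept_ids)


def iterative_outlier_removal(bundle: CohortBundle, variant_idx, k: int = 10,
                              k_outlier: int = 5, sd_limit: float = 6.0,
                              max_iter: int = 20) -> PCAResult:
    """Repeat PCA, removing samples > ``sd_limit`` SDs from the median on any
    of the first ``k_outlier`` PCs, until no sample is flagged.

    SDs and medians are recomputed on the current iteration's scores.
    Raises if the loop would remove every sample.
    """
    current = bundle
    removed_per_iter: list = []
    result = None
    for iteration in range(1, max_iter + 1):
        result = compute_pcs(current, variant_idx_for(current, bundle, variant_idx), k=k)
        s = result.scores.iloc[:, :k_outlier]
        med = s.median(axis=0)
        sd = s.std(axis=0, ddof=1).replace(0.0, np.inf)
        flagged = ((s - med).abs() > sd_limit * sd).any(axis=1)
        result.iterations = iteration
        result.removed_per_iteration = list(removed_per_iter)
        if not flagged.any():
            return result
        ids = list(s.index[flagged])
        removed_per_iter.append(ids)
        keep = ~current.samples.index.isin(ids)
        if not keep.any():
            raise ValueError("outlier removal flagged every sample; degenerate input")
        current = current.subset(sample_idx=keep)
    result.removed_per_iteration = removed_per_iter
    return result


def variant_idx_for(current: CohortBundle, original: CohortBundle, variant_idx):
    """Map variant positions chosen on ``original`` onto ``current`` (same
    variant set, possibly fewer samples)."""
    if current is original:
        return variant_idx
    ids = original.variants.index[np.asarray(variant_idx)]
    return np.flatnonzero(current.variants.index.isin(ids))


def attach_pcs(bundle: CohortBundle, result: PCAResult, n: int = 2) -> CohortBundle:
    """Join the first ``n`` PC scores onto the bundle's sample table, keeping
    only samples retained by the outlier loop."""
    keep = bundle.samples.index.isin(result.scores.index)
    out = bundle.subset(sample_idx=np.flatnonzero(keep))
    out.samples = out.samples.join(result.scores.iloc[:, :n])
    return out
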