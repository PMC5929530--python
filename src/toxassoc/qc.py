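"""Variant- and sample-level quality control.

Implements the exact Hardy-Weinberg test, call-rate filters, a
method-of-moments IBD (PI_HAT) relatedness scan, exclusion of carriers of
listed risk variants (e.g. the four DPYD toxicity alleles), and batch
concordance checks.  Every filter appends a step to a :class:`QCReport`
recording threshold, counts and removed item ids, so the dimension chain from
input to output is fully reconstructable.

Filter conventions (literal readings of the thresholds they implement):
variants are retained at call rate >= 0.99 and HWE p > 1e-6; samples are
retained at call rate strictly > 0.97.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core import MISSING, CohortBundle

logger = logging.getLogger("toxassoc.qc")


@dataclass
class QCReport:
    """Ordered record of applied filters and the resulting dimension chain."""

    input_shape: tuple
    steps: list = field(default_factory=list)
    output_shape: tuple | None = None

    def add(self, name: str, threshold, n_tested: int, removed_ids: list) -> None:
        self.steps.append({
            "filter": name,
            "threshold": threshold,
            "tested": int(n_tested),
            "removed": len(removed_ids),
            "removed_ids": [str(i) for i in removed_ids],
        })

    def to_json(self, **kwargs) -> str:
        return json.dumps({
            "input_shape": list(self.input_shape),
            "output_shape": list(self.output_shape) if self.output_shape else None,
            "steps": self.steps,
        }, **kwargs)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact (mid-p-less) Hardy-Weinberg equilibrium test.

    Sums the probabilities of every heterozygote count compatible with the
    observed allele totals (same parity) whose exact sampling probability is
    at most that of the observed count.  Monomorphic input returns 1 by
    convention.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers: {counts}")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotyped individual is required")
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    pvals = _hwe_pvalue_table(n, n_rare)
    return float(pvals[(n_het - n_rare % 2) // 2])


@lru_cache(maxsize=200_000)
def _hwe_pvalue_table(n: int, n_rare: int) -> np.ndarray:
    """Exact-test p-value for every admissible heterozygote count given n
    individuals and n_rare copies of the rarer allele (parity-ordered)."""
    h = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_rare = (n_rare - h) // 2
    hom_common = n - hom_rare - h
    log_unnorm = (h * np.log(2.0)
                  - gammaln(hom_rare + 1) - gammaln(h + 1) - gammaln(hom_common + 1))
    log_probs = log_unnorm - logsumexp(log_unnorm)
    # p(h) = sum of probabilities <= prob(h); relative tolerance absorbs
    # float noise in the "probability <= observed" comparison
    order = np.argsort(log_probs, kind="stable")
    sorted_lp = log_probs[order]
    cum = np.logaddexp.accumulate(sorted_lp)
    idx = np.searchsorted(sorted_lp, log_probs + 1e-10, side="right") - 1
    pvals = np.exp(cum[idx])
    return np.minimum(pvals, 1.0)


def hwe_pvalues(bundle: CohortBundle) -> np.ndarray:
    """Exact HWE p-value per variant from called genotype counts."""
    g = bundle.genotypes
    called = g != MISSING
    n0 = ((g == 0) & called).sum(axis=0)
    n1 = (g == 1).sum(axis=0)
    n2 = (g == 2).sum(axis=0)
    out = np.ones(bundle.n_variants)
    cache: dict = {}
    for j in range(bundle.n_variants):
        key = (int(n0[j]), int(n1[j]), int(n2[j]))
        if key not in cache:
            if sum(key) == 0:
                cache[key] = 1.0
            else:
                cache[key] = hwe_exact_test(*key)
        out[j] = cache[key]
    return out


# ---------------------------------------------------------------------------
# Call-rate filters
# ---------------------------------------------------------------------------

def filter_variants(bundle: CohortBundle, call_rate_min: float = 0.99,
                    hwe_p_min: float = 1e-6) -> tuple[CohortBundle, QCReport]:
    """Drop variants with call rate < ``call_rate_min`` or HWE p <= ``hwe_p_min``."""
    report = QCReport(input_shape=(bundle.n_samples, bundle.n_variants))
    cr = bundle.variant_call_rate()
    low_cr = cr < call_rate_min
    report.add("variant_call_rate", call_rate_min, bundle.n_variants,
               list(bundle.variants.index[low_cr]))
    kept = bundle.subset(variant_idx=~low_cr)

    hwe_p = hwe_pvalues(kept)
    fail_hwe = hwe_p <= hwe_p_min
    report.add("variant_hwe", hwe_p_min, kept.n_variants,
               list(kept.variants.index[fail_hwe]))
    kept = kept.subset(variant_idx=~fail_hwe)
    report.output_shape = (kept.n_samples, kept.n_variants)
    return kept, report


def filter_samples(bundle: CohortBundle,
                   call_rate_min: float = 0.97) -> tuple[CohortBundle, QCReport]:
    """Drop samples whose call rate is not strictly above ``call_rate_min``.

    Single-pass: variant call rates are not recomputed afterwards unless the
    variant filter is re-run on the output.
    """
    report = QCReport(input_shape=(bundle.n_samples, bundle.n_variants))
    cr = bundle.sample_call_rate()
    drop = cr <= call_rate_min
    report.add("sample_call_rate", call_rate_min, bundle.n_samples,
               list(bundle.samples.index[drop]))
    kept = bundle.subset(sample_idx=~drop)
    report.output_shape = (kept.n_samples, kept.n_variants)
    return kept, report


# ---------------------------------------------------------------------------
# Relatedness (method-of-moments IBD)
# ---------------------------------------------------------------------------

def ibd_estimates(bundle: CohortBundle, variant_idx=None,
                  min_variants: int = 50) -> pd.DataFrame:
    """PI_HAT per sample pair by the method of moments on IBS counts.

    Expected IBS|IBD probabilities use sample allele frequencies without
    finite-sample bias corrections; intended for common, LD-pruned variants
    (pass their positions as ``variant_idx``).  Pairs' observed IBS counts
    are rescaled for per-pair missingness by their called fraction.
    """
    sub = bundle if variant_idx is None else bundle.subset(variant_idx=variant_idx)
    maf = sub.maf()
    informative = np.flatnonzero(np.nan_to_num(maf) >= 0.01)
    if informative.size < min_variants:
        warnings.warn(
            f"only {informative.size} informative variants; relatedness scan skipped"
        )
        return pd.DataFrame(columns=["id1", "id2", "ibs0", "ibs1", "ibs2", "pi_hat"])
    sub = sub.subset(variant_idx=informative)

    g = sub.genotypes
    called = (g != MISSING).astype(np.float64)
    A = [(g == k).astype(np.float64) for k in (0, 1, 2)]
    both = called @ called.T
    ibs2 = A[0] @ A[0].T + A[1] @ A[1].T + A[2] @ A[2].T
    ibs0 = A[0] @ A[2].T + A[2] @ A[0].T
    ibs1 = both - ibs2 - ibs0

    p = sub.allele1_freq()
    q = 1 - p
    e0_ibd0 = float(np.sum(2 * p**2 * q**2))
    e1_ibd0 = float(np.sum(4 * p**3 * q + 4 * p * q**3))
    e1_ibd1 = float(np.sum(2 * p**2 * q + 2 * p * q**2))
    m = sub.n_variants

    rows = []
    n = sub.n_samples
    ids = sub.samples.index
    for i in range(n):
        for j in range(i + 1, n):
            nb = both[i, j]
            if nb < min_variants:
                continue
            scale = m / nb
            o0, o1, o2 = ibs0[i, j] * scale, ibs1[i, j] * scale, ibs2[i, j] * scale
            p0 = o0 / e0_ibd0 if e0_ibd0 > 0 else 0.0
            p1 = (o1 - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
            p0, p1 = max(p0, 0.0), max(p1, 0.0)
            p2 = max(1.0 - p0 - p1, 0.0)
            total = p0 + p1 + p2
            pi_hat = (p2 + 0.5 * p1) / total if total > 0 else 0.0
            rows.append((ids[i], ids[j], ibs0[i, j], ibs1[i, j], ibs2[i, j],
                         min(pi_hat, 1.0)))
    return pd.DataFrame(rows, columns=["id1", "id2", "ibs0", "ibs1", "ibs2", "pi_hat"])


def relatedness_scan(bundle: CohortBundle, pi_hat_min: float = 0.4,
                     variant_idx=None) -> tuple[pd.DataFrame, list]:
    """Flag pairs with PI_HAT >= ``pi_hat_min`` (first-degree and closer);
    for each flagged pair mark the lower-call-rate member for removal."""
    pairs = ibd_estimates(bundle, variant_idx=variant_idx)
    if pairs.empty:
        return pairs, []
    call_rate = pd.Series(bundle.sample_call_rate(), index=bundle.samples.index)
    removal: list = []
    for _, row in pairs[pairs["pi_hat"] >= pi_hat_min].iterrows():
        a, b = row["id1"], row["id2"]
        if a in removal or b in removal:
            continue
        removal.append(a if call_rate[a] < call_rate[b] else b)
    return pairs, removal


def remove_related(bundle: CohortBundle, pi_hat_min: float = 0.4,
                   variant_idx=None) -> tuple[CohortBundle, QCReport]:
    report = QCReport(input_shape=(bundle.n_samples, bundle.n_variants))
    _, removal = relatedness_scan(bundle, pi_hat_min, variant_idx)
    report.add("relatedness_pi_hat", pi_hat_min, bundle.n_samples, removal)
    keep = ~bundle.samples.index.isin(removal)
    kept = bundle.subset(sample_idx=keep)
    report.output_shape = (kept.n_samples, kept.n_variants)
    return kept, report


# ---------------------------------------------------------------------------
# Known risk-variant carrier exclusion
# ---------------------------------------------------------------------------

def exclude_known_risk_carriers(bundle: CohortBundle,
                                variant_ids: list) -> tuple[CohortBundle, QCReport]:
    """Remove every sample carrying >= 1 minor allele at any listed variant.

    A missing genotype at a listed variant counts as non-carrier (exclusion
    requires observed copies).  Listed ids absent from the bundle are logged,
    not errors.
    """
    report = QCReport(input_shape=(bundle.n_samples, bundle.n_variants))
    present = [v for v in variant_ids if v in bundle.variants.index]
    absent = sorted(set(variant_ids) - set(present))
    if absent:
        logger.warning("risk-variant ids not in bundle (ignored): %s", absent)
    carriers = np.zeros(bundle.n_samples, dtype=bool)
    if present:
        cols = [bundle.variants.index.get_loc(v) for v in present]
        g = bundle.genotypes[:, cols]
        p = bundle.allele1_freq()[cols]
        # count copies of the *minor* allele at each listed variant
        minor_copies = np.where(p[None, :] <= 0.5, g, 2 - g)
        minor_copies = np.where(g == MISSING, 0, minor_copies)
        carriers = (minor_copies > 0).any(axis=1)
    removed = list(bundle.samples.index[carriers])
    report.add("risk_variant_carriers", list(variant_ids), bundle.n_samples, removed)
    kept = bundle.subset(sample_idx=~carriers)
    report.output_shape = (kept.n_samples, kept.n_variants)
    return kept, report


# ---------------------------------------------------------------------------
# Batch concordance
# ---------------------------------------------------------------------------

def batch_concordance(bundle: CohortBundle, pcs: np.ndarray | None = None,
                      n_pcs: int = 5) -> dict:
    """Check that genotyping batches are statistically exchangeable.

    (1) per-variant 2x2 allele-count chi-squared between the two (largest)
    batches, with a genomic-inflation-style summary and Bonferroni flags;
    (2) point-biserial correlation of each of the first ``n_pcs`` principal
    components with batch membership.  Single batch -> no-op report.
    """
    from scipy import stats as sps

    batches = bundle.samples["batch"]
    levels = batches.value_counts().index.tolist()
    if len(levels) < 2:
        return {"n_batches": len(levels), "note": "single batch; no comparison"}
    b1, b2 = levels[:2]
    in1 = (batches == b1).to_numpy()
    in2 = (batches == b2).to_numpy()

    g = bundle.genotypes
    called = g != MISSING
    gz = np.where(called, g, 0)

    def allele_counts(mask):
        a1 = gz[mask].sum(axis=0).astype(float)
        n2 = 2.0 * called[mask].sum(axis=0)
        return a1, n2 - a1

    a1_1, a2_1 = allele_counts(in1)
    a1_2, a2_2 = allele_counts(in2)
    table = np.stack([a1_1, a2_1, a1_2, a2_2], axis=1)
    row1 = a1_1 + a2_1
    row2 = a1_2 + a2_2
    col1 = a1_1 + a1_2
    col2 = a2_1 + a2_2
    total = row1 + row2
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.stack([
            row1 * col1, row1 * col2, row2 * col1, row2 * col2
        ], axis=1) / total[:, None]
        chi2 = np.nansum((table - expected) ** 2 / expected, axis=1)
    valid = (col1 > 0) & (col2 > 0) & (row1 > 0) & (row2 > 0)
    chi2 = np.where(valid, chi2, np.nan)
    pvals = sps.chi2.sf(chi2, df=1)

    ok = np.isfinite(chi2)
    inflation = (np.median(chi2[ok]) / sps.chi2.ppf(0.5, 1)) if ok.sum() >= 100 else None
    n_tested = int(ok.sum())
    bonf = 0.05 / max(n_tested, 1)
    flagged = list(bundle.variants.index[ok & (pvals < bonf)])

    result = {
        "n_batches": len(levels),
        "batches_compared": (str(b1), str(b2)),
        "n_variants_tested": n_tested,
        "frac_p_below_0.05": float(np.nanmean(pvals[ok] < 0.05)) if n_tested else np.nan,
        "chi2_inflation": inflation,
        "bonferroni_threshold": bonf,
        "flagged_variants": flagged,
        "per_variant_p": pd.Series(pvals, index=bundle.variants.index),
    }

    if pcs is not None:
        pcs = np.asarray(pcs, dtype=float)
        k = min(n_pcs, pcs.shape[1])
        ind = in1.astype(float)
        cors = []
        for j in range(k):
            r, p = sps.pearsonr(pcs[:, j], ind)
            cors.append({"pc": j + 1, "r": float(r), "p": float(p)})
        result["pc_batch_correlation"] = cors
    return result
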