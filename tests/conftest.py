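"""Shared fixtures and independent oracle helpers.

All cohorts are generated programmatically at test time from fixed seeds.
The helpers here (batched logistic IRLS, enumeration-based HWE) are
independent re-derivations used as oracles; they never call the package's
own code paths for the quantity under test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import toxassoc as tx


def make_bundle(genotypes, sample_cols=None, variant_cols=None):
    """Small hand-built CohortBundle from a genotype array."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    samples = pd.DataFrame(sample_cols or {}, index=pd.Index(
        [f"S{i}" for i in range(n)], name="sample_id"))
    base = {"chrom": 1, "pos": np.arange(m) + 1, "a1": "A", "a2": "C"}
    base.update(variant_cols or {})
    variants = pd.DataFrame(base, index=pd.Index(
        [f"v{j}" for j in range(m)], name="variant_id"))
    return tx.CohortBundle(g, samples, variants)


@pytest.fixture(scope="session")
def null_cohort():
    """Homogeneous cohort, common variants, no genetic effects."""
    spec = tx.CohortSpec(
        n_samples=400, n_variants=1500, seed=101, missing_rate=0.0,
        maf_beta=(2, 2), region_blocks=(),
        ancestry=tx.AncestrySpec(1, 0.0, (1.0,)),
    )
    return tx.simulate_cohort(spec)


@pytest.fixture(scope="session")
def rare_variant_cohort():
    """Mostly rare variants (exome-array-like) for gene-level tests:
    5 variants per gene, ~1000 genes, no genetic effects."""
    spec = tx.CohortSpec(
        n_samples=400, n_variants=5000, seed=202, missing_rate=0.0,
        maf_beta=(0.3, 4.0), region_blocks=(),
        ancestry=tx.AncestrySpec(1, 0.0, (1.0,)),
    )
    return tx.simulate_cohort(spec)


@pytest.fixture(scope="session")
def stratified_cohort():
    """Two diverged subpopulations with an ancestry effect on liability."""
    spec = tx.CohortSpec(
        n_samples=400, n_variants=1200, seed=55, missing_rate=0.0,
        maf_beta=(2, 2), region_blocks=(),
        ancestry=tx.AncestrySpec(2, 0.05, (0.5, 0.5)),
    )
    effects = tx.EffectSpec(ancestry_beta=0.8,
                            region_effect=tx.RegionEffectSpec(beta=0.0))
    return tx.simulate_cohort(spec, effects)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE p by direct enumeration with a log-factorial table
    (independent arithmetic from the package's gammaln/logsumexp route)."""
    n = n_hom_ref + n_het + n_hom_alt
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0
    logfact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    hom_r = (n_rare - hets) // 2
    hom_c = n - hom_r - hets
    logw = hets * np.log(2.0) - logfact[hom_r] - logfact[hets] - logfact[hom_c]
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    p_obs = probs[hets == n_het][0]
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


def batched_logistic_irls(X: np.ndarray, Y: np.ndarray, iters: int = 30):
    """IRLS fits of logit(y) ~ X for every column of Y.

    Returns (mu, beta, hessians) with mu (n x B), beta (k x B), and the
    final per-fit Hessians (B x k x k).
    """
    n, k = X.shape
    B = Y.shape[1]
    beta = np.zeros((k, B))
    ridge = 1e-8 * np.eye(k)
    H = None
    for _ in range(iters):
        mu = 1.0 / (1.0 + np.exp(-np.clip(X @ beta, -30, 30)))
        W = mu * (1 - mu) + 1e-12
        grad = X.T @ (Y - mu)
        H = np.einsum("nk,nB,nj->Bkj", X, W, X) + ridge
        step = np.linalg.solve(H, grad.T[:, :, None])[:, :, 0].T
        step = np.clip(step, -4, 4)  # damped for separated permutations
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    return mu, beta, H


def gene_fixture(seed: int, n: int = 60, maf=(0.3, 0.35, 0.4, 0.45, 0.25),
                 case_prob: float = 0.5, with_covars: bool = True):
    """n-sample single-gene fixture under the null (no genetic effect)."""
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, np.asarray(maf), size=(n, len(maf))).astype(np.int8)
    cov = rng.standard_normal((n, 2))
    y = rng.binomial(1, case_prob, n)
    cols = {"c1": cov[:, 0], "c2": cov[:, 1]} if with_covars else {}
    bundle = make_bundle(G, sample_cols=cols,
                         variant_cols={"gene": "G1", "protein_altering": True})
    outcome = pd.Series(y, index=bundle.samples.index)
    return bundle, outcome, G.astype(float), cov, y.astype(float)
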