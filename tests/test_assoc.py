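"""Single-variant association: logistic fits, allelic chi-squared, lambda,
marker scan and plot exports."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import toxassoc as tx
from conftest import make_bundle


def _grid_search_logistic(y, g, tol=1e-4):
    """Brute-force maximizer of the Bernoulli log-likelihood of
    logit(p) = b0 + b1 g on a refined 2-D grid (independent oracle)."""
    def ll(b0, b1):
        eta = b0 + b1 * g
        return np.sum(y * eta - np.log1p(np.exp(eta)))

    lo0 = lo1 = -6.0
    hi0 = hi1 = 6.0
    best = (0.0, 0.0)
    for _ in range(8):
        b0s = np.linspace(lo0, hi0, 41)
        b1s = np.linspace(lo1, hi1, 41)
        vals = np.array([[ll(a, c) for c in b1s] for a in b0s])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best = (b0s[i], b1s[j])
        span0 = (hi0 - lo0) / 8
        span1 = (hi1 - lo1) / 8
        lo0, hi0 = best[0] - span0, best[0] + span0
        lo1, hi1 = best[1] - span1, best[1] + span1
        if span1 < tol / 4:
            break
    return best


def test_logistic_matches_grid_search_oracle():
    y = np.array([1, 1, 1, 0, 1, 0, 0, 0], dtype=float)
    g = np.array([2, 1, 1, 1, 0, 0, 1, 0], dtype=np.int8)
    bundle = make_bundle(g[:, None])
    res = tx.logistic_assoc(bundle, pd.Series(y.astype(int),
                                              index=bundle.samples.index))
    _, b1 = _grid_search_logistic(y, g.astype(float))
    assert res["beta"].iloc[0] == pytest.approx(b1, abs=1e-3)


def test_separation_flagged_not_reported():
    """A variant carried only by cases has no finite OR: flagged."""
    y = np.array([1] * 5 + [0] * 5)
    g = np.array([2, 1, 1, 2, 1, 0, 0, 0, 0, 0], dtype=np.int8)
    bundle = make_bundle(g[:, None])
    res = tx.logistic_assoc(bundle, pd.Series(y, index=bundle.samples.index))
    assert res["status"].iloc[0] == "separation"
    assert np.isnan(res["or"].iloc[0])


def test_monomorphic_variant_flagged(null_cohort):
    g = null_cohort.genotypes.copy()
    g[:, 0] = 0
    b = tx.CohortBundle(g, null_cohort.samples.copy(),
                        null_cohort.variants.copy())
    y = tx.dichotomize(b.samples, "DMN")
    res = tx.logistic_assoc(b, y, variant_idx=[0])
    assert res["status"].iloc[0] == "monomorphic"


def test_results_invariant_to_sample_order(null_cohort):
    y = tx.dichotomize(null_cohort.samples, "DMN")
    perm = np.random.default_rng(0).permutation(null_cohort.n_samples)
    shuffled = null_cohort.subset(sample_idx=perm)
    r1 = tx.logistic_assoc(null_cohort, y, variant_idx=range(5))
    r2 = tx.logistic_assoc(shuffled, y.iloc[perm], variant_idx=range(5))
    assert np.allclose(r1["beta"], r2["beta"], atol=1e-8)


def test_allele_swap_inverts_odds_ratio(null_cohort):
    y = tx.dichotomize(null_cohort.samples, "DMN")
    flipped = tx.CohortBundle((2 - null_cohort.genotypes).astype(np.int8),
                              null_cohort.samples.copy(),
                              null_cohort.variants.copy())
    r1 = tx.logistic_assoc(null_cohort, y, variant_idx=range(5))
    r2 = tx.logistic_assoc(flipped, y, variant_idx=range(5))
    assert np.allclose(r1["or"], 1.0 / r2["or"], rtol=1e-6)
    assert np.allclose(r1["p"], r2["p"], atol=1e-9)


# ---------------------------------------------------------------------------
# Allelic chi-squared
# ---------------------------------------------------------------------------

def test_allelic_chi2_equal_frequencies_is_zero():
    chi2, p = tx.allelic_chi2((30, 170), (30, 170))
    assert chi2 == 0.0 and p == 1.0


def test_allelic_chi2_hand_oracle():
    table = np.array([[30, 170], [10, 190]], dtype=float)
    expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
    want = ((table - expected) ** 2 / expected).sum()
    chi2, p = tx.allelic_chi2((30, 170), (10, 190))
    assert chi2 == pytest.approx(want, rel=1e-12)
    assert p == pytest.approx(stats.chi2.sf(want, 1), rel=1e-12)


def test_allelic_chi2_scales_with_counts():
    c1, _ = tx.allelic_chi2((30, 170), (10, 190))
    c2, _ = tx.allelic_chi2((60, 340), (20, 380))
    assert c2 == pytest.approx(2 * c1, rel=1e-12)


def test_allelic_chi2_zero_margin_flagged():
    chi2, p = tx.allelic_chi2((0, 200), (0, 200))
    assert np.isnan(chi2) and np.isnan(p)


def test_allelic_scan_matches_scalar_computation(null_cohort):
    y = tx.dichotomize(null_cohort.samples, "DMN").to_numpy().astype(float)
    chi2 = tx.allelic_scan(null_cohort.genotypes[:, :20], y)
    for j in range(20):
        g = null_cohort.genotypes[:, j]
        cases = g[y == 1]
        ctrls = g[y == 0]
        want, _ = tx.allelic_chi2((cases.sum(), 2 * len(cases) - cases.sum()),
                                  (ctrls.sum(), 2 * len(ctrls) - ctrls.sum()))
        assert chi2[j] == pytest.approx(want, rel=1e-9)


def test_score_and_allelic_statistics_agree_asymptotically(null_cohort):
    """No covariates, complete data: the logistic score statistic and the
    allelic chi-squared correlate > 0.99 across common variants."""
    from toxassoc.region import _score_scan
    y = tx.dichotomize(null_cohort.samples, "DMN").to_numpy().astype(float)
    common = np.flatnonzero(np.nan_to_num(null_cohort.maf()) >= 0.05)[:500]
    g = null_cohort.genotypes[:, common]
    a = tx.allelic_scan(g, y)
    s = _score_scan(g, y, None)
    ok = np.isfinite(a) & np.isfinite(s)
    assert np.corrcoef(a[ok], s[ok])[0, 1] > 0.99


# ---------------------------------------------------------------------------
# Genomic inflation
# ---------------------------------------------------------------------------

def test_lambda_definition_and_scaling():
    base = np.full(200, 0.45493642311957283)
    assert tx.genomic_inflation(base) == pytest.approx(1.0, rel=1e-9)
    assert tx.genomic_inflation(2 * base) == pytest.approx(2.0, rel=1e-9)


def test_lambda_near_one_under_null(null_cohort):
    y = tx.dichotomize(null_cohort.samples, "DMN").to_numpy().astype(float)
    chi2 = tx.allelic_scan(null_cohort.genotypes, y)
    lam = tx.genomic_inflation(chi2[np.isfinite(chi2)])
    assert 0.9 < lam < 1.1


def test_lambda_omitted_when_too_few_statistics():
    with pytest.warns(UserWarning, match="lambda omitted"):
        assert tx.genomic_inflation(np.ones(10)) is None


# ---------------------------------------------------------------------------
# Marker scan
# ---------------------------------------------------------------------------

def test_marker_scan_consistent_with_genotyped_snp(null_cohort):
    y = tx.dichotomize(null_cohort.samples, "DMN")
    j = 3
    snp = tx.logistic_assoc(null_cohort, y, variant_idx=[j])
    markers = pd.DataFrame(
        [null_cohort.genotypes[:, j].astype(float)], index=["m_same"],
        columns=null_cohort.samples.index)
    scan = tx.marker_scan(markers, y)
    assert scan.loc["m_same", "chi2"] == pytest.approx(snp["chi2"].iloc[0],
                                                       rel=1e-8)


def test_marker_scan_skips_constant_and_sets_bonferroni(null_cohort):
    y = tx.dichotomize(null_cohort.samples, "DMN")
    rng = np.random.default_rng(1)
    rows = {"m_const": np.zeros(null_cohort.n_samples),
            **{f"m{k}": rng.binomial(2, 0.3, null_cohort.n_samples)
               for k in range(9)}}
    markers = pd.DataFrame(rows, dtype=float).T
    markers.columns = null_cohort.samples.index
    scan = tx.marker_scan(markers, y)
    assert "m_const" not in scan.index
    assert len(scan) == 9
    assert scan["bonferroni_threshold"].iloc[0] == pytest.approx(0.05 / 9)


# ---------------------------------------------------------------------------
# Plot exports
# ---------------------------------------------------------------------------

def test_qq_table_expected_quantiles():
    res = pd.DataFrame({"p": [0.5, 0.1, 0.9], "chrom": 1,
                        "pos": [10, 20, 30]})
    out = tx.export_plot_data(res)
    n = 3
    want = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    assert np.allclose(out["qq"]["expected"], want)
    assert np.allclose(out["qq"]["observed"],
                       sorted(-np.log10(res["p"]), reverse=True))


def test_qq_diagonal_under_uniform_p():
    rng = np.random.default_rng(0)
    res = pd.DataFrame({"p": rng.random(5000), "chrom": 1,
                        "pos": np.arange(5000)})
    out = tx.export_plot_data(res)
    mid = out["qq"].iloc[1000:4000]  # away from the noisy extreme tail
    assert np.max(np.abs(mid["observed"] - mid["expected"])) < 0.15


def test_empty_results_export_empty_tables():
    out = tx.export_plot_data(pd.DataFrame(columns=["p", "chrom", "pos"]))
    assert out["qq"].empty and out["manhattan"].empty


def test_manhattan_coordinates_increase_within_chromosome(null_cohort):
    y = tx.dichotomize(null_cohort.samples, "DMN")
    res = tx.logistic_assoc(null_cohort, y, variant_idx=range(50))
    man = tx.export_plot_data(res)["manhattan"]
    for _, grp in man.groupby("chrom"):
        assert (np.diff(grp["x"]) >= 0).all()
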