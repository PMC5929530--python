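"""Quality-control filters: HWE exact test, call rates, relatedness,
carrier exclusion, batch concordance."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest

import toxassoc as tx
from conftest import hwe_enumeration_oracle, make_bundle


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

def test_hwe_monomorphic_is_one():
    assert tx.hwe_exact_test(17, 0, 0) == 1.0
    assert tx.hwe_exact_test(0, 0, 9) == 1.0


@pytest.mark.parametrize("counts", [(10, 10, 10), (25, 50, 25), (3, 1, 0),
                                    (0, 100, 0), (40, 5, 40), (7, 13, 2)])
def test_hwe_matches_enumeration_oracle(counts):
    got = tx.hwe_exact_test(*counts)
    want = hwe_enumeration_oracle(*counts)
    assert got == pytest.approx(want, rel=1e-12)


def test_hwe_exhaustive_small_n():
    """Every configuration with up to 40 individuals equals the independent
    enumeration oracle (the full n <= 200 sweep runs in the acceptance
    suite)."""
    for n in range(1, 41):
        for n0 in range(n + 1):
            for n1 in range(n - n0 + 1):
                n2 = n - n0 - n1
                assert tx.hwe_exact_test(n0, n1, n2) == pytest.approx(
                    hwe_enumeration_oracle(n0, n1, n2), rel=1e-12), (n0, n1, n2)


def test_hwe_perfect_proportions_modal():
    # (25, 50, 25) is the modal configuration: p = 1 within tolerance
    assert tx.hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-9)


def test_hwe_rejects_bad_counts():
    with pytest.raises(ValueError):
        tx.hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        tx.hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# Call-rate filters
# ---------------------------------------------------------------------------

def _qc_bundle():
    rng = np.random.default_rng(8)
    g = rng.binomial(2, 0.4, size=(100, 6)).astype(np.int8)
    g[:2, 0] = tx.MISSING          # call rate 0.98 -> removed
    g[0, 1] = tx.MISSING           # call rate 0.99 -> retained
    # variant 2: gross heterozygote excess, HWE p << 1e-6 -> removed
    g[:, 2] = 1
    return make_bundle(g)


def test_variant_filter_call_rate_and_hwe_boundaries():
    bundle = _qc_bundle()
    kept, report = tx.filter_variants(bundle)
    assert "v0" not in kept.variants.index          # call rate 0.98 < 0.99
    assert "v1" in kept.variants.index              # call rate exactly 0.99
    assert "v2" not in kept.variants.index          # HWE failure
    names = [s["filter"] for s in report.steps]
    assert names == ["variant_call_rate", "variant_hwe"]
    assert report.input_shape == (100, 6)
    assert report.output_shape == (100, kept.n_variants)


def test_hwe_threshold_is_strictly_greater_than():
    """A variant is retained iff its exact HWE p exceeds 1e-6."""
    # find genotype configurations straddling the threshold
    low = high = None
    for het in range(0, 60):
        p = tx.hwe_exact_test((60 - het) // 2, het, 60 - het - (60 - het) // 2)
        if p <= 1e-6 and low is None:
            low = p
        if 1e-6 < p < 1e-4:
            high = p
    assert low is not None and high is not None  # both regimes reachable


def test_sample_filter_boundary_is_strict():
    rng = np.random.default_rng(1)
    g = rng.binomial(2, 0.4, size=(4, 100)).astype(np.int8)
    g[0, :3] = tx.MISSING   # call rate exactly 0.97 -> removed (strict >)
    g[1, :2] = tx.MISSING   # call rate 0.98 -> retained
    bundle = make_bundle(g)
    kept, report = tx.filter_samples(bundle)
    assert "S0" not in kept.samples.index
    assert "S1" in kept.samples.index
    assert report.steps[0]["removed_ids"] == ["S0"]


def test_filters_are_idempotent():
    bundle = _qc_bundle()
    once, _ = tx.filter_variants(bundle)
    twice, rep = tx.filter_variants(once)
    assert twice.n_variants == once.n_variants
    assert all(s["removed"] == 0 for s in rep.steps)
    s_once, _ = tx.filter_samples(bundle)
    s_twice, rep = tx.filter_samples(s_once)
    assert s_twice.n_samples == s_once.n_samples


def test_report_serializes_dimension_chain():
    bundle = _qc_bundle()
    _, report = tx.filter_variants(bundle)
    payload = json.loads(report.to_json())
    assert payload["input_shape"] == [100, 6]
    assert len(payload["steps"]) == 2


# ---------------------------------------------------------------------------
# Relatedness
# ---------------------------------------------------------------------------

def _population_genotypes(rng, n, m, p):
    return rng.binomial(2, p, size=(n, m)).astype(np.int8)


def test_duplicate_sample_detected_and_lower_call_rate_member_removed():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.1, 0.5, 300)
    g = _population_genotypes(rng, 20, 300, p)
    g[1] = g[0]                      # duplicate pair S0/S1
    g[1, :5] = tx.MISSING            # S1 has the lower call rate
    bundle = make_bundle(g)
    pairs, removal = tx.relatedness_scan(bundle)
    top = pairs.sort_values("pi_hat", ascending=False).iloc[0]
    assert {top["id1"], top["id2"]} == {"S0", "S1"}
    assert top["pi_hat"] > 0.9
    assert removal == ["S1"]


def test_unrelated_samples_have_low_pi_hat():
    rng = np.random.default_rng(5)
    p = rng.uniform(0.1, 0.5, 500)
    bundle = make_bundle(_population_genotypes(rng, 30, 500, p))
    pairs, removal = tx.relatedness_scan(bundle)
    assert removal == []
    assert pairs["pi_hat"].mean() < 0.1


def test_parent_child_pi_hat_near_half():
    rng = np.random.default_rng(11)
    m = 800
    p = rng.uniform(0.2, 0.5, m)
    hap = lambda: (rng.random(m) < p).astype(np.int8)
    father = hap() + hap()
    mother_hap = hap()
    transmitted = np.where(rng.random(m) < 0.5, (father > 1).astype(np.int8),
                           (father > 0).astype(np.int8))
    child = transmitted + mother_hap
    others = _population_genotypes(rng, 18, m, p)
    bundle = make_bundle(np.vstack([father, child, others]))
    pairs, removal = tx.relatedness_scan(bundle)
    pc = pairs[(pairs["id1"] == "S0") & (pairs["id2"] == "S1")].iloc[0]
    assert 0.35 < pc["pi_hat"] < 0.65
    assert len(removal) == 1 and removal[0] in ("S0", "S1")


def test_scan_skipped_with_too_few_informative_variants():
    bundle = make_bundle(np.ones((5, 10), dtype=np.int8))
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        pairs, removal = tx.relatedness_scan(bundle)
    assert pairs.empty and removal == []
    assert any("skipped" in str(x.message) for x in w)


# ---------------------------------------------------------------------------
# Risk-carrier exclusion
# ---------------------------------------------------------------------------

def test_carrier_exclusion_rules():
    rng = np.random.default_rng(2)
    g = rng.binomial(2, 0.3, size=(6, 4)).astype(np.int8)
    g[:, 0] = 0
    g[1, 0] = 1              # S1 heterozygous carrier -> removed
    g[2, 0] = tx.MISSING     # missing counts as non-carrier -> retained
    bundle = make_bundle(g)
    kept, report = tx.exclude_known_risk_carriers(bundle, ["v0"])
    assert "S1" not in kept.samples.index
    assert "S2" in kept.samples.index
    assert report.steps[0]["removed_ids"] == ["S1"]


def test_carrier_exclusion_no_carriers_and_absent_ids(caplog):
    bundle = make_bundle(np.zeros((4, 2), dtype=np.int8))
    kept, _ = tx.exclude_known_risk_carriers(bundle, ["v0", "rs_absent"])
    assert kept.n_samples == 4
    assert "rs_absent" in caplog.text


def test_carrier_exclusion_counts_minor_allele_when_a1_is_major():
    # allele 1 frequency > 0.5: dosage 2 means zero *minor* alleles
    g = np.array([[2], [2], [1], [2]], dtype=np.int8)
    bundle = make_bundle(g)
    kept, _ = tx.exclude_known_risk_carriers(bundle, ["v0"])
    # S2 (het) carries one minor allele; homozygous-major samples retained
    assert list(kept.samples.index) == ["S0", "S1", "S3"]


# ---------------------------------------------------------------------------
# Batch concordance
# ---------------------------------------------------------------------------

def test_random_split_batches_are_concordant(null_cohort):
    report = tx.batch_concordance(null_cohort)
    assert abs(report["frac_p_below_0.05"] - 0.05) < 3 * np.sqrt(
        0.05 * 0.95 / report["n_variants_tested"])
    assert report["flagged_variants"] == []


def test_planted_frequency_shift_is_flagged():
    rng = np.random.default_rng(6)
    n, m = 400, 200
    g = rng.binomial(2, 0.3, size=(n, m)).astype(np.int8)
    batch = np.array(["b1"] * 200 + ["b2"] * 200)
    g[batch == "b2", 0] = rng.binomial(2, 0.62, size=200)  # ~0.3 freq shift
    bundle = make_bundle(g, sample_cols={"batch": batch})
    report = tx.batch_concordance(bundle)
    assert "v0" in report["flagged_variants"]


def test_identical_batches_have_zero_statistics():
    rng = np.random.default_rng(7)
    half = rng.binomial(2, 0.4, size=(30, 50)).astype(np.int8)
    g = np.vstack([half, half])     # batch 2 is a copy of batch 1
    batch = np.array(["b1"] * 30 + ["b2"] * 30)
    bundle = make_bundle(g, sample_cols={"batch": batch})
    report = tx.batch_concordance(bundle)
    p = report["per_variant_p"].dropna()
    assert (p > 0.999).all()


def test_single_batch_is_noop():
    bundle = make_bundle(np.zeros((5, 3), dtype=np.int8),
                         sample_cols={"batch": "b1"})
    report = tx.batch_concordance(bundle)
    assert report["n_batches"] == 1 and "note" in report


def test_pc_batch_correlation_reported(null_cohort):
    pcs = np.random.default_rng(0).standard_normal((null_cohort.n_samples, 5))
    report = tx.batch_concordance(null_cohort, pcs=pcs)
    cors = report["pc_batch_correlation"]
    assert len(cors) == 5
    assert all(abs(c["r"]) < 0.25 for c in cors)
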