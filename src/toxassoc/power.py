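"""Multiple-testing thresholds and case-control power / sample size.

Power is for the 1-df allelic (2N chromosomes) comparison of risk-allele
frequency between cases and controls, with the case allele frequency induced
by the per-allele odds ratio:

    p_case = OR * p / (1 - p + OR * p),   p_control = p.

Two computations are offered.  ``method="exact"`` (default) enumerates the
joint binomial distribution of case/control allele counts and accumulates
the probability that the Pearson allelic chi-squared exceeds its critical
value — this is the power of the test actually performed, and matches
simulation by construction.  ``method="normal"`` is the classic
two-proportion normal approximation (pooled SD under the null for the
critical value, unpooled under the alternative).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats


@dataclass
class PowerQuery:
    """Design query for the allelic case-control test."""

    maf: float
    odds_ratio: float
    alpha: float = 8.4e-7
    case_fraction: float = 133 / 502
    target_power: float = 0.80

    def __post_init__(self):
        if not 0 < self.maf < 1:
            raise ValueError("risk-allele frequency must be in (0, 1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        for name in ("alpha", "case_fraction", "target_power"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @property
    def case_freq(self) -> float:
        odds = self.odds_ratio * self.maf / (1 - self.maf)
        return odds / (1 + odds)


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> dict:
    """Family-wise threshold alpha/n, exact rational arithmetic plus a
    2-significant-figure display form."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    frac = Fraction(family_alpha).limit_denominator(10**9) / n_tests
    value = float(frac)
    display = f"{value:.1e}"
    return {"value": value, "exact": frac, "display": display}


def _allele_counts(n_total: int, case_fraction: float) -> tuple[int, int]:
    m_case = int(round(2 * n_total * case_fraction))
    return m_case, 2 * n_total - m_case


def power_at_n(query: PowerQuery, n_total: int, alpha: float | None = None,
               method: str = "exact") -> float:
    """Power of the allelic chi-squared test at ``n_total`` individuals.

    OR = 1 returns alpha exactly (degenerate null identity, by convention).
    """
    alpha = query.alpha if alpha is None else alpha
    if query.odds_ratio == 1.0:
        return alpha
    p1, p0 = query.case_freq, query.maf
    m1, m0 = _allele_counts(n_total, query.case_fraction)
    if m1 < 1 or m0 < 1:
        raise ValueError("sample size too small for the case fraction")
    if method == "normal":
        return _power_normal(p1, p0, m1, m0, alpha)
    if method == "exact":
        return _power_exact(p1, p0, m1, m0, alpha)
    raise ValueError(f"unknown method {method!r}")


def _power_normal(p1, p0, m1, m0, alpha) -> float:
    za = stats.norm.isf(alpha / 2)
    pbar = (m1 * p1 + m0 * p0) / (m1 + m0)
    sd0 = np.sqrt(pbar * (1 - pbar) * (1 / m1 + 1 / m0))
    sd1 = np.sqrt(p1 * (1 - p1) / m1 + p0 * (1 - p0) / m0)
    d = p1 - p0
    return float(stats.norm.sf((za * sd0 - d) / sd1)
                 + stats.norm.cdf((-za * sd0 - d) / sd1))


def _support(m, p, k: float = 12.0) -> np.ndarray:
    """Binomial count support truncated to +-k SDs (mass beyond ~1e-30)."""
    sd = np.sqrt(m * p * (1 - p))
    lo = max(0, int(np.floor(m * p - k * sd)) - 2)
    hi = min(m, int(np.ceil(m * p + k * sd)) + 2)
    return np.arange(lo, hi + 1)


def _power_exact(p1, p0, m1, m0, alpha) -> float:
    a1 = _support(m1, p1)
    a0 = _support(m0, p0)
    w1 = stats.binom.pmf(a1, m1, p1)
    w0 = stats.binom.pmf(a0, m0, p0)
    A1 = a1[:, None]
    A0 = a0[None, :]
    tot = A1 + A0
    M = m1 + m0
    pb = tot / M
    denom = pb * (1 - pb) * (1 / m1 + 1 / m0)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, (A1 / m1 - A0 / m0) ** 2 / denom, 0.0)
    crit = stats.chi2.isf(alpha, 1)
    return float((w1[:, None] * (w0[None, :] * (chi2 > crit))).sum())


def sample_size_for_power(query: PowerQuery, method: str = "exact",
                          n_max: int = 1_000_000) -> int:
    """Smallest total N with power >= the query's target, holding the case
    fraction fixed.  Bisection followed by a downward linear refinement
    (power in N is monotone up to allele-count rounding)."""
    if query.odds_ratio == 1.0:
        raise ValueError("power target unreachable at OR = 1")
    if query.target_power <= query.alpha:
        raise ValueError("target power must exceed alpha")
    # bracket cheaply with the normal approximation before exact refinement
    if power_at_n(query, n_max, method="normal") < query.target_power:
        raise ValueError(f"target power unreachable below n={n_max}")
    lo, hi = 2, n_max
    if method == "exact":
        guess = sample_size_for_power(query, method="normal", n_max=n_max)
        lo = max(2, guess // 2)
        hi = min(n_max, max(guess * 2, lo + 2))
        while power_at_n(query, hi, method=method) < query.target_power:
            lo, hi = hi, min(n_max, hi * 2)
            if hi == lo:
                raise ValueError(f"target power unreachable below n={n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at_n(query, mid, method=method) >= query.target_power:
            hi = mid
        else:
            lo = mid
    while hi > 2 and power_at_n(query, hi - 1, method=method) >= query.target_power:
        hi -= 1
    return hi


def simulate_power(query: PowerQuery, n_total: int, alpha: float,
                   n_reps: int = 2000, seed: int = 0) -> float:
    """Monte-Carlo power of the allelic chi-squared test (independent
    cross-check of the analytic computation)."""
    rng = np.random.default_rng(seed)
    m1, m0 = _allele_counts(n_total, query.case_fraction)
    a1 = rng.binomial(m1, query.case_freq, size=n_reps)
    a0 = rng.binomial(m0, query.maf, size=n_reps)
    tot = a1 + a0
    M = m1 + m0
    pb = tot / M
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = (a1 / m1 - a0 / m0) ** 2 / (pb * (1 - pb) * (1 / m1 + 1 / m0))
    chi2 = np.nan_to_num(chi2)
    crit = stats.chi2.isf(alpha, 1)
    return float(np.mean(chi2 > crit))
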