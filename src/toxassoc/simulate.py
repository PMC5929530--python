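"""Synthetic cohort generator.

Emulates the statistical structure of an exome-array adverse-drug-reaction
cohort: a few hundred European-ancestry patients, tens of thousands of mostly
rare protein-altering variants, a dense-LD region standing in for the MHC,
two genotyping batches, mild population stratification, and ordinal NCI-CTC
toxicity grades (0-4) produced by a liability-threshold model.

Genotypes outside LD blocks are Hardy-Weinberg-consistent within each
subpopulation (binomial draws from Balding-Nichols subpopulation
frequencies).  LD blocks are drawn as two haplotypes per individual from a
finite haplotype pool whose haplotypes follow a latent Gaussian AR(1)
process, so adjacent-SNP r^2 > 0 while marginal frequencies are preserved.

Grades: each symptom has a latent liability = genetic effects + ancestry
effect + standard-normal noise, cut at fixed thresholds into grades 0-4.
Default thresholds are calibrated so the four dichotomized outcomes hit the
study's affected/unaffected margins (133/369 DMN, 50/199 DM, 36/218 HFS,
13/241 severe HFS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MISSING, SYMPTOMS, CohortBundle

#: Conventional MHC span used for the stand-in dense-LD region (1-based, closed).
MHC_CHROM = 6
MHC_START = 29_600_000
MHC_END = 33_100_000


class SpecError(ValueError):
    """Invalid simulation specification."""


@dataclass
class LDBlockSpec:
    """A run of adjacent variants drawn from a finite haplotype pool.

    ``pool_size`` haplotypes are generated per subpopulation from a latent
    AR(1) Gaussian with lag-one correlation ``rho``; individuals draw two
    haplotypes with replacement.
    """

    n_variants: int = 50
    pool_size: int = 20
    rho: float = 0.9

    def __post_init__(self):
        if self.pool_size < 2:
            raise SpecError("haplotype pool must contain at least 2 haplotypes")
        if not 0 <= self.rho < 1:
            raise SpecError("rho must be in [0, 1)")


@dataclass
class AncestrySpec:
    """k-subpopulation mixture with Balding-Nichols allele-frequency divergence."""

    n_populations: int = 2
    fst: float = 0.005
    proportions: tuple = (0.6, 0.4)

    def __post_init__(self):
        if len(self.proportions) != self.n_populations:
            raise SpecError("one mixing proportion per subpopulation required")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise SpecError("mixing proportions must sum to 1")
        if self.fst < 0 or self.fst >= 1:
            raise SpecError("fst must be in [0, 1)")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``maf_beta`` shapes the ancestral minor-allele-frequency distribution
    (a Beta(a, b) scaled to [maf_min, 0.5]; heavily right-skewed by default so
    most variants are rare, as on an exome array).  ``region_blocks`` are
    placed contiguously inside the MHC span on chromosome 6.
    """

    n_samples: int = 504
    n_variants: int = 2000
    maf_beta: tuple = (0.25, 2.5)
    maf_min: float = 0.001
    maf_point_mass: float | None = None  # overrides maf_beta when set
    region_blocks: tuple = (LDBlockSpec(),)
    ancestry: AncestrySpec = field(default_factory=AncestrySpec)
    batch_proportions: dict = field(default_factory=lambda: {"batch1": 0.735, "batch2": 0.265})
    capecitabine_fraction: float = 254 / 504
    male_fraction: float = 0.60
    missing_rate: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_variants < 1:
            raise SpecError("n_samples and n_variants must be >= 1")
        for p in (self.missing_rate, self.capecitabine_fraction, self.male_fraction):
            if not 0 <= p <= 1:
                raise SpecError("probabilities must lie in [0, 1]")
        n_region = sum(b.n_variants for b in self.region_blocks)
        if n_region > self.n_variants:
            raise SpecError("region blocks exceed total variant count")

    @classmethod
    def study_scale(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """Cohort at the scale of the study: 504 samples, ~60k mostly rare
        protein-altering variants, ~2.3k SNPs in the MHC stand-in region."""
        kw = dict(
            n_samples=504,
            n_variants=59_277,
            region_blocks=tuple(LDBlockSpec(n_variants=51, pool_size=20, rho=0.9)
                                for _ in range(45)),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)


def default_grade_cutpoints() -> dict:
    """Liability thresholds per symptom, calibrated to the study margins.

    Returns for each symptom the cumulative probabilities P(grade >= k),
    k = 1..4, converted to standard-normal thresholds.  Severe rates solve
    the composite-outcome targets under independent symptom liabilities:
    DMN 133/502 over all patients, DM 50/249 and the two HFS splits
    36/254, 13/254 in the Capecitabine subgroup.
    """
    f_dmn = 133 / 502
    f_dm = 50 / 249
    sev_d = 1 - np.sqrt(1 - f_dm)          # diarrhoea == mucositis severe rate
    sev_n = 1 - (1 - f_dmn) / (1 - f_dm)   # neutropenia severe rate
    hfs2 = 36 / 254                        # HFS grade >= 2
    hfs3 = 13 / 254                        # HFS grade 3 (no grade 4 observed)
    tail = {
        "diarrhoea": (0.55, 0.25, sev_d, 0.02),
        "mucositis": (0.55, 0.25, sev_d, 0.02),
        "neutropenia": (0.45, 0.20, sev_n, 0.015),
        "hfs": (0.50, hfs2, hfs3, 0.0),
    }
    return {s: stats.norm.isf(np.asarray(p)) for s, p in tail.items()}


@dataclass
class RegionEffectSpec:
    """Planted multi-SNP effect inside the dense-LD region."""

    n_causal: int = 10
    beta: float = 0.0
    symptoms: tuple = ("hfs",)


@dataclass
class EffectSpec:
    """Genetic and covariate effects on the symptom liabilities.

    ``variant_effects`` maps variant id -> per-allele effect on the liability
    scale, applied to the symptoms in ``variant_symptoms``.  ``ancestry_beta``
    shifts liability by subpopulation membership (mean-centred indicator).
    A zero-effect spec yields grades independent of genotype.
    """

    cutpoints: dict | None = None
    variant_effects: dict = field(default_factory=dict)
    variant_symptoms: tuple = SYMPTOMS
    region_effect: RegionEffectSpec = field(default_factory=RegionEffectSpec)
    ancestry_beta: float = 0.0

    def resolved_cutpoints(self) -> dict:
        cp = self.cutpoints if self.cutpoints is not None else default_grade_cutpoints()
        for s, t in cp.items():
            t = np.asarray(t, dtype=float)
            if not np.all(np.diff(t) > 0):
                raise SpecError(f"{s} cut-points must be strictly increasing")
        return cp


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _scaled_maf(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    if spec.maf_point_mass is not None:
        return np.full(n, float(spec.maf_point_mass))
    a, b = spec.maf_beta
    return spec.maf_min + (0.5 - spec.maf_min) * rng.beta(a, b, size=n)


def _subpop_freqs(p: np.ndarray, fst: float, k: int, rng: np.random.Generator) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies, shape (k, n_variants)."""
    if fst <= 0:
        return np.tile(p, (k, 1))
    scale = (1 - fst) / fst
    a = np.clip(p * scale, 1e-6, None)
    b = np.clip((1 - p) * scale, 1e-6, None)
    return np.clip(rng.beta(a, b, size=(k, p.size)), 1e-6, 1 - 1e-6)


def _block_haplotypes(freqs: np.ndarray, block: LDBlockSpec,
                      rng: np.random.Generator) -> np.ndarray:
    """Haplotype pool (pool_size x L) with AR(1) latent structure."""
    L = freqs.size
    z = np.empty((block.pool_size, L))
    z[:, 0] = rng.standard_normal(block.pool_size)
    innov = rng.standard_normal((block.pool_size, L))
    c = np.sqrt(1 - block.rho**2)
    for j in range(1, L):
        z[:, j] = block.rho * z[:, j - 1] + c * innov[:, j]
    thresh = stats.norm.isf(freqs)  # P(z > thresh) = freq
    return (z > thresh[None, :]).astype(np.int8)


def simulate_genotypes(spec: CohortSpec) -> CohortBundle:
    """Draw a cohort's genotype matrix and metadata tables from ``spec``.

    Bit-reproducible: identical spec (including seed) gives identical output.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_freq, rng_geno, rng_meta, rng_miss = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]

    n, m = spec.n_samples, spec.n_variants
    anc = spec.ancestry
    p_anc = _scaled_maf(spec, rng_freq, m)
    pk = _subpop_freqs(p_anc, anc.fst, anc.n_populations, rng_freq)

    pop = rng_meta.choice(anc.n_populations, size=n, p=list(anc.proportions))

    # layout: region blocks occupy the first variants (MHC), rest genome-wide
    n_region = sum(b.n_variants for b in spec.region_blocks)
    genotypes = np.empty((n, m), dtype=np.int8)

    # independent (non-block) variants: binomial within subpopulation => HWE
    free = np.arange(n_region, m)
    if free.size:
        genotypes[:, free] = rng_geno.binomial(2, pk[pop][:, free]).astype(np.int8)

    # LD blocks: finite haplotype pools per subpopulation
    start = 0
    for block in spec.region_blocks:
        idx = np.arange(start, start + block.n_variants)
        for k in range(anc.n_populations):
            members = np.flatnonzero(pop == k)
            if members.size == 0:
                continue
            pool = _block_haplotypes(pk[k, idx], block, rng_geno)
            draws = rng_geno.integers(0, block.pool_size, size=(members.size, 2))
            genotypes[np.ix_(members, idx)] = pool[draws[:, 0]] + pool[draws[:, 1]]
        start += block.n_variants

    if spec.missing_rate > 0:
        mask = rng_miss.random((n, m)) < spec.missing_rate
        genotypes[mask] = MISSING

    # ---- metadata tables ----
    sample_ids = [f"S{i:05d}" for i in range(n)]
    batch_labels = list(spec.batch_proportions)
    batch = rng_meta.choice(batch_labels, size=n,
                            p=list(spec.batch_proportions.values()))
    treatment = np.where(rng_meta.random(n) < spec.capecitabine_fraction,
                         "Capecitabine", "5FU")
    sex = np.where(rng_meta.random(n) < spec.male_fraction, 1, 2)
    age = np.clip(rng_meta.normal(63.0, 11.5, size=n), 25, 90).round(1)
    samples = pd.DataFrame(
        {"sex": sex, "age": age, "batch": batch, "treatment": treatment,
         "population": pop},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    variants = _variant_table(spec, n_region, rng_meta)
    return CohortBundle(
        genotypes=genotypes, samples=samples, variants=variants,
        metadata={"dosage_allele": "a1", "spec_seed": spec.seed},
    )


def _variant_table(spec: CohortSpec, n_region: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    m = spec.n_variants
    ids = [f"var{j:06d}" for j in range(m)]
    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    # region variants evenly spaced across the MHC span on chr 6
    if n_region:
        chrom[:n_region] = MHC_CHROM
        pos[:n_region] = np.linspace(MHC_START, MHC_END, n_region).astype(int)
    rest = m - n_region
    if rest:
        autosomes = np.arange(1, 23)
        chrom[n_region:] = np.sort(rng.choice(autosomes, size=rest))
        # positions increasing within chromosome
        for c in autosomes:
            sel = np.flatnonzero(chrom[n_region:] == c) + n_region
            if c == MHC_CHROM:
                # keep genome-wide chr6 variants outside the MHC stand-in
                pos[sel] = np.sort(rng.integers(MHC_END + 1, 170_000_000, size=sel.size))
            else:
                pos[sel] = np.sort(rng.integers(1, 240_000_000, size=sel.size))
    in_region = np.zeros(m, dtype=bool)
    in_region[:n_region] = True
    gene = np.array([f"GENE{j // 5:05d}" for j in range(m)])
    return pd.DataFrame(
        {"chrom": chrom, "pos": pos, "a1": "A", "a2": "C",
         "gene": gene, "protein_altering": True, "in_region": in_region},
        index=pd.Index(ids, name="variant_id"),
    )


# ---------------------------------------------------------------------------
# Grades
# ---------------------------------------------------------------------------

def simulate_grades(bundle: CohortBundle, effects: EffectSpec,
                    seed: int = 0) -> pd.DataFrame:
    """Generate per-sample NCI-CTC grades from the liability-threshold model.

    Per symptom: liability = sum_v beta_v (g_v - mean g_v) + ancestry term +
    N(0, 1) noise; grade = number of thresholds the liability exceeds.
    Missing genotypes contribute the variant mean (mean imputation).
    Returns a grade table aligned to the bundle's samples, including the
    ``treatment`` and ``batch`` columns.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = bundle.n_samples
    cutpoints = effects.resolved_cutpoints()

    var_effects = dict(effects.variant_effects)
    unknown = set(var_effects) - set(bundle.variants.index)
    if unknown:
        raise SpecError(f"effect variant ids not in bundle: {sorted(unknown)[:5]}")

    # region effect: first n_causal region variants, evenly spread
    region_ids: list = []
    re = effects.region_effect
    if re.beta != 0 and re.n_causal > 0:
        in_region = np.flatnonzero(bundle.variants["in_region"].to_numpy())
        if in_region.size == 0:
            raise SpecError("region effect requested but bundle has no region variants")
        take = np.linspace(0, in_region.size - 1, min(re.n_causal, in_region.size))
        region_ids = list(bundle.variants.index[in_region[take.astype(int)]])

    def centred_dosage(vid: str) -> np.ndarray:
        j = bundle.variants.index.get_loc(vid)
        g = bundle.genotypes[:, j].astype(float)
        called = g != MISSING
        mean = g[called].mean() if called.any() else 0.0
        g[~called] = mean
        return g - mean

    genetic = {s: np.zeros(n) for s in SYMPTOMS}
    for vid, beta in var_effects.items():
        gc = centred_dosage(vid)
        for s in effects.variant_symptoms:
            genetic[s] += beta * gc
    for vid in region_ids:
        gc = centred_dosage(vid)
        for s in re.symptoms:
            genetic[s] += re.beta * gc

    ancestry_term = np.zeros(n)
    if effects.ancestry_beta != 0 and "population" in bundle.samples:
        popv = bundle.samples["population"].to_numpy(dtype=float)
        ancestry_term = effects.ancestry_beta * (popv - popv.mean())

    out = {}
    for s in SYMPTOMS:
        liability = genetic[s] + ancestry_term + rng.standard_normal(n)
        thresh = np.asarray(cutpoints[s], dtype=float)
        out[s] = (liability[:, None] > thresh[None, :]).sum(axis=1)
    grades = pd.DataFrame(out, index=bundle.samples.index, dtype="Int64")
    for col in ("treatment", "batch"):
        if col in bundle.samples:
            grades[col] = bundle.samples[col]
    return grades


def simulate_cohort(spec: CohortSpec, effects: EffectSpec | None = None,
                    grade_seed: int | None = None) -> CohortBundle:
    """Genotypes plus grades in one call; grade columns joined onto samples."""
    effects = effects if effects is not None else EffectSpec()
    bundle = simulate_genotypes(spec)
    seed = grade_seed if grade_seed is not None else spec.seed + 1
    grades = simulate_grades(bundle, effects, seed=seed)
    bundle.samples = bundle.samples.join(grades[list(SYMPTOMS)])
    return bundle
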