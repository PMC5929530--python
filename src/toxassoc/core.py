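"""Core data containers for the association pipeline.

The central object is :class:`CohortBundle`, which couples an additive-dosage
genotype matrix with aligned sample and variant tables.  Genotypes are stored
as ``int8`` with values ``{0, 1, 2}`` counting copies of allele 1 (the first
allele of the variant record, PLINK A1 convention) and a dedicated missing
sentinel :data:`MISSING` kept out of band of valid dosages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Out-of-band missing-genotype sentinel. Never -9 or NaN inside the matrix.
MISSING: int = -1

#: Symptom columns expected in a grade table.
SYMPTOMS = ("diarrhoea", "mucositis", "neutropenia", "hfs")

#: Recognised treatment labels.
TREATMENTS = ("5FU", "Capecitabine")


class BundleError(ValueError):
    """Raised when a bundle violates its structural invariants."""


@dataclass
class CohortBundle:
    """Genotypes plus aligned sample/variant metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_variants)`` int8 array of allele-1 dosages with
        :data:`MISSING` for no-calls.
    samples
        One row per sample, indexed by unique sample id.  Typical columns:
        ``sex``, ``age``, ``batch``, ``treatment``, per-symptom grades and
        derived outcome/PC columns added by downstream stages.
    variants
        One row per variant, indexed by unique variant id, with at least
        ``chrom``, ``pos`` (1-based), ``a1``, ``a2``.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        g = self.genotypes
        if g.ndim != 2:
            raise BundleError("genotype matrix must be 2-D (samples x variants)")
        if g.shape[0] != len(self.samples):
            raise BundleError(
                f"sample count {len(self.samples)} != genotype rows {g.shape[0]}"
            )
        if g.shape[1] != len(self.variants):
            raise BundleError(
                f"variant count {len(self.variants)} != genotype columns {g.shape[1]}"
            )
        if not self.samples.index.is_unique:
            raise BundleError("sample identifiers are not unique")
        if not self.variants.index.is_unique:
            raise BundleError("variant identifiers are not unique")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise BundleError(f"{bad.sum()} genotype values outside {{0,1,2,missing}}")

    # -- shapes -----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    # -- derived quantities -----------------------------------------------
    def called_mask(self) -> np.ndarray:
        """Boolean mask of called (non-missing) genotypes."""
        return self.genotypes != MISSING

    def allele1_freq(self) -> np.ndarray:
        """Per-variant frequency of allele 1 among called genotypes (NaN if none)."""
        called = self.called_mask()
        n2 = 2.0 * called.sum(axis=0)
        counts = np.where(called, self.genotypes, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n2 > 0, counts / n2, np.nan)

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency."""
        p = self.allele1_freq()
        return np.minimum(p, 1.0 - p)

    def variant_call_rate(self) -> np.ndarray:
        return self.called_mask().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return self.called_mask().mean(axis=1)

    # -- subsetting -------------------------------------------------------
    def subset(self, sample_idx=None, variant_idx=None) -> "CohortBundle":
        """Positional subset; preserves order of the supplied indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        vi = np.arange(self.n_variants) if variant_idx is None else np.asarray(variant_idx)
        if si.dtype == bool:
            si = np.flatnonzero(si)
        if vi.dtype == bool:
            vi = np.flatnonzero(vi)
        return CohortBundle(
            genotypes=self.genotypes[np.ix_(si, vi)].copy(),
            samples=self.samples.iloc[si].copy(),
            variants=self.variants.iloc[vi].copy(),
            metadata=dict(self.metadata),
        )

    def equals(self, other: "CohortBundle") -> bool:
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and list(self.samples.index) == list(other.samples.index)
            and list(self.variants.index) == list(other.variants.index)
        )
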