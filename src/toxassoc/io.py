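"""Readers and writers for PLINK 1 binary filesets and delimited tables.

The .bed codec implements the SNP-major 2-bit PLINK 1 encoding directly:
magic bytes ``0x6c 0x1b`` followed by the mode byte (``0x01`` = SNP-major),
then one block of ``ceil(n_samples/4)`` bytes per variant.  Within a byte,
genotypes are packed least-significant pair first with codes::

    00 -> homozygous A1 (dosage 2)
    01 -> missing
    10 -> heterozygous (dosage 1)
    11 -> homozygous A2 (dosage 0)

Dosage counts allele 1 of the .bim record throughout; minor-allele frequency
is always recomputed downstream, never assumed from file order.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MISSING, SYMPTOMS, TREATMENTS, CohortBundle

_MAGIC = bytes((0x6C, 0x1B))
_SNP_MAJOR = 0x01

# 2-bit code -> dosage of A1
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# dosage (0,1,2) -> 2-bit code; missing handled separately
_DOSAGE_TO_CODE = {0: 0b11, 1: 0b10, 2: 0b00, MISSING: 0b01}


class PlinkFormatError(ValueError):
    """Malformed .bed/.bim/.fam content."""


class GradeTableError(ValueError):
    """Invalid grade/treatment table content."""


# ---------------------------------------------------------------------------
# PLINK binary fileset
# ---------------------------------------------------------------------------

def read_plink(prefix: str | os.PathLike) -> CohortBundle:
    """Read a ``.bed/.bim/.fam`` fileset into a :class:`CohortBundle`.

    Raises
    ------
    PlinkFormatError
        On bad magic bytes, individual-major mode, or a .bed payload size
        inconsistent with the .bim/.fam line counts.
    """
    prefix = Path(prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"id": str, "a1": str, "a2": str},
    )
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:2] != _MAGIC:
        raise PlinkFormatError(
            f"{prefix}.bed does not start with the PLINK magic bytes 0x6c 0x1b"
        )
    if raw[2] != _SNP_MAJOR:
        raise PlinkFormatError(
            f"{prefix}.bed is not SNP-major (mode byte 0x{raw[2]:02x}); "
            "individual-major files are not supported"
        )
    n_samples, n_variants = len(fam), len(bim)
    bytes_per_variant = (n_samples + 3) // 4
    expected = 3 + bytes_per_variant * n_variants
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{prefix}.bed has {len(raw)} bytes; expected {expected} for "
            f"{n_samples} samples x {n_variants} variants"
        )
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    blocks = payload.reshape(n_variants, bytes_per_variant)
    # unpack 4 genotypes per byte, least-significant pair first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_variants, bytes_per_variant * 4)[:, :n_samples]
    genotypes = _CODE_TO_DOSAGE[codes].T  # samples x variants

    samples = pd.DataFrame(
        {"fid": fam["fid"].values, "sex": fam["sex"].values,
         "phenotype": fam["phenotype"].values},
        index=pd.Index(fam["iid"], name="sample_id"),
    )
    variants = pd.DataFrame(
        {"chrom": bim["chrom"].values, "pos": bim["pos"].values,
         "cm": bim["cm"].values, "a1": bim["a1"].values, "a2": bim["a2"].values},
        index=pd.Index(bim["id"], name="variant_id"),
    )
    return CohortBundle(
        genotypes=genotypes, samples=samples, variants=variants,
        metadata={"dosage_allele": "a1", "source": str(prefix)},
    )


def write_plink(bundle: CohortBundle, prefix: str | os.PathLike) -> None:
    """Write a bundle as a SNP-major ``.bed/.bim/.fam`` fileset.

    Missing phenotype/grade information is written with the .fam missing
    code -9; positions are written 1-based as stored.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n_samples = bundle.n_samples

    g = bundle.genotypes.T  # variants x samples
    codes = np.empty_like(g, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[g == dosage] = code
    pad = (-n_samples) % 4
    if pad:
        codes = np.pad(codes, ((0, 0), (0, pad)), constant_values=0)
    quads = codes.reshape(codes.shape[0], -1, 4)
    packed = (
        quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(bytes([_SNP_MAJOR]))
        fh.write(packed.tobytes())

    s = bundle.samples
    fam = pd.DataFrame({
        "fid": s["fid"] if "fid" in s else s.index,
        "iid": s.index,
        "father": 0,
        "mother": 0,
        "sex": s["sex"] if "sex" in s else 0,
        "phenotype": s["phenotype"] if "phenotype" in s else -9,
    })
    fam["phenotype"] = fam["phenotype"].fillna(-9)
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    v = bundle.variants
    bim = pd.DataFrame({
        "chrom": v["chrom"],
        "id": v.index,
        "cm": v["cm"] if "cm" in v else 0,
        "pos": v["pos"],
        "a1": v["a1"],
        "a2": v["a2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Grade / treatment tables
# ---------------------------------------------------------------------------

def read_grades(path: str | os.PathLike, sep: str = "\t") -> pd.DataFrame:
    """Read a per-sample toxicity grade table.

    The header must name a sample-id column (``sample`` or ``sample_id``),
    the four symptom columns (:data:`~toxassoc.core.SYMPTOMS`), ``treatment``
    and ``batch``.  Grades must be integers 0-4; empty cells are missing.
    NCI-CTC grades outside 0-4 or unknown treatment labels are rejected at
    parse time with the offending sample named.
    """
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.lower() for c in df.columns]
    id_col = "sample_id" if "sample_id" in df.columns else "sample"
    if id_col not in df.columns:
        raise GradeTableError("grade table needs a 'sample' or 'sample_id' column")
    missing_cols = [c for c in (*SYMPTOMS, "treatment", "batch") if c not in df.columns]
    if missing_cols:
        raise GradeTableError(f"grade table is missing columns: {missing_cols}")
    df = df.set_index(id_col)
    validate_grades(df)
    for col in SYMPTOMS:
        df[col] = pd.array(df[col], dtype="Int64")
    return df


def validate_grades(df: pd.DataFrame) -> None:
    """Enforce grade bounds and treatment labels on a grade table in memory."""
    for col in SYMPTOMS:
        vals = pd.to_numeric(df[col], errors="raise")
        bad = vals.dropna()
        offenders = bad[(bad < 0) | (bad > 4) | (bad != bad.round())]
        if len(offenders):
            sid = offenders.index[0]
            raise GradeTableError(
                f"sample {sid!r}: {col} grade {offenders.iloc[0]} outside 0-4"
            )
    if df["treatment"].isna().any():
        sid = df.index[df["treatment"].isna()][0]
        raise GradeTableError(f"sample {sid!r}: treatment label is required")
    unknown = set(df["treatment"].dropna()) - set(TREATMENTS)
    if unknown:
        raise GradeTableError(
            f"unknown treatment label(s) {sorted(unknown)}; expected one of {TREATMENTS}"
        )


def attach_grades(bundle: CohortBundle, grades: pd.DataFrame) -> CohortBundle:
    """Join grade-table columns onto the bundle's sample table (inner on id)."""
    common = bundle.samples.index.intersection(grades.index)
    keep = np.flatnonzero(bundle.samples.index.isin(common))
    out = bundle.subset(sample_idx=keep)
    out.samples = out.samples.join(grades, how="left", rsuffix="_grades")
    return out


# ---------------------------------------------------------------------------
# Annotation and imputed-marker tables
# ---------------------------------------------------------------------------

def read_annotation(path: str | os.PathLike, sep: str = "\t") -> pd.DataFrame:
    """Read a variant annotation table (variant_id, gene, protein_altering...).

    A variant annotated to several genes appears on several rows.
    """
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.lower() for c in df.columns]
    if "variant_id" not in df.columns or "gene" not in df.columns:
        raise ValueError("annotation table needs 'variant_id' and 'gene' columns")
    if "protein_altering" in df.columns:
        df["protein_altering"] = df["protein_altering"].astype(bool)
    return df


def read_marker_matrix(path: str | os.PathLike, sep: str = "\t") -> pd.DataFrame:
    """Read a markers-x-samples dosage table standing in for HLA imputation
    output (alleles, amino acids, SNP genotypes), dosages in [0, 2]."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    vals = df.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and ((finite < 0) | (finite > 2)).any():
        raise ValueError("marker dosages must lie in [0, 2]")
    return df
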