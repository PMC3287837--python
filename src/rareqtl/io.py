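"""Data model and file I/O: genotypes, gene maps, covariates, traits.

Genotypes are additive minor-allele dosages in {0, 1, 2}.  Readers resolve
missingness (mean imputation with a warning) and orient every column to the
minor allele, so downstream modules can assume complete, minor-oriented
matrices.  Subject alignment across files is always by identifier, never by
row position.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: MAF cutoffs used to partition variants into rare and common.
MAF_CUTOFFS = (0.005, 0.01, 0.05)

COVARIATE_COLUMNS = ("sex", "age", "smoking", "population")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Subjects x variants additive minor-allele dosage matrix.

    Every entry is in {0, 1, 2}; no missing values are allowed here —
    readers must resolve missingness before construction.
    """

    subject_ids: list[str]
    variant_ids: list[str]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D matrix")
        n, m = self.dosage.shape
        if n != len(self.subject_ids) or m != len(self.variant_ids):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.variant_ids)} variants"
            )
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if m < 1:
            raise ValueError("need at least 1 variant")
        if not np.isin(self.dosage, (0, 1, 2)).all():
            bad = np.unique(self.dosage[~np.isin(self.dosage, (0, 1, 2))])
            raise ValueError(f"dosage entries must be in {{0,1,2}}; found {bad.tolist()}")
        self.dosage = self.dosage.astype(np.int8)

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        return self.dosage[:, self.variant_ids.index(variant_id)]

    def mafs(self) -> np.ndarray:
        """Minor allele frequency of every column, on the full sample."""
        p = self.dosage.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class VariantInfo:
    """Per-variant metadata: gene assignment and sample MAF."""

    variant_id: str
    gene: str | None
    maf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"maf must be in [0, 0.5]; got {self.maf}")


@dataclass
class GenePartition:
    """Rare/common split of one gene's polymorphic variants at one cutoff.

    ``rare_idx`` and ``common_idx`` are disjoint variant (column) index
    arrays; monomorphic variants belong to neither.
    """

    gene: str
    cutoff: float
    rare_idx: np.ndarray
    common_idx: np.ndarray

    def __post_init__(self) -> None:
        self.rare_idx = np.asarray(self.rare_idx, dtype=int)
        self.common_idx = np.asarray(self.common_idx, dtype=int)
        if np.intersect1d(self.rare_idx, self.common_idx).size:
            raise ValueError("rare_idx and common_idx must be disjoint")

    @property
    def n_rare(self) -> int:
        return self.rare_idx.size

    @property
    def n_common(self) -> int:
        return self.common_idx.size


@dataclass
class CovariateTable:
    """Covariates aligned with GenotypeMatrix.subject_ids: sex, age,
    smoking, population group."""

    subject_ids: list[str]
    sex: np.ndarray  # binary
    age: np.ndarray  # years
    smoking: np.ndarray  # binary
    population: np.ndarray  # categorical labels

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        n = len(self.subject_ids)
        self.sex = np.asarray(self.sex, dtype=float)
        self.age = np.asarray(self.age, dtype=float)
        self.smoking = np.asarray(self.smoking, dtype=float)
        self.population = np.asarray(self.population)
        for name in ("sex", "age", "smoking", "population"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"covariate '{name}' has length {arr.shape}, expected {n}")
        for name in ("sex", "age", "smoking"):
            arr = getattr(self, name)
            if not np.isfinite(arr).all():
                raise ValueError(f"covariate '{name}' contains missing/non-finite values")
        if not np.isin(self.sex, (0, 1)).all() or not np.isin(self.smoking, (0, 1)).all():
            raise ValueError("sex and smoking must be binary 0/1")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Covariate design (no intercept): sex, age, smoking and one dummy
        per population level beyond the first (reference coding)."""
        levels = sorted(np.unique(self.population).tolist())
        cols = [self.sex, self.age, self.smoking]
        names = ["sex", "age", "smoking"]
        for lev in levels[1:]:
            cols.append((self.population == lev).astype(float))
            names.append(f"population[{lev}]")
        return np.column_stack(cols), names


@dataclass
class TraitPanel:
    """Quantitative trait replicates: subjects x replicates."""

    trait_name: str
    subject_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.subject_ids = [str(s) for s in self.subject_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] != len(self.subject_ids):
            raise ValueError("trait rows do not match subject_ids")
        if self.values.shape[1] < 1:
            raise ValueError("need at least 1 replicate")
        if not np.isfinite(self.values).all():
            raise ValueError("trait values must be finite")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def replicate(self, r: int) -> np.ndarray:
        return self.values[:, r]


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def compute_maf(dosage_column: Sequence[int] | np.ndarray) -> float:
    """Minor allele frequency of one dosage column.

    Returns ``min(p, 1-p)`` with ``p = sum(column) / (2n)``; if the stored
    allele is already the minor allele this equals ``p``.
    """
    col = np.asarray(dosage_column)
    if col.size == 0:
        raise ValueError("cannot compute MAF of an empty dosage column")
    if not np.isin(col, (0, 1, 2)).all():
        raise ValueError("dosage entries must be in {0,1,2}")
    p = float(col.sum()) / (2.0 * col.size)
    return min(p, 1.0 - p)


def partition_gene(
    variants: Sequence[VariantInfo],
    cutoff: float,
    indices: Sequence[int] | None = None,
) -> GenePartition:
    """Split one gene's variants into rare (maf < cutoff, strict) and
    common (maf >= cutoff); monomorphic variants (maf == 0) are excluded.

    ``indices`` optionally supplies the genotype-matrix column index of each
    variant; defaults to positions within ``variants``.
    """
    if not variants:
        raise ValueError("variants must be non-empty")
    genes = {v.gene for v in variants}
    if len(genes) != 1:
        raise ValueError(f"variants span multiple genes: {sorted(map(str, genes))}")
    if indices is None:
        indices = list(range(len(variants)))
    if len(indices) != len(variants):
        raise ValueError("indices length mismatch")
    rare, common = [], []
    for idx, v in zip(indices, variants):
        if v.maf == 0.0:
            continue
        (rare if v.maf < cutoff else common).append(idx)
    return GenePartition(
        gene=str(next(iter(genes))),
        cutoff=cutoff,
        rare_idx=np.asarray(rare, dtype=int),
        common_idx=np.asarray(common, dtype=int),
    )


def partition_all_genes(
    variant_info: Sequence[VariantInfo], cutoff: float
) -> dict[str, GenePartition]:
    """Partition every gene present in ``variant_info`` at one cutoff.

    Variant indices refer to positions in ``variant_info`` (and therefore to
    genotype-matrix columns when the two are aligned).
    """
    by_gene: dict[str, tuple[list[VariantInfo], list[int]]] = {}
    for i, v in enumerate(variant_info):
        if v.gene is None:
            continue
        by_gene.setdefault(v.gene, ([], []))
        by_gene[v.gene][0].append(v)
        by_gene[v.gene][1].append(i)
    return {
        g: partition_gene(vs, cutoff, indices=idx) for g, (vs, idx) in by_gene.items()
    }


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _impute_column(col: np.ndarray, label: str) -> np.ndarray:
    """Replace NaNs with the rounded mean dosage of the observed entries."""
    missing = np.isnan(col)
    if missing.any():
        observed = col[~missing]
        if observed.size == 0:
            fill = 0.0
        else:
            fill = float(np.round(observed.mean()))
        warnings.warn(
            f"{int(missing.sum())} missing genotype(s) in {label}: "
            f"imputed to rounded mean dosage {int(fill)}",
            stacklevel=3,
        )
        col = col.copy()
        col[missing] = fill
    return col


def read_genotypes(
    path: str | Path, format: str = "matrix"
) -> tuple[GenotypeMatrix, list[VariantInfo]]:
    """Read genotypes from a tab-delimited matrix or a VCF.

    Columns are oriented to the minor allele: when the stored/ALT allele
    frequency exceeds 0.5 the column is recoded ``2 - g`` and the flip is
    logged.  Missing genotypes are imputed to the rounded column mean with
    a warning.  Returned ``VariantInfo`` has ``gene=None``; attach genes
    with :func:`build_variant_info`.
    """
    path = Path(path)
    if format == "matrix":
        gm = _read_matrix(path)
    elif format == "vcf":
        gm = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    info = [
        VariantInfo(variant_id=v, gene=None, maf=m)
        for v, m in zip(gm.variant_ids, gm.mafs())
    ]
    return gm, info


def _orient_minor(dosage: np.ndarray, variant_ids: list[str]) -> np.ndarray:
    p = dosage.mean(axis=0) / 2.0
    flip = p > 0.5
    if flip.any():
        for v in np.asarray(variant_ids)[flip]:
            logger.info("variant %s stored on major allele; recoded 2-g", v)
        dosage = dosage.copy()
        dosage[:, flip] = 2 - dosage[:, flip]
    return dosage


def _read_matrix(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    variant_ids = [str(c) for c in df.columns]
    subject_ids = [str(i) for i in df.index]
    raw = df.to_numpy()
    values = np.full(raw.shape, np.nan)
    mask = ~pd.isna(raw)
    if mask.any():
        values[mask] = pd.to_numeric(raw[mask].ravel(), errors="raise")
    for j, vid in enumerate(variant_ids):
        values[:, j] = _impute_column(values[:, j], f"variant {vid}")
    if not np.isin(values, (0, 1, 2)).all():
        bad = np.unique(values[~np.isin(values, (0, 1, 2))])
        raise ValueError(f"matrix file {path} contains invalid dosages {bad.tolist()}")
    dosage = _orient_minor(values.astype(np.int8), variant_ids)
    return GenotypeMatrix(subject_ids, variant_ids, dosage)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    variant_ids: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record not supported: {rec.CHROM}:{rec.POS} "
                f"({rec.REF}>{','.join(rec.ALT)})"
            )
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types
        col = np.full(len(subject_ids), np.nan)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        col = _impute_column(col, f"variant {vid}")
        variant_ids.append(str(vid))
        columns.append(col)
    if not columns:
        raise ValueError(f"no variant records in {path}")
    dosage = _orient_minor(
        np.column_stack(columns).astype(np.int8), variant_ids
    )
    return GenotypeMatrix(subject_ids, variant_ids, dosage)


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read the variant -> gene assignment table (columns variant_id, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"variant_id", "gene"}.issubset(df.columns):
        raise ValueError(f"gene map {path} must have columns variant_id, gene")
    return dict(zip(df["variant_id"], df["gene"]))


def build_variant_info(
    gm: GenotypeMatrix, gene_map: dict[str, str]
) -> list[VariantInfo]:
    """Attach gene assignments and sample MAFs to the matrix's variants.

    Variants absent from the map get ``gene=None`` (ignored by gene tests).
    """
    mafs = gm.mafs()
    return [
        VariantInfo(variant_id=v, gene=gene_map.get(v), maf=float(m))
        for v, m in zip(gm.variant_ids, mafs)
    ]


def read_covariates(path: str | Path, subject_ids: Sequence[str]) -> CovariateTable:
    """Read covariates and align them to ``subject_ids`` by identifier."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", *COVARIATE_COLUMNS}
    if not required.issubset(df.columns):
        raise ValueError(f"covariate file {path} must have columns {sorted(required)}")
    df = df.set_index("subject_id")
    missing = [s for s in subject_ids if str(s) not in df.index]
    if missing:
        raise ValueError(
            f"covariate file {path} is missing subjects: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    df = df.loc[[str(s) for s in subject_ids]]
    return CovariateTable(
        subject_ids=list(map(str, subject_ids)),
        sex=df["sex"].to_numpy(dtype=float),
        age=df["age"].to_numpy(dtype=float),
        smoking=df["smoking"].to_numpy(dtype=float),
        population=df["population"].to_numpy(dtype=str),
    )


def read_traits(
    path: str | Path, subject_ids: Sequence[str], trait_name: str | None = None
) -> TraitPanel:
    """Read a trait panel (subject_id then one column per replicate),
    aligned to ``subject_ids`` by identifier."""
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError(f"trait file {path} must have a subject_id column")
    df = df.set_index("subject_id")
    missing = [s for s in subject_ids if str(s) not in df.index]
    if missing:
        raise ValueError(f"trait file {path} is missing subjects: {missing[:5]}")
    df = df.loc[[str(s) for s in subject_ids]]
    name = trait_name if trait_name is not None else Path(path).stem
    return TraitPanel(
        trait_name=name,
        subject_ids=list(map(str, subject_ids)),
        values=df.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.dosage, index=gm.subject_ids, columns=gm.variant_ids)
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


def write_gene_map(variant_info: Iterable[VariantInfo], path: str | Path) -> None:
    rows = [(v.variant_id, v.gene) for v in variant_info if v.gene is not None]
    pd.DataFrame(rows, columns=["variant_id", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def write_covariates(cov: CovariateTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "subject_id": cov.subject_ids,
            "sex": cov.sex.astype(int),
            "age": cov.age,
            "smoking": cov.smoking.astype(int),
            "population": cov.population,
        }
    ).to_csv(path, sep="\t", index=False)


def write_traits(panel: TraitPanel, path: str | Path) -> None:
    df = pd.DataFrame(
        panel.values,
        index=pd.Index(panel.subject_ids, name="subject_id"),
        columns=[f"rep{r + 1}" for r in range(panel.n_replicates)],
    )
    df.to_csv(path, sep="\t")


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal uncompressed VCF 4.2 (one biallelic SNV
    per variant, GT only).  Dosage g maps to 0/0, 0/1, 1/1."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.subject_ids)
            + "\n"
        )
        for j, vid in enumerate(gm.variant_ids):
            gts = "\t".join(gt_map[int(g)] for g in gm.dosage[:, j])
            fh.write(f"1\t{j + 1}\t{vid}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")
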