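"""Input/output for genotype, metabolome, phenotype, and cross-table data.

All delimited files use one dialect: UTF-8, tab-separated, first row holds
column (marker / metabolite / trait) identifiers, first column holds the
line / entry identifier, and ``NA`` marks a missing value.

Inbred parental genotypes are coded {-1, +1}; 0 denotes a heterozygous call
and fractional values may appear after mean imputation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "NA"

__all__ = [
    "GenotypeMatrix",
    "MetabolomeMatrix",
    "PhenotypeTable",
    "CrossTable",
    "read_genotypes",
    "write_genotypes",
    "filter_snps",
    "impute_missing",
    "read_metabolome",
    "write_metabolome",
    "subset_metabolome",
    "read_phenotypes",
    "write_phenotypes",
    "read_crosses",
    "write_crosses",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class GenotypeMatrix:
    """Parental lines x markers, codes in [-1, 1] with NaN for missing."""

    line_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray
    marker_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        _check_unique(self.line_ids, "line ids")
        _check_unique(self.marker_ids, "marker ids")
        finite = self.codes[np.isfinite(self.codes)]
        if finite.size and (finite.min() < -1 or finite.max() > 1):
            raise ValueError("genotype codes must lie in [-1, 1]")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.codes).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency from the {-1,0,+1} coding."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = (np.nanmean(self.codes, axis=0) + 1.0) / 2.0
        return np.minimum(p, 1.0 - p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.line_ids, columns=self.marker_ids)


@dataclass
class MetabolomeMatrix:
    """Rows x metabolites intensity matrix, optionally with replicates.

    ``replicate_index`` labels each row's biological replicate; ``None``
    means the matrix is replicate-averaged (one row per line).
    """

    line_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray
    replicate_index: list[str] | None = None
    meta: pd.DataFrame | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.line_ids), len(self.metabolite_ids)):
            raise ValueError("values shape does not match ids")
        _check_unique(self.metabolite_ids, "metabolite ids")
        if self.replicate_index is None:
            _check_unique(self.line_ids, "line ids")
        else:
            if len(self.replicate_index) != len(self.line_ids):
                raise ValueError("replicate_index length mismatch")
            pairs = list(zip(self.line_ids, self.replicate_index))
            _check_unique(pairs, "(line, replicate) pairs")
        if not self.normalized:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and finite.min() < 0:
                raise ValueError("raw intensities must be non-negative")

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.metabolite_ids)


@dataclass
class PhenotypeTable:
    """Entries (lines or hybrids) x traits; NaN marks missing phenotypes."""

    entry_ids: list[str]
    traits: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entry_ids), len(self.traits)):
            raise ValueError("values shape does not match ids")
        _check_unique(self.entry_ids, "entry ids")
        if np.isinf(self.values).any():
            raise ValueError("phenotypes must be finite or missing")

    def trait_vector(self, trait: str, entries: Sequence[str] | None = None) -> pd.Series:
        if trait not in self.traits:
            raise KeyError(f"unknown trait {trait!r}")
        s = pd.Series(self.values[:, self.traits.index(trait)], index=self.entry_ids)
        return s if entries is None else s.loc[list(entries)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.entry_ids, columns=self.traits)


@dataclass
class CrossTable:
    """Hybrid id plus its female and male parents."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    COLUMNS = ("hybrid_id", "parent_female", "parent_male")

    def __post_init__(self) -> None:
        if list(self.table.columns) != list(self.COLUMNS):
            raise ValueError(f"cross table must have columns {self.COLUMNS}")
        self.table = self.table.reset_index(drop=True)
        _check_unique(self.table["hybrid_id"].tolist(), "hybrid ids")
        pairs = [frozenset(p) for p in zip(self.table["parent_female"], self.table["parent_male"])]
        _check_unique(pairs, "unordered parent pairs")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "CrossTable":
        return cls(pd.DataFrame(list(records), columns=list(cls.COLUMNS)))

    def validate_parents(self, G: GenotypeMatrix) -> None:
        known = set(G.line_ids)
        missing = (set(self.table["parent_female"]) | set(self.table["parent_male"])) - known
        if missing:
            raise ValueError(f"parents absent from genotype matrix: {sorted(missing)[:5]}")

    @property
    def hybrid_ids(self) -> list[str]:
        return self.table["hybrid_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# genotype readers


def _map_letter_codes(column: pd.Series, marker: str) -> np.ndarray:
    """Map letter-pair genotype strings to {-1, 0, +1}.

    The homozygote of the alphabetically first allele maps to +1, the other
    homozygote to -1, heterozygotes to 0.
    """
    out = np.full(len(column), np.nan)
    alleles = set()
    for v in column.dropna():
        if len(v) != 2:
            raise ValueError(f"marker {marker}: malformed genotype {v!r}")
        alleles.update(v)
    alleles = sorted(alleles)
    if len(alleles) > 2:
        raise ValueError(f"marker {marker}: more than two alleles {alleles}")
    for i, v in enumerate(column):
        if pd.isna(v):
            continue
        a, b = v[0], v[1]
        if a != b:
            out[i] = 0.0
        else:
            out[i] = 1.0 if a == alleles[0] else -1.0
    return out


def read_genotypes(path: str | Path, format: str = "delimited") -> GenotypeMatrix:
    """Read a genotype matrix.

    ``format`` is one of ``delimited`` (lines x markers, numeric codes or
    letter pairs like ``AA``/``AC``), ``vcf`` (biallelic SNPs; multi-allelic
    records are skipped with a logged count), or ``hapmap``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        return _read_genotypes_delimited(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    if format == "hapmap":
        return _read_genotypes_hapmap(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_delimited(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING], dtype=str)
    line_ids = df.index.astype(str).tolist()
    marker_ids = df.columns.astype(str).tolist()
    codes = np.full(df.shape, np.nan)
    for j, m in enumerate(marker_ids):
        col = df.iloc[:, j]
        non_missing = col.dropna()
        numeric = pd.to_numeric(non_missing, errors="coerce")
        if non_missing.empty or numeric.notna().all():
            codes[:, j] = pd.to_numeric(col, errors="coerce").to_numpy()
        else:
            codes[:, j] = _map_letter_codes(col, m)
    missing_frac = np.isnan(codes).mean(axis=0) if codes.size else np.array([])
    n_all_missing = int((missing_frac == 1.0).sum()) if codes.size else 0
    if n_all_missing:
        logger.warning("%d marker(s) entirely missing", n_all_missing)
    return GenotypeMatrix(line_ids, marker_ids, codes)


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    """Biallelic-SNP VCF reader; REF hom -> +1, ALT hom -> -1, het -> 0."""
    try:
        from cyvcf2 import VCF  # optional dependency
    except ImportError:  # pragma: no cover - exercised only without cyvcf2
        return _read_genotypes_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    meta_rows: list[tuple[str, int]] = []
    cols: list[np.ndarray] = []
    skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped += 1
            continue
        gt = np.asarray(rec.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        col = np.where(gt == 0, 1.0, np.where(gt == 1, 0.0, np.where(gt == 3, -1.0, np.nan)))
        marker_ids.append(rec.ID or f"{rec.CHROM}_{rec.POS}")
        meta_rows.append((rec.CHROM, rec.POS))
        cols.append(col)
    if skipped:
        logger.warning("skipped %d non-biallelic VCF record(s)", skipped)
    codes = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    meta = pd.DataFrame(meta_rows, index=marker_ids, columns=["chromosome", "position"])
    return GenotypeMatrix(samples, marker_ids, codes, marker_meta=meta)


def _read_genotypes_vcf_text(path: Path) -> GenotypeMatrix:
    """Minimal plain-text VCF fallback used when cyvcf2 is unavailable."""
    samples: list[str] = []
    marker_ids: list[str] = []
    meta_rows: list[tuple[str, int]] = []
    cols: list[np.ndarray] = []
    skipped = 0
    gt_map = {"0/0": 1.0, "0|0": 1.0, "1/1": -1.0, "1|1": -1.0,
              "0/1": 0.0, "1/0": 0.0, "0|1": 0.0, "1|0": 0.0}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            alt = fields[4]
            if "," in alt or alt == ".":
                skipped += 1
                continue
            gts = [f.split(":")[0] for f in fields[9:]]
            cols.append(np.array([gt_map.get(g, np.nan) for g in gts]))
            marker_ids.append(fields[2] if fields[2] != "." else f"{fields[0]}_{fields[1]}")
            meta_rows.append((fields[0], int(fields[1])))
    if skipped:
        logger.warning("skipped %d non-biallelic VCF record(s)", skipped)
    codes = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    meta = pd.DataFrame(meta_rows, index=marker_ids, columns=["chromosome", "position"])
    return GenotypeMatrix(samples, marker_ids, codes, marker_meta=meta)


def _read_genotypes_hapmap(path: Path) -> GenotypeMatrix:
    """HapMap format: 11 fixed columns then one column per line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    fixed = df.columns[:11]
    samples = df.columns[11:].astype(str).tolist()
    marker_ids = df[fixed[0]].astype(str).tolist()
    codes = np.full((len(samples), len(marker_ids)), np.nan)
    for j in range(len(marker_ids)):
        cells = df.iloc[j, 11:]
        cells = cells.where(~cells.isin(["NN", "N", MISSING]), other=np.nan)
        codes[:, j] = _map_letter_codes(cells, marker_ids[j])
    meta = pd.DataFrame(
        {"chromosome": df["chrom"].values, "position": pd.to_numeric(df["pos"]).values},
        index=marker_ids,
    ) if {"chrom", "pos"}.issubset(df.columns) else None
    return GenotypeMatrix(samples, marker_ids, codes, marker_meta=meta)


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    G.to_frame().to_csv(path, sep="\t", na_rep=MISSING)


# ---------------------------------------------------------------------------
# genotype QC


def filter_snps(
    G: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.1
) -> GenotypeMatrix:
    """Drop markers with MAF strictly below ``maf_min`` or missing rate
    strictly above ``missing_max``; boundary values are kept."""
    maf = G.maf()
    miss = G.missing_fraction()
    keep = ~((maf < maf_min) | np.isnan(maf) | (miss > missing_max))
    if not keep.any():
        raise ValueError("all markers removed by QC filtering")
    logger.info("filter_snps: retained %d / %d markers", int(keep.sum()), G.n_markers)
    meta = G.marker_meta.loc[np.array(G.marker_ids)[keep]] if G.marker_meta is not None else None
    return GenotypeMatrix(
        list(G.line_ids),
        [m for m, k in zip(G.marker_ids, keep) if k],
        G.codes[:, keep],
        marker_meta=meta,
    )


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing codes by the per-marker mean of non-missing codes."""
    codes = G.codes.copy()
    nan_mask = np.isnan(codes)
    if not nan_mask.any():
        return replace(G, codes=codes)
    n_obs = (~nan_mask).sum(axis=0)
    if (n_obs == 0).any():
        bad = [m for m, n in zip(G.marker_ids, n_obs) if n == 0]
        raise ValueError(f"markers with no observed calls (filter first): {bad[:5]}")
    col_means = np.nansum(codes, axis=0) / n_obs
    codes[nan_mask] = np.broadcast_to(col_means, codes.shape)[nan_mask]
    return replace(G, codes=codes)


# ---------------------------------------------------------------------------
# metabolome / phenotype / cross table io


def read_metabolome(
    path: str | Path,
    meta_path: str | Path | None = None,
    replicate_column: str | None = "replicate",
) -> MetabolomeMatrix:
    """Read a metabolome matrix; an optional ``replicate`` column (after the
    line-id column) labels biological replicates. ``meta_path`` points to a
    delimited metabolite metadata table (annotation, category, tissue)."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])
    replicate_index = None
    if replicate_column is not None and replicate_column in df.columns:
        replicate_index = df[replicate_column].astype(str).tolist()
        df = df.drop(columns=[replicate_column])
    meta = None
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep="\t", index_col=0, na_values=[MISSING])
    return MetabolomeMatrix(
        df.index.astype(str).tolist(),
        df.columns.astype(str).tolist(),
        df.to_numpy(dtype=float),
        replicate_index=replicate_index,
        meta=meta,
    )


def write_metabolome(Mx: MetabolomeMatrix, path: str | Path, meta_path: str | Path | None = None) -> None:
    df = Mx.to_frame()
    if Mx.replicate_index is not None:
        df.insert(0, "replicate", Mx.replicate_index)
    df.to_csv(path, sep="\t", na_rep=MISSING)
    if meta_path is not None and Mx.meta is not None:
        Mx.meta.to_csv(meta_path, sep="\t", na_rep=MISSING)


def subset_metabolome(Mx: MetabolomeMatrix, tissue: str) -> MetabolomeMatrix:
    """Keep only metabolites whose metadata tissue label equals ``tissue``."""
    if Mx.meta is None or "tissue" not in Mx.meta.columns:
        raise ValueError("metabolite metadata with a 'tissue' column is required")
    tissues = Mx.meta["tissue"].reindex(Mx.metabolite_ids)
    if tissue not in set(tissues.dropna()):
        raise ValueError(f"unknown tissue label {tissue!r}")
    keep = (tissues == tissue).to_numpy()
    return MetabolomeMatrix(
        list(Mx.line_ids),
        [m for m, k in zip(Mx.metabolite_ids, keep) if k],
        Mx.values[:, keep],
        replicate_index=None if Mx.replicate_index is None else list(Mx.replicate_index),
        meta=Mx.meta.loc[np.array(Mx.metabolite_ids)[keep]],
        normalized=Mx.normalized,
    )


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING])
    return PhenotypeTable(
        df.index.astype(str).tolist(), df.columns.astype(str).tolist(), df.to_numpy(dtype=float)
    )


def write_phenotypes(P: PhenotypeTable, path: str | Path) -> None:
    P.to_frame().to_csv(path, sep="\t", na_rep=MISSING)


def read_crosses(path: str | Path) -> CrossTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CrossTable(df[list(CrossTable.COLUMNS)])


def write_crosses(C: CrossTable, path: str | Path) -> None:
    C.table.to_csv(path, sep="\t", index=False)
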