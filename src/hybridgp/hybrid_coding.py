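"""Hybrid-level feature construction from parental genotypes and metabolomes.

A hybrid's genotype is the midpoint of its two inbred parents. Its
metabolite features are the additive coding A = (M + F) / 2 and the
dominance coding D = |M - F| / 2, where M and F are the parental metabolite
matrices. Both codings are symmetric in the parents, so reciprocal crosses
share one feature row.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import CrossTable, GenotypeMatrix, MetabolomeMatrix

MODEL_TAGS = ("GP", "MP", "MMP", "M_GP", "MM_GP")

__all__ = ["FeatureSet", "MODEL_TAGS", "infer_hybrid_genotypes", "code_metabolites", "assemble_features"]


@dataclass
class FeatureSet:
    """Design matrices for one model configuration.

    Z_G is hybrids x markers; A_M and D_M are hybrids x metabolites. Models
    without a genomic (or metabolomic) term carry ``None`` for the absent
    blocks.
    """

    hybrid_ids: list[str]
    model_tag: str
    Z_G: np.ndarray | None = None
    A_M: np.ndarray | None = None
    D_M: np.ndarray | None = None
    marker_ids: list[str] | None = None
    metabolite_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.model_tag!r}")
        n = len(self.hybrid_ids)
        for name, mat in (("Z_G", self.Z_G), ("A_M", self.A_M), ("D_M", self.D_M)):
            if mat is not None and mat.shape[0] != n:
                raise ValueError(f"{name} row count mismatch")
        if self.D_M is not None and (self.D_M < 0).any():
            raise ValueError("dominance coding must be non-negative")

    @property
    def blocks(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        if self.Z_G is not None:
            out["G"] = self.Z_G
        if self.A_M is not None:
            out["Ma"] = self.A_M
        if self.D_M is not None:
            out["Md"] = self.D_M
        return out

    def concatenated(self) -> np.ndarray:
        """Single feature matrix [Z_G | A_M | D_M] for tree-based engines."""
        return np.hstack(list(self.blocks.values()))

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "model_tag": self.model_tag,
            "n_hybrids": len(self.hybrid_ids),
            "marker_ids": self.marker_ids,
            "metabolite_ids": self.metabolite_ids,
            "blocks": list(self.blocks),
        }
        for name, key, cols in (
            ("Z_G", "G", self.marker_ids),
            ("A_M", "Ma", self.metabolite_ids),
            ("D_M", "Md", self.metabolite_ids),
        ):
            mat = self.blocks.get(key)
            if mat is not None:
                pd.DataFrame(mat, index=self.hybrid_ids, columns=cols).to_csv(
                    directory / f"{name}.tsv", sep="\t"
                )
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _parent_rows(ids: list[str], crosses: CrossTable) -> tuple[list[int], list[int]]:
    index = {lid: i for i, lid in enumerate(ids)}
    missing = [
        p
        for p in pd.concat([crosses.table["parent_female"], crosses.table["parent_male"]])
        if p not in index
    ]
    if missing:
        raise KeyError(f"parents absent from input: {sorted(set(missing))[:5]}")
    f = [index[p] for p in crosses.table["parent_female"]]
    m = [index[p] for p in crosses.table["parent_male"]]
    return f, m


def infer_hybrid_genotypes(G: GenotypeMatrix, crosses: CrossTable) -> np.ndarray:
    """Hybrid genotype = mean of the two parental codes, per marker."""
    if np.isnan(G.codes).any():
        raise ValueError("impute missing genotypes before inferring hybrids")
    non_inbred = ~np.isin(G.codes, (-1.0, 1.0))
    if non_inbred.any():
        warnings.warn(
            f"{int(non_inbred.sum())} non-inbred parental code(s); midpoint coding still applied",
            stacklevel=2,
        )
    fi, mi = _parent_rows(G.line_ids, crosses)
    return (G.codes[fi] + G.codes[mi]) / 2.0


def code_metabolites(
    Mline: MetabolomeMatrix, crosses: CrossTable
) -> tuple[np.ndarray, np.ndarray]:
    """Additive and dominance metabolite codings per cross:
    A = (M + F) / 2, D = |M - F| / 2."""
    if Mline.replicate_index is not None:
        raise ValueError("metabolome must be replicate-averaged")
    fi, mi = _parent_rows(Mline.line_ids, crosses)
    F = Mline.values[fi]
    M = Mline.values[mi]
    return (M + F) / 2.0, np.abs(M - F) / 2.0


def assemble_features(
    model_tag: str,
    G: GenotypeMatrix | None,
    Mline: MetabolomeMatrix | None,
    crosses: CrossTable,
    marker_ids: list[str] | None = None,
) -> FeatureSet:
    """Build the FeatureSet for one model configuration.

    GP: genotypes only. MP: full-metabolome A/D. MMP: selected-marker A/D.
    M_GP: genotypes + full-metabolome A/D. MM_GP: genotypes + selected-marker
    A/D. ``marker_ids`` (from MWAS) is required for MMP and MM_GP.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}")
    needs_geno = model_tag in ("GP", "M_GP", "MM_GP")
    needs_metab = model_tag in ("MP", "MMP", "M_GP", "MM_GP")
    Z = A = D = None
    kept_markers = kept_metabs = None
    if needs_geno:
        if G is None:
            raise ValueError(f"{model_tag} requires a genotype matrix")
        Z = infer_hybrid_genotypes(G, crosses)
        kept_markers = list(G.marker_ids)
    if needs_metab:
        if Mline is None:
            raise ValueError(f"{model_tag} requires a metabolome matrix")
        if model_tag in ("MMP", "MM_GP"):
            if not marker_ids:
                raise ValueError(
                    f"{model_tag} requires selected metabolic markers; run the "
                    "MWAS step (or pass marker_ids) first"
                )
            missing = [m for m in marker_ids if m not in set(Mline.metabolite_ids)]
            if missing:
                raise KeyError(f"markers absent from metabolome: {missing[:5]}")
            cols = [Mline.metabolite_ids.index(m) for m in marker_ids]
            Mline = MetabolomeMatrix(
                list(Mline.line_ids),
                [Mline.metabolite_ids[c] for c in cols],
                Mline.values[:, cols],
                meta=Mline.meta,
                normalized=Mline.normalized,
            )
        A, D = code_metabolites(Mline, crosses)
        kept_metabs = list(Mline.metabolite_ids)
    return FeatureSet(
        hybrid_ids=crosses.hybrid_ids,
        model_tag=model_tag,
        Z_G=Z,
        A_M=A,
        D_M=D,
        marker_ids=kept_markers,
        metabolite_ids=kept_metabs,
    )
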