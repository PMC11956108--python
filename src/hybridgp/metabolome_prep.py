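"""Metabolome preprocessing: replicate-concordance filtering, normalization,
replicate averaging, and per-metabolite variability (CV) profiling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import MetabolomeMatrix

__all__ = [
    "MetaboliteQCReport",
    "replicate_concordance_filter",
    "normalize",
    "average_replicates",
    "coefficient_of_variation",
]


@dataclass
class MetaboliteQCReport:
    """Per-metabolite replicate-difference p-value, kept flag, CV, and mean."""

    table: pd.DataFrame  # columns: p_value, kept, cv, mean

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="NA", index_label="metabolite_id")


def _replicate_pair(Mx: MetabolomeMatrix) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a two-replicate matrix into aligned (rep1, rep2) line blocks."""
    if Mx.replicate_index is None:
        raise ValueError("metabolome carries no replicate structure")
    df = Mx.to_frame()
    df.index = pd.MultiIndex.from_arrays(
        [Mx.line_ids, Mx.replicate_index], names=["line", "replicate"]
    )
    counts = df.groupby(level="line").size()
    offenders = counts[counts != 2].index.tolist()
    if offenders:
        raise ValueError(f"lines without exactly two replicates: {offenders[:10]}")
    lines = sorted(counts.index)
    reps = sorted(set(Mx.replicate_index))
    r1 = df.xs(reps[0], level="replicate").loc[lines].to_numpy()
    r2 = df.xs(reps[1], level="replicate").loc[lines].to_numpy()
    return r1, r2, lines


def replicate_concordance_filter(
    Mx: MetabolomeMatrix, alpha: float = 0.01, method: str = "paired-t"
) -> tuple[MetabolomeMatrix, MetaboliteQCReport]:
    """Remove metabolites whose two biological replicates differ significantly.

    For each metabolite a two-sided test compares replicate-1 and
    replicate-2 intensities across lines (``paired-t`` by default,
    ``two-sample-t`` selectable); metabolites with p < ``alpha`` are dropped.
    Identical replicates yield p = 1 and are kept.
    """
    r1, r2, _ = _replicate_pair(Mx)
    m = Mx.n_metabolites
    pvals = np.ones(m)
    for j in range(m):
        if method == "paired-t":
            d = r1[:, j] - r2[:, j]
            if np.allclose(d, 0.0):
                pvals[j] = 1.0
                continue
            res = stats.ttest_rel(r1[:, j], r2[:, j])
        elif method == "two-sample-t":
            if np.allclose(r1[:, j], r1[0, j]) and np.allclose(r2[:, j], r2[0, j]) \
                    and np.isclose(r1[0, j], r2[0, j]):
                pvals[j] = 1.0
                continue
            res = stats.ttest_ind(r1[:, j], r2[:, j])
        else:
            raise ValueError(f"unknown replicate test {method!r}")
        pvals[j] = 1.0 if np.isnan(res.pvalue) else res.pvalue
    kept = pvals >= alpha

    averaged = average_replicates(Mx)
    cv = coefficient_of_variation(averaged)
    means = averaged.values.mean(axis=0)
    report = MetaboliteQCReport(
        pd.DataFrame(
            {"p_value": pvals, "kept": kept, "cv": cv, "mean": means},
            index=Mx.metabolite_ids,
        )
    )
    filtered = MetabolomeMatrix(
        list(Mx.line_ids),
        [mid for mid, k in zip(Mx.metabolite_ids, kept) if k],
        Mx.values[:, kept],
        replicate_index=list(Mx.replicate_index),
        meta=None if Mx.meta is None else Mx.meta.loc[np.array(Mx.metabolite_ids)[kept]],
        normalized=Mx.normalized,
    )
    return filtered, report


def normalize(Mx: MetabolomeMatrix, method: str = "zscore") -> MetabolomeMatrix:
    """Normalize each metabolite column.

    ``zscore``: center to mean 0, scale to unit variance (population, i.e.
    n-denominator, convention). ``log-zscore``: log(1 + x) then z-score.
    Constant columns map to all-zeros with a warning.
    """
    x = Mx.values.copy()
    if np.isnan(x).any():
        col_means = np.nanmean(x, axis=0)
        idx = np.where(np.isnan(x))
        x[idx] = col_means[idx[1]]
    if method == "log-zscore":
        x = np.log1p(x)
    elif method != "zscore":
        raise ValueError(f"unknown normalization method {method!r}")
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant metabolite column(s) set to zero",
            stacklevel=2,
        )
    sd_safe = np.where(constant, 1.0, sd)
    z = (x - mu) / sd_safe
    z[:, constant] = 0.0
    return MetabolomeMatrix(
        list(Mx.line_ids),
        list(Mx.metabolite_ids),
        z,
        replicate_index=None if Mx.replicate_index is None else list(Mx.replicate_index),
        meta=Mx.meta,
        normalized=True,
    )


def average_replicates(Mx: MetabolomeMatrix) -> MetabolomeMatrix:
    """Collapse replicates to one row per line by the mean."""
    if Mx.replicate_index is None:
        return Mx
    df = Mx.to_frame()
    df.index = pd.Index(Mx.line_ids, name="line")
    avg = df.groupby(level="line", sort=True).mean()
    return MetabolomeMatrix(
        avg.index.tolist(),
        list(Mx.metabolite_ids),
        avg.to_numpy(),
        replicate_index=None,
        meta=Mx.meta,
        normalized=Mx.normalized,
    )


def coefficient_of_variation(Mx: MetabolomeMatrix) -> np.ndarray:
    """Per-metabolite CV = sample SD / mean on raw, replicate-averaged
    intensities; NaN (with a warning) where the mean is zero."""
    if Mx.normalized:
        raise ValueError("CV must be computed on raw intensities, not normalized values")
    if Mx.replicate_index is not None:
        Mx = average_replicates(Mx)
    if (Mx.values < 0).any():
        raise ValueError("negative intensities")
    mean = Mx.values.mean(axis=0)
    sd = Mx.values.std(axis=0, ddof=1)
    cv = np.full(Mx.n_metabolites, np.nan)
    nz = mean != 0
    cv[nz] = sd[nz] / mean[nz]
    if (~nz).any():
        warnings.warn(
            f"{int((~nz).sum())} metabolite(s) with zero mean: CV undefined",
            stacklevel=2,
        )
    return cv
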