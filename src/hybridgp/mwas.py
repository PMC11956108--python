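"""Metabolome-wide association: LASSO-path first-entry p-values, marker
selection, shared-marker summaries, and marker correlation profiling.

For each metabolite the statistic is the largest regularization strength at
which its LASSO coefficient is nonzero (lambda_entry, zero if it never
enters the path). With predictors and trait standardized, the p-value is
the probability that an independent standardized predictor would have
entered the path at a strength at least as large. The analytic backend
computes this as a level-crossing probability of the Gaussian process
x' r(alpha) along the residual path: the first-segment crossing reduces to
the exact Pearson-correlation null with n - 2 degrees of freedom (which
resolves arbitrarily small p-values for early entrants), and crossings at
later path knots are integrated by sampling the knot-residual Gaussian
vector. A permutation backend (B permutations of the trait, full path
recomputation) provides the distribution-free oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lars_path

from .data_io import GenotypeMatrix, MetabolomeMatrix, PhenotypeTable

__all__ = [
    "MWASResult",
    "lasso_entry_pvalues",
    "select_markers",
    "shared_markers",
    "marker_correlations",
    "metabolite_genomic_variance",
]


@dataclass
class MWASResult:
    trait: str
    table: pd.DataFrame  # index metabolite_id; columns lambda_entry, p_value, r2, significant
    alpha: float = 0.05

    def __post_init__(self) -> None:
        t = self.table
        if ((t["p_value"] < 0) | (t["p_value"] > 1)).any():
            raise ValueError("p-values outside [0, 1]")
        if (t["lambda_entry"] < 0).any():
            raise ValueError("negative entry strength")

    def write(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "trait", self.trait)
        out.to_csv(path, sep="\t", na_rep="NA", index_label="metabolite_id")


def _standardize(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=0)
    sd = a.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (a - mu) / sd


def _entry_strengths(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """LASSO path entry strengths plus the path itself.

    Returns (lambda_entry per predictor, knot penalties, knot residuals);
    lambda_entry is 0 for predictors that never enter.
    """
    n, m = X.shape
    alphas, _, coefs = lars_path(X, y, method="lasso")
    entry = np.zeros(m)
    nz = coefs != 0
    for j in range(m):
        hits = np.flatnonzero(nz[j])
        if hits.size:
            entry[j] = alphas[hits[0] - 1] if hits[0] > 0 else alphas[0]
    residuals = y[:, None] - X @ coefs
    return entry, alphas, residuals


def _marginal_tail(lam: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of an absolute Pearson correlation equal to the
    entry strength, under the exact null with n - 2 df (the first-segment
    crossing probability)."""
    lam = np.clip(lam, 0.0, 1.0)
    p = np.ones_like(lam)
    pos = lam > 0
    r = lam[pos]
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p[pos] = 2.0 * stats.t.sf(t, df=n - 2)
    return np.clip(p, 0.0, 1.0)


def _crossing_pvalues(
    lam: np.ndarray,
    alphas: np.ndarray,
    residuals: np.ndarray,
    n: int,
    n_draws: int = 20000,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of the entry strength of an independent predictor.

    A null standardized predictor x enters the path at knot t once its
    correlation with the knot residual, c_t = |x' r_t| / n, reaches the
    knot penalty alpha_t; its entry strength is the largest such alpha_t.
    Along the knots the vector of z_t = x' r_t is Gaussian with covariance
    R'R, so the exceedance probability of the null entry strength is
    estimated by sampling. The exact Pearson tail (first knot, where the
    residual is y itself) is used as a floor so that extreme entrants keep
    analytically resolved small p-values.
    """
    p = np.ones_like(lam)
    pos = lam > 0
    if not pos.any():
        return p
    rng = np.random.default_rng(seed)
    T = residuals.shape[1]
    gram = residuals.T @ residuals
    jitter = 1e-10 * max(np.trace(gram) / T, 1.0)
    L = np.linalg.cholesky(gram + jitter * np.eye(T))
    upper = alphas[:, None]
    lamstar = np.empty(n_draws)
    chunk = max(1, int(2e7) // T)
    done = 0
    while done < n_draws:
        s = min(chunk, n_draws - done)
        c = np.abs(L @ rng.standard_normal((T, s))) / n
        entry = np.where(c >= upper, upper, 0.0)
        lamstar[done : done + s] = entry.max(axis=0)
        done += s
    lamstar.sort()
    exceed = (n_draws - np.searchsorted(lamstar, lam[pos], side="left")) / n_draws
    # the exact Pearson tail is a valid floor only down to the second knot;
    # freezing it there keeps the floor monotone and negligible in the bulk
    floor_at = np.maximum(lam[pos], alphas[1] if len(alphas) > 1 else 0.0)
    p[pos] = np.maximum(exceed, _marginal_tail(floor_at, n))
    return np.clip(p, 0.0, 1.0)


def lasso_entry_pvalues(
    Mline: MetabolomeMatrix,
    y_parent: PhenotypeTable,
    trait: str,
    alpha: float = 0.05,
    backend: str = "analytic",
    n_permutations: int = 2000,
    n_draws: int = 20000,
    seed: int | None = None,
) -> MWASResult:
    """Associate each metabolite with a parental-line trait via the LASSO
    path first-entry statistic.

    ``backend='analytic'`` converts entry strengths through the Gaussian
    level-crossing null of the path (``n_draws`` samples for the knot
    integral, exact correlation tail); ``backend='permutation'`` estimates
    p-values from ``n_permutations`` trait permutations with full path
    recomputation.
    """
    if Mline.replicate_index is not None:
        raise ValueError("metabolome must be replicate-averaged before MWAS")
    y_all = y_parent.trait_vector(trait).reindex(Mline.line_ids)
    ok = y_all.notna().to_numpy()
    y = y_all.to_numpy()[ok]
    n = y.size
    if n < 10:
        raise ValueError(f"too few lines with phenotypes for MWAS (n={n})")
    if np.all(y == y[0]):
        raise ValueError(f"trait {trait!r} is constant")
    X = _standardize(Mline.values[ok])
    ys = _standardize(y.reshape(-1, 1)).ravel()

    lam, alphas, residuals = _entry_strengths(X, ys)
    if backend == "analytic":
        pvals = _crossing_pvalues(
            lam, alphas, residuals, n, n_draws=n_draws, seed=0 if seed is None else seed
        )
    elif backend == "permutation":
        rng = np.random.default_rng(seed)
        exceed = np.zeros_like(lam)
        for _ in range(n_permutations):
            lam_b, _, _ = _entry_strengths(X, ys[rng.permutation(n)])
            exceed += lam_b >= lam
        pvals = (1.0 + exceed) / (n_permutations + 1.0)
        pvals[lam == 0] = 1.0
    else:
        raise ValueError(f"unknown backend {backend!r}")

    # marginal explained variance of each metabolite
    sd = Mline.values[ok].std(axis=0)
    r = np.zeros(Mline.n_metabolites)
    nzsd = sd > 0
    if nzsd.any():
        xc = Mline.values[ok][:, nzsd] - Mline.values[ok][:, nzsd].mean(axis=0)
        yc = y - y.mean()
        r[nzsd] = (xc.T @ yc) / (np.linalg.norm(xc, axis=0) * np.linalg.norm(yc))
    table = pd.DataFrame(
        {
            "lambda_entry": lam,
            "p_value": pvals,
            "r2": r**2,
            "significant": pvals < alpha,
        },
        index=Mline.metabolite_ids,
    )
    return MWASResult(trait=trait, table=table, alpha=alpha)


def select_markers(res: MWASResult, alpha: float = 0.05, bh_correct: bool = False) -> list[str]:
    """Metabolites with p strictly below ``alpha``, ordered by ascending p.

    ``bh_correct`` applies Benjamini-Hochberg to the p-values first (off by
    default: raw p < alpha is the primary selection rule).
    """
    p = res.table["p_value"]
    if bh_correct:
        m = len(p)
        order = np.argsort(p.to_numpy(), kind="stable")
        q = np.empty(m)
        ranked = p.to_numpy()[order] * m / (np.arange(m) + 1)
        q[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        p = pd.Series(np.clip(q, 0, 1), index=p.index)
    sel = p[p < alpha].sort_values(kind="stable")
    return sel.index.tolist()


def shared_markers(results: list[MWASResult], min_traits: int, alpha: float = 0.05) -> list[str]:
    """Metabolites significant (p < alpha) in at least ``min_traits`` traits."""
    if min_traits < 1:
        raise ValueError("min_traits must be >= 1")
    if len(results) < min_traits:
        raise ValueError("fewer results than min_traits")
    counts: dict[str, int] = {}
    order: list[str] = []
    for res in results:
        for mid in select_markers(res, alpha=alpha):
            if mid not in counts:
                counts[mid] = 0
                order.append(mid)
            counts[mid] += 1
    return [mid for mid in order if counts[mid] >= min_traits]


def marker_correlations(
    Mline: MetabolomeMatrix, markers: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations and two-sided p-values among markers;
    pairs involving a constant marker are NaN."""
    if len(markers) < 2:
        raise ValueError("need at least two markers")
    df = Mline.to_frame()[markers]
    k = len(markers)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    x = df.to_numpy()
    const = x.std(axis=0) == 0
    for i in range(k):
        for j in range(i, k):
            if const[i] or const[j]:
                continue
            res = stats.pearsonr(x[:, i], x[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=markers, columns=markers),
        pd.DataFrame(p, index=markers, columns=markers),
    )


def metabolite_genomic_variance(
    G: GenotypeMatrix, Mline: MetabolomeMatrix, marker: str
) -> float:
    """Fraction of a metabolite's variance captured by genome-wide kinship:
    single-kernel REML of the metabolite on K_G, returning
    phi_G^2 / (phi_G^2 + sigma_e^2). NaN if the fit fails to converge."""
    from .gblup import KernelSet, build_kernel, reml_fit

    df = Mline.to_frame()
    common = [lid for lid in G.line_ids if lid in set(df.index)]
    y = df.loc[common, marker].to_numpy()
    if y.std() == 0:
        raise ValueError(f"metabolite {marker!r} is constant")
    rows = [G.line_ids.index(lid) for lid in common]
    Z = G.codes[rows]
    K = build_kernel(Z, Z.shape[1])
    kernels = KernelSet(labels=["G"], matrices=[K])
    X = np.ones((len(common), 1))
    fit = reml_fit(y, X, kernels)
    if not fit.converged:
        return float("nan")
    phi = fit.variance_components["G"]
    sig = fit.variance_components["residual"]
    return float(phi / (phi + sig)) if (phi + sig) > 0 else float("nan")
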