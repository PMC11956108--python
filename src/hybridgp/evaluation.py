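"""Repeated k-fold cross-validation of the model configurations, predictive
ability, model comparison, and the random-metabolite control."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .boosting import fit_boosting, predict_boosting, tune_hyperparameters
from .data_io import CrossTable, GenotypeMatrix, MetabolomeMatrix, PhenotypeTable
from .gblup import KernelSet, TrainTestSplit, build_kernel, predict_blup, reml_fit
from .hybrid_coding import FeatureSet, assemble_features
from .mwas import lasso_entry_pvalues, select_markers

__all__ = [
    "ModelBundle",
    "CVResult",
    "predictive_ability",
    "cross_validate",
    "compare_models",
    "random_metabolite_control",
    "percent_change",
]


@dataclass
class ModelBundle:
    """Everything one trait's evaluation needs: QC'd parental genotypes,
    replicate-averaged normalized metabolome, hybrid crosses + phenotypes,
    and parental phenotypes for in-fold marker selection."""

    G: GenotypeMatrix | None
    Mline: MetabolomeMatrix | None
    crosses: CrossTable
    hybrid_phenotypes: PhenotypeTable
    parent_phenotypes: PhenotypeTable | None = None
    mwas_alpha: float = 0.05


@dataclass
class CVResult:
    model_tag: str
    engine: str
    trait: str
    k: int
    repeats: int
    abilities: np.ndarray  # repeats x k
    fold_assignments: list[np.ndarray] = field(default_factory=list)
    seed: int | None = None

    @property
    def mean(self) -> float:
        return float(self.abilities.mean())

    @property
    def sd(self) -> float:
        return float(self.abilities.std(ddof=1))

    @property
    def repeat_means(self) -> np.ndarray:
        return self.abilities.mean(axis=1)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (self.model_tag, self.engine, self.trait, r, f, self.abilities[r, f])
            for r in range(self.repeats)
            for f in range(self.k)
        ]
        return pd.DataFrame(
            rows, columns=["model", "engine", "trait", "repeat", "fold", "ability"]
        )


def predictive_ability(
    observed: np.ndarray, predicted: np.ndarray, definition: str = "squared-pearson"
) -> float:
    """Determination coefficient between observed and predicted values.

    Default: squared Pearson correlation (0 with a warning if either vector
    is constant). ``definition='one-minus-sse'`` gives 1 - SSE/SST instead.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size != predicted.size:
        raise ValueError("length mismatch")
    if observed.size < 3:
        raise ValueError("need at least 3 pairs")
    if definition == "one-minus-sse":
        sst = np.sum((observed - observed.mean()) ** 2)
        if sst == 0:
            warnings.warn("constant observed vector: ability set to 0", stacklevel=2)
            return 0.0
        return float(1.0 - np.sum((observed - predicted) ** 2) / sst)
    if definition != "squared-pearson":
        raise ValueError(f"unknown definition {definition!r}")
    tol = 1e-12
    if observed.std() <= tol * max(1.0, np.abs(observed).max()) or predicted.std() <= tol * max(
        1.0, np.abs(predicted).max()
    ):
        warnings.warn("constant vector: ability set to 0", stacklevel=2)
        return 0.0
    r = np.corrcoef(observed, predicted)[0, 1]
    return float(r**2)


def fold_partition(n: int, k: int, seed: int, repeat: int) -> list[np.ndarray]:
    """Seeded random partition into k near-equal folds, reproducible from
    (seed, repeat)."""
    rng = np.random.default_rng([seed, repeat])
    return [np.sort(f) for f in np.array_split(rng.permutation(n), k)]


def _fold_markers(
    bundle: ModelBundle, trait: str, train_crosses: CrossTable
) -> list[str]:
    """MWAS marker selection restricted to parents of the training hybrids."""
    assert bundle.parent_phenotypes is not None and bundle.Mline is not None
    parents = sorted(
        set(train_crosses.table["parent_female"]) | set(train_crosses.table["parent_male"])
    )
    with_pheno = [
        p
        for p in parents
        if p in set(bundle.parent_phenotypes.entry_ids)
        and np.isfinite(bundle.parent_phenotypes.trait_vector(trait, [p]).iloc[0])
    ]
    rows = [bundle.Mline.line_ids.index(p) for p in with_pheno]
    sub = MetabolomeMatrix(
        with_pheno,
        list(bundle.Mline.metabolite_ids),
        bundle.Mline.values[rows],
        meta=bundle.Mline.meta,
        normalized=bundle.Mline.normalized,
    )
    res = lasso_entry_pvalues(sub, bundle.parent_phenotypes, trait, alpha=bundle.mwas_alpha)
    return select_markers(res, alpha=bundle.mwas_alpha)


def global_markers(bundle: ModelBundle, trait: str) -> list[str]:
    """Marker selection on all parental lines (the fixed-list CV mode)."""
    if bundle.parent_phenotypes is None or bundle.Mline is None:
        raise ValueError("parental phenotypes and metabolome are required for MWAS")
    res = lasso_entry_pvalues(
        bundle.Mline, bundle.parent_phenotypes, trait, alpha=bundle.mwas_alpha
    )
    return select_markers(res, alpha=bundle.mwas_alpha)


def _feature_kernels(features: FeatureSet) -> KernelSet:
    labels, mats = [], []
    for lbl, block in features.blocks.items():
        labels.append(lbl)
        mats.append(build_kernel(block, block.shape[1]))
    return KernelSet(labels=labels, matrices=mats)


def _subset_crosses(crosses: CrossTable, idx: np.ndarray) -> CrossTable:
    return CrossTable(crosses.table.iloc[idx].reset_index(drop=True))


def cross_validate(
    model_tag: str,
    engine: str,
    bundle: ModelBundle,
    trait: str,
    k: int = 10,
    repeats: int = 20,
    seed: int = 0,
    marker_mode: str = "per-fold",
    markers: list[str] | None = None,
    tune: bool = False,
    n_trials: int = 20,
    inner_folds: int = 5,
) -> CVResult:
    """Repeated k-fold CV of one (model, engine, trait) combination.

    Each repeat draws a fresh seeded partition into k near-equal folds; the
    model is fitted on k-1 folds and scored on the held-out fold by
    predictive ability. In ``marker_mode='per-fold'`` (the strict default)
    metabolic-marker selection is re-run inside every training fold using
    only parents of training hybrids; ``'global'`` selects once on all
    parental data (pass ``markers`` to fix the list explicitly). Boosting
    hyperparameter tuning, when enabled, also runs inside the training fold.
    """
    if engine not in ("kernel", "boosting"):
        raise ValueError(f"unknown engine {engine!r}")
    if marker_mode not in ("per-fold", "global"):
        raise ValueError(f"unknown marker_mode {marker_mode!r}")
    y_all = bundle.hybrid_phenotypes.trait_vector(trait, bundle.crosses.hybrid_ids)
    keep = y_all.notna().to_numpy()
    crosses = _subset_crosses(bundle.crosses, np.flatnonzero(keep))
    y = y_all.to_numpy()[keep]
    n = y.size
    if n < 3 * k:
        raise ValueError(f"too few hybrids ({n}) for {k}-fold CV")

    needs_selection = model_tag in ("MMP", "MM_GP")
    fixed_markers = markers
    if needs_selection and marker_mode == "global" and fixed_markers is None:
        fixed_markers = global_markers(bundle, trait)
        if not fixed_markers:
            raise ValueError(
                f"{model_tag}: MWAS selected no markers; lower alpha or use another model"
            )
    per_fold_selection = needs_selection and marker_mode == "per-fold" and markers is None

    # feature blocks that do not depend on the fold
    static_features = None
    if not per_fold_selection:
        static_features = assemble_features(
            model_tag, bundle.G, bundle.Mline, crosses, marker_ids=fixed_markers
        )
        static_kernels = _feature_kernels(static_features) if engine == "kernel" else None
        static_X = static_features.concatenated() if engine == "boosting" else None
    geno_kernel = None
    if per_fold_selection and engine == "kernel" and model_tag == "MM_GP":
        Z = assemble_features("GP", bundle.G, None, crosses).Z_G
        geno_kernel = build_kernel(Z, Z.shape[1])
        geno_block = Z
    elif per_fold_selection and model_tag == "MM_GP":
        geno_block = assemble_features("GP", bundle.G, None, crosses).Z_G

    abilities = np.zeros((repeats, k))
    assignments: list[np.ndarray] = []
    for rep in range(repeats):
        folds = fold_partition(n, k, seed, rep)
        labels = np.empty(n, dtype=int)
        for f, idx in enumerate(folds):
            labels[idx] = f
        assignments.append(labels)
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            if per_fold_selection:
                sel = _fold_markers(bundle, trait, _subset_crosses(crosses, train_idx))
                if not sel:
                    raise ValueError(
                        f"{model_tag}: MWAS selected no markers in repeat {rep} fold {f}"
                    )
                feats = assemble_features("MMP", None, bundle.Mline, crosses, marker_ids=sel)
                blocks = {}
                if model_tag == "MM_GP":
                    blocks["G"] = geno_block
                blocks["Ma"] = feats.A_M
                blocks["Md"] = feats.D_M
                if engine == "kernel":
                    lbls, mats = [], []
                    for lbl, blk in blocks.items():
                        lbls.append(lbl)
                        if lbl == "G" and geno_kernel is not None:
                            mats.append(geno_kernel)
                        else:
                            mats.append(build_kernel(blk, blk.shape[1]))
                    kernels = KernelSet(labels=lbls, matrices=mats)
                else:
                    X_feat = np.hstack(list(blocks.values()))
            else:
                kernels = static_kernels  # type: ignore[assignment]
                X_feat = static_X  # type: ignore[assignment]

            if engine == "kernel":
                split = TrainTestSplit.from_kernels(kernels, train_idx, test_idx)
                fit = reml_fit(y[train_idx], None, kernels.subset(train_idx))
                pred = predict_blup(fit, split, y[train_idx])
            else:
                params = None
                if tune:
                    params, _ = tune_hyperparameters(
                        X_feat[train_idx],
                        y[train_idx],
                        n_trials=n_trials,
                        inner_folds=inner_folds,
                        seed=seed,
                    )
                model = fit_boosting(X_feat[train_idx], y[train_idx], params, seed=seed)
                pred = model.estimator.predict(X_feat[test_idx])
            abilities[rep, f] = predictive_ability(y[test_idx], pred)
    return CVResult(
        model_tag=model_tag,
        engine=engine,
        trait=trait,
        k=k,
        repeats=repeats,
        abilities=abilities,
        fold_assignments=assignments,
        seed=seed,
    )


def _compact_letters(names: list[str], means: np.ndarray, sig: np.ndarray) -> dict[str, str]:
    """Compact letter display by insert-and-absorb on the significance matrix."""
    order = np.argsort(-means, kind="stable")
    groups: list[set[int]] = [set(order.tolist())]
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            if not sig[a, b]:
                continue
            new_groups = []
            for g in groups:
                if a in g and b in g:
                    new_groups.extend([g - {a}, g - {b}])
                else:
                    new_groups.append(g)
            # absorb subsets
            groups = []
            for g in sorted(new_groups, key=len, reverse=True):
                if g and not any(g <= h for h in groups):
                    groups.append(g)
    groups.sort(key=lambda g: -max(means[i] for i in g))
    letters = {i: "" for i in range(len(names))}
    for gi, g in enumerate(groups):
        for i in g:
            letters[i] += chr(ord("a") + gi)
    return {names[i]: "".join(sorted(letters[i])) for i in range(len(names))}


def compare_models(results: list[CVResult], alpha: float = 0.05) -> pd.DataFrame:
    """Paired two-sided t-tests on repeat-level mean abilities, plus a
    compact letter display: models sharing a letter do not differ at alpha."""
    if len({(r.trait, r.engine, r.repeats, r.seed) for r in results}) != 1:
        raise ValueError("results must share trait, engine, repeats, and fold seed")
    names = [r.model_tag for r in results]
    m = len(results)
    means = np.array([r.repeat_means.mean() for r in results])
    pmat = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = results[i].repeat_means - results[j].repeat_means
            if np.allclose(d, 0.0):
                p = 1.0
            else:
                p = stats.ttest_rel(results[i].repeat_means, results[j].repeat_means).pvalue
            pmat[i, j] = pmat[j, i] = p
    letters = _compact_letters(names, means, pmat < alpha)
    rows = []
    for i in range(m):
        for j in range(m):
            if i != j:
                rows.append((names[i], names[j], means[i], means[j], pmat[i, j]))
    table = pd.DataFrame(rows, columns=["model_a", "model_b", "mean_a", "mean_b", "p_value"])
    table["letter_a"] = table["model_a"].map(letters)
    table["letter_b"] = table["model_b"].map(letters)
    return table


def random_metabolite_control(
    bundle: ModelBundle,
    trait: str,
    n_markers: int,
    n_draws: int = 10,
    seed: int = 0,
    k: int = 10,
    repeats: int = 20,
    engine: str = "kernel",
    model_tag: str = "MM_GP",
    **cv_kwargs,
) -> tuple[list[CVResult], float]:
    """Re-run the marker-assisted configuration with ``n_draws`` random
    metabolite draws of size ``n_markers`` in place of MWAS markers."""
    if bundle.Mline is None:
        raise ValueError("full metabolome required")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    if n_markers > bundle.Mline.n_metabolites:
        raise ValueError("n_markers exceeds metabolome size")
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_draws):
        draw = rng.choice(bundle.Mline.n_metabolites, size=n_markers, replace=False)
        ids = [bundle.Mline.metabolite_ids[i] for i in np.sort(draw)]
        results.append(
            cross_validate(
                model_tag,
                engine,
                bundle,
                trait,
                k=k,
                repeats=repeats,
                seed=seed,
                marker_mode="global",
                markers=ids,
                **cv_kwargs,
            )
        )
    return results, float(np.mean([r.mean for r in results]))


def percent_change(a: float, b: float) -> float:
    """100 * (a - b) / b."""
    if b == 0:
        raise ZeroDivisionError("baseline is zero")
    return 100.0 * (a - b) / b
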