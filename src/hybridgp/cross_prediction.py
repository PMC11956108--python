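"""Enumerate, predict, and rank all potential crosses among a parent panel,
and summarize selection gains."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boosting import BoostingModel, predict_boosting
from .data_io import CrossTable, GenotypeMatrix, MetabolomeMatrix
from .gblup import KernelSet, MixedModelFit, TrainTestSplit, predict_blup
from .hybrid_coding import assemble_features

logger = logging.getLogger(__name__)

__all__ = [
    "CrossPredictionTable",
    "enumerate_crosses",
    "predict_all_crosses",
    "top_bottom_summary",
    "selection_gain",
]


@dataclass
class CrossPredictionTable:
    table: pd.DataFrame  # parent_female, parent_male, predicted, rank, observed_in_training

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def enumerate_crosses(parent_ids: list[str]) -> CrossTable:
    """All unordered parent pairs (selfs excluded, reciprocals collapsed),
    in lexicographic order; n parents give n(n-1)/2 crosses."""
    if len(parent_ids) < 2:
        raise ValueError("need at least two parents")
    if len(set(parent_ids)) != len(parent_ids):
        raise ValueError("duplicate parent ids")
    ids = sorted(parent_ids)
    records = [
        (f"{a}x{b}", a, b) for i, a in enumerate(ids) for b in ids[i + 1 :]
    ]
    return CrossTable.from_records(records)


def predict_all_crosses(
    model: MixedModelFit | BoostingModel,
    G: GenotypeMatrix,
    Mline: MetabolomeMatrix | None,
    training_crosses: CrossTable,
    y_train: np.ndarray,
    model_tag: str = "MM_GP",
    marker_ids: list[str] | None = None,
    engine: str = "kernel",
    batch_size: int = 4096,
) -> CrossPredictionTable:
    """Predict every enumerable cross among the parents of ``G``.

    Features for each cross are built from the parents; kernel predictions
    use the conditional mean given the observed training hybrids (with the
    training block factorized once), boosting predictions the fitted
    ensemble. Crosses whose parents lack metabolome data are excluded with a
    logged count. The table is sorted descending by prediction.
    """
    parents = list(G.line_ids)
    if Mline is not None and model_tag != "GP":
        with_metab = set(Mline.line_ids)
        usable = [p for p in parents if p in with_metab]
        dropped = len(parents) - len(usable)
        if dropped:
            logger.warning("excluded crosses of %d parent(s) lacking metabolome data", dropped)
        parents = usable
    all_crosses = enumerate_crosses(parents)

    train_feats = assemble_features(
        model_tag, G, Mline, training_crosses, marker_ids=marker_ids
    )
    trained_pairs = {
        frozenset(p)
        for p in zip(
            training_crosses.table["parent_female"], training_crosses.table["parent_male"]
        )
    }
    observed = np.array(
        [
            frozenset(p) in trained_pairs
            for p in zip(all_crosses.table["parent_female"], all_crosses.table["parent_male"])
        ]
    )

    n_new = len(all_crosses)
    preds = np.empty(n_new)
    for start in range(0, n_new, batch_size):
        chunk = CrossTable(all_crosses.table.iloc[start : start + batch_size].reset_index(drop=True))
        feats = assemble_features(model_tag, G, Mline, chunk, marker_ids=marker_ids)
        if engine == "kernel":
            assert isinstance(model, MixedModelFit)
            labels, K11, K21, K22 = [], [], [], []
            for lbl, tr_block in train_feats.blocks.items():
                te_block = feats.blocks[lbl]
                q = tr_block.shape[1]
                labels.append(lbl)
                K11.append(tr_block @ tr_block.T / q)
                K21.append(te_block @ tr_block.T / q)
                K22.append(te_block @ te_block.T / q)
            split = TrainTestSplit(
                train_idx=np.arange(len(training_crosses)),
                test_idx=np.arange(len(chunk)),
                labels=labels,
                K11=K11,
                K21=K21,
                K22=K22,
            )
            preds[start : start + len(chunk)] = predict_blup(model, split, y_train)
        elif engine == "boosting":
            assert isinstance(model, BoostingModel)
            preds[start : start + len(chunk)] = predict_boosting(model, feats)
        else:
            raise ValueError(f"unknown engine {engine!r}")

    out = pd.DataFrame(
        {
            "parent_female": all_crosses.table["parent_female"],
            "parent_male": all_crosses.table["parent_male"],
            "predicted": preds,
            "observed_in_training": observed,
        }
    )
    out = out.sort_values("predicted", ascending=False, kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, n_new + 1)
    return CrossPredictionTable(out)


def top_bottom_summary(table: CrossPredictionTable, k: int = 100) -> dict[str, float]:
    """Mean +/- SD of the top-k, bottom-k, and all predictions, plus the
    percent difference of top vs bottom means."""
    preds = table.table["predicted"].to_numpy()
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > preds.size:
        raise ValueError("k exceeds the number of crosses")
    srt = np.sort(preds)[::-1]
    top, bottom = srt[:k], srt[-k:]
    sd = lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    bottom_mean = float(bottom.mean())
    return {
        "k": k,
        "top_mean": float(top.mean()),
        "top_sd": sd(top),
        "bottom_mean": bottom_mean,
        "bottom_sd": sd(bottom),
        "population_mean": float(preds.mean()),
        "population_sd": sd(preds),
        "top_vs_bottom_percent": 100.0 * (top.mean() - bottom_mean) / bottom_mean
        if bottom_mean != 0
        else float("nan"),
    }


def selection_gain(top_mean: float, baseline_mean: float) -> dict[str, float]:
    """Absolute and percent gain of selecting the top crosses over a
    baseline mean: 100 * (top - baseline) / baseline."""
    if baseline_mean == 0:
        raise ZeroDivisionError("baseline mean is zero")
    absolute = top_mean - baseline_mean
    return {"absolute": absolute, "percent": 100.0 * absolute / baseline_mean}
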