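"""Six per-perturbation evaluation metrics with mean ± sd aggregation.

Each test perturbation is scored separately against its ground-truth cells:
pseudo-bulk mean squared error, Pearson correlation of the expression
*change* relative to control, maximum mean discrepancy, energy distance,
and the fractions of genes whose predicted change agrees with / opposes the
true change in sign. Every metric is computed on all genes and on the
top-50 highly-variable-gene subset; aggregates are unweighted across
perturbations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats

from ._utils import child_seed
from .model import mmd

log = logging.getLogger("sccvae")

__all__ = [
    "pseudo_bulk",
    "mse_metric",
    "pearson_change",
    "energy_distance",
    "fraction_same_changed",
    "top_k_hvg",
    "MetricsReport",
    "evaluate",
]

METRICS = ("MSE", "PearsonR", "MMD", "EnergyDist", "FracSame", "FracChanged")


def pseudo_bulk(cells: np.ndarray) -> np.ndarray:
    """Per-gene arithmetic mean over a population of cells."""
    cells = np.atleast_2d(np.asarray(cells, dtype=float))
    if cells.shape[0] == 0:
        raise ValueError("empty batch")
    return cells.mean(axis=0)


def mse_metric(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared difference of the two pseudo-bulk vectors."""
    return float(((pseudo_bulk(pred) - pseudo_bulk(truth)) ** 2).mean())


def pearson_change(pred: np.ndarray, truth: np.ndarray, control: np.ndarray) -> float:
    """Pearson correlation across genes between predicted and true change
    from the control pseudo-bulk; NaN when either change has zero variance."""
    cb = pseudo_bulk(control)
    d_pred = pseudo_bulk(pred) - cb
    d_true = pseudo_bulk(truth) - cb
    if np.std(d_pred) == 0 or np.std(d_true) == 0:
        log.info("pearson_change undefined: zero-variance change vector")
        return float("nan")
    return float(scipy.stats.pearsonr(d_pred, d_true).statistic)


def energy_distance(X: np.ndarray, Y: np.ndarray) -> float:
    """Energy distance 2 E||x-y|| - E||x-x'|| - E||y-y'|| (V-statistic)."""
    X, Y = np.atleast_2d(X), np.atleast_2d(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("dimension mismatch")
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("samples must be nonempty")
    dxy = scipy.spatial.distance.cdist(X, Y).mean()
    dxx = scipy.spatial.distance.cdist(X, X).mean()
    dyy = scipy.spatial.distance.cdist(Y, Y).mean()
    return float(max(2.0 * dxy - dxx - dyy, 0.0))


def fraction_same_changed(
    pred: np.ndarray, truth: np.ndarray, control: np.ndarray, epsilon: float = 0.0
) -> tuple[float, float]:
    """Fractions of genes whose predicted change matches / opposes the true
    change in sign.

    Genes whose true or predicted change lies inside the dead-zone
    ``|delta| <= epsilon`` are excluded from both numerators but stay in the
    denominator, so the two fractions need not sum to 1.
    """
    cb = pseudo_bulk(control)
    d_pred = pseudo_bulk(pred) - cb
    d_true = pseudo_bulk(truth) - cb
    m = len(d_true)
    live = (np.abs(d_true) > epsilon) & (np.abs(d_pred) > epsilon)
    same = int((live & (np.sign(d_pred) == np.sign(d_true))).sum())
    changed = int((live & (np.sign(d_pred) == -np.sign(d_true))).sum())
    return same / m, changed / m


def top_k_hvg(X: np.ndarray, k: int = 50) -> np.ndarray:
    """Indices of the k genes of greatest variance across all cells;
    ties broken deterministically by gene index."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m = X.shape[1]
    if not 1 <= k <= m:
        raise ValueError(f"k={k} out of range [1, {m}]")
    var = X.var(axis=0)
    # stable sort on (-variance, index)
    order = np.lexsort((np.arange(m), -var))
    return np.sort(order[:k])


@dataclass
class MetricsReport:
    """Long-form per-perturbation metric table plus aggregate summaries."""

    table: pd.DataFrame  # columns: perturbation, gene_set, metric, value
    bandwidths: dict
    partial: bool = False

    def summary(self) -> pd.DataFrame:
        """Unweighted mean and sd per metric per gene set (NaNs excluded, logged)."""
        return (
            self.table.groupby(["gene_set", "metric"], sort=False)["value"]
            .agg(["mean", "std"])
            .reset_index()
        )

    def pivot(self, gene_set: str = "all") -> pd.DataFrame:
        sub = self.table[self.table.gene_set == gene_set]
        return sub.pivot(index="perturbation", columns="metric", values="value")

    def save_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def summary_dict(self) -> dict:
        out: dict = {}
        for (gs, metric), grp in self.table.groupby(["gene_set", "metric"], sort=False):
            out.setdefault(gs, {})[metric] = {
                "mean": float(grp.value.mean()),
                "sd": float(grp.value.std()),
            }
        return out


def evaluate(
    predictions: dict[str, np.ndarray],
    truth: dict[str, np.ndarray],
    control: np.ndarray,
    hvg_k: int = 50,
    epsilon: float = 0.0,
    mmd_bandwidths=None,
    max_cells: int = 500,
    seed: int = 0,
) -> MetricsReport:
    """Score every predicted perturbation against its ground-truth cells.

    ``mmd_bandwidths``: kernel length-scales shared across perturbations;
    by default the median heuristic on the pooled truth vs control (fixed
    once and recorded in the report). MMD and energy distance subsample at
    most ``max_cells`` cells per side (seeded) for O(n^2) control.
    """
    from .model import median_heuristic_bandwidths

    control = np.atleast_2d(control)
    missing = sorted(set(truth) - set(predictions))
    if missing:
        log.warning("missing predictions for %d perturbations: %s", len(missing), missing[:5])
    rng = np.random.default_rng(child_seed(seed, "evaluate"))
    all_truth = np.vstack([v for v in truth.values()]) if truth else control
    pool = all_truth if len(all_truth) <= max_cells else all_truth[rng.choice(len(all_truth), max_cells, replace=False)]
    cpool = control if len(control) <= max_cells else control[rng.choice(len(control), max_cells, replace=False)]
    gene_sets = {"all": np.arange(control.shape[1]), "top50": top_k_hvg(all_truth, min(hvg_k, control.shape[1]))}
    if mmd_bandwidths is None:
        mmd_bandwidths = {gs: median_heuristic_bandwidths(pool[:, gidx], cpool[:, gidx]) for gs, gidx in gene_sets.items()}
    rows = []
    for p in sorted(truth):
        if p not in predictions:
            continue
        pred, tr = np.atleast_2d(predictions[p]), np.atleast_2d(truth[p])
        pred_s = pred if len(pred) <= max_cells else pred[rng.choice(len(pred), max_cells, replace=False)]
        tr_s = tr if len(tr) <= max_cells else tr[rng.choice(len(tr), max_cells, replace=False)]
        for gs, gidx in gene_sets.items():
            frac_same, frac_changed = fraction_same_changed(pred[:, gidx], tr[:, gidx], control[:, gidx], epsilon)
            vals = {
                "MSE": mse_metric(pred[:, gidx], tr[:, gidx]),
                "PearsonR": pearson_change(pred[:, gidx], tr[:, gidx], control[:, gidx]),
                "MMD": mmd(pred_s[:, gidx], tr_s[:, gidx], mmd_bandwidths[gs]),
                "EnergyDist": energy_distance(pred_s[:, gidx], tr_s[:, gidx]),
                "FracSame": frac_same,
                "FracChanged": frac_changed,
            }
            rows.extend({"perturbation": p, "gene_set": gs, "metric": k, "value": v} for k, v in vals.items())
    return MetricsReport(
        table=pd.DataFrame(rows, columns=["perturbation", "gene_set", "metric", "value"]),
        bandwidths={gs: np.asarray(b).tolist() for gs, b in mmd_bandwidths.items()},
        partial=bool(missing),
    )
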