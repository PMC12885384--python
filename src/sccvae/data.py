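"""Dataset I/O, perturbation filtering, and train/val/test splits.

The in-memory container is an :class:`anndata.AnnData` with normalized
expression in ``.X`` (cells x genes) and a per-cell perturbation annotation
in ``.obs`` — the target gene symbol, or a control token for non-targeting
guides. All functions here take and return AnnData.

Two curation filters gate which perturbations enter the benchmark:
a minimum-cell-count filter (default 200 cells) and a distinguishability
filter that keeps a perturbation only when a cross-validated logistic
regression separates its cells from controls with mean accuracy above a
threshold (default 0.6), so that retained perturbations require nontrivial
predictions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_score

from ._utils import child_seed

log = logging.getLogger("sccvae")

PERTURBATION_KEY = "perturbation"
CONTROL_TOKEN = "non-targeting"

__all__ = [
    "PERTURBATION_KEY",
    "CONTROL_TOKEN",
    "read_dataset",
    "validate_dataset",
    "perturbation_counts",
    "filter_min_cells",
    "DistinguishabilityFilter",
    "filter_distinguishable",
    "SplitAssignment",
    "make_split",
    "dense_X",
]


def dense_X(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    if scipy.sparse.issparse(X):
        X = X.toarray()
    return np.asarray(X, dtype=float)


def validate_dataset(
    adata: ad.AnnData,
    perturbation_key: str = PERTURBATION_KEY,
    control_token: str = CONTROL_TOKEN,
) -> ad.AnnData:
    """Check the dataset contract; drop cells whose target is unmeasured."""
    if perturbation_key not in adata.obs:
        raise KeyError(f"missing per-cell annotation column {perturbation_key!r}")
    pert = adata.obs[perturbation_key].astype(str)
    genes = set(map(str, adata.var_names))
    ok = (pert == control_token) | pert.isin(genes)
    if not ok.all():
        dropped = pert[~ok].unique().tolist()
        warnings.warn(
            f"dropping {int((~ok).sum())} cells whose perturbation target is not a measured gene: {dropped[:5]}..."
        )
        adata = adata[ok.to_numpy()].copy()
    if int((adata.obs[perturbation_key].astype(str) == control_token).sum()) == 0:
        raise ValueError(f"dataset contains no control cells (token {control_token!r})")
    lo, hi = float(np.min(adata.X)), float(np.max(adata.X))
    if hi > 1e4 or lo < -1e3:
        warnings.warn(f"expression range [{lo:.3g}, {hi:.3g}] looks un-normalized; inputs are assumed pre-normalized")
    counts = perturbation_counts(adata, perturbation_key, control_token)
    log.info(
        "dataset: %d cells x %d genes, %d perturbations, %d control cells",
        adata.n_obs,
        adata.n_vars,
        len(counts),
        int((adata.obs[perturbation_key].astype(str) == control_token).sum()),
    )
    return adata


def read_dataset(
    path: str | Path,
    format: str = "h5ad",
    perturbation_key: str = PERTURBATION_KEY,
    control_token: str = CONTROL_TOKEN,
) -> ad.AnnData:
    """Read an expression dataset from h5ad, an MTX directory, or a wide TSV.

    TSV layout: first column cell id (index), one ``perturbation`` column,
    remaining columns genes. MTX directory layout: ``matrix.mtx`` (cells x
    genes or genes x cells), ``barcodes.tsv``, ``features.tsv`` and
    ``annotation.tsv`` (cell_id <tab> perturbation).
    """
    path = Path(path)
    if format == "h5ad":
        adata = ad.read_h5ad(path)
    elif format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if perturbation_key not in frame.columns:
            raise KeyError(f"missing per-cell annotation column {perturbation_key!r}")
        pert = frame.pop(perturbation_key).astype(str)
        adata = ad.AnnData(
            X=frame.to_numpy(dtype=float),
            obs=pd.DataFrame({perturbation_key: pert.to_numpy()}, index=frame.index.astype(str)),
            var=pd.DataFrame(index=frame.columns.astype(str)),
        )
    elif format == "mtx_dir":
        X = scipy.io.mmread(path / "matrix.mtx").tocsr()
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
        if X.shape == (len(features), len(barcodes)) and X.shape[0] != X.shape[1]:
            X = X.T.tocsr()
        ann = pd.read_csv(path / "annotation.tsv", sep="\t", index_col=0)
        if perturbation_key not in ann.columns:
            raise KeyError(f"missing per-cell annotation column {perturbation_key!r}")
        adata = ad.AnnData(
            X=X,
            obs=pd.DataFrame(
                {perturbation_key: ann.loc[barcodes, perturbation_key].astype(str).to_numpy()},
                index=barcodes.to_numpy(),
            ),
            var=pd.DataFrame(index=features.to_numpy()),
        )
    else:
        raise ValueError(f"unknown format {format!r}; one of h5ad, mtx_dir, tsv")
    return validate_dataset(adata, perturbation_key, control_token)


def perturbation_counts(
    adata: ad.AnnData,
    perturbation_key: str = PERTURBATION_KEY,
    control_token: str = CONTROL_TOKEN,
) -> pd.Series:
    """Cell counts per non-control perturbation."""
    pert = adata.obs[perturbation_key].astype(str)
    counts = pert.value_counts()
    return counts[counts.index != control_token]


def filter_min_cells(
    adata: ad.AnnData,
    min_cells: int = 200,
    perturbation_key: str = PERTURBATION_KEY,
    control_token: str = CONTROL_TOKEN,
) -> ad.AnnData:
    """Remove every perturbation with strictly fewer than ``min_cells`` cells.

    A perturbation with exactly ``min_cells`` cells is retained; control
    cells are never touched.
    """
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    counts = perturbation_counts(adata, perturbation_key, control_token)
    keep_perts = set(counts[counts >= min_cells].index)
    pert = adata.obs[perturbation_key].astype(str)
    keep = (pert == control_token) | pert.isin(keep_perts)
    removed = sorted(set(counts.index) - keep_perts)
    if removed:
        log.info("filter_min_cells(%d): removed %d perturbations: %s", min_cells, len(removed), removed[:10])
    if not keep_perts:
        warnings.warn("filter_min_cells removed every perturbation")
    return adata[keep.to_numpy()].copy()


class DistinguishabilityFilter(BaseEstimator):
    """Keep perturbations a classifier can tell apart from controls.

    For each perturbation independently, an L2-regularized logistic
    regression (all genes as features, class-balanced) is scored by
    stratified k-fold cross-validated accuracy against control cells; the
    perturbation is retained iff the mean score strictly exceeds
    ``threshold``. Each class is subsampled (seeded) to at most
    ``max_cells_per_class`` cells for tractability.

    Attributes
    ----------
    scores_ : pd.Series, mean CV accuracy per perturbation (NaN = skipped).
    retained_ : list of retained perturbation ids.
    """

    def __init__(
        self,
        threshold: float = 0.6,
        folds: int = 5,
        max_cells_per_class: int = 2000,
        C: float = 1.0,
        random_state: int = 0,
        perturbation_key: str = PERTURBATION_KEY,
        control_token: str = CONTROL_TOKEN,
    ):
        self.threshold = threshold
        self.folds = folds
        self.max_cells_per_class = max_cells_per_class
        self.C = C
        self.random_state = random_state
        self.perturbation_key = perturbation_key
        self.control_token = control_token

    def fit(self, adata: ad.AnnData, y=None):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        pert = adata.obs[self.perturbation_key].astype(str).to_numpy()
        X = dense_X(adata)
        ctrl_idx = np.nonzero(pert == self.control_token)[0]
        rng = np.random.default_rng(child_seed(self.random_state, "distinguishability"))
        scores = {}
        for p in pd.unique(pert[pert != self.control_token]):
            p_idx = np.nonzero(pert == p)[0]
            if len(p_idx) < self.folds or len(ctrl_idx) < self.folds:
                log.info("skipping %s: class too small for %d-fold CV", p, self.folds)
                scores[p] = np.nan
                continue
            pi = rng.choice(p_idx, min(len(p_idx), self.max_cells_per_class), replace=False)
            ci = rng.choice(ctrl_idx, min(len(ctrl_idx), self.max_cells_per_class), replace=False)
            Xp = np.vstack([X[pi], X[ci]])
            yp = np.r_[np.ones(len(pi)), np.zeros(len(ci))]
            clf = LogisticRegression(C=self.C, class_weight="balanced", max_iter=2000)
            cv = StratifiedKFold(self.folds, shuffle=True, random_state=child_seed(self.random_state, f"cv:{p}"))
            scores[p] = float(cross_val_score(clf, Xp, yp, cv=cv, scoring="accuracy").mean())
        self.scores_ = pd.Series(scores, name="cv_accuracy")
        self.retained_ = sorted(self.scores_[self.scores_ > self.threshold].index)
        return self

    def transform(self, adata: ad.AnnData) -> ad.AnnData:
        pert = adata.obs[self.perturbation_key].astype(str)
        keep = (pert == self.control_token) | pert.isin(self.retained_)
        return adata[keep.to_numpy()].copy()


def filter_distinguishable(
    adata: ad.AnnData,
    score_threshold: float = 0.6,
    folds: int = 5,
    seed: int = 0,
    **kwargs,
) -> tuple[ad.AnnData, pd.Series]:
    """Functional wrapper: returns (filtered dataset, per-perturbation scores)."""
    filt = DistinguishabilityFilter(threshold=score_threshold, folds=folds, random_state=seed, **kwargs)
    filt.fit(adata)
    return filt.transform(adata), filt.scores_


@dataclass
class SplitAssignment:
    """Per-cell train/val/test roles for one split.

    ``in_distribution``: every perturbation's cells partition ~70/10/20.
    ``out_of_distribution``: 20% of perturbations (one of 5 rotating,
    seeded groups) contribute all their cells to test and none to train or
    val; remaining perturbations' cells partition ~85/15 train/val;
    control cells are never held out.
    """

    scheme: str
    split_index: int
    roles: pd.Series  # index: cell id, values in {train, val, test}
    held_out_perturbations: frozenset = field(default_factory=frozenset)
    seed: int = 0

    def cells(self, role: str) -> pd.Index:
        return self.roles.index[self.roles == role]

    def save_tsv(self, path: str | Path) -> None:
        self.roles.rename("role").rename_axis("cell_id").to_csv(path, sep="\t")


def _partition(idx: np.ndarray, fractions: dict[str, float], rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Shuffle and partition; floor counts for non-train roles, remainder to train."""
    idx = rng.permutation(idx)
    out, start = {}, 0
    for role, frac in fractions.items():
        if role == "train":
            continue
        k = int(np.floor(frac * len(idx)))
        out[role] = idx[start : start + k]
        start += k
    out["train"] = idx[start:]
    return out


def make_split(
    adata: ad.AnnData,
    scheme: str = "in_distribution",
    split_index: int = 0,
    fractions: dict[str, float] | None = None,
    seed: int = 0,
    perturbation_key: str = PERTURBATION_KEY,
    control_token: str = CONTROL_TOKEN,
    n_ood_splits: int = 5,
) -> SplitAssignment:
    """Build a seeded split assignment.

    For the out-of-distribution scheme the perturbation list is permuted
    once by ``seed`` and cut into ``n_ood_splits`` groups; ``split_index``
    selects the held-out group, so across indices 0..4 every perturbation
    is held out exactly once.
    """
    pert = adata.obs[perturbation_key].astype(str)
    perts = sorted(perturbation_counts(adata, perturbation_key, control_token).index)
    roles = pd.Series("train", index=adata.obs_names.astype(str))
    if scheme == "in_distribution":
        fractions = fractions or {"train": 0.7, "val": 0.1, "test": 0.2}
        if abs(sum(fractions.values()) - 1) > 1e-9:
            raise ValueError("fractions must sum to 1")
        held = frozenset()
        for i, p in enumerate([control_token, *perts]):
            rng = np.random.default_rng(child_seed(seed, f"id:{p}"))
            idx = np.nonzero((pert == p).to_numpy())[0]
            for role, cells in _partition(idx, fractions, rng).items():
                roles.iloc[cells] = role
    elif scheme == "out_of_distribution":
        fractions = fractions or {"train": 0.85, "val": 0.15}
        if abs(sum(fractions.values()) - 1) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if len(perts) < n_ood_splits:
            raise ValueError(f"need at least {n_ood_splits} perturbations for the OOD rotation, got {len(perts)}")
        if not 0 <= split_index < n_ood_splits:
            raise ValueError(f"split_index must lie in [0, {n_ood_splits})")
        rng = np.random.default_rng(child_seed(seed, "ood-rotation"))
        order = rng.permutation(np.asarray(perts, dtype=object))
        held = frozenset(np.array_split(order, n_ood_splits)[split_index].tolist())
        for p in [control_token, *perts]:
            idx = np.nonzero((pert == p).to_numpy())[0]
            if p in held:
                roles.iloc[idx] = "test"
                continue
            prng = np.random.default_rng(child_seed(seed, f"ood:{split_index}:{p}"))
            for role, cells in _partition(idx, fractions, prng).items():
                roles.iloc[cells] = role
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return SplitAssignment(
        scheme=scheme, split_index=split_index, roles=roles, held_out_perturbations=held, seed=seed
    )
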