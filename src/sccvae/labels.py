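"""Per-gene perturbation labels from PCA of the transposed control matrix.

The model needs a label for every perturbation — including ones never seen
in training — so labels are built from control cells only: each measured
gene is treated as an observation described by its expression across the
``l`` control cells, and its label is the projection onto the top-``k``
principal axes of that genes-by-cells matrix. Genes that co-express under
natural control-cell heterogeneity receive similar labels, which is the
model's inductive bias that functionally similar genes perturb similarly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from ._utils import child_seed

__all__ = ["PerturbationLabeler", "fit_labels", "label_for_gene"]


class PerturbationLabeler(BaseEstimator, TransformerMixin):
    """Fit per-gene labels on a control expression matrix.

    Parameters
    ----------
    n_components : int, default 64
        Number of principal components retained per gene label.
    max_cells : int, default 10_000
        Control cells are subsampled (seeded) to at most this many before
        the PCA fit, bounding memory at large ``l``.
    random_state : int or None
        Seed for the cell subsample. The PCA itself is deterministic (full
        SVD with a fixed sign convention), so refits with different seeds
        differ only through the subsample.

    Attributes
    ----------
    embedding_ : (m, k) array — one label row per gene.
    gene_ids_ : list of str.
    cell_mean_ : per-cell centering record of the fit.
    """

    def __init__(self, n_components: int = 64, max_cells: int = 10_000, random_state: int | None = None):
        self.n_components = n_components
        self.max_cells = max_cells
        self.random_state = random_state

    def fit(self, X: np.ndarray, gene_ids=None):
        """``X`` is an (l control cells, m genes) expression matrix."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (cells x genes)")
        l, m = X.shape
        if l < 2 or m < 2:
            raise ValueError("need at least 2 control cells and 2 genes")
        if gene_ids is None:
            gene_ids = [f"g{i}" for i in range(m)]
        if len(gene_ids) != m:
            raise ValueError("gene_ids length does not match gene dimension")
        if l > self.max_cells:
            rng = np.random.default_rng(
                None if self.random_state is None else child_seed(self.random_state, "label-subsample")
            )
            X = X[rng.choice(l, self.max_cells, replace=False)]
            l = self.max_cells
        k = self.n_components
        if not 1 <= k <= min(m, l):
            raise ValueError(f"n_components={k} out of range [1, {min(m, l)}]")
        G = X.T  # genes as observations, cells as coordinates
        self.cell_mean_ = G.mean(axis=0)
        Gc = G - self.cell_mean_
        if np.allclose(Gc, 0):
            raise ValueError("degenerate input: all genes have identical control profiles")
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(Gc)
        # fixed sign convention: orient each axis so its largest-|.| loading is positive
        flip = np.sign(pca.components_[np.arange(k), np.abs(pca.components_).argmax(axis=1)])
        flip[flip == 0] = 1.0
        self.components_ = pca.components_ * flip[:, None]
        self.embedding_ = scores * flip[None, :]
        self.explained_variance_ = pca.explained_variance_
        self.gene_ids_ = list(gene_ids)
        self._index = {g: i for i, g in enumerate(self.gene_ids_)}
        return self

    def transform(self, genes) -> np.ndarray:
        """Label vectors for a list of gene identifiers (seen or unseen targets)."""
        return np.vstack([self.label_for_gene(g) for g in genes])

    def label_for_gene(self, gene: str) -> np.ndarray:
        if gene not in self._index:
            near = sorted(self.gene_ids_, key=lambda g: _prefix_distance(g, gene))[:3]
            raise KeyError(f"gene {gene!r} not among the {len(self.gene_ids_)} measured genes; nearest matches: {near}")
        return self.embedding_[self._index[gene]].copy()

    # --- TSV round-trip ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = [f"pc{i + 1}" for i in range(self.embedding_.shape[1])]
        return pd.DataFrame(self.embedding_, index=pd.Index(self.gene_ids_, name="gene_id"), columns=cols)

    def save_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.17g")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PerturbationLabeler":
        obj = cls(n_components=frame.shape[1])
        obj.embedding_ = frame.to_numpy(dtype=float)
        obj.gene_ids_ = [str(g) for g in frame.index]
        obj._index = {g: i for i, g in enumerate(obj.gene_ids_)}
        return obj

    @classmethod
    def load_tsv(cls, path: str | Path) -> "PerturbationLabeler":
        return cls.from_frame(
            pd.read_csv(path, sep="\t", index_col="gene_id", float_precision="round_trip")
        )


def _prefix_distance(a: str, b: str) -> tuple[int, str]:
    common = 0
    for x, y in zip(a.lower(), b.lower()):
        if x != y:
            break
        common += 1
    return (-common, a)


def fit_labels(control_matrix: np.ndarray, k: int, seed: int | None = None, gene_ids=None) -> PerturbationLabeler:
    """Thin functional wrapper over :class:`PerturbationLabeler`."""
    return PerturbationLabeler(n_components=k, random_state=seed).fit(control_matrix, gene_ids=gene_ids)


def label_for_gene(labels: PerturbationLabeler, gene: str) -> np.ndarray:
    return labels.label_for_gene(gene)
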