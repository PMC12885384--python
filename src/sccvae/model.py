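"""The hybrid causal variational autoencoder.

Four components trained jointly on Perturb-seq-style data:

* an *expression encoder* mapping a control cell ``X`` to a diagonal
  Gaussian posterior over exogenous module noises ``Z`` (prior ``N(0, I)``),
* a *shift encoder* mapping a perturbation label (the target gene's
  control-co-expression PCA vector) to a latent shift ``S^p``,
* the linear *SCM layer* ``U^p = (I - A)^{-1} (Z + c^p S^p)`` with ``A``
  masked by a (learned or pre-specified) DAG structure,
* an *expression decoder* mapping ``U^p`` back to gene space.

The objective is an evidence lower bound plus a distribution-matching term:
per-population reconstruction MSE (control cells reconstruct themselves;
perturbed predictions are generated from control cells and paired with a
seeded sample of real perturbed cells), a KL(q(Z|X) || N(0, I)) term over
control cells weighted by ``beta``, and a multi-bandwidth RBF maximum mean
discrepancy between predicted and real perturbed cells weighted by
``gamma``. Per-perturbation penetrance scalars ``c^p`` (init 1.0) are
trained jointly.

All gradients are hand-derived (see ``_nn``) and verified against finite
differences in the test suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._nn import MLP, Adam, GaussianEncoder, Param
from ._utils import child_seed
from .data import CONTROL_TOKEN, PERTURBATION_KEY, dense_X
from .labels import PerturbationLabeler
from .scm import GraphMask, SCMParameters, make_random_dag_mask, solve_scm

__all__ = ["GaussianPosterior", "SCCVAE", "mmd", "kl_diag_gaussian", "median_heuristic_bandwidths"]


@dataclass
class GaussianPosterior:
    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mean).all() and np.isfinite(self.log_variance).all()):
            raise ValueError("non-finite posterior parameters")


def kl_diag_gaussian(mu: np.ndarray, log_var: np.ndarray) -> float:
    """Mean over cells of KL(N(mu, diag(exp(log_var))) || N(0, I))."""
    mu = np.atleast_2d(mu)
    log_var = np.atleast_2d(log_var)
    per_cell = 0.5 * (np.exp(log_var) + mu**2 - 1.0 - log_var).sum(axis=1)
    return float(per_cell.mean())


def _pairwise_sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d = (A**2).sum(1)[:, None] + (B**2).sum(1)[None, :] - 2.0 * A @ B.T
    return np.maximum(d, 0.0)


def median_heuristic_bandwidths(X: np.ndarray, Y: np.ndarray, factors=(0.5, 1.0, 2.0)) -> np.ndarray:
    """Kernel length-scales: median pooled pairwise distance times each factor."""
    P = np.vstack([X, Y])
    D = _pairwise_sq_dists(P, P)
    off = D[~np.eye(len(P), dtype=bool)]
    med = float(np.sqrt(np.median(off))) if off.size else 1.0
    if med <= 0:
        med = 1.0
    return med * np.asarray(factors, dtype=float)


def mmd(X: np.ndarray, Y: np.ndarray, bandwidths=None) -> float:
    """Biased V-statistic estimate of squared MMD with a sum of RBF kernels.

    ``bandwidths`` are kernel length-scales ``h`` with kernel
    ``k(x, y) = exp(-||x - y||^2 / (2 h^2))``; by default the median
    heuristic at factors (0.5, 1, 2). Symmetric in (X, Y) and zero for
    identical samples.
    """
    value, _ = _mmd_with_grad(np.atleast_2d(X), np.atleast_2d(Y), bandwidths, want_grad=False)
    return value


def _mmd_with_grad(X: np.ndarray, Y: np.ndarray, bandwidths=None, want_grad: bool = True):
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("samples must be 2-D with matching gene dimension")
    if len(X) == 0 or len(Y) == 0:
        raise ValueError("samples must be nonempty")
    if bandwidths is None:
        bandwidths = median_heuristic_bandwidths(X, Y)
    n, m = len(X), len(Y)
    Dxx = _pairwise_sq_dists(X, X)
    Dyy = _pairwise_sq_dists(Y, Y)
    Dxy = _pairwise_sq_dists(X, Y)
    total = 0.0
    dX = np.zeros_like(X) if want_grad else None
    for h in np.atleast_1d(bandwidths):
        g = 1.0 / (2.0 * h * h)
        Kxx, Kyy, Kxy = np.exp(-g * Dxx), np.exp(-g * Dyy), np.exp(-g * Dxy)
        total += Kxx.mean() + Kyy.mean() - 2.0 * Kxy.mean()
        if want_grad:
            rxx = Kxx.sum(axis=1)
            rxy = Kxy.sum(axis=1)
            dX += -(4.0 * g / (n * n)) * (rxx[:, None] * X - Kxx @ X)
            dX += (4.0 * g / (n * m)) * (rxy[:, None] * X - Kxy @ Y)
    return float(max(total, 0.0)), dX


class SCCVAE(BaseEstimator):
    """Hybrid causal VAE for perturbation-response prediction.

    Parameters mirror the model description in the module docstring; the
    architecture defaults suit genome-scale inputs, while desk-scale
    benchmarks pass smaller ``n_latent``/``hidden`` values.

    Key fitted attributes
    ---------------------
    encoder_, decoder_, shift_encoder_ : the neural components.
    A_ : masked latent adjacency (Param; ``scm_params_`` wraps it).
    mask_ : the :class:`~sccvae.scm.GraphMask` in force.
    shift_table_ : dict perturbation -> (S: (n,) array, c: float); the
        control token maps to (0, 0.0).
    labeler_ : the fitted :class:`~sccvae.labels.PerturbationLabeler`.
    loss_history_ : per-epoch DataFrame of loss terms and validation loss.
    """

    def __init__(
        self,
        n_latent: int = 512,
        n_label: int = 64,
        hidden: tuple = (1024, 1024),
        shift_hidden: tuple = (256, 256),
        beta: float = 1e-2,
        gamma: float = 1.0,
        mask_kind: str = "learned_upper_triangular",
        graph_mask: GraphMask | None = None,
        random_mask_density: float = 0.1,
        mmd_bandwidth_factors: tuple = (0.5, 1.0, 2.0),
        batch_size: int = 128,
        lr: float = 1e-3,
        penetrance_lr: float | None = None,
        shift_weight_decay: float = 0.0,
        epochs: int = 100,
        linear_skip: bool = True,
        val_batch_cells: int = 256,
        seed: int = 0,
        perturbation_key: str = PERTURBATION_KEY,
        control_token: str = CONTROL_TOKEN,
    ):
        self.n_latent = n_latent
        self.n_label = n_label
        self.hidden = hidden
        self.shift_hidden = shift_hidden
        self.beta = beta
        self.gamma = gamma
        self.mask_kind = mask_kind
        self.graph_mask = graph_mask
        self.random_mask_density = random_mask_density
        self.mmd_bandwidth_factors = mmd_bandwidth_factors
        self.batch_size = batch_size
        self.lr = lr
        self.penetrance_lr = penetrance_lr
        self.shift_weight_decay = shift_weight_decay
        self.epochs = epochs
        self.linear_skip = linear_skip
        self.val_batch_cells = val_batch_cells
        self.seed = seed
        self.perturbation_key = perturbation_key
        self.control_token = control_token

    # ------------------------------------------------------------------ setup
    def _build(self, m: int) -> None:
        if self.beta < 0 or self.gamma < 0 or self.n_latent < 1:
            raise ValueError("beta, gamma must be >= 0 and n_latent >= 1")
        n = self.n_latent
        rng = np.random.default_rng(child_seed(self.seed, "init"))
        if self.mask_kind == "learned_upper_triangular":
            self.mask_ = GraphMask.upper_triangular(n)
        elif self.mask_kind == "none_conditional":
            self.mask_ = GraphMask.none(n)
        elif self.mask_kind == "random_dag":
            self.mask_ = make_random_dag_mask(n, self.random_mask_density, child_seed(self.seed, "random-mask"))
        elif self.mask_kind == "prespecified_dag":
            if self.graph_mask is None:
                raise ValueError("prespecified_dag requires graph_mask")
            if self.graph_mask.n != n:
                raise ValueError("graph_mask size does not match n_latent")
            self.mask_ = self.graph_mask
        else:
            raise ValueError(f"unknown mask_kind {self.mask_kind!r}")
        self.encoder_ = GaussianEncoder(m, list(self.hidden), n, rng, skip=self.linear_skip)
        self.decoder_ = MLP([n, *reversed(self.hidden), m], rng, skip=self.linear_skip, residual_body=self.linear_skip)
        self.shift_encoder_ = MLP(
            [self.n_label, *self.shift_hidden, n], rng, zero_init_last=True, skip=self.linear_skip
        )
        self.A_ = Param(np.zeros((n, n)))  # identity-initialized SCM: (I - A) = I
        self._m = m

    @property
    def scm_params_(self) -> SCMParameters:
        return SCMParameters(A=self.A_.value * self.mask_.mask, mask=self.mask_)

    def _M(self) -> np.ndarray:
        """(I - A)^{-1}; n is small so the explicit inverse is cheap."""
        return np.linalg.inv(np.eye(self.n_latent) - self.A_.value * self.mask_.mask)

    # ------------------------------------------------------------- components
    def encode_expression(self, X: np.ndarray) -> GaussianPosterior:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self._m:
            raise ValueError(f"X has {X.shape[1]} genes, model was built for {self._m}")
        mu, lv, _ = self.encoder_.forward(X)
        return GaussianPosterior(mean=mu, log_variance=lv)

    @staticmethod
    def sample_z(posterior: GaussianPosterior, seed: int | None = None, eps: np.ndarray | None = None) -> np.ndarray:
        if eps is None:
            eps = np.random.default_rng(seed).standard_normal(posterior.mean.shape)
        return posterior.mean + np.exp(posterior.log_variance / 2.0) * eps

    def encode_shift(self, label: np.ndarray) -> np.ndarray:
        label = np.asarray(label, dtype=float).reshape(1, -1)
        if label.shape[1] != self.n_label:
            raise ValueError(f"label has dimension {label.shape[1]}, expected {self.n_label}")
        S, _ = self.shift_encoder_.forward(label)
        return S.ravel()

    def _shift_for(self, perturbation: str | None, label: np.ndarray | None, c: float | None):
        """Resolve (S, c) from a perturbation id, a raw label, or the control token."""
        if perturbation is not None and perturbation == self.control_token:
            return np.zeros(self.n_latent), 0.0
        if label is None:
            if perturbation is None:
                return np.zeros(self.n_latent), 0.0
            if perturbation in self.shift_table_:
                S, c_learned = self.shift_table_[perturbation]
                return S, (c_learned if c is None else float(c))
            label = self.labeler_.label_for_gene(perturbation)
        S = self.encode_shift(label)
        return S, (1.0 if c is None else float(c))

    def forward(
        self,
        X: np.ndarray,
        perturbation: str | None = None,
        label: np.ndarray | None = None,
        c: float | None = None,
        seed: int | None = None,
        eps: np.ndarray | None = None,
        use_posterior_mean: bool = False,
    ):
        """Generate perturbed expression from control cells.

        Returns ``(X_hat, Z, U)``. With the control token (or no label)
        this is a plain VAE reconstruction pass.
        """
        post = self.encode_expression(X)
        Z = post.mean if use_posterior_mean else self.sample_z(post, seed=seed, eps=eps)
        S, c_eff = self._shift_for(perturbation, label, c)
        U = solve_scm(self.scm_params_, Z, S, c_eff)
        X_hat, _ = self.decoder_.forward(U)
        return X_hat, Z, U

    # ------------------------------------------------------------------ loss
    def _loss_terms(self, Xc, pert_batches, rng) -> dict:
        """Loss on given batches without gradients (used for validation).

        ``pert_batches``: list of (label, c, X_target). Reconstruction is
        averaged per population then across populations, control included
        as one population; KL over control cells; MMD over non-control
        populations.
        """
        post = self.encode_expression(Xc)
        eps = rng.standard_normal(post.mean.shape)
        Z = self.sample_z(post, eps=eps)
        params = self.scm_params_
        recons, mmds = [], []
        Xhat0, _ = self.decoder_.forward(solve_scm(params, Z))
        recons.append(float(((Xhat0 - Xc) ** 2).mean()))
        for label, c, Xt in pert_batches:
            S = self.encode_shift(label)
            idx = rng.choice(len(Xc), size=min(len(Xt), len(Xc)), replace=False)
            Xhat, _ = self.decoder_.forward(solve_scm(params, Z[idx], S, c))
            t = Xt if len(Xt) == len(idx) else Xt[rng.choice(len(Xt), len(idx), replace=False)]
            recons.append(float(((Xhat - t) ** 2).mean()))
            mmds.append(mmd(Xhat, Xt, self._bandwidths(Xhat, Xt)))
        kl = kl_diag_gaussian(post.mean, post.log_variance)
        out = {
            "recon": float(np.mean(recons)),
            "kl": kl,
            "mmd": float(np.mean(mmds)) if mmds else 0.0,
        }
        out["total"] = out["recon"] + self.beta * out["kl"] + self.gamma * out["mmd"]
        return out

    def _bandwidths(self, X, Y):
        return median_heuristic_bandwidths(X, Y, self.mmd_bandwidth_factors)

    # -------------------------------------------------------------- training
    def _step(self, Xc, Xp, label, cp: Param | None, opt: Adam, rng) -> dict:
        """One joint gradient step on a control batch and one population.

        ``Xp``/``label``/``cp`` may be None for a control-only step.
        """
        opt.zero_grad()
        B, m = Xc.shape
        n = self.n_latent
        mu, lv, enc_cache = self.encoder_.forward(Xc)
        eps = rng.standard_normal((B, n))
        sigma = np.exp(lv / 2.0)
        z = mu + sigma * eps
        M = self._M()
        # control branch
        U0 = z @ M.T
        Xhat0, dec_cache0 = self.decoder_.forward(U0)
        recon0 = float(((Xhat0 - Xc) ** 2).mean())
        kl = kl_diag_gaussian(mu, lv)
        terms = {"recon": recon0, "kl": kl, "mmd": 0.0}
        dXhat0 = (Xhat0 - Xc) * (2.0 / (B * m))
        n_pop = 1
        dz = np.zeros_like(z)
        dM_acc = np.zeros((n, n))
        if Xp is not None:
            n_pop = 2
            S2d, shift_cache = self.shift_encoder_.forward(label.reshape(1, -1))
            S = S2d.ravel()
            c = float(cp.value)
            bp = z + c * S
            Up = bp @ M.T
            Xhatp, dec_cachep = self.decoder_.forward(Up)
            reconp = float(((Xhatp - Xp) ** 2).mean())
            mmd_val, dmmd = _mmd_with_grad(Xhatp, Xp, self._bandwidths(Xhatp, Xp))
            terms["recon"] = (recon0 + reconp) / 2.0
            terms["mmd"] = mmd_val
            dXhatp = (Xhatp - Xp) * (2.0 / (B * m)) / n_pop + self.gamma * dmmd
            dUp = self.decoder_.backward(dXhatp, dec_cachep)
            dbp = dUp @ M
            dM_acc += dUp.T @ bp
            dz += dbp
            cp.grad += float((dbp * S).sum())
            self.shift_encoder_.backward(c * dbp.sum(axis=0, keepdims=True), shift_cache)
        dU0 = self.decoder_.backward(dXhat0 / n_pop, dec_cache0)
        dz += dU0 @ M
        dM_acc += dU0.T @ z
        # d/dA through M = (I-A)^{-1}: dL/dA = M^T (dL/dM) M^T, masked
        self.A_.grad += (M.T @ dM_acc @ M.T) * self.mask_.mask
        dmu = dz + (self.beta / B) * mu
        dlv = dz * eps * 0.5 * sigma + (self.beta / B) * 0.5 * (np.exp(lv) - 1.0)
        self.encoder_.backward(dmu, dlv, enc_cache)
        opt.step()
        terms["total"] = terms["recon"] + self.beta * terms["kl"] + self.gamma * terms["mmd"]
        if not np.isfinite(terms["total"]):
            raise FloatingPointError(f"training diverged: non-finite loss {terms}")
        return terms

    def fit(self, adata, split=None, labeler: PerturbationLabeler | None = None):
        """Train on an AnnData with per-cell perturbation annotation.

        ``split`` is a :class:`~sccvae.data.SplitAssignment`; cells with
        role ``train`` are trained on and role ``val`` drives model
        selection (best-validation checkpoint). Without a split, a seeded
        90/10 per-population holdout is used.
        """
        from .data import make_split  # local import to avoid cycle at module load

        X = dense_X(adata)
        pert = adata.obs[self.perturbation_key].astype(str).to_numpy()
        self.genes_ = [str(g) for g in adata.var_names]
        self._build(X.shape[1])
        if split is None:
            split = make_split(
                adata,
                "in_distribution",
                fractions={"train": 0.9, "val": 0.1, "test": 0.0},
                seed=child_seed(self.seed, "auto-split"),
                perturbation_key=self.perturbation_key,
                control_token=self.control_token,
            )
        roles = split.roles.reindex(adata.obs_names.astype(str)).to_numpy()
        train_mask = roles == "train"
        val_mask = roles == "val"
        ctrl = pert == self.control_token
        Xc_train = X[train_mask & ctrl]
        Xc_val = X[val_mask & ctrl]
        if len(Xc_train) == 0:
            raise ValueError("no control cells in the training role")
        self.control_X_ = Xc_train
        train_perts = sorted(set(pert[train_mask & ~ctrl]))
        if labeler is None:
            labeler = PerturbationLabeler(
                n_components=self.n_label, random_state=child_seed(self.seed, "labels")
            ).fit(Xc_train, gene_ids=self.genes_)
        self.labeler_ = labeler
        labels = {p: labeler.label_for_gene(p) for p in train_perts}
        Xp_train = {p: X[train_mask & (pert == p)] for p in train_perts}
        Xp_val = {p: X[val_mask & (pert == p)] for p in train_perts}
        self.cp_ = {p: Param(np.array(1.0)) for p in train_perts}
        params = [
            *self.encoder_.params,
            *self.decoder_.params,
            *self.shift_encoder_.params,
            self.A_,
            *self.cp_.values(),
        ]
        opt = Adam(params, lr=self.lr)
        # inductive bias for the shift factorization: guide-specific efficiency
        # belongs in the per-perturbation scalars (fast), while the label ->
        # shift map represents the target gene's direct effect (regularized)
        opt.add_group(list(self.cp_.values()), lr=self.penetrance_lr)
        opt.add_group(self.shift_encoder_.params, weight_decay=self.shift_weight_decay)
        rng = np.random.default_rng(child_seed(self.seed, "train"))
        history = []
        best = (np.inf, None)
        cap = self.val_batch_cells
        for epoch in range(self.epochs):
            order = list(train_perts)
            rng.shuffle(order)
            epoch_terms = []
            if not order:
                for _ in range(max(1, len(Xc_train) // self.batch_size)):
                    Xc = Xc_train[rng.choice(len(Xc_train), min(self.batch_size, len(Xc_train)), replace=False)]
                    epoch_terms.append(self._step(Xc, None, None, None, opt, rng))
            for p in order:
                bs = self.batch_size
                Xc = Xc_train[rng.choice(len(Xc_train), min(bs, len(Xc_train)), replace=False)]
                pool = Xp_train[p]
                Xp = pool[rng.choice(len(pool), len(Xc), replace=len(pool) < len(Xc))]
                epoch_terms.append(self._step(Xc, Xp, labels[p], self.cp_[p], opt, rng))
            val = self._validation_loss(Xc_val if len(Xc_val) else Xc_train[:cap], Xp_val, labels, cap)
            row = {k: float(np.mean([t[k] for t in epoch_terms])) for k in ("total", "recon", "kl", "mmd")}
            row.update(epoch=epoch, val_loss=val)
            history.append(row)
            if val < best[0]:
                best = (val, [p.value.copy() for p in params])
        if best[1] is not None:
            for p, v in zip(params, best[1]):
                p.value[...] = v
        self.best_val_loss_ = best[0]
        self.loss_history_ = pd.DataFrame(history)
        self._fix_penetrance_gauge(train_perts)
        self.shift_table_ = {self.control_token: (np.zeros(self.n_latent), 0.0)}
        for p in train_perts:
            self.shift_table_[p] = (self.encode_shift(labels[p]), float(self.cp_[p].value))
        return self

    def _fix_penetrance_gauge(self, train_perts) -> None:
        """Fix the scale gauge of the (c, S) factorization.

        Only the products c^p S^p are identified by training; the split
        between scalar and vector is a gauge choice. Rescale so the mean
        learned penetrance over training perturbations is 1 — penetrance
        is then expressed relative to the average training guide, which
        makes grid-searched penetrances for unseen perturbations
        comparable across runs. Products (hence all predictions for
        trained perturbations) are unchanged.
        """
        if not train_perts:
            return
        scale = float(np.mean([self.cp_[p].value for p in train_perts]))
        if not np.isfinite(scale) or abs(scale) < 1e-3:
            return
        for p in train_perts:
            self.cp_[p].value /= scale
        out_layers = [self.shift_encoder_.layers[-1]]
        if self.shift_encoder_.skip is not None:
            out_layers.append(self.shift_encoder_.skip)
        for layer in out_layers:
            layer.W.value *= scale
            layer.b.value *= scale

    def _validation_loss(self, Xc_val, Xp_val, labels, cap) -> float:
        rng = np.random.default_rng(child_seed(self.seed, "val"))
        Xc = Xc_val if len(Xc_val) <= cap else Xc_val[rng.choice(len(Xc_val), cap, replace=False)]
        batches = []
        for p, Xv in Xp_val.items():
            if len(Xv) == 0:
                continue
            Xv = Xv if len(Xv) <= cap else Xv[rng.choice(len(Xv), cap, replace=False)]
            batches.append((labels[p], float(self.cp_[p].value), Xv))
        return float(self._loss_terms(Xc, batches, rng)["total"])

    # ------------------------------------------------------------ generation
    def predict(
        self,
        perturbation: str | None = None,
        label: np.ndarray | None = None,
        c: float | None = None,
        n_cells: int = 64,
        seed: int | None = None,
        control_X: np.ndarray | None = None,
    ) -> np.ndarray:
        """Generate ``n_cells`` in-silico expression profiles for a perturbation.

        Control cells are sampled (with replacement if needed) from the
        training control pool unless ``control_X`` is given.
        """
        pool = self.control_X_ if control_X is None else np.atleast_2d(control_X)
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pool), n_cells, replace=len(pool) < n_cells)
        eps = rng.standard_normal((n_cells, self.n_latent))
        X_hat, _, _ = self.forward(pool[idx], perturbation=perturbation, label=label, c=c, eps=eps)
        return X_hat
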