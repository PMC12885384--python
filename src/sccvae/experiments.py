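"""Benchmark study runners on the synthetic screen.

These functions reproduce, at desk scale and with known ground truth, the
study designs the model is meant for: exact-solver and estimator oracles,
penetrance recovery for a held-out strong perturbation, a five-fold
out-of-distribution rotation against the control-distribution baseline,
the graph-mask ablation, the latent-distance / expression-MMD concordance,
and the curation-filter behavior. Both the test suite and the
reproduction script call these with a single seed.

Problem sizes (200 genes, 32 latent modules, 80 training epochs, 300
generated cells per evaluated perturbation) are the package's benchmark
defaults: large enough for the effects to be resolved, small enough to run
on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.integrate
import scipy.stats

from ._utils import child_seed
from .data import CONTROL_TOKEN, PERTURBATION_KEY, SplitAssignment, dense_X, filter_distinguishable, filter_min_cells, make_split
from .labels import PerturbationLabeler
from .latent import distance_concordance, embed_perturbations
from .metrics import energy_distance, mse_metric, pseudo_bulk
from .model import SCCVAE, kl_diag_gaussian, mmd
from .scm import GraphMask, SCMParameters, solve_scm
from .shift import ShiftSearchConfig, select_shift
from .synthetic import default_benchmark, simulate

__all__ = [
    "BENCHMARK_MODEL_KW",
    "scm_solver_oracle",
    "latent_covariance_check",
    "mean_shift_identity_check",
    "kl_closed_form_check",
    "estimator_oracle_check",
    "penetrance_recovery",
    "ood_benchmark",
    "ablation_study",
    "filtering_study",
]

# model configuration for all benchmark trainings (desk-scale counterpart of
# the genome-scale defaults)
BENCHMARK_MODEL_KW = dict(
    n_latent=32,
    n_label=32,
    hidden=(128, 128),
    shift_hidden=(32,),
    shift_weight_decay=1e-3,
    gamma=10.0,  # distribution matching must outweigh the paired-MSE collapse pull
    batch_size=64,
    lr=2e-3,
    epochs=80,
)


# --------------------------------------------------------------- exact oracles
def scm_solver_oracle(seed: int, n_systems: int = 200, max_n: int = 10) -> float:
    """Max abs deviation between the matrix solve and an independent
    topological forward substitution over random triangular SCMs."""
    rng = np.random.default_rng(child_seed(seed, "solver-oracle"))
    worst = 0.0
    for _ in range(n_systems):
        n = int(rng.integers(2, max_n + 1))
        mask = np.triu((rng.random((n, n)) < 0.5).astype(np.int8), 1)
        A = rng.normal(size=(n, n)) * mask
        params = SCMParameters(A=A, mask=GraphMask(n, "learned_upper_triangular", mask))
        Z = rng.normal(size=(5, n))
        S = rng.normal(size=n)
        c = float(rng.normal())
        U = solve_scm(params, Z, S, c)
        # forward substitution: nodes in reverse index order depend only on later ones
        U_ref = np.zeros_like(Z)
        b = Z + c * S
        for i in range(n - 1, -1, -1):
            U_ref[:, i] = b[:, i] + U_ref @ A[i]
        worst = max(worst, float(np.abs(U - U_ref).max()))
    return worst


def latent_covariance_check(seed: int, n_cells: int = 100_000) -> float:
    """Max abs deviation of the empirical latent control covariance from the
    analytic (I - A*)^{-1} (I - A*)^{-T} on the benchmark ground truth."""
    from .scm import latent_control_covariance

    spec = default_benchmark(seed=child_seed(seed, "benchmark"))
    rng = np.random.default_rng(child_seed(seed, "covariance"))
    Z = rng.standard_normal((n_cells, spec.n_true))
    U = solve_scm(spec.scm, Z)
    emp = np.cov(U.T)
    return float(np.abs(emp - latent_control_covariance(spec.scm)).max())


def mean_shift_identity_check(seed: int) -> float:
    """Max abs error of: population-mean latent effect == c* (I - A*)^{-1} S*."""
    spec = default_benchmark(seed=child_seed(seed, "benchmark"))
    rng = np.random.default_rng(child_seed(seed, "mean-shift"))
    worst = 0.0
    for p in spec.perturbations:
        Z = rng.standard_normal((500, spec.n_true))
        diff = (solve_scm(spec.scm, Z, p.shift, p.penetrance) - solve_scm(spec.scm, Z)).mean(axis=0)
        expected = solve_scm(spec.scm, np.zeros((1, spec.n_true)), p.shift, p.penetrance).ravel()
        worst = max(worst, float(np.abs(diff - expected).max()))
    return worst


def kl_closed_form_check(seed: int, n_pairs: int = 20) -> float:
    """Max abs deviation of the closed-form KL from 1-D numerical integration."""
    rng = np.random.default_rng(child_seed(seed, "kl"))
    worst = 0.0
    for _ in range(n_pairs):
        mu = float(rng.normal())
        sigma = float(rng.uniform(0.3, 2.0))
        q = scipy.stats.norm(mu, sigma)
        p = scipy.stats.norm(0.0, 1.0)
        ref, _ = scipy.integrate.quad(lambda x: q.pdf(x) * (q.logpdf(x) - p.logpdf(x)), mu - 12 * sigma, mu + 12 * sigma)
        got = kl_diag_gaussian(np.array([[mu]]), np.array([[2 * np.log(sigma)]]))
        worst = max(worst, abs(got - ref))
    return worst


def estimator_oracle_check(seed: int, n_points: int = 500) -> dict:
    """MMD and energy-distance estimators against naive double-loop sums,
    plus their identical-sample and two-point closed forms."""
    rng = np.random.default_rng(child_seed(seed, "estimators"))
    X = rng.normal(size=(n_points, 3))
    Y = rng.normal(size=(n_points, 3)) + 0.5

    def naive_mean_k(A, B, h=1.0):
        s = 0.0
        for a in A:
            for b in B:
                s += np.exp(-((a - b) ** 2).sum() / (2 * h * h))
        return s / (len(A) * len(B))

    mmd_ref = naive_mean_k(X, X) + naive_mean_k(Y, Y) - 2 * naive_mean_k(X, Y)
    mmd_err = abs(mmd(X, Y, bandwidths=[1.0]) - mmd_ref)

    def naive_mean_d(A, B):
        s = 0.0
        for a in A:
            for b in B:
                s += np.sqrt(((a - b) ** 2).sum())
        return s / (len(A) * len(B))

    ed_ref = 2 * naive_mean_d(X, Y) - naive_mean_d(X, X) - naive_mean_d(Y, Y)
    ed_err = abs(energy_distance(X, Y) - ed_ref)
    ident = max(mmd(X, X, bandwidths=[1.0]), energy_distance(X, X))
    two_point = abs(energy_distance(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])) - 10.0)
    return {"mmd_max_abs_diff": float(mmd_err), "energy_max_abs_diff": float(ed_err),
            "identical_sample_value": float(ident), "two_point_closed_form_error": float(two_point)}


# ------------------------------------------------------------ training studies
def _holdout_split(adata, q: str, seed: int) -> SplitAssignment:
    """Hold one perturbation out entirely; 85/15 train/val elsewhere."""
    pert = adata.obs[PERTURBATION_KEY].astype(str).to_numpy()
    roles = pd.Series("train", index=adata.obs_names.astype(str))
    rng = np.random.default_rng(child_seed(seed, "holdout"))
    for p in sorted(set(pert)):
        idx = np.nonzero(pert == p)[0]
        if p == q:
            roles.iloc[idx] = "test"
            continue
        val = rng.choice(idx, int(0.15 * len(idx)), replace=False)
        roles.iloc[val] = "val"
    return SplitAssignment("out_of_distribution", 0, roles, frozenset({q}), seed)


def penetrance_recovery(seed: int, epochs: int | None = None) -> dict:
    """Hold out a strong (c* = 2) perturbation, train on the remaining 19,
    and grid-search its penetrance against its observed pseudo-bulk over
    [-1, 3] in steps of 0.1."""
    spec = default_benchmark(seed=child_seed(seed, "benchmark"))
    adata, truth = simulate(spec)
    X = dense_X(adata)
    pert = adata.obs[PERTURBATION_KEY].astype(str).to_numpy()
    strong = [p.target_gene for p in spec.perturbations if p.penetrance == 2.0]
    if not strong:  # vanishingly rare under the default draw
        strong = [max(spec.perturbations, key=lambda p: p.penetrance).target_gene]
    q = strong[0]
    c_true = next(p.penetrance for p in spec.perturbations if p.target_gene == q)
    split = _holdout_split(adata, q, seed)
    kw = dict(BENCHMARK_MODEL_KW)
    if epochs is not None:
        kw["epochs"] = epochs
    model = SCCVAE(seed=child_seed(seed, "model"), **kw).fit(adata, split=split)
    target = pseudo_bulk(X[pert == q])
    cfg = ShiftSearchConfig(seed=child_seed(seed, "search"))
    c_hat, curve = select_shift(model, model.labeler_.label_for_gene(q), model.control_X_, target, cfg)
    i = int(np.nanargmin(curve.mse.to_numpy()))
    lo, hi = max(i - 1, 0), min(i + 1, len(curve) - 1)
    local_min = bool(curve.mse.iloc[lo] >= curve.mse.iloc[i] and curve.mse.iloc[hi] >= curve.mse.iloc[i])
    return {
        "held_out": q,
        "c_true": float(c_true),
        "c_selected": float(c_hat),
        "abs_error": float(abs(c_hat - c_true)),
        "is_local_minimum": local_min,
        "curve": curve,
    }


def _predict_heldout(model, q, X, pert, n_cells, seed):
    cfg = ShiftSearchConfig(seed=child_seed(seed, f"search:{q}"))
    target = pseudo_bulk(X[pert == q])
    c_hat, _ = select_shift(model, model.labeler_.label_for_gene(q), model.control_X_, target, cfg)
    pred = model.predict(
        label=model.labeler_.label_for_gene(q), c=c_hat, n_cells=n_cells, seed=child_seed(seed, f"predict:{q}")
    )
    return c_hat, pred


def ood_benchmark(seed: int, n_splits: int = 5, n_cells: int = 300, epochs: int | None = None) -> dict:
    """Five-fold out-of-distribution rotation: for every held-out
    perturbation, compare the model's generated cells against the
    control-distribution baseline on pseudo-bulk MSE and MMD, and collect
    the latent-distance / expression-MMD concordance per split."""
    spec = default_benchmark(seed=child_seed(seed, "benchmark"))
    adata, truth = simulate(spec)
    X = dense_X(adata)
    pert = adata.obs[PERTURBATION_KEY].astype(str).to_numpy()
    kw = dict(BENCHMARK_MODEL_KW)
    if epochs is not None:
        kw["epochs"] = epochs
    rows, concord = [], []
    for split_index in range(n_splits):
        split = make_split(adata, "out_of_distribution", split_index, seed=child_seed(seed, "rotation"))
        model = SCCVAE(seed=child_seed(seed, f"model:{split_index}"), **kw).fit(adata, split=split)
        roles = split.roles.reindex(adata.obs_names.astype(str)).to_numpy()
        ctrl_pool = X[(pert == CONTROL_TOKEN) & (roles == "val")]
        rng = np.random.default_rng(child_seed(seed, f"baseline:{split_index}"))
        selected = {}
        for q in sorted(split.held_out_perturbations):
            truth_cells = X[pert == q]
            c_hat, pred = _predict_heldout(model, q, X, pert, n_cells, child_seed(seed, str(split_index)))
            baseline = ctrl_pool[rng.choice(len(ctrl_pool), min(n_cells, len(ctrl_pool)), replace=False)]
            # one fixed kernel scale per perturbation so model and baseline
            # MMDs are comparable
            from .model import median_heuristic_bandwidths

            bw = median_heuristic_bandwidths(truth_cells, baseline)
            rows.append(
                {
                    "split": split_index,
                    "perturbation": q,
                    "selected_c": c_hat,
                    "model_mse": mse_metric(pred, truth_cells),
                    "baseline_mse": mse_metric(baseline, truth_cells),
                    "model_mmd": mmd(pred, truth_cells[: len(pred)], bw),
                    "baseline_mmd": mmd(baseline, truth_cells[: len(baseline)], bw),
                }
            )
            selected[q] = c_hat
        # latent-distance vs expression-MMD concordance over all perturbations
        perts = sorted(set(pert) - {CONTROL_TOKEN})
        emb = embed_perturbations(model, perts, c_overrides=selected, seed=child_seed(seed, "embed"))
        cells = {p: X[pert == p] for p in perts}
        _, r = distance_concordance(emb, cells, X[pert == CONTROL_TOKEN], CONTROL_TOKEN, seed=child_seed(seed, "concord"))
        concord.append(r)
    table = pd.DataFrame(rows)
    return {
        "table": table,
        "frac_mse_better": float((table.model_mse < table.baseline_mse).mean()),
        "frac_mmd_better": float((table.model_mmd < table.baseline_mmd).mean()),
        "concordance_r": [float(r) for r in concord],
        "mean_concordance_r": float(np.nanmean(concord)),
    }


def ablation_study(seed: int, model_seeds=(0, 1, 2), split_index: int = 0, n_cells: int = 300, epochs: int | None = None) -> pd.DataFrame:
    """Graph-mask ablation on one OOD split: learned upper-triangular mask
    vs the mask-free conditional decoder vs a random pre-specified DAG,
    each trained at several seeds; reports mean held-out MMD per run."""
    spec = default_benchmark(seed=child_seed(seed, "benchmark"))
    adata, truth = simulate(spec)
    X = dense_X(adata)
    pert = adata.obs[PERTURBATION_KEY].astype(str).to_numpy()
    split = make_split(adata, "out_of_distribution", split_index, seed=child_seed(seed, "rotation"))
    kw = dict(BENCHMARK_MODEL_KW)
    if epochs is not None:
        kw["epochs"] = epochs
    # fixed per-perturbation kernel scales so MMDs are comparable across variants
    from .model import median_heuristic_bandwidths

    ctrl = X[pert == CONTROL_TOKEN][:500]
    bw = {q: median_heuristic_bandwidths(X[pert == q], ctrl) for q in split.held_out_perturbations}
    rows = []
    for variant in ["learned_upper_triangular", "none_conditional", "random_dag"]:
        for ms in model_seeds:
            model = SCCVAE(mask_kind=variant, seed=child_seed(seed, f"{variant}:{ms}") + ms, **kw).fit(adata, split=split)
            mmds = []
            for q in sorted(split.held_out_perturbations):
                _, pred = _predict_heldout(model, q, X, pert, n_cells, child_seed(seed, f"{variant}:{ms}:{q}"))
                mmds.append(mmd(pred, X[pert == q][: len(pred)], bw[q]))
            rows.append({"variant": variant, "model_seed": ms, "mean_mmd": float(np.mean(mmds))})
    return pd.DataFrame(rows)


def filtering_study(seed: int, repeats: int = 20) -> dict:
    """Curation-filter behavior: a 199-cell perturbation must be removed by
    the min-cell filter; a null (c* = 0) perturbation must fail the
    distinguishability gate at threshold 0.6 while strong perturbations
    pass, across seeded repeats."""
    passed = 0
    min_cell_ok = 0
    for rep in range(repeats):
        spec = default_benchmark(
            seed=child_seed(seed, f"filter:{rep}"),
            m=120,
            n_groups=2,
            perts_per_group=3,
            cells_per_perturbation=250,
            n_control_cells=1000,
        )
        spec.perturbations[0].n_cells = 199  # below the 200-cell gate
        spec.perturbations[1].penetrance = 0.0  # null perturbation
        adata, _ = simulate(spec)
        small = spec.perturbations[0].target_gene
        null = spec.perturbations[1].target_gene
        strong = [p.target_gene for p in spec.perturbations[2:]]
        filtered = filter_min_cells(adata, 200)
        remaining = set(filtered.obs[PERTURBATION_KEY].astype(str)) - {CONTROL_TOKEN}
        if remaining == {null, *strong}:
            min_cell_ok += 1
        final, scores = filter_distinguishable(filtered, 0.6, seed=child_seed(seed, f"cv:{rep}"))
        kept = set(final.obs[PERTURBATION_KEY].astype(str)) - {CONTROL_TOKEN}
        if kept == set(strong):
            passed += 1
    return {"repeats": repeats, "min_cell_filter_exact": min_cell_ok, "distinguishability_passed": passed}
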