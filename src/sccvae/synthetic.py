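"""Synthetic Perturb-seq generator with known latent ground truth.

Emulates the structure of an essential-gene CRISPRi screen: one control
population plus many single-gene perturbation populations, all generated
from a shared ground-truth linear latent SCM. Each cell draws exogenous
noise ``Z ~ N(0, I)``, propagates it (plus a perturbation-specific shift
``c* S*``) through the true DAG, and is observed through a fixed linear
gene-loading map with Gaussian measurement noise. Every gene belongs to
one latent module (plus small dense crosstalk), so control co-expression
carries genuine module structure for the PCA perturbation labels.

The generator returns the complete ground truth (adjacency, loadings,
shifts, penetrances, latent values) so that every downstream stage —
filtering, labels, training, shift selection, evaluation — can be tested
for recovery against known parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import yaml

from ._utils import child_seed
from .data import CONTROL_TOKEN, PERTURBATION_KEY
from .scm import GraphMask, SCMParameters, make_random_dag_mask, solve_scm, validate_dag

__all__ = ["PerturbationSpec", "SyntheticSpec", "GroundTruth", "simulate", "default_benchmark"]


@dataclass
class PerturbationSpec:
    target_gene: str
    shift: np.ndarray  # S*: sparse direct effect on <= 3 latent modules
    penetrance: float  # c*
    n_cells: int
    group: int = 0


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic screen; all randomness is seeded."""

    n_true: int
    m: int
    A_true: np.ndarray
    mask_true: GraphMask
    module_map: np.ndarray  # gene -> latent module index
    loadings: np.ndarray  # (m, n_true) observation map
    observation_noise_sd: float
    perturbations: list[PerturbationSpec]
    n_control_cells: int
    seed: int
    nonlinearity: str | None = None  # None (linear) or "tanh"
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not validate_dag(self.mask_true.mask):
            raise ValueError("ground-truth graph must be acyclic")
        if not self.gene_ids:
            self.gene_ids = [f"G{i:04d}" for i in range(self.m)]
        gene_set = set(self.gene_ids)
        for p in self.perturbations:
            if p.target_gene not in gene_set:
                raise ValueError(f"perturbation target {p.target_gene} is not a measured gene")
            if int((np.asarray(p.shift) != 0).sum()) > 3:
                raise ValueError("true shifts must be sparse (<= 3 latent modules)")

    @property
    def scm(self) -> SCMParameters:
        return SCMParameters(A=self.A_true, mask=self.mask_true)


@dataclass
class GroundTruth:
    """Everything the generator knows and the model must recover."""

    spec: SyntheticSpec
    latent_U: dict[str, np.ndarray]  # population -> (cells, n_true) endogenous values
    latent_mean_effects: dict[str, np.ndarray]  # population -> c* (I-A*)^{-1} S*

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.spec.mask_true.save(outdir / "graph")
        np.savetxt(outdir / "A_true.tsv", self.spec.A_true, delimiter="\t")
        np.savetxt(outdir / "loadings.tsv", self.spec.loadings, delimiter="\t")
        rows = [
            {
                "perturbation": p.target_gene,
                "penetrance": p.penetrance,
                "group": p.group,
                **{f"S{i}": s for i, s in enumerate(p.shift)},
            }
            for p in self.spec.perturbations
        ]
        pd.DataFrame(rows).to_csv(outdir / "shifts.tsv", sep="\t", index=False)
        meta = {
            "n_true": self.spec.n_true,
            "m": self.spec.m,
            "observation_noise_sd": self.spec.observation_noise_sd,
            "n_control_cells": self.spec.n_control_cells,
            "seed": self.spec.seed,
            "nonlinearity": self.spec.nonlinearity,
        }
        (outdir / "spec.yaml").write_text(yaml.safe_dump(meta))


def simulate(spec: SyntheticSpec) -> tuple[ad.AnnData, GroundTruth]:
    """Generate the dataset and its ground-truth record; deterministic given the recipe's seed."""
    rng = np.random.default_rng(child_seed(spec.seed, "simulate"))
    params = spec.scm
    populations = [(CONTROL_TOKEN, None, 0.0, spec.n_control_cells)] + [
        (p.target_gene, p.shift, p.penetrance, p.n_cells) for p in spec.perturbations
    ]
    X_parts, pert_col, latent_U, effects = [], [], {}, {}
    for name, S, c, n_cells in populations:
        Z = rng.standard_normal((n_cells, spec.n_true))
        U = solve_scm(params, Z, S, c)
        H = U @ spec.loadings.T
        if spec.nonlinearity == "tanh":
            H = np.tanh(H)
        if spec.observation_noise_sd > 0:
            H = H + spec.observation_noise_sd * rng.standard_normal(H.shape)
        X_parts.append(H)
        pert_col.extend([name] * n_cells)
        latent_U[name] = U
        base = np.zeros(spec.n_true) if S is None else np.asarray(S, dtype=float)
        effects[name] = solve_scm(params, np.zeros((1, spec.n_true)), base, c).ravel()
    X = np.vstack(X_parts)
    obs = pd.DataFrame(
        {PERTURBATION_KEY: pd.Categorical(pert_col)},
        index=pd.Index([f"cell{i:06d}" for i in range(len(X))], name="cell_id"),
    )
    adata = ad.AnnData(X=X.astype(np.float32), obs=obs, var=pd.DataFrame(index=pd.Index(spec.gene_ids, name="gene_id")))
    adata.uns["synthetic_seed"] = spec.seed
    return adata, GroundTruth(spec=spec, latent_U=latent_U, latent_mean_effects=effects)


def default_benchmark(
    seed: int = 0,
    n_true: int = 16,
    m: int = 200,
    n_groups: int = 4,
    perts_per_group: int = 5,
    cells_per_perturbation: int = 300,
    n_control_cells: int = 2000,
    observation_noise_sd: float = 0.3,
    shift_norm: float = 2.0,
    penetrance_choices: tuple = (0.5, 1.0, 2.0),
    penetrance_weights: tuple = (0.2, 0.6, 0.2),
) -> SyntheticSpec:
    """The repository's canonical desk-scale benchmark.

    16 true latent modules observed through 200 genes; 20 perturbations in
    4 functional groups of 5 that share a sparse shift support (so
    same-group perturbations have similar latent effects, like perturbation
    modules of co-functional genes), 300 cells per perturbation and 2000
    control cells. True penetrances are drawn from {0.5, 1, 2} with a
    dominant mode at 1: guides in a screen mostly act at a common
    efficiency, with occasional weak and strong outliers, which is what
    makes the strong outliers' penetrance recoverable by grid search.
    """
    rng = np.random.default_rng(child_seed(seed, "benchmark-spec"))
    mask = make_random_dag_mask(n_true, edge_density=0.2, seed=child_seed(seed, "benchmark-graph"))
    weights = rng.uniform(0.3, 0.8, size=(n_true, n_true)) * rng.choice([-1.0, 1.0], size=(n_true, n_true))
    A_true = weights * mask.mask
    module_map = rng.integers(0, n_true, size=m)
    loadings = 0.05 * rng.standard_normal((m, n_true))  # dense crosstalk
    main = rng.uniform(0.5, 1.5, size=m) * rng.choice([-1.0, 1.0], size=m)
    loadings[np.arange(m), module_map] += main
    if 3 * n_groups > n_true:
        raise ValueError("need 3 disjoint latent modules per functional group")
    module_order = rng.permutation(n_true)
    # the DAG's topological order, so pathway edges added below stay acyclic
    topo = np.empty(n_true, dtype=int)
    topo[np.random.default_rng(child_seed(seed, "benchmark-graph")).permutation(n_true)] = np.arange(n_true)
    perts = []
    for g in range(n_groups):
        # disjoint supports: each functional group perturbs its own pathway;
        # pathway modules are chained with strong positive edges so that
        # co-functional genes co-express in control cells (the co-expression
        # prior the perturbation labels rely on)
        support = module_order[3 * g : 3 * g + 3]
        chain = support[np.argsort(topo[support])]
        for parent, child in zip(chain[:-1], chain[1:]):
            A_true[child, parent] = rng.uniform(0.6, 0.9)
            mask.mask[child, parent] = 1
        base = np.zeros(n_true)
        base[support] = rng.uniform(0.8, 1.2, size=3) * rng.choice([-1.0, 1.0], size=3)
        base *= shift_norm / np.linalg.norm(base)
        # targets: co-expressed genes of one designated module of the
        # pathway (a complex whose members share a function, hence similar
        # control co-expression profiles and similar perturbational
        # effects), with positive loading so the profile is sign-coherent
        # with the group's shift direction
        per_module = [(int(((module_map == s) & (main > 0)).sum()), s) for s in support]
        designated = max(per_module)[1]
        candidates = list(np.nonzero((module_map == designated) & (main > 0))[0])
        if len(candidates) < perts_per_group:
            candidates += list(np.nonzero(np.isin(module_map, support) & (module_map != designated) & (main > 0))[0])
        if len(candidates) < perts_per_group:
            # guarantee the pathway has enough positively-loading member
            # genes by flipping the sign of some of its genes' loadings
            flippable = [g for g in np.nonzero(np.isin(module_map, support) & (main < 0))[0] if g not in candidates]
            for g in flippable[: perts_per_group - len(candidates)]:
                loadings[g, module_map[g]] -= 2 * main[g]
                main[g] = -main[g]
                candidates.append(g)
        if len(candidates) < perts_per_group:
            raise ValueError("too few genes per latent module; increase m or reduce perts_per_group")
        targets = rng.choice(np.asarray(candidates), size=perts_per_group, replace=False)
        for t in targets:
            shift = base.copy()
            jitter = 0.1 * rng.standard_normal(3)
            shift[support] += jitter
            perts.append(
                PerturbationSpec(
                    target_gene=f"G{t:04d}",
                    shift=shift,
                    penetrance=float(rng.choice(penetrance_choices, p=penetrance_weights)),
                    n_cells=cells_per_perturbation,
                    group=g,
                )
            )
    return SyntheticSpec(
        n_true=n_true,
        m=m,
        A_true=A_true,
        mask_true=mask,
        module_map=module_map,
        loadings=loadings,
        observation_noise_sd=observation_noise_sd,
        perturbations=perts,
        n_control_cells=n_control_cells,
        seed=seed,
    )
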