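"""Linear structural causal model over latent gene modules.

The latent space of the model is a set of ``n`` gene-module activities
``U`` driven by exogenous noises ``Z ~ N(0, I)`` through a linear SCM

    U_i = sum_{j in pa(i)} A_ij U_j + Z_i + c * S_i,

where ``A`` is a weighted adjacency masked by a directed acyclic graph,
``S`` is a perturbation-specific shift vector and ``c`` a scalar
penetrance. In matrix form ``U = (I - A)^{-1} (Z + c S)``.

This module holds the graph masks (learned upper-triangular, pre-specified
DAG, random DAG, and the mask-free "conditional" ablation), the exact solve
of the shifted system, and the analytic control covariance used as an
oracle elsewhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from ._utils import check_square_binary

__all__ = [
    "GraphMask",
    "SCMParameters",
    "SingularSCMError",
    "make_random_dag_mask",
    "validate_dag",
    "solve_scm",
    "latent_control_covariance",
]

MASK_KINDS = (
    "learned_upper_triangular",
    "prespecified_dag",
    "random_dag",
    "none_conditional",
)


class SingularSCMError(np.linalg.LinAlgError):
    """Raised when (I - A) is not invertible for a user-supplied mask."""


def validate_dag(mask: np.ndarray) -> bool:
    """True iff the directed graph encoded by ``mask`` is acyclic.

    ``mask[i, j] = 1`` encodes the edge ``j -> i`` (module j regulates
    module i). Self-loops count as cycles. Implemented with Kahn's
    topological sort.
    """
    mask = check_square_binary(mask)
    n = mask.shape[0]
    # in-degree of node i = number of parents = row sum
    indeg = mask.sum(axis=1).astype(int)
    children = [np.nonzero(mask[:, j])[0] for j in range(n)]
    stack = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    while stack:
        j = stack.pop()
        seen += 1
        for i in children[j]:
            indeg[i] -= 1
            if indeg[i] == 0:
                stack.append(i)
    return seen == n


@dataclass
class GraphMask:
    """Binary structure mask for the adjacency ``A``.

    ``mask[i, j] = 1`` iff ``A_ij`` is allowed to be nonzero, i.e. module
    ``j`` may directly regulate module ``i``.
    """

    n: int
    kind: str
    mask: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("module count n must be >= 1")
        if self.kind not in MASK_KINDS:
            raise ValueError(f"unknown mask kind {self.kind!r}; one of {MASK_KINDS}")
        self.mask = check_square_binary(self.mask)
        if self.mask.shape != (self.n, self.n):
            raise ValueError("mask shape does not match n")
        if self.kind == "learned_upper_triangular":
            upper = np.triu(self.mask, 1)
            lower = np.tril(self.mask, -1)
            if not (np.array_equal(self.mask, upper) or np.array_equal(self.mask, lower)):
                raise ValueError("learned_upper_triangular mask must be strictly triangular")
        elif self.kind == "none_conditional":
            if self.mask.any():
                raise ValueError("none_conditional mask must be all-zero")
        else:  # prespecified_dag / random_dag
            if not validate_dag(self.mask):
                raise ValueError(f"{self.kind} mask must encode an acyclic graph")

    @classmethod
    def upper_triangular(cls, n: int) -> "GraphMask":
        """Dense strictly upper-triangular mask (the learned-graph default)."""
        return cls(n=n, kind="learned_upper_triangular", mask=np.triu(np.ones((n, n), dtype=np.int8), 1))

    @classmethod
    def none(cls, n: int) -> "GraphMask":
        """All-zero mask: no SCM mixing, decoder sees ``Z + c S`` directly."""
        return cls(n=n, kind="none_conditional", mask=np.zeros((n, n), dtype=np.int8))

    def n_edges(self) -> int:
        return int(self.mask.sum())

    # --- edge-list serialization: TSV of allowed edges + JSON header -------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        rows, cols = np.nonzero(self.mask)
        with open(prefix.with_suffix(".edges.tsv"), "w") as fh:
            fh.write("source\ttarget\n")
            for i, j in zip(rows, cols):
                fh.write(f"{j}\t{i}\n")  # edge j -> i
        header = {"n": int(self.n), "kind": self.kind, "seed": self.seed}
        prefix.with_suffix(".json").write_text(json.dumps(header))

    @classmethod
    def load(cls, prefix: str | Path) -> "GraphMask":
        prefix = Path(prefix)
        header = json.loads(prefix.with_suffix(".json").read_text())
        mask = np.zeros((header["n"], header["n"]), dtype=np.int8)
        with open(prefix.with_suffix(".edges.tsv")) as fh:
            next(fh)
            for line in fh:
                j, i = map(int, line.split())
                mask[i, j] = 1
        return cls(n=header["n"], kind=header["kind"], mask=mask, seed=header["seed"])


def make_random_dag_mask(n: int, edge_density: float, seed: int) -> GraphMask:
    """Random DAG mask: under a seeded node permutation, each of the
    C(n, 2) orientable pairs carries an edge independently with probability
    ``edge_density``."""
    if n < 1:
        raise ValueError("module count n must be >= 1")
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)  # order[k] = node at topological position k
    upper = np.triu(rng.random((n, n)) < edge_density, 1)
    mask = np.zeros((n, n), dtype=np.int8)
    # position a < b: node order[b] may depend on node order[a]
    pos_a, pos_b = np.nonzero(upper)
    mask[order[pos_b], order[pos_a]] = 1
    return GraphMask(n=n, kind="random_dag", mask=mask, seed=seed)


@dataclass
class SCMParameters:
    """Weighted adjacency under a structure mask; exogenous noise sd fixed at 1."""

    A: np.ndarray
    mask: GraphMask
    exogenous_sd: float = field(default=1.0, init=False)  # sigma_i = 1 by convention

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (self.mask.n, self.mask.n):
            raise ValueError("A shape does not match mask")
        if np.abs(self.A * (1 - self.mask.mask)).max(initial=0.0) > 0:
            raise ValueError("A has weight on a masked-out edge")

    @property
    def n(self) -> int:
        return self.mask.n

    def i_minus_a(self) -> np.ndarray:
        return np.eye(self.n) - self.A


def _solve_against(params: SCMParameters, B: np.ndarray) -> np.ndarray:
    """Solve (I - A) X^T = B^T row-wise, i.e. return B @ (I - A)^{-T}.

    Uses a triangular solve when the mask is strictly triangular (det = 1,
    always solvable); otherwise a general LU solve with a singularity check.
    """
    IA = params.i_minus_a()
    M = params.mask.mask
    if not np.tril(M, -1).any():
        return scipy.linalg.solve_triangular(IA, B.T, lower=False).T
    if not np.triu(M, 1).any():
        return scipy.linalg.solve_triangular(IA, B.T, lower=True).T
    try:
        return np.linalg.solve(IA, B.T).T
    except np.linalg.LinAlgError as err:
        raise SingularSCMError("(I - A) is singular for the supplied mask") from err


def solve_scm(
    params: SCMParameters,
    Z: np.ndarray,
    S: np.ndarray | None = None,
    c: float = 0.0,
) -> np.ndarray:
    """Exact solve of the shifted linear SCM.

    Parameters
    ----------
    Z : (batch, n) exogenous values.
    S : (n,) shift vector, or None for the control system.
    c : scalar penetrance multiplying the shift.

    Returns
    -------
    (batch, n) endogenous values ``U`` with ``U = A U + Z + c S`` exactly;
    ``S=None`` or ``c=0`` gives the control solution ``(I - A)^{-1} Z``.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != params.n:
        raise ValueError(f"Z has {Z.shape[1]} columns, expected {params.n}")
    b = Z if S is None or c == 0.0 else Z + c * np.asarray(S, dtype=float)
    return _solve_against(params, b)


def latent_control_covariance(params: SCMParameters) -> np.ndarray:
    """Exact covariance (I-A)^{-1} (I-A)^{-T} of U under the control SCM."""
    M = _solve_against(params, np.eye(params.n))  # = (I-A)^{-T}
    return M.T @ M
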