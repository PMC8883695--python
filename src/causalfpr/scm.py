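"""Linear Gaussian Markovian structural causal models.

Each observable node is assigned a linear function of its graph parents plus
an independent Gaussian error term:

    V_j = sum_{i in pa(j)} b_ij V_i + U_j,   U_j ~ N(0, sd_j^2), independent.

Two motifs are built in:

* confounder -- C = U_C, X = beta*C + U_X, Y = alpha*X + gamma*C + U_Y.
  C is a common cause of treatment X and outcome Y, opening the backdoor
  path X <- C -> Y; the total effect of X on Y is alpha.
* collider -- C = alpha*X + beta*W + U_C, Y = gamma*C + U_Y.  Treatment X
  and a second cause W collide in C, which transmits the effect to Y; the
  total effect of X on Y is alpha*gamma, entirely indirect.

The implied covariance of the observable vector is available in closed form
(Wright's path-tracing / the reduced-form identity) and serves as the
analytic oracle for the sampler.  True average, direct and indirect effects
are computed by path tracing: ACE is the sum over directed paths of the
product of edge coefficients, DE the coefficient on the direct edge (0 when
absent), IE = ACE - DE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import Dag, Edge, Node, NodeNotFoundError, directed_paths

__all__ = [
    "LinearSCM",
    "SampleMatrix",
    "EffectTriple",
    "confounder_model",
    "collider_model",
    "simulate",
    "implied_covariance",
    "true_effects",
    "zscore",
]


@dataclass(frozen=True)
class SampleMatrix:
    """An n x p sample with one column per observable node (dag order)."""

    values: np.ndarray
    columns: tuple[Node, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[1] != len(self.columns):
            raise ValueError("values must be n x p with p == len(columns)")
        if v.shape[0] < 1:
            raise ValueError("at least one row required")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite sample values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: Node) -> np.ndarray:
        try:
            return self.values[:, self.columns.index(name)]
        except ValueError as exc:
            raise NodeNotFoundError(f"unknown column {name!r}") from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class EffectTriple:
    """Average, direct and indirect causal effect; ACE = DE + IE."""

    ace: float
    de: float
    ie: float

    def __post_init__(self) -> None:
        if all(map(math.isfinite, (self.ace, self.de, self.ie))):
            if abs(self.ace - (self.de + self.ie)) > 1e-12:
                raise ValueError("effect decomposition violated: ACE != DE + IE")


@dataclass(frozen=True)
class LinearSCM:
    """A Dag with per-edge structural coefficients and per-node error SDs."""

    dag: Dag
    coeff: dict[Edge, float]
    error_sd: dict[Node, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sds = dict(self.error_sd) or {n: 1.0 for n in self.dag.nodes}
        for n in self.dag.nodes:
            sds.setdefault(n, 1.0)
        object.__setattr__(self, "error_sd", sds)
        object.__setattr__(self, "coeff", dict(self.coeff))
        if set(self.coeff) != set(self.dag.edges):
            raise ValueError("coeff keys must equal dag.edges exactly")
        if set(sds) != set(self.dag.nodes):
            raise ValueError("error_sd keys must equal dag.nodes")
        if any(sd <= 0 for sd in sds.values()):
            raise ValueError("error SDs must be strictly positive")

    @property
    def nodes(self) -> tuple[Node, ...]:
        return self.dag.nodes


CONFOUNDER_DAG = Dag(("C", "X", "Y"), (("C", "X"), ("X", "Y"), ("C", "Y")))
COLLIDER_DAG = Dag(("W", "X", "C", "Y"), (("X", "C"), ("W", "C"), ("C", "Y")))


def confounder_model(alpha: float, beta: float, gamma: float) -> LinearSCM:
    """Confounder motif: C -> X (beta), X -> Y (alpha), C -> Y (gamma)."""
    return LinearSCM(
        CONFOUNDER_DAG,
        {("C", "X"): beta, ("X", "Y"): alpha, ("C", "Y"): gamma},
    )


def collider_model(alpha: float, beta: float, gamma: float) -> LinearSCM:
    """Collider motif: X -> C (alpha), W -> C (beta), C -> Y (gamma)."""
    return LinearSCM(
        COLLIDER_DAG,
        {("X", "C"): alpha, ("W", "C"): beta, ("C", "Y"): gamma},
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate(m: LinearSCM, n: int, seed=None) -> SampleMatrix:
    """Draw ``n`` joint samples by topological-order evaluation.

    ``seed`` may be an int, a ``numpy.random.Generator``, or None.  Calls
    with the same integer seed return identical samples.
    """
    if n < 1:
        raise ValueError("sample count must be >= 1")
    rng = _as_rng(seed)
    cols = {n_: None for n_ in m.nodes}
    for node in m.dag.topological_order():
        val = m.error_sd[node] * rng.standard_normal(n)
        for parent in m.dag.parents(node):
            val = val + m.coeff[(parent, node)] * cols[parent]
        cols[node] = val
    return SampleMatrix(np.column_stack([cols[c] for c in m.nodes]), m.nodes)


def zscore(data: SampleMatrix) -> SampleMatrix:
    """Re-standardize each column to mean 0, SD 1 (ddof=1)."""
    v = data.values
    sd = v.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be z-scored")
    return SampleMatrix((v - v.mean(axis=0)) / sd, data.columns)


def implied_covariance(m: LinearSCM) -> pd.DataFrame:
    """Exact covariance of the observable vector.

    With B[i, j] the coefficient on edge node_i -> node_j and D the diagonal
    matrix of squared error SDs, the reduced form V = (I - B^T)^{-1} U gives
    Cov(V) = (I - B^T)^{-1} D (I - B^T)^{-T}.
    """
    p = len(m.nodes)
    idx = {node: i for i, node in enumerate(m.nodes)}
    b = np.zeros((p, p))
    for (u, v), c in m.coeff.items():
        b[idx[u], idx[v]] = c
    d = np.diag([m.error_sd[n] ** 2 for n in m.nodes])
    inv = np.linalg.inv(np.eye(p) - b.T)
    cov = inv @ d @ inv.T
    return pd.DataFrame(cov, index=list(m.nodes), columns=list(m.nodes))


def true_effects(m: LinearSCM, x: Node, y: Node) -> EffectTriple:
    """Path-tracing ACE, DE, IE of ``x`` on ``y`` in the model ``m``.

    ACE sums, over every directed path from x to y, the product of the
    structural coefficients along the path; DE is the coefficient on the
    edge x -> y when present (else 0); IE = ACE - DE.
    """
    ace = 0.0
    for path in directed_paths(m.dag, x, y):
        prod = 1.0
        for edge in path.edges():
            prod *= m.coeff[edge]
        ace += prod
    de = m.coeff.get((x, y), 0.0)
    return EffectTriple(ace=ace, de=de, ie=ace - de)
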