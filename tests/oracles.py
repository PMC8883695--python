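"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles, without
importing the implementation's graph or regression machinery, so that
agreement between package and oracle is informative.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Brute-force d-separation: enumerate every simple path and apply the
# chain/fork/collider blocking rule literally.
# ---------------------------------------------------------------------------

def _descendants(edges: set[tuple[str, str]], node: str) -> set[str]:
    out: set[str] = set()
    frontier = [node]
    while frontier:
        cur = frontier.pop()
        for u, v in edges:
            if u == cur and v not in out:
                out.add(v)
                frontier.append(v)
    return out


def _simple_paths(nodes, edges, x, y):
    neighbors: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        neighbors[u].add(v)
        neighbors[v].add(u)
    paths = []

    def walk(trail):
        if trail[-1] == y:
            paths.append(tuple(trail))
            return
        for nxt in neighbors[trail[-1]]:
            if nxt not in trail:
                walk(trail + [nxt])

    walk([x])
    return paths


def _path_blocked(edges: set[tuple[str, str]], path: tuple[str, ...], z: set[str]) -> bool:
    """Definition-1 blocking of one path by z."""
    for i in range(1, len(path) - 1):
        a, m, b = path[i - 1], path[i], path[i + 1]
        into_left = (a, m) in edges
        into_right = (b, m) in edges
        if into_left and into_right:
            # collider: blocks unless m or one of its descendants is in z
            if m not in z and not (_descendants(edges, m) & z):
                return True
        else:
            # chain or fork: blocks iff m in z
            if m in z:
                return True
    return False


def brute_force_d_separated(nodes, edges, x, y, z) -> bool:
    edge_set = set(edges)
    zset = set(z)
    for path in _simple_paths(nodes, edge_set, x, y):
        if not _path_blocked(edge_set, path, zset):
            return False
    return True


# ---------------------------------------------------------------------------
# DAG enumeration / random generation for the oracle-equivalence suite.
# ---------------------------------------------------------------------------

def all_dags(labels: tuple[str, ...]):
    """Every labeled DAG on the given nodes whose edges respect *some* order.

    Enumerates all subsets of ordered pairs and keeps the acyclic ones
    (checked by Kahn's algorithm written out here).
    """
    pairs = [(a, b) for a in labels for b in labels if a != b]
    for mask in range(2 ** len(pairs)):
        edges = tuple(p for i, p in enumerate(pairs) if mask >> i & 1)
        if _is_acyclic(labels, edges):
            yield edges


def _is_acyclic(nodes, edges) -> bool:
    indeg = {n: 0 for n in nodes}
    for _, v in edges:
        indeg[v] += 1
    queue = [n for n in nodes if indeg[n] == 0]
    seen = 0
    while queue:
        cur = queue.pop()
        seen += 1
        for u, v in edges:
            if u == cur:
                indeg[v] -= 1
                if indeg[v] == 0:
                    queue.append(v)
    return seen == len(nodes)


def random_dag(labels: tuple[str, ...], rng: np.random.Generator, p_edge=0.5):
    """Random DAG: random node order, independent edges along the order."""
    order = list(labels)
    rng.shuffle(order)
    edges = []
    for i, j in itertools.combinations(range(len(order)), 2):
        if rng.random() < p_edge:
            edges.append((order[i], order[j]))
    return tuple(edges)


def all_triples(labels):
    """Every (x, y, z) query on the label set, z over subsets of the rest."""
    for x, y in itertools.combinations(labels, 2):
        rest = [n for n in labels if n not in (x, y)]
        for k in range(len(rest) + 1):
            for z in itertools.combinations(rest, k):
                yield x, y, frozenset(z)


# ---------------------------------------------------------------------------
# Textbook OLS (normal equations with intercept column).
# ---------------------------------------------------------------------------

def textbook_ols(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Slopes of y ~ 1 + x by explicit normal equations."""
    design = np.column_stack([np.ones(len(y)), x])
    coef = np.linalg.solve(design.T @ design, design.T @ y)
    return coef[1:]


# ---------------------------------------------------------------------------
# Quadrature Bayes factor: BF01 = m(y | H0) / m(y | H1) with each marginal
# likelihood computed by tensor-product Gauss-Legendre integration of the
# Gaussian likelihood over the N(0, prior_sd^2) slope priors.  sigma2 is the
# plug-in residual variance of the full model, matching the model under test.
# ---------------------------------------------------------------------------

def _log_marginal(yc, xc, sigma2, prior_sd, npts=201, half_width=8.0):
    n, p = xc.shape
    if p == 0:
        return -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * float(yc @ yc) / sigma2
    grid, weights = np.polynomial.legendre.leggauss(npts)
    lim = half_width * prior_sd
    grid = grid * lim
    weights = weights * lim
    axes = [grid] * p
    waxes = [weights] * p
    mesh = np.meshgrid(*axes, indexing="ij")
    bs = np.stack([m.ravel() for m in mesh], axis=1)  # (npts^p, p)
    resid = yc[None, :] - bs @ xc.T  # (npts^p, n)
    log_lik = -0.5 * n * np.log(2 * np.pi * sigma2) - 0.5 * np.sum(resid**2, axis=1) / sigma2
    log_prior = np.sum(
        -0.5 * np.log(2 * np.pi * prior_sd**2) - 0.5 * (bs / prior_sd) ** 2, axis=1
    )
    wmesh = np.meshgrid(*waxes, indexing="ij")
    log_w = np.sum(np.log(np.stack([m.ravel() for m in wmesh], axis=1)), axis=1)
    terms = log_lik + log_prior + log_w
    mx = terms.max()
    return mx + np.log(np.sum(np.exp(terms - mx)))


def quadrature_bf01(y, x_interest, x_adjust, prior_sd=1.0):
    """Savage-Dickey-free BF01 via explicit marginal-likelihood quadrature.

    ``x_adjust`` is an (n, k) array (k may be 0).  Intercepts are handled by
    centering, mirroring the flat-intercept convention of the model.
    """
    x_full = np.column_stack([x_interest] + ([x_adjust] if x_adjust.size else []))
    n, p = x_full.shape
    yc = y - y.mean()
    xc_full = x_full - x_full.mean(axis=0)
    ols = np.linalg.solve(xc_full.T @ xc_full, xc_full.T @ yc)
    rss = float(yc @ yc - ols @ (xc_full.T @ yc))
    sigma2 = rss / (n - p - 1)
    xc_null = xc_full[:, 1:]
    log_m1 = _log_marginal(yc, xc_full, sigma2, prior_sd)
    log_m0 = _log_marginal(yc, xc_null, sigma2, prior_sd)
    return float(np.exp(log_m0 - log_m1))


# ---------------------------------------------------------------------------
# Interventional ACE by mutilated-graph simulation: sever edges into the
# treatment, force its value, and differentiate the mean outcome numerically.
# ---------------------------------------------------------------------------

def do_simulation_ace(model, x: str, y: str, n: int, rng: np.random.Generator, h=1.0):
    """(E[Y | do(X=h)] - E[Y | do(X=-h)]) / 2h on the mutilated graph."""

    def mean_outcome(forced: float) -> float:
        cols: dict[str, np.ndarray] = {}
        for node in model.dag.topological_order():
            if node == x:
                cols[node] = np.full(n, forced)
                continue
            val = model.error_sd[node] * rng.standard_normal(n)
            for parent in model.dag.parents(node):
                val = val + model.coeff[(parent, node)] * cols[parent]
            cols[node] = val
        return float(cols[y].mean())

    return (mean_outcome(h) - mean_outcome(-h)) / (2 * h)
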