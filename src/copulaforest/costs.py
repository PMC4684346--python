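"""Node-cost functions and the exhaustive best-split search.

Three node costs drive tree growth:

* ``sse`` — per-response sum of squared deviations from the node mean
  (the classical univariate regression-tree cost, summed over columns);
* ``mahalanobis`` — sum of squared Mahalanobis distances
  ``(y - mu) Lambda^-1 (y - mu)^T`` with ``Lambda`` the covariance of the
  full training responses, frozen per forest;
* ``copula`` — ``D_C = D1 + alpha * D2`` where ``D1 = 6 p Psi`` penalises
  the copula distance between the node responses and the training-set
  (root) copula, and ``D2`` is the per-response variance-normalised SSE.

A split sends rows with ``x[:, j] <= z`` left; candidate thresholds are
the observed in-node values of the feature, and the partition maximising
``cost(parent) - cost(left) - cost(right)`` wins.  Ties break on the
smallest feature index, then the smallest threshold, so trees are
reproducible.  The search evaluates all prefixes of the feature-sorted
node in one vectorised sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .copula import (
    GRID_CELL_BUDGET,
    EmpiricalCopula,
    copula_distance,
    empirical_copula,
    sobol_points,
)

KINDS = ("sse", "mahalanobis", "copula")

#: below this node size the empirical copula is vacuous and Psi := 0
MIN_COPULA_NODE = 3


@dataclass
class SplitCriterion:
    """Frozen root-level statistics plus the choice of node cost."""

    kind: str
    alpha: float = 1.0
    grid_resolution: int = 10
    lambda_inv: np.ndarray | None = None
    root_sigma2: np.ndarray | None = None
    root_copula: EmpiricalCopula | None = field(default=None, repr=False)
    mc_points: np.ndarray | None = field(default=None, repr=False)
    allow_negative_gain: bool = True

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown criterion kind {self.kind!r}; expected one of {KINDS}")
        if self.kind == "copula" and self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def make_criterion(
    kind: str,
    Y: np.ndarray,
    alpha: float = 1.0,
    grid_resolution: int = 10,
    mc_dim_threshold: int = 3,
    mc_n_points: int = 2048,
    mc_seed: int = 0,
    allow_negative_gain: bool = True,
    ridge: float = 1e-8,
) -> SplitCriterion:
    """Build a criterion with its root statistics computed from the
    training responses ``Y`` (n x r).

    For ``mahalanobis``, ``Lambda`` is the training covariance inverted
    by pseudo-inverse after a ``ridge * trace`` diagonal lift (rank
    deficiency at small r or collinear drugs).  For ``copula``, the root
    copula lattice and per-response root variances are frozen here; for
    ``r > mc_dim_threshold`` the lattice is replaced by a seeded Sobol
    point set and Psi is evaluated by quasi-Monte Carlo.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim != 2:
        raise ValueError("Y must be an n x r matrix")
    r = Y.shape[1]
    if kind == "sse":
        return SplitCriterion(kind="sse", allow_negative_gain=allow_negative_gain)
    if kind == "mahalanobis":
        cov = np.atleast_2d(np.cov(Y, rowvar=False, ddof=1))
        lam = cov + (ridge * np.trace(cov) + 1e-300) * np.eye(r)
        return SplitCriterion(
            kind="mahalanobis",
            lambda_inv=np.linalg.pinv(lam),
            allow_negative_gain=allow_negative_gain,
        )
    sigma2 = Y.var(axis=0, ddof=0)
    if np.any(sigma2 <= 0):
        bad = int(np.argmin(sigma2))
        raise ValueError(f"response column {bad} has zero variance at the root")
    use_grid = r <= mc_dim_threshold and grid_resolution**r <= GRID_CELL_BUDGET
    mc_points = None if use_grid else sobol_points(r, mc_n_points, seed=mc_seed)
    root_cop = empirical_copula(Y, K=grid_resolution, build_grid=use_grid)
    return SplitCriterion(
        kind="copula",
        alpha=alpha,
        grid_resolution=grid_resolution,
        root_sigma2=sigma2,
        root_copula=root_cop,
        mc_points=mc_points,
        allow_negative_gain=allow_negative_gain,
    )


# ---------------------------------------------------------------------------
# single-node costs


def cost_sse(y_node: np.ndarray) -> float:
    """Sum of squared deviations from the node mean (univariate)."""
    y = np.asarray(y_node, dtype=float).ravel()
    if y.size < 1:
        raise ValueError("empty node")
    return float(np.sum((y - y.mean()) ** 2))


def cost_mahalanobis(Y_node: np.ndarray, crit: SplitCriterion) -> float:
    """Sum over node rows of (y - mu) Lambda^-1 (y - mu)^T."""
    if crit.kind != "mahalanobis" or crit.lambda_inv is None:
        raise ValueError("criterion is not a prepared mahalanobis criterion")
    Y = np.atleast_2d(np.asarray(Y_node, dtype=float))
    D = Y - Y.mean(axis=0)
    return float(np.einsum("ia,ab,ib->", D, crit.lambda_inv, D))


def cost_copula(Y_node: np.ndarray, crit: SplitCriterion) -> tuple[float, float, float]:
    """Copula node cost ``(D_C, D1, D2)`` with ``D_C = D1 + alpha D2``.

    ``D1 = 6 p Psi`` compares the node's empirical copula with the
    frozen root copula (responses re-ranked within the node, so the
    comparison is marginal-free); ``D2`` sums per-response SSE divided
    by the root variance.  Nodes smaller than ``MIN_COPULA_NODE`` rows,
    and the univariate case, have ``Psi := 0`` — a 1-2 point copula and
    a one-dimensional "dependence structure" are both vacuous.  Columns
    may contain NaN: ``D2`` sums over observed entries and ``Psi`` uses
    complete rows only.
    """
    if crit.kind != "copula" or crit.root_copula is None:
        raise ValueError("criterion is not a prepared copula criterion")
    Y = np.atleast_2d(np.asarray(Y_node, dtype=float))
    p, r = Y.shape
    d2 = 0.0
    for j in range(r):
        col = Y[:, j]
        obs = col[~np.isnan(col)]
        if obs.size:
            d2 += cost_sse(obs) / crit.root_sigma2[j]
    complete = Y[~np.isnan(Y).any(axis=1)]
    if r == 1 or complete.shape[0] < MIN_COPULA_NODE:
        d1 = 0.0
    else:
        node_cop = empirical_copula(
            complete, K=crit.grid_resolution, build_grid=crit.mc_points is None
        )
        psi = copula_distance(node_cop, crit.root_copula, points=crit.mc_points)
        d1 = 6.0 * complete.shape[0] * psi
    return d1 + crit.alpha * d2, d1, float(d2)


def node_cost(Y_node: np.ndarray, crit: SplitCriterion) -> float:
    """Dispatch to the criterion's cost (sse sums over response columns)."""
    Y = np.atleast_2d(np.asarray(Y_node, dtype=float))
    if crit.kind == "sse":
        return float(sum(cost_sse(Y[:, j]) for j in range(Y.shape[1])))
    if crit.kind == "mahalanobis":
        return cost_mahalanobis(Y, crit)
    return cost_copula(Y, crit)[0]


# ---------------------------------------------------------------------------
# vectorised prefix sweeps (left child = prefix of the feature-sorted node)


def _prefix_sse_cols(Ys: np.ndarray) -> np.ndarray:
    """SSE of every prefix, per column: out[s-1, j] = SSE(Ys[:s, j])."""
    p = Ys.shape[0]
    s = np.arange(1, p + 1)[:, None]
    c = np.cumsum(Ys, axis=0)
    c2 = np.cumsum(Ys**2, axis=0)
    return np.maximum(c2 - c**2 / s, 0.0)


def _prefix_mahalanobis(Ys: np.ndarray, lambda_inv: np.ndarray) -> np.ndarray:
    """Mahalanobis cost of every prefix via running scatter matrices."""
    p = Ys.shape[0]
    s = np.arange(1, p + 1)[:, None, None]
    cs = np.cumsum(Ys, axis=0)
    cp = np.cumsum(Ys[:, :, None] * Ys[:, None, :], axis=0)
    S = cp - cs[:, :, None] * cs[:, None, :] / s
    return np.einsum("pab,ab->p", S, lambda_inv)


def _prefix_copula_d1(Ys: np.ndarray, crit: SplitCriterion) -> np.ndarray:
    """D1 of every prefix of the (feature-sorted) node responses.

    Ranks within each prefix come from cumulative comparison counts
    (average ranks for ties), prefix copula lattices from one scatter
    plus running sums — O(p^2 r + p K^r) for all p prefixes together.
    """
    p, r = Ys.shape
    K = crit.grid_resolution
    sizes = np.arange(1, p + 1, dtype=float)
    if r == 1:
        return np.zeros(p)
    if crit.mc_points is not None:
        # quasi-Monte-Carlo route (r > 3): per-prefix evaluation
        d1 = np.zeros(p)
        for s in range(MIN_COPULA_NODE, p + 1):
            _, d1[s - 1], _ = cost_copula(Ys[:s], crit)
        d1[: MIN_COPULA_NODE - 1] = 0.0
        return d1
    gidx = []
    for j in range(r):
        col = Ys[:, j]
        le = np.cumsum(col[None, :] <= col[:, None], axis=1)
        lt = np.cumsum(col[None, :] < col[:, None], axis=1)
        avg_rank = (le + lt + 1) / 2.0  # [i, s-1]: average rank of y_i in prefix s
        u = avg_rank / sizes[None, :]
        g = np.ceil(u * K - 1e-9).astype(np.intp) - 1
        np.clip(g, 0, K - 1, out=g)
        gidx.append(g)
    ss, ii = np.tril_indices(p)  # sample ii (<= ss) belongs to prefix ss+1
    hist = np.zeros((p,) + (K,) * r)
    np.add.at(hist, (ss, *[g[ii, ss] for g in gidx]), 1.0)
    for ax in range(1, r + 1):
        np.cumsum(hist, axis=ax, out=hist)
    C = hist / sizes.reshape((p,) + (1,) * r)
    psi = np.abs(C - crit.root_copula.grid_values[None]).mean(axis=tuple(range(1, r + 1)))
    d1 = 6.0 * sizes * psi
    d1[: MIN_COPULA_NODE - 1] = 0.0
    return d1


def _prefix_costs(Ys: np.ndarray, crit: SplitCriterion):
    """(cost, d1, d2) arrays over all prefixes of Ys (d1/d2 None unless copula)."""
    if crit.kind == "sse":
        return _prefix_sse_cols(Ys).sum(axis=1), None, None
    if crit.kind == "mahalanobis":
        return _prefix_mahalanobis(Ys, crit.lambda_inv), None, None
    d2 = (_prefix_sse_cols(Ys) / crit.root_sigma2[None, :]).sum(axis=1)
    d1 = _prefix_copula_d1(Ys, crit)
    return d1 + crit.alpha * d2, d1, d2


@dataclass
class SplitCandidate:
    """One candidate partition: rows with ``x[:, feature] <= threshold`` go left."""

    feature: int
    threshold: float
    gain: float
    left_rows: np.ndarray
    right_rows: np.ndarray
    d1_left: float | None = None
    d2_left: float | None = None
    d1_right: float | None = None
    d2_right: float | None = None


def _feature_candidates(ds, rows: np.ndarray, f: int, crit: SplitCriterion,
                        parent_cost: float, min_child: int = 1) -> list[SplitCandidate]:
    """All valid candidates for one feature, thresholds in ascending order."""
    vals = ds.X[rows, f]
    order = np.argsort(vals, kind="stable")
    sorted_rows = rows[order]
    v = vals[order]
    p = len(rows)
    positions = np.flatnonzero(v[:-1] < v[1:]) + 1  # left sizes s with v[s-1] < v[s]
    if min_child > 1:
        positions = positions[(positions >= min_child) & (p - positions >= min_child)]
    if positions.size == 0:
        return []
    Ys = ds.Y[sorted_rows]
    if np.isnan(Ys).any():
        lc = np.empty(p)
        rc = np.empty(p)
        d1l = d2l = d1r = d2r = np.full(p, np.nan)
        if crit.kind == "copula":
            d1l, d2l, d1r, d2r = (np.empty(p) for _ in range(4))
        for s in positions:
            if crit.kind == "copula":
                lc[s - 1], d1l[s - 1], d2l[s - 1] = cost_copula(Ys[:s], crit)
                rcost, d1r[p - s - 1], d2r[p - s - 1] = cost_copula(Ys[s:], crit)
                rc[p - s - 1] = rcost
            else:
                lc[s - 1] = node_cost(Ys[:s], crit)
                rc[p - s - 1] = node_cost(Ys[s:], crit)
    else:
        lc, d1l, d2l = _prefix_costs(Ys, crit)
        rc, d1r, d2r = _prefix_costs(Ys[::-1], crit)
    out = []
    for s in positions:
        gain = parent_cost - lc[s - 1] - rc[p - s - 1]
        cand = SplitCandidate(
            feature=int(f),
            threshold=float(v[s - 1]),
            gain=float(gain),
            left_rows=sorted_rows[:s],
            right_rows=sorted_rows[s:],
        )
        if crit.kind == "copula":
            cand.d1_left = float(d1l[s - 1])
            cand.d2_left = float(d2l[s - 1])
            cand.d1_right = float(d1r[p - s - 1])
            cand.d2_right = float(d2r[p - s - 1])
        out.append(cand)
    return out


def enumerate_split_candidates(ds, node_rows, feature_pool, crit: SplitCriterion,
                               parent_cost: float | None = None,
                               min_child: int = 1) -> list[SplitCandidate]:
    """Every valid (feature, threshold) candidate for this node, with
    per-child (D1, D2) recorded under the copula criterion (the raw
    material of the Pareto-frontier alpha selection).  ``min_child > 1``
    additionally discards partitions leaving either child smaller than
    that (a minimum-leaf-size rule)."""
    rows = np.asarray(node_rows, dtype=np.intp)
    if rows.size < 2:
        return []
    if parent_cost is None:
        parent_cost = node_cost(ds.Y[rows], crit)
    cands: list[SplitCandidate] = []
    for f in sorted(int(j) for j in feature_pool):
        cands.extend(_feature_candidates(ds, rows, f, crit, parent_cost, min_child))
    return cands


def best_split(ds, node_rows, feature_pool, crit: SplitCriterion,
               parent_cost: float | None = None,
               min_child: int = 1) -> SplitCandidate | None:
    """Arg-max-gain partition of the node, or None when no feature in the
    pool separates the rows.  Deterministic: ties resolve to the smallest
    feature index, then the smallest threshold."""
    cands = enumerate_split_candidates(ds, node_rows, feature_pool, crit, parent_cost, min_child)
    best = None
    for c in cands:  # candidates arrive feature-asc, threshold-asc
        # gains equal up to accumulated rounding count as ties (two features
        # can induce the same partition), so the first candidate wins
        if best is None or c.gain > best.gain + 1e-9 * (1.0 + abs(best.gain)):
            best = c
    return best
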