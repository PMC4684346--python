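"""Empirical copulas, reference copulas, and copula-distance integrals.

A copula is a multivariate CDF on the unit hypercube with uniform
marginals; by Sklar's theorem it carries the dependence structure of a
random vector separated from the marginals.  The empirical copula of a
sample is obtained by rank-transforming each margin to pseudo-observations
and counting joint events.  The distance between two copulas used here is
the integral over the hypercube of the absolute difference of the copula
functions, approximated either on a regular lattice or by quasi-Monte
Carlo for higher dimensions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc, rankdata

#: refuse to materialise copula grids larger than this many cells
GRID_CELL_BUDGET = 4_000_000

_FRECHET_FAMILIES = ("upper_frechet", "lower_frechet", "independence", "clayton")


def pseudo_observations(Y_sub: np.ndarray, denominator: str = "n") -> np.ndarray:
    """Within-column rank transform of a p x r sample onto (0, 1].

    Column ``j`` of the result holds ``rank(y_ij)/p`` with average ranks
    for ties, so the transform is invariant under strictly increasing
    maps of any column and the top rank maps exactly to 1.  The
    ``denominator="n+1"`` variant rescales by ``p+1`` instead (the
    common bias-reducing convention), at the price of never reaching 1.
    """
    Y_sub = np.atleast_2d(np.asarray(Y_sub, dtype=float))
    if Y_sub.shape[0] < 1:
        raise ValueError("need at least one sample")
    p = Y_sub.shape[0]
    ranks = np.apply_along_axis(rankdata, 0, Y_sub) if Y_sub.shape[1] > 1 else rankdata(Y_sub, axis=0)
    denom = p if denominator == "n" else p + 1
    return np.asarray(ranks, dtype=float) / denom


@dataclass
class EmpiricalCopula:
    """Rank-based empirical copula, optionally tabulated on a K^r lattice.

    ``grid_values[k1-1, ..., kr-1]`` is the copula at ``u=(k1/K,...,kr/K)``:
    the fraction of pseudo-observations jointly below ``u``.
    """

    pseudo_obs: np.ndarray
    grid_resolution: int
    grid_values: np.ndarray | None = field(default=None, repr=False)

    @property
    def dim(self) -> int:
        return self.pseudo_obs.shape[1]

    @property
    def n(self) -> int:
        return self.pseudo_obs.shape[0]

    def evaluate(self, U: np.ndarray) -> np.ndarray:
        """Copula value at arbitrary points U (q x r): joint <= counting."""
        U = np.atleast_2d(np.asarray(U, dtype=float))
        return np.all(self.pseudo_obs[None, :, :] <= U[:, None, :] + 1e-12, axis=2).mean(axis=1)


def _grid_from_pseudo(pobs: np.ndarray, K: int) -> np.ndarray:
    """Tabulate the empirical copula of pseudo-observations on a K^r lattice.

    Sample i contributes to every lattice point u >= pobs_i componentwise;
    this is a sparse deposit at ceil(u*K) followed by a running sum along
    each axis, O(p + r K^r) rather than O(p K^r).
    """
    p, r = pobs.shape
    idx = np.ceil(pobs * K - 1e-9).astype(np.intp) - 1
    np.clip(idx, 0, K - 1, out=idx)
    hist = np.zeros((K,) * r)
    np.add.at(hist, tuple(idx.T), 1.0)
    for ax in range(r):
        np.cumsum(hist, axis=ax, out=hist)
    hist /= p
    return hist


def empirical_copula(Y_sub: np.ndarray, K: int = 10, build_grid: bool = True) -> EmpiricalCopula:
    """Estimate the empirical copula of a p x r sample at grid resolution K.

    With ``build_grid=False`` only the pseudo-observations are kept and
    the copula is evaluated lazily (the Monte-Carlo route for large r,
    where a K^r lattice would not fit in memory).
    """
    Y_sub = np.atleast_2d(np.asarray(Y_sub, dtype=float))
    if K < 2:
        raise ValueError("grid resolution K must be >= 2")
    pobs = pseudo_observations(Y_sub)
    r = pobs.shape[1]
    grid = None
    if build_grid:
        if K**r > GRID_CELL_BUDGET:
            raise ValueError(
                f"K^r = {K}^{r} exceeds the grid budget of {GRID_CELL_BUDGET} cells; "
                "use build_grid=False and Monte-Carlo evaluation points instead"
            )
        grid = _grid_from_pseudo(pobs, K)
    return EmpiricalCopula(pseudo_obs=pobs, grid_resolution=K, grid_values=grid)


def copula_distance(
    node_cop: EmpiricalCopula,
    root_cop: EmpiricalCopula,
    points: np.ndarray | None = None,
) -> float:
    """Integral over [0,1]^r of |C_node - C_root| (the distance Psi).

    On matching lattices this is the lattice average of the absolute
    difference; given explicit ``points`` (q x r, e.g. a seeded Sobol
    set) both copulas are evaluated there instead.
    """
    if node_cop.dim != root_cop.dim:
        raise ValueError(f"dimension mismatch: {node_cop.dim} vs {root_cop.dim}")
    if points is not None:
        return float(np.mean(np.abs(node_cop.evaluate(points) - root_cop.evaluate(points))))
    if node_cop.grid_values is None or root_cop.grid_values is None:
        raise ValueError("both copulas need grids (or pass Monte-Carlo points)")
    if node_cop.grid_resolution != root_cop.grid_resolution:
        raise ValueError(
            f"grid resolution mismatch: {node_cop.grid_resolution} vs {root_cop.grid_resolution}"
        )
    return float(np.mean(np.abs(node_cop.grid_values - root_cop.grid_values)))


@dataclass(frozen=True)
class ReferenceCopula:
    """A closed-form copula: Frechet bounds, independence, or bivariate Clayton."""

    family: str
    xi: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in _FRECHET_FAMILIES:
            raise ValueError(f"unknown copula family {self.family!r}")
        if self.family == "clayton" and self.xi <= 0:
            raise ValueError("Clayton parameter xi must be > 0")


def reference_copula_value(ref: ReferenceCopula, u: np.ndarray) -> np.ndarray:
    """Evaluate a reference copula at points u (q x r or a single point).

    C_U = min(u) (comonotone upper bound), C_L = max(sum(u)-(r-1), 0)
    (countermonotone lower bound), C_I = prod(u), and the bivariate
    Clayton ``(u1^-xi + u2^-xi - 1)^(-1/xi)``.
    """
    U = np.atleast_2d(np.asarray(u, dtype=float))
    if np.any((U < 0) | (U > 1)):
        raise ValueError("points must lie in the unit hypercube")
    r = U.shape[1]
    if ref.family == "upper_frechet":
        out = U.min(axis=1)
    elif ref.family == "lower_frechet":
        out = np.maximum(U.sum(axis=1) - (r - 1), 0.0)
    elif ref.family == "independence":
        out = U.prod(axis=1)
    else:  # clayton
        if r != 2:
            raise ValueError("the Clayton copula is defined here for r = 2 only")
        with np.errstate(divide="ignore", over="ignore"):
            out = (U[:, 0] ** -ref.xi + U[:, 1] ** -ref.xi - 1.0) ** (-1.0 / ref.xi)
        out = np.where((U == 0).any(axis=1), 0.0, out)
    out = np.asarray(out, dtype=float)
    return out if np.ndim(u) > 1 else float(out[0])


def reference_copula_grid(ref: ReferenceCopula, r: int, K: int) -> np.ndarray:
    """Tabulate a reference copula on the same K^r lattice convention
    as :func:`empirical_copula` (entry at u = (k1/K, ..., kr/K))."""
    axes = [np.arange(1, K + 1) / K] * r
    mesh = np.meshgrid(*axes, indexing="ij")
    U = np.stack([m.ravel() for m in mesh], axis=1)
    return reference_copula_value(ref, U).reshape((K,) * r)


def sample_clayton(xi: float, p: int, seed) -> np.ndarray:
    """Draw p pairs from the bivariate Clayton copula (conditional inverse).

    With U1 uniform and T uniform, setting the conditional CDF
    dC/du1 equal to T and solving gives
    ``U2 = (U1^-xi (T^(-xi/(1+xi)) - 1) + 1)^(-1/xi)``.
    Numerically stabilised through logs so the independence limit
    xi -> 0+ is usable.  Sample Kendall's tau converges to xi/(xi+2).
    """
    if xi <= 0:
        raise ValueError("Clayton parameter xi must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u1 = rng.random(p)
    t = rng.random(p)
    # b = u1^-xi * (t^(-xi/(1+xi)) - 1), evaluated as expm1/log1p for small xi
    b = np.exp(-xi * np.log(u1)) * np.expm1((-xi / (1.0 + xi)) * np.log(t))
    u2 = np.exp((-1.0 / xi) * np.log1p(b))
    return np.column_stack([u1, u2])


def frechet_gap_integrals(
    r: int,
    method: str = "grid",
    resolution: int | None = None,
    samples: int = 1_000_000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Estimate (integral C_U - C_L, integral C_U - C_I, integral C_U) over [0,1]^r.

    The first value bounds the copula distance Psi between *any* two
    r-variate copulas.  ``method="grid"`` integrates by the midpoint
    rule on ``resolution^r`` cells (deterministic; analytic values are
    1/(r+1) - 1/(r+1)! , 1/(r+1) - 2^-r and 1/(r+1)); ``method="monte_carlo"``
    averages over ``samples`` seeded uniform points.
    """
    if r < 2:
        raise ValueError("need dimension r >= 2")
    if method == "grid":
        K = resolution if resolution is not None else {2: 400, 3: 200}.get(r, 50)
        if K**r > 5 * GRID_CELL_BUDGET:
            raise ValueError("grid too large for this dimension; use method='monte_carlo'")
        centers = (np.arange(K) + 0.5) / K
        mesh = np.meshgrid(*([centers] * r), indexing="ij", sparse=True)
        cu = mesh[0]
        total = mesh[0]
        ci = mesh[0]
        for m in mesh[1:]:
            cu = np.minimum(cu, m)
            total = total + m
            ci = ci * m
        cl = np.maximum(total - (r - 1), 0.0)
        vol = 1.0  # unit hypercube, midpoint weights are uniform
        gap_l = float(np.mean(cu - cl)) * vol
        gap_i = float(np.mean(cu - ci)) * vol
        int_u = float(np.mean(cu)) * vol
        return gap_l, gap_i, int_u
    if method == "monte_carlo":
        rng = np.random.default_rng(seed)
        gap_l = gap_i = int_u = 0.0
        done = 0
        while done < samples:  # chunked to bound memory
            q = min(500_000, samples - done)
            U = rng.random((q, r))
            cu = U.min(axis=1)
            cl = np.maximum(U.sum(axis=1) - (r - 1), 0.0)
            ci = U.prod(axis=1)
            gap_l += float(np.sum(cu - cl))
            gap_i += float(np.sum(cu - ci))
            int_u += float(np.sum(cu))
            done += q
        return gap_l / samples, gap_i / samples, int_u / samples
    raise ValueError(f"unknown method {method!r}")


def bivariate_gap_region1_integral(resolution: int = 400) -> float:
    """Midpoint-rule integral of C_U - C_L over the triangle u > v, u + v > 1.

    On that region C_U - C_L = v - (u + v - 1) = 1 - u; the exact value
    is 1/24, one quarter of the full bivariate gap 1/6.
    """
    K = resolution
    centers = (np.arange(K) + 0.5) / K
    u, v = np.meshgrid(centers, centers, indexing="ij")
    mask = (u > v) & (u + v > 1)
    return float(np.sum((1.0 - u)[mask]) / K**2)


def sobol_points(r: int, n_points: int = 2048, seed: int = 0) -> np.ndarray:
    """Seeded scrambled-Sobol quasi-uniform points in [0,1]^r (for
    Monte-Carlo evaluation of Psi when a lattice is impractical)."""
    m = max(1, math.ceil(math.log2(n_points)))
    return qmc.Sobol(d=r, scramble=True, seed=seed).random_base2(m)[:n_points]
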