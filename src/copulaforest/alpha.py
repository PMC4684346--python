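"""Choosing the copula-cost weight alpha.

The copula node cost ``D_C = D1 + alpha * D2`` trades dependence
preservation (D1) against variance reduction (D2).  Two data-driven
selectors are provided:

* **grid** — evaluate a small set of candidate alphas on a secondary
  train/test split of the training data and keep the one with the best
  mean per-response Pearson correlation;
* **pareto** — treat candidate first splits as a two-objective
  minimisation of (D1, D2), extract the Pareto frontier of the child
  (D1, D2) clouds over probe trees, approximate each frontier by two
  straight lines, and convert each fitted slope rho into a candidate
  ``alpha = -1/rho`` (a steep frontier segment, |rho| > 1, prices D1
  reduction highly and yields alpha < 1; a shallow one yields
  alpha > 1).  The pooled means of the two buckets are then compared by
  the grid selector's scoring rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .costs import enumerate_split_candidates, make_criterion
from .dataset import Dataset
from .forest import build_forest, forest_predict
from .metrics import pearson_r

DEFAULT_ALPHA_GRID = np.logspace(np.log10(0.1), np.log10(10.0), 10)


@dataclass(frozen=True)
class ParetoPoint:
    """A candidate split child's (D1, D2) pair."""

    d1: float
    d2: float
    feature: int = -1
    threshold: float = float("nan")
    side: str = ""


@dataclass
class AlphaChoice:
    """A selected alpha plus the full table of evaluated candidates."""

    alpha: float
    method: str
    candidates_evaluated: list[tuple[float, float]] = field(default_factory=list)
    score_metric: str = "pearson"


@dataclass(frozen=True)
class FrontierAlphas:
    """Alphas fitted from the two frontier segments (either may be None)."""

    alpha_high: float | None  # from the shallow segment, > 1
    alpha_low: float | None  # from the steep segment, < 1


def pareto_frontier(points: list[ParetoPoint]) -> list[ParetoPoint]:
    """Non-dominated subset, sorted by increasing d1.

    Point i is dominated by j when (d1_j < d1_i and d2_j <= d2_i) or
    (d1_j <= d1_i and d2_j < d2_i); exact duplicates are kept once.
    """
    if not points:
        raise ValueError("no points")
    seen: set[tuple[float, float]] = set()
    uniq = []
    for pt in points:
        key = (pt.d1, pt.d2)
        if key not in seen:
            seen.add(key)
            uniq.append(pt)
    front = [
        p for p in uniq
        if not any(
            (q.d1 < p.d1 and q.d2 <= p.d2) or (q.d1 <= p.d1 and q.d2 < p.d2)
            for q in uniq
        )
    ]
    return sorted(front, key=lambda p: (p.d1, p.d2))


def _ls_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, SSR) of the least-squares line y ~ x."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(resid @ resid)


def fit_frontier_alphas(frontier: list[ParetoPoint]) -> FrontierAlphas:
    """Two-segment piecewise-linear fit of the frontier in the (d1, d2)
    plane; each negatively sloped segment contributes alpha = -1/rho.

    The breakpoint minimises total squared residual over partitions
    with at least 2 points per segment; short frontiers (< 4 points)
    get a single line.  Segments with non-negative slope yield nothing.
    When both segments land in the same bucket their alphas average.
    """
    if len(frontier) < 2:
        return FrontierAlphas(None, None)
    d1 = np.array([p.d1 for p in frontier])
    d2 = np.array([p.d2 for p in frontier])
    slopes: list[float] = []
    if len(frontier) < 4:
        slopes.append(_ls_line(d1, d2)[0])
    else:
        best = None
        for b in range(2, len(frontier) - 1):
            s1, r1 = _ls_line(d1[:b], d2[:b])
            s2, r2 = _ls_line(d1[b:], d2[b:])
            if best is None or r1 + r2 < best[0]:
                best = (r1 + r2, s1, s2)
        slopes.extend(best[1:])
    high, low = [], []
    for rho in slopes:
        if rho >= -1e-9:  # flat or rising segments carry no usable trade-off
            continue
        a = -1.0 / rho
        (high if a > 1 else low).append(a)
    return FrontierAlphas(
        alpha_high=float(np.mean(high)) if high else None,
        alpha_low=float(np.mean(low)) if low else None,
    )


def _secondary_split(n: int, split_frac: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    cut = int(np.ceil(split_frac * n))
    return perm[:cut], perm[cut:]


def _score_alpha(ds: Dataset, alpha: float, train_rows, test_rows, fp: dict, seed) -> float:
    train = ds.subset_rows(train_rows)
    crit = make_criterion(
        "copula", train.Y, alpha=alpha,
        grid_resolution=fp.get("grid_resolution", 10),
        allow_negative_gain=fp.get("allow_negative_gain", True),
    )
    f = build_forest(
        train, crit, T=fp.get("T", 150), m=fp.get("m", 10),
        n_size=fp.get("n_size", 5), bootstrap_frac=fp.get("bootstrap_frac", 1.0),
        seed=seed,
    )
    pred = forest_predict(ds.X[test_rows], f, train.Y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = [pearson_r(ds.Y[test_rows, j], pred[:, j]) for j in range(ds.n_responses)]
    return float(np.nanmean(scores))


def select_alpha_grid(
    ds: Dataset,
    grid: np.ndarray | list[float] | None = None,
    split_frac: float = 0.7,
    forest_params: dict | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> AlphaChoice:
    """Evaluate each candidate alpha on one secondary train/test split of
    the training data and return the best scorer.

    The default grid is 10 log-spaced values on [0.1, 10].  Every forest
    is grown from the same substream so candidates differ only in alpha.
    """
    grid = DEFAULT_ALPHA_GRID if grid is None else np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("empty alpha grid")
    if not 0 < split_frac < 1:
        raise ValueError("split_frac must be in (0, 1)")
    fp = forest_params or {}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    split_ss, forest_ss = ss.spawn(2)
    rng = np.random.Generator(np.random.PCG64(split_ss))
    train_rows, test_rows = _secondary_split(ds.n, split_frac, rng)
    if len(train_rows) < 2 * fp.get("n_size", 5):
        raise ValueError("secondary training split too small; lower split_frac or n_size")
    if len(test_rows) < 2:
        raise ValueError("secondary test split too small")
    table = [
        (float(a), _score_alpha(ds, float(a), train_rows, test_rows, fp, forest_ss))
        for a in grid
    ]
    best_alpha = max(table, key=lambda t: (np.nan_to_num(t[1], nan=-np.inf)))[0]
    return AlphaChoice(alpha=best_alpha, method="grid", candidates_evaluated=table)


def first_split_pareto_points(
    ds: Dataset, fp: dict, n_trees_probe: int,
    seed: int | np.random.SeedSequence = 0,
) -> list[list[ParetoPoint]]:
    """Per-probe-tree, per-child (D1, D2) clouds of all candidate first
    splits.  D1 and D2 do not involve alpha, so probe trees only need
    the root statistics; bootstrap and feature-subset draws mirror
    :func:`copulaforest.forest.build_forest`.

    Candidates leaving a child below the minimum copula node size are
    excluded: such a child has D1 := 0 by convention (its empirical
    copula is vacuous), and a one-point child also has D2 = 0, so
    keeping them would let a degenerate (0, 0) point dominate every
    frontier.
    """
    from .costs import MIN_COPULA_NODE

    crit = make_criterion("copula", ds.Y, alpha=1.0,
                          grid_resolution=fp.get("grid_resolution", 10))
    m = min(fp.get("m", 10), ds.n_features)
    frac = fp.get("bootstrap_frac", 1.0)
    n_boot = int(np.ceil(frac * ds.n))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    clouds: list[list[ParetoPoint]] = []
    for child in ss.spawn(n_trees_probe):
        rng = np.random.Generator(np.random.PCG64(child))
        rows = rng.choice(ds.n, size=n_boot, replace=True)
        pool = rng.choice(ds.n_features, size=m, replace=False)
        cands = enumerate_split_candidates(ds, rows, pool, crit, min_child=MIN_COPULA_NODE)
        left = [ParetoPoint(c.d1_left, c.d2_left, c.feature, c.threshold, "left")
                for c in cands]
        right = [ParetoPoint(c.d1_right, c.d2_right, c.feature, c.threshold, "right")
                 for c in cands]
        clouds.extend(([left] if left else []) + ([right] if right else []))
    return clouds


def select_alpha_pareto(
    ds: Dataset,
    forest_params: dict | None = None,
    n_trees_probe: int = 20,
    split_frac: float = 0.7,
    seed: int | np.random.SeedSequence = 0,
) -> AlphaChoice:
    """Pareto-frontier alpha selection.

    Fits frontier alphas for both children of the first split of each
    probe tree, pools the > 1 and < 1 buckets across trees, and scores
    the two pooled means by the grid selector's secondary-split rule,
    returning the better.  If every frontier is flat (e.g. D1 identically
    zero) the choice falls back to alpha = 1 with a warning.
    """
    if n_trees_probe < 1:
        raise ValueError("need at least one probe tree")
    fp = forest_params or {}
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    probe_ss, score_ss = ss.spawn(2)
    highs, lows = [], []
    for cloud in first_split_pareto_points(ds, fp, n_trees_probe, probe_ss):
        fa = fit_frontier_alphas(pareto_frontier(cloud))
        if fa.alpha_high is not None:
            highs.append(fa.alpha_high)
        if fa.alpha_low is not None:
            lows.append(fa.alpha_low)
    pooled = [float(np.mean(b)) for b in (highs, lows) if b]
    if not pooled:
        warnings.warn("no usable frontier slopes; falling back to alpha = 1")
        return AlphaChoice(alpha=1.0, method="pareto", candidates_evaluated=[(1.0, float("nan"))])
    rng = np.random.Generator(np.random.PCG64(probe_ss.spawn(1)[0]))
    train_rows, test_rows = _secondary_split(ds.n, split_frac, rng)
    table = [(a, _score_alpha(ds, a, train_rows, test_rows, fp, score_ss)) for a in pooled]
    best_alpha = max(table, key=lambda t: np.nan_to_num(t[1], nan=-np.inf))[0]
    return AlphaChoice(alpha=best_alpha, method="pareto", candidates_evaluated=table)
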