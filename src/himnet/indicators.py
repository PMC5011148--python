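"""Dynamics indicators for real-valued series and distance matrices.

* Increment entropy (IncEnt): the Shannon entropy of quantized
  sign/magnitude words built from consecutive increments of a series.
  Higher values mean a less predictable series.
* Mean/variance changepoint detection via PELT (Pruned Exact Linear Time):
  exact minimization of per-segment twice-negative-Gaussian-log-likelihood
  plus a linear penalty β per changepoint.
* CROPS: enumeration of every PELT-optimal segmentation across a continuous
  penalty range with few PELT runs.
* Classical multidimensional scaling of a distance matrix.
* A thin wrapper around igraph's multilevel (Louvain) community detection.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .graph import Graph

__all__ = [
    "IncEntParams",
    "increment_entropy",
    "ChangepointConfig",
    "ChangepointResult",
    "segment_cost_meanvar",
    "pelt_meanvar",
    "crops_sweep",
    "mds_embedding",
    "louvain_communities",
]

_VAR_FLOOR = 1e-12  # keeps log(sigma^2) finite on constant segments


# ---------------------------------------------------------------------------
# Increment entropy


@dataclass(frozen=True)
class IncEntParams:
    """Increment-entropy parameters.

    m
        Word length: number of consecutive increments per word (>= 2).
    R
        Quantization resolution: magnitudes are binned into 0..R.
    scale
        Quantization scale sigma: ``"window"`` (default) uses the standard
        deviation of the increments inside each m-window; ``"global"`` uses
        the standard deviation of the whole increment series.
    """

    m: int = 2
    R: int = 2
    scale: str = "window"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"word length m must be >= 2, got {self.m}")
        if self.R < 1:
            raise ValueError(f"resolution R must be >= 1, got {self.R}")
        if self.scale not in ("window", "global"):
            raise ValueError(f"scale must be 'window' or 'global', got {self.scale!r}")


def increment_entropy(x, params: IncEntParams | None = None) -> float:
    """Increment entropy of a series, in bits.

    Each increment v is coded as a two-letter symbol: its strict sign
    (-1/0/+1) and a magnitude bin q = min(floor(|v| * R / sigma), R), with
    q = 0 when the quantization scale sigma is 0.  A word is the m-gram of
    symbols in one sliding window of m increments; the result is the
    Shannon entropy (base 2) of the empirical word distribution, divided
    by (m - 1).
    """
    p = params or IncEntParams()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if x.size < p.m + 2:
        raise ValueError(f"series of length {x.size} too short for m={p.m}")
    v = np.diff(x)
    n_words = v.size - p.m + 1
    global_sigma = float(v.std()) if p.scale == "global" else None
    words: Counter = Counter()
    for i in range(n_words):
        win = v[i:i + p.m]
        sigma = global_sigma if global_sigma is not None else float(win.std())
        signs = np.sign(win).astype(int)
        # a spread at rounding level (e.g. increments of a sampled straight
        # line) is quantization noise, not signal: treat the scale as zero
        if sigma <= 1e-9 * float(np.abs(win).max(initial=0.0)):
            sigma = 0.0
        if sigma > 0:
            q = np.minimum(np.floor(np.abs(win) * p.R / sigma), p.R).astype(int)
        else:
            q = np.zeros(p.m, dtype=int)
        words[tuple(zip(signs, q))] += 1
    counts = np.array(list(words.values()), dtype=np.float64)
    freq = counts / counts.sum()
    h = float(-(freq * np.log2(freq)).sum())
    return h / (p.m - 1)


# ---------------------------------------------------------------------------
# Changepoint detection (mean/variance PELT + CROPS)


@dataclass(frozen=True)
class ChangepointConfig:
    """Penalty configuration for PELT / CROPS.

    Either ``penalty`` (a single β >= 0) or ``penalty_range``
    ``(β_min, β_max)`` for the CROPS sweep.  ``min_segment_length`` must be
    at least 2 so every segment supports a variance estimate.
    """

    penalty: float | None = None
    penalty_range: tuple[float, float] | None = None
    min_segment_length: int = 2

    def __post_init__(self) -> None:
        if self.min_segment_length < 2:
            raise ValueError("min_segment_length must be >= 2")
        if self.penalty is not None and self.penalty < 0:
            raise ValueError("penalty must be nonnegative")
        if self.penalty_range is not None:
            lo, hi = self.penalty_range
            if not lo <= hi:
                raise ValueError(f"empty penalty range ({lo}, {hi})")


@dataclass(frozen=True)
class ChangepointResult:
    """Optimal segmentation of a series.

    ``changepoints`` are 1-based: a changepoint at index k splits the series
    into ..k and k+1.. .  ``cost`` is the total unpenalized segment cost;
    ``segment_params`` holds the per-segment (mean, variance) MLEs.
    """

    changepoints: tuple[int, ...]
    penalty: float
    cost: float
    segment_params: tuple[tuple[float, float], ...]

    @property
    def n_changepoints(self) -> int:
        return len(self.changepoints)

    def segments(self, n: int) -> list[tuple[int, int]]:
        """1-based inclusive (start, end) of each segment of a length-n series."""
        bounds = [0, *self.changepoints, n]
        return [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]


class _MeanVarCost:
    """O(1) per-segment Gaussian mean+variance cost from cumulative sums."""

    def __init__(self, x: np.ndarray):
        self.n = x.size
        self.s1 = np.concatenate([[0.0], np.cumsum(x)])
        self.s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def __call__(self, i: int, j: int) -> float:
        """Cost of the 0-based half-open segment x[i:j]."""
        n = j - i
        s = self.s1[j] - self.s1[i]
        ss = self.s2[j] - self.s2[i]
        var = max(ss / n - (s / n) ** 2, _VAR_FLOOR)
        return n * (math.log(2 * math.pi) + math.log(var) + 1.0)

    def params(self, i: int, j: int) -> tuple[float, float]:
        n = j - i
        mu = (self.s1[j] - self.s1[i]) / n
        var = max((self.s2[j] - self.s2[i]) / n - mu * mu, _VAR_FLOOR)
        return mu, var


def segment_cost_meanvar(x, i: int, j: int, min_segment_length: int = 2) -> float:
    """Twice the negative Gaussian log-likelihood of segment x[i..j] (1-based,
    inclusive) under per-segment MLE mean and variance:
    n * (log(2π) + log(σ̂²) + 1), with σ̂² floored at 1e-12."""
    x = np.asarray(x, dtype=np.float64)
    if j - i + 1 < min_segment_length:
        raise ValueError(f"segment [{i}, {j}] shorter than {min_segment_length}")
    if not 1 <= i <= j <= x.size:
        raise ValueError(f"segment [{i}, {j}] out of range for length {x.size}")
    return _MeanVarCost(x)(i - 1, j)


def pelt_meanvar(x, config: ChangepointConfig | None = None,
                 penalty: float | None = None) -> ChangepointResult:
    """Exact penalized mean/variance segmentation via PELT.

    Minimizes  Σ_segments cost + β · (number of changepoints)  by dynamic
    programming; candidate last-changepoints t are pruned once
    F(t) + C(t+1..s) > F(s), which cannot exclude the optimum because the
    cost is additive and refitting each segment never increases it.
    """
    cfg = config or ChangepointConfig()
    if penalty is None:
        penalty = cfg.penalty
    if penalty is None:
        x_arr = np.asarray(x, dtype=np.float64)
        penalty = 2.0 * math.log(x_arr.size)  # BIC-like default
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    n = x.size
    L = cfg.min_segment_length
    if n < 2 * L:
        # no admissible split: the single segment is the optimum
        cost_fn = _MeanVarCost(x)
        if n < L:
            raise ValueError(f"series of length {n} shorter than one segment ({L})")
        return ChangepointResult((), float(penalty), cost_fn(0, n),
                                 (cost_fn.params(0, n),))
    cost = _MeanVarCost(x)
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    # t failing the pruning inequality at step s stays admissible until
    # step s + L: for s' in (s, s+L) the boundary s is itself too close to
    # s' to stand in for t, so the exclusion argument only bites at s + L.
    drop_at: dict[int, int] = {}
    for s in range(L, n + 1):
        candidates = [t for t in candidates if drop_at.get(t, n + L) > s]
        best, arg = np.inf, 0
        for t in candidates:
            if s - t < L:
                continue
            val = F[t] + cost(t, s) + penalty
            if val < best:
                best, arg = val, t
        F[s] = best
        last[s] = arg
        for t in candidates:
            if s - t >= L and t not in drop_at and F[t] + cost(t, s) > F[s]:
                drop_at[t] = s + L
        if s - L + 1 >= L or s - L + 1 == 0:
            candidates.append(s - L + 1)
    cps = []
    s = n
    while s > 0:
        t = last[s]
        if t > 0:
            cps.append(t)
        s = t
    cps = tuple(sorted(cps))
    bounds = [0, *cps, n]
    segs = tuple(cost.params(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1))
    total = sum(cost(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1))
    return ChangepointResult(cps, float(penalty), float(total), segs)


def crops_sweep(x, config: ChangepointConfig) -> list[dict]:
    """All PELT-optimal segmentations over a continuous penalty range.

    Returns a list of records, each with keys ``penalty_interval``,
    ``changepoints``, ``cost`` and ``n_changepoints``, ordered by interval.
    Every returned segmentation is PELT-optimal for every penalty in its
    interval, and the intervals partition [β_min, β_max].  The recursion of
    CROPS guarantees at most 2 + (number of distinct segmentations) PELT
    runs: when the changepoint counts at the interval ends differ by more
    than one, PELT is re-run at the crossing penalty
    β* = (cost_low - cost_high) / (k_high - k_low).
    """
    if config.penalty_range is None:
        raise ValueError("crops_sweep requires a penalty_range")
    b_lo, b_hi = config.penalty_range
    if not b_lo < b_hi:
        raise ValueError(f"empty penalty range ({b_lo}, {b_hi})")
    x = np.asarray(x, dtype=np.float64)
    results: dict[float, ChangepointResult] = {}

    def run(beta: float) -> ChangepointResult:
        if beta not in results:
            results[beta] = pelt_meanvar(x, config, penalty=beta)
        return results[beta]

    intervals: list[tuple[float, float, ChangepointResult]] = []

    def recurse(lo: float, hi: float, r_lo: ChangepointResult,
                r_hi: ChangepointResult) -> None:
        if r_lo.n_changepoints == r_hi.n_changepoints:
            intervals.append((lo, hi, r_lo))
            return
        if r_lo.n_changepoints == r_hi.n_changepoints + 1:
            # exactly one crossing; it is where the penalized costs tie
            beta_star = (r_lo.cost - r_hi.cost) / (
                r_hi.n_changepoints - r_lo.n_changepoints
            )
            beta_star = min(max(beta_star, lo), hi)
            intervals.append((lo, beta_star, r_lo))
            intervals.append((beta_star, hi, r_hi))
            return
        beta_star = (r_lo.cost - r_hi.cost) / (
            r_hi.n_changepoints - r_lo.n_changepoints
        )
        beta_star = min(max(beta_star, lo), hi)
        r_star = run(beta_star)
        if r_star.n_changepoints in (r_lo.n_changepoints, r_hi.n_changepoints):
            # no new segmentation between these: the crossing is exact
            intervals.append((lo, beta_star, r_lo))
            intervals.append((beta_star, hi, r_hi))
            return
        recurse(lo, beta_star, r_lo, r_star)
        recurse(beta_star, hi, r_star, r_hi)

    recurse(b_lo, b_hi, run(b_lo), run(b_hi))
    intervals.sort(key=lambda rec: rec[0])
    merged: list[dict] = []
    for lo, hi, res in intervals:
        if hi <= lo:
            continue
        if merged and merged[-1]["changepoints"] == res.changepoints:
            merged[-1]["penalty_interval"] = (merged[-1]["penalty_interval"][0], hi)
            continue
        merged.append({
            "penalty_interval": (lo, hi),
            "changepoints": res.changepoints,
            "cost": res.cost,
            "n_changepoints": res.n_changepoints,
        })
    return merged


# ---------------------------------------------------------------------------
# Classical MDS


def mds_embedding(d, k: int = 2) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Double-centers -D²/2, takes the top-k nonnegative eigenpairs and scales
    the eigenvectors by the square roots of their eigenvalues.  For a truly
    k-dimensional Euclidean distance matrix this reproduces the original
    configuration up to rigid motion; coordinates beyond the count of
    positive eigenvalues are zero.  Each eigenvector's first nonzero entry
    is made positive, for reproducible output.
    """
    d = np.asarray(d, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0) or np.any(np.abs(np.diag(d)) > 1e-12):
        raise ValueError("distances must be nonnegative with a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d * d) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, k))
    for dim in range(min(k, n)):
        lam = evals[dim]
        if lam <= 1e-12:
            break
        vec = evecs[:, dim]
        nz = np.nonzero(np.abs(vec) > 1e-12)[0]
        if nz.size and vec[nz[0]] < 0:
            vec = -vec
        coords[:, dim] = math.sqrt(lam) * vec
    return coords


# ---------------------------------------------------------------------------
# Community detection (thin wrapper)


def louvain_communities(g: Graph, seed: int | None = None) -> dict:
    """Louvain (multilevel) community detection, delegated to igraph.

    Returns ``{"membership": {label: community}, "modularity": float,
    "n_communities": int, "seed": seed}``.  Not re-implemented here: the
    algorithm's internals are out of scope and an established
    implementation is used.
    """
    import igraph as ig

    a = g.adjacency
    edges, weights = [], []
    for i in range(g.n):
        for j in range(i + 1, g.n):
            if a[i, j] != 0.0:
                edges.append((i, j))
                weights.append(float(a[i, j]))
    graph = ig.Graph(n=g.n, edges=edges)
    if seed is not None:
        import random

        random.seed(seed)
    part = graph.community_multilevel(weights=weights or None)
    membership = {lab: int(c) for lab, c in zip(g.node_labels, part.membership)}
    return {
        "membership": membership,
        "modularity": float(part.modularity),
        "n_communities": len(set(part.membership)),
        "seed": seed,
    }
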