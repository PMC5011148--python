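import itertools
import math

import numpy as np
import pytest

from himnet.graph import full_graph, graph_from_edges
from himnet.indicators import (
    ChangepointConfig,
    IncEntParams,
    crops_sweep,
    increment_entropy,
    louvain_communities,
    mds_embedding,
    pelt_meanvar,
    segment_cost_meanvar,
)


def brute_force_meanvar(x, penalty, min_len=2):
    """Exhaustive minimizer of total segment cost + penalty * n_changepoints."""
    n = len(x)
    best = (segment_cost_meanvar(x, 1, n), ())
    positions = range(min_len, n - min_len + 1)
    for k in range(1, n // min_len):
        for cps in itertools.combinations(positions, k):
            bounds = [0, *cps, n]
            if any(b - a < min_len for a, b in zip(bounds, bounds[1:])):
                continue
            cost = sum(
                segment_cost_meanvar(x, a + 1, b) for a, b in zip(bounds, bounds[1:])
            )
            total = cost + penalty * k
            if total < best[0] + penalty * len(best[1]) - 1e-12:
                best = (cost, cps)
    return best


class TestIncrementEntropy:
    def test_constant_series_is_zero(self):
        assert increment_entropy(np.full(20, 3.7)) == 0.0

    def test_linear_ramp_is_zero(self):
        assert increment_entropy(np.linspace(0, 1, 25)) == 0.0

    def test_alternating_series_is_one_bit(self):
        x = np.tile([0.0, 1.0], 6)
        assert increment_entropy(x, IncEntParams(m=2, R=2)) == pytest.approx(1.0)

    def test_word_count_upper_bound(self, rng):
        x = rng.random(40)
        p = IncEntParams(m=3, R=2)
        h = increment_entropy(x, p)
        n_windows = (x.size - 1) - p.m + 1
        assert 0.0 <= h <= math.log2(n_windows) / (p.m - 1) + 1e-12

    def test_global_scale_variant_differs_on_spiky_series(self):
        x = np.concatenate([np.zeros(10), [5.0], np.zeros(10)]) + np.sin(np.arange(21)) * 1e-3
        hw = increment_entropy(x, IncEntParams(scale="window"))
        hg = increment_entropy(x, IncEntParams(scale="global"))
        assert hg < hw  # global scale maps the tiny wiggles to size bin 0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            increment_entropy([1.0, 2.0, 3.0], IncEntParams(m=2))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            increment_entropy([0.0, np.nan, 1.0, 2.0, 3.0])

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            IncEntParams(m=1)
        with pytest.raises(ValueError):
            IncEntParams(R=0)


class TestSegmentCost:
    def test_matches_defining_formula(self, rng):
        x = rng.normal(size=100)
        var = x.var()
        expected = 100 * (math.log(2 * math.pi) + math.log(var) + 1.0)
        assert segment_cost_meanvar(x, 1, 100) == pytest.approx(expected, rel=1e-12)

    def test_constant_segment_uses_variance_floor(self):
        c = segment_cost_meanvar(np.full(10, 2.0), 1, 10)
        assert np.isfinite(c)
        assert c == pytest.approx(10 * (math.log(2 * math.pi) + math.log(1e-12) + 1))

    def test_splitting_never_increases_cost(self, rng):
        x = rng.normal(size=30)
        whole = segment_cost_meanvar(x, 1, 30)
        for k in range(2, 29):
            split = segment_cost_meanvar(x, 1, k) + segment_cost_meanvar(x, k + 1, 30)
            assert split <= whole + 1e-9

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            segment_cost_meanvar([1.0, 2.0, 3.0], 1, 1)


class TestPelt:
    def test_constant_series_has_no_changepoints(self):
        res = pelt_meanvar(np.full(40, 1.3), penalty=2 * math.log(40))
        assert res.changepoints == ()

    def test_clear_mean_shift_detected_at_boundary(self, rng):
        x = np.concatenate([
            rng.normal(0.0, 1.0, 20),
            rng.normal(10.0, 1.0, 20),
        ])
        # penalty above the small-segment variance-overfit regime
        res = pelt_meanvar(x, penalty=30.0)
        assert res.changepoints == (20,)
        (mu1, _), (mu2, _) = res.segment_params
        assert mu1 == pytest.approx(0.0, abs=1.0)
        assert mu2 == pytest.approx(10.0, abs=1.0)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_search_on_short_series(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 15))
        x = rng.normal(size=n)
        if seed % 3 == 0:  # plant a shift in a third of the cases
            x[n // 2:] += rng.uniform(1, 5)
        beta = float(rng.uniform(0.5, 3.0) * math.log(n))
        res = pelt_meanvar(x, penalty=beta)
        bf_cost, bf_cps = brute_force_meanvar(x, beta)
        assert res.cost + beta * len(res.changepoints) == pytest.approx(
            bf_cost + beta * len(bf_cps), rel=1e-10
        )

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError, match="penalty"):
            pelt_meanvar(np.zeros(10), penalty=-1.0)

    def test_segments_partition_series(self, rng):
        x = np.concatenate([rng.normal(0, 1, 15), rng.normal(5, 0.2, 15)])
        res = pelt_meanvar(x, penalty=3.0)
        segs = res.segments(30)
        assert segs[0][0] == 1 and segs[-1][1] == 30
        for (a1, b1), (a2, b2) in zip(segs, segs[1:]):
            assert a2 == b1 + 1


class TestCrops:
    def test_structureless_series_single_regime(self):
        x = np.full(30, 0.7)
        sweep = crops_sweep(x, ChangepointConfig(penalty_range=(2 * math.log(30), 10 * math.log(30))))
        assert len(sweep) == 1
        assert sweep[0]["changepoints"] == ()

    def test_two_segment_toy_crossover(self, rng):
        x = np.concatenate([rng.normal(0, 1.0, 20), rng.normal(10, 1.0, 20)])
        lo_cost = segment_cost_meanvar(x, 1, 20) + segment_cost_meanvar(x, 21, 40)
        hi_cost = segment_cost_meanvar(x, 1, 40)
        beta_star = hi_cost - lo_cost  # analytic crossover for one changepoint
        sweep = crops_sweep(x, ChangepointConfig(penalty_range=(2 * math.log(40), beta_star * 2)))
        cps = [rec["changepoints"] for rec in sweep]
        assert (20,) in cps
        assert () in cps
        for rec in sweep:
            if rec["changepoints"] == (20,):
                assert rec["penalty_interval"][1] == pytest.approx(beta_star, rel=1e-6)

    def test_segmentations_optimal_inside_intervals(self, rng):
        x = np.concatenate([rng.normal(0, 1, 15), rng.normal(4, 0.3, 15), rng.normal(-2, 2, 10)])
        sweep = crops_sweep(x, ChangepointConfig(penalty_range=(2.0, 40.0)))
        for rec in sweep:
            lo, hi = rec["penalty_interval"]
            for beta in (lo + 1e-6, (lo + hi) / 2, hi - 1e-6):
                direct = pelt_meanvar(x, penalty=beta)
                penalized = direct.cost + beta * direct.n_changepoints
                claimed = rec["cost"] + beta * rec["n_changepoints"]
                assert claimed == pytest.approx(penalized, rel=1e-9)

    def test_changepoint_count_nonincreasing_in_penalty(self, rng):
        x = np.concatenate([rng.normal(m, 0.5, 12) for m in (0, 4, -1, 6)])
        sweep = crops_sweep(x, ChangepointConfig(penalty_range=(1.0, 60.0)))
        counts = [rec["n_changepoints"] for rec in sweep]
        assert counts == sorted(counts, reverse=True)

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            crops_sweep(np.zeros(20), ChangepointConfig(penalty_range=(5.0, 5.0)))


class TestMds:
    def test_equilateral_triangle_recovered(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = mds_embedding(d, k=2)
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert rec == pytest.approx(d, abs=1e-9)

    def test_planar_configuration_recovered(self, rng):
        pts = rng.normal(size=(10, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        coords = mds_embedding(d, k=2)
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert np.abs(rec - d).max() < 1e-8

    def test_extra_dimensions_are_zero(self):
        d = np.ones((3, 3)) - np.eye(3)
        coords = mds_embedding(d, k=5)
        assert coords[:, 2:] == pytest.approx(np.zeros((3, 3)))

    def test_matches_sklearn_eigenvalues(self, rng):
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ours = mds_embedding(d, k=3)
        rec = np.linalg.norm(ours[:, None] - ours[None, :], axis=-1)
        assert np.abs(rec - d).max() < 1e-8

    def test_asymmetric_input_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            mds_embedding(d)


class TestLouvainWrapper:
    def test_two_cliques_two_communities(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        g = graph_from_edges(8, edges)
        out = louvain_communities(g, seed=0)
        assert out["n_communities"] == 2
        ms = out["membership"]
        assert len({ms[l] for l in g.node_labels[:4]}) == 1
        assert len({ms[l] for l in g.node_labels[4:]}) == 1

    def test_uniform_clique_single_community(self):
        out = louvain_communities(full_graph(6), seed=0)
        assert out["n_communities"] == 1
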