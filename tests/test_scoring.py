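import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cosinet as cn
from cosinet.scoring import (
    BoxParams,
    DegenerateGeneError,
    box_counts,
    cosinet_score,
    pair_delta,
    rho,
    score_all_samples,
)
from cosinet.subnetwork import Subnetwork


def brute_force_counts(xv, yv, xk, yk, b, q):
    """Sample-enumeration oracle for the three box counts."""
    def trimmed(vals):
        lo = np.quantile(vals, (1 - q) / 2)
        hi = np.quantile(vals, 1 - (1 - q) / 2)
        return hi - lo

    wx, wy = b * trimmed(xv), b * trimmed(yv)
    n_x = n_y = n_xy = 0
    for xi, yi in zip(xv, yv):
        in_x = abs(xi - xk) <= wx / 2
        in_y = abs(yi - yk) <= wy / 2
        n_x += in_x
        n_y += in_y
        n_xy += in_x and in_y
    return n_x, n_y, n_xy, len(xv)


def _two_gene_world(rng, n1=20, n2=25, n_extra=3):
    genes = ["gx", "gy"]
    n = n1 + n2 + n_extra
    values = 5 + 2 * rng.standard_normal((2, n))
    samples = [f"s{i}" for i in range(n)]
    expr = cn.ExpressionMatrix(values, genes, samples)
    assignment = {
        s: ("c1" if i < n1 else "c2") for i, s in enumerate(samples[: n1 + n2])
    }
    design = cn.ConditionDesign(assignment, "c1", "c2")
    return expr, design


def _pair_subnetwork(z=5.0):
    zm = np.array([[0.0, z], [z, 0.0]])
    return Subnetwork(genes=["gx", "gy"], z_sub=zm, t=abs(z), edges=[("gx", "gy")])


class TestBoxCounts:
    def test_unit_spaced_fixture(self):
        # values 0..10, xk=5, b=0.2 -> width 2, closed box [4, 6] holds 4,5,6
        x = np.arange(11, dtype=float)
        n_x, n_y, n_xy, n = box_counts(x, x, 5.0, 5.0, BoxParams(b=0.2))
        assert (n_x, n_y, n_xy, n) == (3, 3, 3, 11)

    def test_full_range_box_at_midpoint_captures_everything(self):
        # a full-range box is centred on the sample value, so it spans the
        # whole expression range exactly when evaluated at the range midpoint
        rng = np.random.default_rng(0)
        x, y = rng.random(30), rng.random(30)
        mid_x = (x.min() + x.max()) / 2
        mid_y = (y.min() + y.max()) / 2
        n_x, n_y, n_xy, n = box_counts(x, y, mid_x, mid_y, BoxParams(b=1.0))
        assert n_x == n_y == n_xy == n == 30

    def test_point_outside_range_counts_zero(self):
        x = np.arange(10, dtype=float)
        n_x, _, n_xy, _ = box_counts(x, x, 100.0, 5.0, BoxParams(b=0.1))
        assert n_x == 0 and n_xy == 0

    def test_degenerate_range_signalled(self):
        with pytest.raises(DegenerateGeneError):
            box_counts(np.ones(10), np.arange(10.0), 1.0, 5.0)

    def test_quantile_trim_shrinks_boxes(self):
        x = np.concatenate([np.linspace(0, 1, 99), [1000.0]])  # one extreme value
        full = box_counts(x, x, 0.5, 0.5, BoxParams(b=0.1, q=1.0))
        trimmed = box_counts(x, x, 0.5, 0.5, BoxParams(b=0.1, q=0.9))
        assert trimmed[0] < full[0]

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            x, y = rng.random(n) * 10, rng.random(n) * 10
            b = float(rng.uniform(0.05, 1.0))
            q = float(rng.uniform(0.5, 1.0))
            k = int(rng.integers(0, n))
            got = box_counts(x, y, float(x[k]), float(y[k]), BoxParams(b=b, q=q))
            assert got == brute_force_counts(x, y, float(x[k]), float(y[k]), b, q)


class TestRho:
    def test_direct_substitution(self):
        assert rho(4, 5, 3, 10) == pytest.approx(0.1)

    def test_outlier_floored_to_zero(self):
        assert rho(5, 5, 2, 10) == 0.0

    def test_count_consistency_enforced(self):
        with pytest.raises(ValueError):
            rho(3, 5, 4, 10)  # n_xy > n_x
        with pytest.raises(ValueError):
            rho(3, 5, 2, 0)

    @given(
        n=st.integers(4, 100),
        data=st.data(),
    )
    @settings(max_examples=100, derandomize=True)
    def test_bounds(self, n, data):
        n_x = data.draw(st.integers(0, n))
        n_y = data.draw(st.integers(0, n))
        n_xy = data.draw(st.integers(0, min(n_x, n_y)))
        assert 0 <= rho(n_x, n_y, n_xy, n) <= 1


class TestPairDelta:
    def test_antisymmetry_under_condition_swap(self):
        rng = np.random.default_rng(2)
        expr, design = _two_gene_world(rng)
        for s in expr.sample_ids[:6]:
            fwd = pair_delta(expr, design, s, "gx", "gy")
            rev = pair_delta(expr, design.swapped(), s, "gx", "gy")
            assert rev.delta == -fwd.delta
            assert (rev.rho1, rev.rho2) == (fwd.rho2, fwd.rho1)

    def test_delta_range_and_identity(self):
        rng = np.random.default_rng(5)
        expr, design = _two_gene_world(rng)
        stats = pair_delta(expr, design, "s0", "gx", "gy")
        assert -100 <= stats.delta <= 100
        assert stats.delta == pytest.approx(100 * (stats.rho2 - stats.rho1))

    def test_unclassified_sample_is_projected(self):
        rng = np.random.default_rng(7)
        expr, design = _two_gene_world(rng, n_extra=2)
        extra = expr.sample_ids[-1]
        assert design.condition_of(extra) is None
        stats = pair_delta(expr, design, extra, "gx", "gy")
        assert not stats.excluded
        assert np.isfinite(stats.delta)

    def test_degenerate_gene_marks_pair_excluded(self):
        rng = np.random.default_rng(9)
        expr, design = _two_gene_world(rng)
        expr.values[0, :20] = 3.14  # gx constant in condition 1
        stats = pair_delta(expr, design, "s0", "gx", "gy")
        assert stats.excluded


class TestCosinetScore:
    def test_matches_manual_aggregation(self):
        rng = np.random.default_rng(13)
        expr, design = _two_gene_world(rng)
        sub = _pair_subnetwork(z=5.0)
        s = expr.sample_ids[0]
        manual = abs(5.0) * pair_delta(expr, design, s, "gx", "gy").delta / 1
        assert cosinet_score(expr, design, sub, s) == pytest.approx(manual, abs=1e-15)

    def test_vectorized_equals_per_sample_exactly(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(5)]
        n1, n2 = 15, 18
        values = 5 + 2 * rng.standard_normal((5, n1 + n2 + 2))
        samples = [f"s{i}" for i in range(n1 + n2 + 2)]
        expr = cn.ExpressionMatrix(values, genes, samples)
        design = cn.ConditionDesign(
            {s: ("c1" if i < n1 else "c2") for i, s in enumerate(samples[: n1 + n2])},
            "c1",
            "c2",
        )
        zm = rng.standard_normal((5, 5)) * 4
        zm = zm + zm.T
        np.fill_diagonal(zm, 0)
        edges = [(genes[i], genes[j]) for i in range(5) for j in range(i + 1, 5)]
        sub = Subnetwork(genes=genes, z_sub=zm, t=0.0, edges=edges)
        table = score_all_samples(expr, design, sub)
        for s in samples:
            assert table.score_of(s) == cosinet_score(expr, design, sub, s)

    def test_duplicated_expression_row_gets_identical_score(self):
        rng = np.random.default_rng(6)
        expr, design = _two_gene_world(rng, n_extra=1)
        donor = design.samples2[0]
        clone = expr.sample_ids[-1]
        expr.values[:, expr.sample_index(clone)] = expr.values[:, expr.sample_index(donor)]
        sub = _pair_subnetwork()
        table = score_all_samples(expr, design, sub)
        assert table.score_of(clone) == table.score_of(donor)

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        expr, design = _two_gene_world(rng)
        sub = _pair_subnetwork()
        a = score_all_samples(expr, design, sub).scores
        b = score_all_samples(expr, design, sub).scores
        assert a.equals(b)

    def test_weighted_mean_divides_by_z_sum(self):
        rng = np.random.default_rng(10)
        expr, design = _two_gene_world(rng)
        sub = _pair_subnetwork(z=5.0)
        plain = score_all_samples(expr, design, sub).scores["cosinet_score"]
        weighted = score_all_samples(expr, design, sub, weighted_mean=True).scores[
            "cosinet_score"
        ]
        np.testing.assert_allclose(weighted, plain / 5.0, atol=1e-14)

    def test_all_pairs_degenerate_is_fatal(self):
        rng = np.random.default_rng(12)
        expr, design = _two_gene_world(rng)
        expr.values[0, :] = 1.0
        with pytest.raises(ValueError, match="no usable"):
            score_all_samples(expr, design, _pair_subnetwork())

    def test_per_pair_audit_consistent(self):
        rng = np.random.default_rng(14)
        expr, design = _two_gene_world(rng)
        table = score_all_samples(expr, design, _pair_subnetwork(z=2.0), per_pair=True)
        stats = table.pair_stats
        for _, row in stats.iterrows():
            assert row["delta"] == pytest.approx(100 * (row["rho2"] - row["rho1"]))
            assert 0 <= row["n_xy1"] <= min(row["n_x1"], row["n_y1"])


class TestIndependenceCalibration:
    def test_independent_pair_has_small_mean_rho(self):
        rng = np.random.default_rng(20)
        n = 500
        x, y = rng.standard_normal(n) * 2 + 5, rng.standard_normal(n) * 2 + 5
        p = BoxParams(b=0.1)
        rhos = [rho(*box_counts(x, y, x[i], y[i], p)) for i in range(n)]
        mean_indep = np.mean(rhos)
        assert mean_indep < 0.02

        cov = np.array([[1.0, 0.95], [0.95, 1.0]])
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        xc, yc = xy[:, 0] * 2 + 5, xy[:, 1] * 2 + 5
        rhos_c = [rho(*box_counts(xc, yc, xc[i], yc[i], p)) for i in range(n)]
        assert np.mean(rhos_c) >= 5 * mean_indep
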