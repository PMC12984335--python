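import numpy as np
import pytest
from scipy import stats

from mffae.de import (
    DeTable,
    bh_adjust,
    call_anomalies,
    concordance,
    differential_expression,
)
from mffae.matrix import AbundanceMatrix


def _mat(values, sample_ids=None):
    values = np.asarray(values, float)
    n, p = values.shape
    ids = sample_ids or [f"s{i}" for i in range(n)]
    return AbundanceMatrix(ids, [f"prot{j}" for j in range(p)], values)


def welch_oracle(a, b):
    """Hand Welch formula with Welch-Satterthwaite df; p from the t survival fn."""
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, 2 * stats.t.sf(abs(t), df)


class TestWelch:
    def test_hand_example(self):
        values = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
        table = differential_expression(_mat(values), ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        t, p = welch_oracle(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert table.p_value[0] == pytest.approx(0.0214, abs=1e-3)
        assert table.p_value[0] == pytest.approx(p, abs=1e-12)
        assert table.log2fc[0] == -3.0

    def test_identical_groups_null(self):
        vals = np.vstack([np.arange(5.0)] * 4) + np.array([[0.0], [1.0], [0.0], [1.0]])
        table = differential_expression(_mat(vals), ["s0", "s1"], ["s2", "s3"])
        assert np.allclose(table.log2fc, 0)
        assert np.allclose(table.p_value, 1.0)
        assert not table.is_dep.any()

    def test_log2fc_is_mean_difference(self, rng):
        vals = np.vstack([np.full((3, 4), 5.0) + rng.normal(0, 0.1, (3, 4)),
                          np.full((3, 4), 3.0) + rng.normal(0, 0.1, (3, 4))])
        m = _mat(vals)
        table = differential_expression(m, m.sample_ids[:3], m.sample_ids[3:])
        expect = vals[:3].mean(axis=0) - vals[3:].mean(axis=0)
        assert np.allclose(table.log2fc, expect)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(100):
            na, nb = rng.integers(2, 9), rng.integers(2, 9)
            a = rng.normal(rng.normal(), rng.uniform(0.5, 2), size=(na, 1))
            b = rng.normal(rng.normal(), rng.uniform(0.5, 2), size=(nb, 1))
            m = _mat(np.vstack([a, b]))
            table = differential_expression(m, m.sample_ids[:na], m.sample_ids[na:])
            _, p = welch_oracle(a.ravel(), b.ravel())
            assert table.p_value[0] == pytest.approx(p, abs=1e-6)

    def test_group_validation(self):
        m = _mat(np.ones((4, 3)))
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(m, ["s0", "s1"], ["s1", "s2"])
        with pytest.raises(ValueError, match="at least 2"):
            differential_expression(m, ["s0"], ["s1", "s2"])
        with pytest.raises(ValueError, match="unknown sample"):
            differential_expression(m, ["s0", "sX"], ["s2", "s3"])

    def test_membership_only_dependence(self, rng):
        """Dropping samples outside both groups leaves the table unchanged."""
        vals = rng.normal(size=(8, 6))
        m = _mat(vals)
        ga, gb = ["s0", "s1", "s2"], ["s3", "s4"]
        full = differential_expression(m, ga, gb)
        trimmed = differential_expression(
            _mat(vals[:5], sample_ids=m.sample_ids[:5]), ga, gb)
        assert np.array_equal(full.p_value, trimmed.p_value)
        assert np.array_equal(full.log2fc, trimmed.log2fc)


class TestBh:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.04]).tolist() == [0.04]

    def test_dominates_raw_and_capped(self, rng):
        p = rng.uniform(1e-6, 1, size=50)
        q = bh_adjust(p)
        assert (q >= p).all() and (q <= 1).all()
        # monotone over the sorted order of raw p
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


def _table(ids, log2fc, adj_p, dep_fc=2.0, dep_p=0.01):
    log2fc = np.asarray(log2fc, float)
    adj_p = np.asarray(adj_p, float)
    return DeTable(list(ids), log2fc, adj_p.copy(), adj_p,
                   (adj_p < dep_p) & (np.abs(log2fc) > dep_fc))


class TestConcordance:
    def test_self_concordance_is_identity_line(self, rng):
        ids = [f"p{i}" for i in range(20)]
        log2fc = rng.normal(0, 3, 20)
        adj_p = rng.uniform(1e-5, 1, 20)
        log2fc[:4], adj_p[:4] = 5.0, 1e-6  # guarantee a non-empty DEP set
        t = _table(ids, log2fc, adj_p)
        res = concordance(t, t)
        assert (res.slope, res.intercept, res.r_squared) == (
            pytest.approx(1.0), pytest.approx(0.0, abs=1e-12), pytest.approx(1.0))
        assert res.overlap_fraction == 1.0

    def test_exact_affine_relation(self, rng):
        ids = [f"p{i}" for i in range(10)]
        x = rng.normal(size=10)
        res = concordance(_table(ids, x, np.full(10, 0.5)),
                          _table(ids, 2 * x + 1, np.full(10, 0.5)))
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_small_noise_recovery(self, rng):
        ids = [f"p{i}" for i in range(1000)]
        x = rng.normal(0, 3, 1000)
        y = x + rng.normal(0, 0.01, 1000)
        res = concordance(_table(ids, x, np.full(1000, 0.5)),
                          _table(ids, y, np.full(1000, 0.5)))
        assert abs(res.slope - 1) < 0.02
        assert res.r_squared > 0.95

    def test_inner_join_and_minimum_overlap(self, rng):
        a = _table([f"p{i}" for i in range(5)], rng.normal(size=5), np.full(5, 0.5))
        b = _table([f"p{i}" for i in range(2, 7)], rng.normal(size=5), np.full(5, 0.5))
        with pytest.raises(ValueError, match="at least 3"):
            concordance(a, _table(["p0", "p1"], [1.0, 2.0], [0.5, 0.5]))
        res = concordance(a, b)  # inner join on p2..p4
        assert res.n_overlap <= 3


class TestCallAnomalies:
    def test_mad_z_flags_lone_extreme(self):
        assert call_anomalies([1.0, 1.0, 1.0, 10.0], method="mad_z", param=3.5) == [3]

    def test_top_k_bounds(self):
        scores = [0.1, 0.5, 0.3, 0.9]
        assert call_anomalies(scores, method="top_k", param=0) == []
        assert call_anomalies(scores, method="top_k", param=4) == [0, 1, 2, 3]
        assert call_anomalies(scores, method="top_k", param=2) == [1, 3]

    def test_top_k_tie_break_stable_order(self):
        # tied third place: earlier sample wins
        assert call_anomalies([0.5, 0.9, 0.5, 0.1], method="top_k", param=3) == [0, 1, 2]

    def test_grouped_calling_is_per_group(self):
        scores = [1.0, 1.0, 1.0, 5.0, 100.0, 100.0, 100.0, 500.0]
        groups = ["t"] * 4 + ["n"] * 4
        flagged = call_anomalies(scores, method="top_k", param=1, groups=groups,
                                 sample_ids=list("abcdefgh"))
        assert flagged == ["d", "h"]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            call_anomalies([1.0, np.inf])
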