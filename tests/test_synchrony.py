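"""ICC estimator, surfaces, strangers control and companion measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropclock.datasets import load_period_by_droplet_size
from dropclock.synchrony import (
    garcia_ojalvo_R,
    icc,
    icc_surface,
    kuramoto_order,
    period_vs_droplet_size,
    strangers_control,
    surface_regression,
)
from dropclock.tables import TrajectorySet


def brute_force_icc(X):
    """Independent oracle: one-way ANOVA from first principles."""
    n, a = X.shape
    grand = X.mean()
    ss_b = sum(a * (X[i].mean() - grand) ** 2 for i in range(n))
    ss_w = sum((X[i, j] - X[i].mean()) ** 2 for i in range(n) for j in range(a))
    ems_b = ss_b / (n - 1)
    ems_w = ss_w / (n * (a - 1))
    return (ems_b - ems_w) / (ems_b + (a - 1) * ems_w)


class TestICC:
    def test_perfect_within_droplet_agreement(self):
        val, _, ems_w = icc(np.array([[1.0, 1.0], [3.0, 3.0]]))
        assert ems_w == 0.0
        assert val == 1.0

    def test_worked_two_droplet_example(self):
        val, ems_b, ems_w = icc(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert ems_b == pytest.approx(4.0)
        assert ems_w == pytest.approx(0.5)
        assert val == pytest.approx(3.5 / 4.5)

    def test_iid_cells_near_zero(self):
        rng = np.random.default_rng(0)
        vals = [icc(rng.normal(size=(200, 4)))[0] for _ in range(100)]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 2 * se + 0.01

    def test_anticorrelated_pairs_reach_lower_bound(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=50)
        X = np.column_stack([z, -z])  # a=2, perfectly anticorrelated
        val, _, _ = icc(X)
        assert val == pytest.approx(-1.0, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        a = int(rng.integers(2, 5))
        X = rng.normal(size=(n, a))
        assert icc(X)[0] == pytest.approx(brute_force_icc(X), abs=1e-12)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 3)))
        with pytest.raises(ValueError):
            icc(np.ones((3, 1)))
        assert np.isnan(icc(np.ones((3, 3)))[0])


def droplet_ts(values, sizes):
    """TrajectorySet with consecutive cells grouped into droplets of the
    given sizes."""
    dids, cids = [], []
    for d, a in enumerate(sizes):
        for j in range(a):
            dids.append(f"d{d}")
            cids.append(f"d{d}_c{j}")
    return TrajectorySet(values=values, cell_ids=cids, droplet_ids=dids)


class TestICCSurface:
    def test_identical_cells_with_droplet_offsets(self):
        t = np.arange(100) * 0.5
        base = np.sin(2 * np.pi * t / 21.0)
        sizes = [2, 2, 2, 3, 3]
        rows = []
        for d, a in enumerate(sizes):
            for _ in range(a):
                rows.append(base + 2.0 * d)  # distinct droplets, equal cells
        surf = icc_surface(droplet_ts(np.vstack(rows), sizes))
        assert set(surf.a_levels) == {2, 3}
        assert np.allclose(surf.values, 1.0)

    def test_sparse_strata_left_missing(self):
        rng = np.random.default_rng(2)
        sizes = [2, 2, 5]  # only one droplet of size 5
        vals = rng.normal(size=(sum(sizes), 50))
        surf = icc_surface(droplet_ts(vals, sizes))
        assert list(surf.a_levels) == [2]

    def test_long_format_roundtrip(self):
        rng = np.random.default_rng(3)
        sizes = [2, 2, 3, 3]
        surf = icc_surface(droplet_ts(rng.normal(size=(10, 40)), sizes))
        frame = surf.to_frame()
        assert set(frame.columns) == {"a", "frame", "icc", "n_droplets"}
        assert len(frame) == len(surf.a_levels) * 40


class TestStrangersControl:
    def test_annihilates_synchronized_structure(self):
        # synchronized droplets (shared phase within droplet) + singleton pool
        rng = np.random.default_rng(4)
        t = np.arange(200) * 0.5
        sizes = [1] * 30 + [2] * 40 + [4] * 12
        rows = []
        for d, a in enumerate(sizes):
            phase = rng.uniform(0, 2 * np.pi)
            for j in range(a):
                jitter = rng.normal(0, 0.05) if a > 1 else rng.uniform(0, 2 * np.pi)
                rows.append(np.sin(2 * np.pi * t / 21.0 + phase + jitter)
                            + 0.05 * rng.normal(size=t.size))
        ts = droplet_ts(np.vstack(rows), sizes)
        real = icc_surface(ts)
        nulls = strangers_control(ts, n_reps=5, seed=0)
        real_mean = np.nanmean(np.abs(real.values))
        null_mean = np.mean([np.nanmean(np.abs(s.values)) for s in nulls])
        assert real_mean > 0.5
        assert null_mean < 0.2
        # replicate means scatter about zero
        null_signed = np.mean([np.nanmean(s.values) for s in nulls])
        assert abs(null_signed) < 0.1

    def test_requires_singletons(self):
        rng = np.random.default_rng(5)
        ts = droplet_ts(rng.normal(size=(4, 30)), [2, 2])
        with pytest.raises(ValueError, match="singleton"):
            strangers_control(ts, n_reps=2, seed=0)


class TestGarciaOjalvoR:
    def test_identical_trajectories(self):
        x = np.sin(np.arange(50) / 3.0)
        assert garcia_ojalvo_R(np.vstack([x, x, x])) == pytest.approx(1.0)

    def test_independent_noise_scales_inverse_a(self):
        rng = np.random.default_rng(6)
        a = 8
        vals = [garcia_ojalvo_R(rng.normal(size=(a, 500))) for _ in range(50)]
        assert np.mean(vals) == pytest.approx(1.0 / a, rel=0.15)

    def test_antiphase_pair_cancels(self):
        x = np.sin(np.arange(100) / 5.0)
        assert garcia_ojalvo_R(np.vstack([x, -x])) == pytest.approx(0.0, abs=1e-12)

    def test_flat_cells_flagged(self):
        assert np.isnan(garcia_ojalvo_R(np.ones((3, 20))))


class TestKuramotoOrder:
    def test_equal_phases(self):
        phases = np.tile(np.linspace(0, 10, 50), (4, 1))
        out = kuramoto_order(phases, ["d0"] * 4)
        assert out[4] == pytest.approx(1.0)

    def test_symmetric_four_phase_cancellation(self):
        phases = np.array([[0.0], [np.pi / 2], [np.pi], [3 * np.pi / 2]])
        out = kuramoto_order(phases, ["d0"] * 4)
        assert out[4] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_random_phases_scale(self):
        # modulus of a 2-D random walk: E[K] ~ sqrt(pi)/(2 sqrt(a))
        rng = np.random.default_rng(7)
        a = 16
        phases = rng.uniform(0, 2 * np.pi, size=(a, 4000))
        out = kuramoto_order(phases, ["d0"] * a)
        assert out[a] == pytest.approx(np.sqrt(np.pi) / (2 * np.sqrt(a)), rel=0.1)


def surface_from(values, a_levels, frames=None):
    from dropclock.synchrony import ICCSurface

    values = np.asarray(values, dtype=float)
    return ICCSurface(
        a_levels=np.asarray(a_levels),
        frames=np.arange(values.shape[1]) if frames is None else frames,
        values=values,
        n_droplets=np.full(len(a_levels), 10),
    )


class TestSurfaceRegression:
    def test_identity_surfaces(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(0, 1, size=(3, 60))
        fit = surface_regression(surface_from(v, [2, 3, 4]), surface_from(v, [2, 3, 4]))
        assert fit.slope == pytest.approx(1.0)
        assert all(abs(b) < 1e-10 for b in fit.intercepts.values())
        assert fit.r_squared == pytest.approx(1.0)

    def test_known_linear_recovery(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 1, size=(3, 80))
        c = {2: 0.1, 3: -0.2, 4: 0.3}
        y = 0.5 * x + np.array([[c[2]], [c[3]], [c[4]]])
        fit = surface_regression(surface_from(y, [2, 3, 4]), surface_from(x, [2, 3, 4]))
        assert fit.slope == pytest.approx(0.5, abs=1e-9)
        for a, b in fit.intercepts.items():
            assert b == pytest.approx(c[a], abs=1e-9)

    def test_independent_surfaces_r2_near_zero(self):
        rng = np.random.default_rng(10)
        y = rng.uniform(0, 1, size=(2, 300))
        x = rng.uniform(0, 1, size=(2, 300))
        fit = surface_regression(surface_from(y, [2, 3]), surface_from(x, [2, 3]))
        assert fit.r_squared < 0.05

    def test_mean_icc_reported_per_stratum(self):
        rng = np.random.default_rng(11)
        y = rng.uniform(0, 1, size=(2, 50))
        fit = surface_regression(surface_from(y, [2, 4]), surface_from(y, [2, 4]))
        for i, a in enumerate([2, 4]):
            assert fit.mean_icc_y[a][0] == pytest.approx(y[i].mean())


class TestPeriodVsDropletSize:
    def test_published_table_spearman(self):
        # per-size period statistics from the ten-day reference experiment
        tab = load_period_by_droplet_size()
        from dropclock.stats import spearman

        a = tab["a"].to_numpy(dtype=float)
        rs_mean, _ = spearman(a, tab["mean_period_primary"].to_numpy())
        rs_var, _ = spearman(a, tab["var_period_primary"].to_numpy())
        rs_mean2, _ = spearman(a, tab["mean_period_secondary"].to_numpy())
        rs_var2, _ = spearman(a, tab["var_period_secondary"].to_numpy())
        assert rs_mean == pytest.approx(0.3669, abs=1e-4)
        assert rs_var == pytest.approx(-0.6316, abs=1e-4)
        assert rs_mean2 == pytest.approx(0.7083, abs=1e-4)
        assert rs_var2 == pytest.approx(-0.7083, abs=1e-4)

    def test_monotone_column_gives_unit_correlation(self):
        periods = np.array([10.0, 10.0, 20.0, 20.0, 20.0, 30.0, 30.0, 30.0, 30.0])
        dids = ["d0", "d0", "d1", "d1", "d1", "d2", "d2", "d2", "d2"]
        tab, tests = period_vs_droplet_size(periods, dids)
        assert tests["mean_period"][0] == pytest.approx(1.0, abs=1e-12)

    def test_small_strata_dropped(self):
        periods = np.array([10.0, 12.0, 13.0])
        dids = ["d0", "d0", "d1"]  # singleton stratum has one cell
        tab, _ = period_vs_droplet_size(periods, dids)
        assert set(tab["a"]) == {2}
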