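"""Gaze density estimation, earth mover's distance, Proximity Index."""
import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from speechosc import (
    GazeGroupSpec,
    SimulationSpec,
    emd,
    emd_permutation_test,
    gaze_density,
    gen_gaze,
    proximity_index,
)
from speechosc.containers import GazeDensityMap

SCREEN = (1920.0, 1200.0)
GRID = (24, 15)


def _delta_map(i, j, nx=10, ny=6, cell=10.0):
    xs = np.arange(nx) * cell + cell / 2
    ys = np.arange(ny) * cell + cell / 2
    d = np.zeros((ny, nx))
    d[j, i] = 1.0 / cell**2
    return GazeDensityMap(xs=xs, ys=ys, density=d)


def _random_map(rng, nx=8, ny=5, cell=10.0):
    xs = np.arange(nx) * cell + cell / 2
    ys = np.arange(ny) * cell + cell / 2
    d = rng.random((ny, nx))
    d /= d.sum() * cell**2
    return GazeDensityMap(xs=xs, ys=ys, density=d)


def _assignment_oracle(map_a, map_b, units=60):
    """Independent EMD oracle: expand rational masses into equal unit atoms
    and solve the resulting assignment problem exactly."""
    def atoms(m):
        w = (m.density * m.cell_area).ravel()
        gx, gy = np.meshgrid(m.xs, m.ys)
        coords = np.column_stack([gx.ravel(), gy.ravel()])
        counts = np.round(w * units).astype(int)
        assert counts.sum() == units
        return np.repeat(coords, counts, axis=0)

    pa, pb = atoms(map_a), atoms(map_b)
    cost = np.linalg.norm(pa[:, None] - pb[None, :], axis=-1)
    r, c = linear_sum_assignment(cost)
    return cost[r, c].sum() / units


class TestGazeDensity:
    def test_single_point_gives_unimodal_unit_mass_map(self):
        m = gaze_density(np.array([[800.0, 500.0]]), SCREEN, GRID)
        j, i = np.unravel_index(np.argmax(m.density), m.density.shape)
        assert abs(m.xs[i] - 800.0) <= SCREEN[0] / GRID[0]
        assert abs(m.ys[j] - 500.0) <= SCREEN[1] / GRID[1]
        assert 0.99 <= m.mass() <= 1.01

    def test_two_separated_clusters_give_bimodal_map(self, rng):
        pts = np.vstack([rng.normal([400, 600], 40, (40, 2)),
                         rng.normal([1500, 600], 40, (40, 2))])
        m = gaze_density(pts, SCREEN, GRID)
        row = m.density[np.argmax(m.density.max(axis=1))]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(row, height=0.25 * row.max())
        assert len(peaks) >= 2

    def test_mass_conserved_for_random_point_sets(self, rng):
        for _ in range(5):
            pts = rng.uniform([0, 0], SCREEN, (12, 2))
            assert 0.99 <= gaze_density(pts, SCREEN, GRID).mass() <= 1.01

    def test_no_valid_points_is_an_error(self):
        with pytest.raises(ValueError, match="no valid"):
            gaze_density(np.array([[np.nan, 1.0], [-50.0, 1e6]]), SCREEN, GRID)


class TestEMD:
    def test_identical_maps_have_zero_distance(self, rng):
        m = _random_map(rng)
        assert emd(m, m) == pytest.approx(0.0, abs=1e-9)

    def test_point_mass_distance_is_exact(self):
        assert emd(_delta_map(1, 1), _delta_map(7, 1)) == pytest.approx(60.0)
        assert emd(_delta_map(0, 0), _delta_map(3, 4)) == pytest.approx(50.0)

    def test_translation_covariance(self):
        base = emd(_delta_map(2, 2), _delta_map(4, 2))
        shifted = emd(_delta_map(2, 2), _delta_map(5, 2))
        assert shifted - base == pytest.approx(10.0)

    def test_metric_axioms_on_random_triples(self, rng):
        for _ in range(6):
            a, b, c = (_random_map(rng) for _ in range(3))
            dab, dba = emd(a, b), emd(b, a)
            assert dab == pytest.approx(dba, rel=1e-6)
            assert emd(a, c) <= dab + emd(b, c) + 1e-6

    def test_three_by_three_matches_assignment_oracle(self):
        xs = np.array([5.0, 15.0, 25.0])
        ys = np.array([5.0, 15.0, 25.0])
        cell = 100.0
        da = np.array([[0.3, 0.1, 0.0], [0.0, 0.2, 0.1], [0.1, 0.0, 0.2]]) / cell
        db = np.array([[0.0, 0.2, 0.2], [0.3, 0.0, 0.0], [0.0, 0.2, 0.1]]) / cell
        a = GazeDensityMap(xs=xs, ys=ys, density=da)
        b = GazeDensityMap(xs=xs, ys=ys, density=db)
        oracle = _assignment_oracle(a, b, units=10)
        assert emd(a, b) == pytest.approx(oracle, rel=1e-9)

    def test_mass_mismatch_rejected(self, rng):
        m = _random_map(rng)
        bad = GazeDensityMap(xs=m.xs, ys=m.ys, density=m.density * 1.2)
        with pytest.raises(ValueError, match="mass"):
            emd(m, bad)

    def test_different_grids_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            emd(_random_map(rng, nx=8), _random_map(rng, nx=9))


class TestPermutationTest:
    def _gaze(self, separation_px, seed=0, n=6):
        mix_a = GazeGroupSpec(means=((700.0, 600.0), (700.0, 600.0)))
        mix_b = GazeGroupSpec(
            means=((700.0 + separation_px, 600.0), (700.0 + separation_px, 600.0))
        )
        spec = SimulationSpec(n_per_group=(n, n), n_frames=3, points_per_frame=4,
                              seed=seed, gaze_groups={"ASD": mix_a, "TD": mix_b})
        gaze, _ = gen_gaze(spec)
        group_of = {p: ("ASD" if p.startswith("ASD") else "TD")
                    for p in gaze["participant"].unique()}
        return gaze, group_of

    def test_separated_groups_detected_cumulatively(self):
        gaze, group_of = self._gaze(400.0, seed=1)
        res = emd_permutation_test(gaze, group_of, n_perm=40,
                                   rng=np.random.default_rng(0),
                                   grid_shape=(16, 10), max_support=80)
        assert res.significant
        assert res.rank == 41

    def test_rank_rule_and_pvalue_consistency(self):
        gaze, group_of = self._gaze(400.0, seed=2)
        res = emd_permutation_test(gaze, group_of, n_perm=40,
                                   rng=np.random.default_rng(0),
                                   grid_shape=(16, 10), max_support=80)
        assert 1 <= res.rank <= res.n_permutations + 1
        assert res.significant == (res.rank > int(np.ceil(0.975 * 40)))
        assert 0 < res.p_value() <= 1

    def test_single_frame_variant(self):
        gaze, group_of = self._gaze(500.0, seed=3)
        res = emd_permutation_test(gaze, group_of, frame=0, n_perm=30,
                                   rng=np.random.default_rng(0),
                                   grid_shape=(16, 10), max_support=80)
        assert res.observed > 0

    def test_too_small_groups_rejected(self):
        gaze, group_of = self._gaze(0.0, n=3)
        tiny = gaze[gaze["participant"].isin(["ASD01", "TD01", "TD02"])]
        with pytest.raises(ValueError, match="2 participants"):
            emd_permutation_test(tiny, group_of, n_perm=5)


class TestProximityIndex:
    def test_graded_divergence_preserves_ordering(self):
        # cohort individuals at increasing distance from the norm center:
        # mean PI must decrease monotonically with divergence
        rng = np.random.default_rng(0)
        frames = []
        import pandas as pd

        rows = []
        for fr in range(3):
            for p in range(6):  # norm group
                for k in range(4):
                    x, y = rng.normal([700, 600], 60)
                    rows.append(("TD%02d" % p, fr, 0.0, x, y))
            for i, dist in enumerate([0.0, 200.0, 500.0]):
                for k in range(4):
                    x, y = rng.normal([700 + dist, 600], 60)
                    rows.append(("ASD%02d" % i, fr, 0.0, x, y))
        gaze = pd.DataFrame(rows, columns=["participant", "frame", "t_ms",
                                           "x_px", "y_px"])
        pi = proximity_index(
            gaze, [f"TD{i:02d}" for i in range(6)],
            ["ASD00", "ASD01", "ASD02"], grid_shape=(16, 10),
        )
        vals = pi.set_index("participant")["mean_pi"]
        assert vals["ASD00"] > vals["ASD01"] > vals["ASD02"]

    def test_minmax_endpoints_per_frame(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        rows = []
        for p in range(5):
            for k in range(4):
                x, y = rng.normal([800, 600], 50)
                rows.append((f"TD{p:02d}", 0, 0.0, x, y))
        # one individual exactly on the norm, one far away
        for k in range(4):
            rows.append(("ASD00", 0, 0.0, *rng.normal([800, 600], 50)))
            rows.append(("ASD01", 0, 0.0, *rng.normal([1800, 200], 30)))
        gaze = pd.DataFrame(rows, columns=["participant", "frame", "t_ms",
                                           "x_px", "y_px"])
        pi = proximity_index(gaze, [f"TD{i:02d}" for i in range(5)],
                             ["ASD00", "ASD01"], grid_shape=(16, 10))
        vals = pi.set_index("participant")["mean_pi"]
        assert vals["ASD00"] == pytest.approx(1.0)
        assert vals["ASD01"] == pytest.approx(0.0)

    def test_missing_frames_excluded_with_count(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        rows = []
        for fr in range(2):
            for p in range(4):
                rows.append((f"TD{p:02d}", fr, 0.0, *rng.normal([800, 600], 50)))
            rows.append(("ASD00", fr, 0.0, *rng.normal([900, 600], 50)))
            rows.append(("ASD01", fr, 0.0, *rng.normal([1000, 600], 50)))
        # ASD02 only appears in frame 1
        rows.append(("ASD02", 1, 0.0, 1200.0, 600.0))
        gaze = pd.DataFrame(rows, columns=["participant", "frame", "t_ms",
                                           "x_px", "y_px"])
        pi = proximity_index(gaze, [f"TD{i:02d}" for i in range(4)],
                             ["ASD00", "ASD01", "ASD02"], grid_shape=(16, 10))
        n = pi.set_index("participant")["n_frames"]
        assert n["ASD00"] == 2 and n["ASD02"] == 1
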