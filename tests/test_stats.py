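"""Group statistics: pooled t, KS, cluster-based permutation tests."""
import numpy as np
import pytest

from speechosc import (
    electrode_cluster_test,
    group_t_pooled,
    ks_two_sample,
    load_reference_cohort,
    make_synthetic_montage,
    montage_adjacency,
    pac_cluster_test,
)


@pytest.fixture(scope="module")
def cohort():
    return load_reference_cohort()


@pytest.fixture(scope="module")
def adjacency110():
    pos = np.array(list(make_synthetic_montage(110).values()))
    return montage_adjacency(pos)


class TestPooledT:
    def test_identical_samples_give_zero(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = group_t_pooled(x, x.copy())
        assert res.statistic == pytest.approx(0.0)
        assert res.eta_sq == pytest.approx(0.0)

    def test_hand_computed_small_case(self):
        res = group_t_pooled([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4

    def test_mullen_receptive_language_from_cohort(self, cohort):
        a = cohort[cohort.group == "ASD"]["mullen_rl_dq"]
        t = cohort[cohort.group == "TD"]["mullen_rl_dq"]
        res = group_t_pooled(a, t)
        assert res.statistic == pytest.approx(-7.71, abs=0.02)
        assert res.df == 56  # pairwise-complete deletion: 30 + 28 - 2
        assert (res.n_x, res.n_y) == (30, 28)

    def test_missing_values_excluded_per_variable(self, cohort):
        a = cohort[cohort.group == "ASD"]["mullen_el_dq"]
        t = cohort[cohort.group == "TD"]["mullen_el_dq"]
        assert group_t_pooled(a, t).df == 55  # one extra missing TD cell

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            group_t_pooled([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            group_t_pooled([1.0, 1.0], [1.0, 1.0])


class TestKS:
    def test_identical_samples_give_zero(self, rng):
        x = rng.standard_normal(30)
        assert ks_two_sample(x, x.copy()).statistic == 0.0

    def test_disjoint_supports_give_one(self):
        assert ks_two_sample([1.0, 2.0, 3.0], [10.0, 11.0]).statistic == 1.0

    def test_cohort_age_comparison(self, cohort):
        a = cohort[cohort.group == "ASD"]["age"]
        t = cohort[cohort.group == "TD"]["age"]
        res = ks_two_sample(a, t)
        assert res.statistic == pytest.approx(0.27, abs=0.005)
        assert res.p > 0.05


class TestElectrodeClusterTest:
    def test_isolated_suprathreshold_electrode_forms_no_cluster(self, adjacency110,
                                                                rng):
        vals = rng.standard_normal((40, 110)) * 0.01
        vals[:20, 0] += 10.0  # huge effect on one electrode only
        groups = np.array(["A"] * 20 + ["B"] * 20)
        res = electrode_cluster_test(vals, groups, adjacency110, n_perm=50, rng=rng)
        assert all(0 not in c["members"] or len(c["members"]) >= 2
                   for c in res.clusters)
        assert not any(c["members"] == [0] for c in res.clusters)

    def test_planted_patch_recovered_with_covariate(self, adjacency110, rng):
        patch = np.r_[0, adjacency110[0].nonzero()[1][:4]]
        vals = rng.standard_normal((60, 110))
        vals[30:, patch] += 1.2
        groups = np.array(["A"] * 30 + ["B"] * 30)
        res = electrode_cluster_test(vals, groups, adjacency110,
                                     covariate=rng.standard_normal(60),
                                     n_perm=200, rng=rng)
        sig = {m for c in res.significant() for m in c["members"]}
        assert len(sig & set(patch.tolist())) >= 3

    def test_cluster_membership_invariant_to_relabeling(self, rng):
        pos = np.array(list(make_synthetic_montage(30).values()))
        adj = montage_adjacency(pos)
        vals = rng.standard_normal((30, 30))
        vals[15:, :6] += 1.5
        groups = np.array(["A"] * 15 + ["B"] * 15)
        res1 = electrode_cluster_test(vals, groups, adj, n_perm=100,
                                      rng=np.random.default_rng(5))
        perm = np.random.default_rng(1).permutation(30)
        res2 = electrode_cluster_test(vals[:, perm], groups, adj[np.ix_(perm, perm)],
                                      n_perm=100, rng=np.random.default_rng(5))
        m1 = sorted(tuple(sorted(c["members"])) for c in res1.clusters)
        m2 = sorted(tuple(sorted(int(perm[m]) for m in c["members"]))
                    for c in res2.clusters)
        assert m1 == m2

    def test_null_family_wise_error_controlled(self, rng):
        # quick check; the full 500-dataset calibration runs in the
        # acceptance suite
        pos = np.array(list(make_synthetic_montage(40).values()))
        adj = montage_adjacency(pos)
        groups = np.array(["A"] * 12 + ["B"] * 12)
        hits = 0
        for _ in range(60):
            vals = rng.standard_normal((24, 40))
            res = electrode_cluster_test(vals, groups, adj, n_perm=100, rng=rng)
            hits += bool(res.significant())
        assert hits <= 10  # ~5% nominal, generous binomial slack at 60 runs

    def test_covariate_schemes_agree_on_strong_effects(self, adjacency110, rng):
        patch = np.r_[0, adjacency110[0].nonzero()[1][:4]]
        vals = rng.standard_normal((60, 110))
        vals[30:, patch] += 2.0
        groups = np.array(["A"] * 30 + ["B"] * 30)
        cov = rng.standard_normal(60)
        for scheme in ("freedman-lane", "shuffle-covariate"):
            res = electrode_cluster_test(vals, groups, adjacency110, covariate=cov,
                                         n_perm=100, rng=rng,
                                         covariate_scheme=scheme)
            assert len(res.significant()) >= 1

    def test_too_small_groups_rejected(self, adjacency110, rng):
        vals = rng.standard_normal((3, 110))
        with pytest.raises(ValueError, match="2 participants"):
            electrode_cluster_test(vals, np.array(["A", "A", "B"]), adjacency110)


class TestPacClusterTest:
    def test_planted_speech_coupling_detected(self, rng):
        n, shape = 16, (14, 18)
        base = rng.standard_normal((n, *shape)) * 0.01 + 0.05
        speech = base + rng.standard_normal((n, *shape)) * 0.01
        speech[:, 4, 10] += 0.04  # coupling in the speech window only
        res = pac_cluster_test(speech, base, n_perm=200, rng=rng)
        sig_cells = {m for c in res.significant() for m in c["members"]}
        assert (4, 10) in sig_cells

    def test_identical_conditions_rarely_significant(self, rng):
        hits = 0
        for _ in range(40):
            n = 12
            base = rng.standard_normal((n, 14, 18)) * 0.01 + 0.05
            speech = base + rng.standard_normal((n, 14, 18)) * 0.01
            res = pac_cluster_test(speech, base, n_perm=100, rng=rng)
            hits += bool(res.significant())
        assert hits <= 8  # ~5% nominal; binomial slack at 40 runs

    def test_single_cell_cluster_allowed_on_the_grid(self, rng):
        n = 10
        base = np.full((n, 6, 6), 0.05) + rng.standard_normal((n, 6, 6)) * 0.002
        speech = base + rng.standard_normal((n, 6, 6)) * 0.002
        speech[:, 2, 3] += 0.05
        res = pac_cluster_test(speech, base, n_perm=100, rng=rng)
        assert any(len(c["members"]) == 1 and c["members"][0] == (2, 3)
                   for c in res.clusters)

    def test_unpaired_input_rejected(self, rng):
        with pytest.raises(ValueError, match="paired"):
            pac_cluster_test(rng.random((5, 4, 4)), rng.random((6, 4, 4)))
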