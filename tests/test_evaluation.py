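"""Cross-validation machinery, predictive ability, sparse design, leakage."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtgp import (
    BlueTable,
    GibbsConfig,
    build_sparse_design,
    fit_gblup,
    make_cv1_partitions,
    percent_improvement,
    predict_st,
    predictive_ability,
    run_mt_cv,
    run_mtme_cv,
    run_st_cv1,
)


class TestPartitions:
    def test_sizes_and_disjointness(self):
        parts = make_cv1_partitions([f"l{i}" for i in range(10)], reps=3, seed=0)
        assert len(parts) == 3
        for p in parts:
            assert len(p.train_ids) == 8 and len(p.test_ids) == 2
            assert not set(p.train_ids) & set(p.test_ids)
            assert set(p.train_ids) | set(p.test_ids) == {f"l{i}" for i in range(10)}

    def test_seed_reproducibility(self):
        a = make_cv1_partitions([f"l{i}" for i in range(20)], reps=5, seed=3)
        b = make_cv1_partitions([f"l{i}" for i in range(20)], reps=5, seed=3)
        assert all(x.test_ids == y.test_ids for x, y in zip(a, b))

    def test_test_frequency_close_to_one_fifth(self):
        ids = [f"l{i}" for i in range(100)]
        parts = make_cv1_partitions(ids, reps=1000, seed=1)
        counts = pd.Series(
            [l for p in parts for l in p.test_ids]).value_counts() / 1000
        assert counts.min() >= 0.15 and counts.max() <= 0.25

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_cv1_partitions(["a"] * 5 + ["b"] * 4, reps=1, seed=0)
        with pytest.raises(ValueError):
            make_cv1_partitions([f"l{i}" for i in range(20)], train_frac=1.0,
                                reps=1, seed=0)


class TestPredictiveAbility:
    @pytest.mark.parametrize(
        "pred, obs, expected",
        [
            ((1, 2, 3), (1, 2, 3), 1.0),
            ((1, 2, 3), (3, 2, 1), -1.0),
            ((1, 2, 3, 4), (1.1, 1.9, 3.2, 3.8), 4.7 / np.sqrt(22.5)),
        ],
    )
    def test_pearson_examples(self, pred, obs, expected):
        assert predictive_ability(pred, obs) == pytest.approx(expected, abs=1e-4)

    def test_zero_variance_or_short_input_is_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(predictive_ability([1, 1, 1], [1, 2, 3]))
        assert np.isnan(predictive_ability([1, 2], [1, 2]))

    @given(
        st.floats(0.1, 10.0),
        st.floats(-5.0, 5.0),
        st.integers(0, 100),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_positive_affine_maps(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r0 = predictive_ability(x, y)
        r1 = predictive_ability(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-10)


class TestPercentImprovement:
    def test_formula(self):
        assert percent_improvement(0.5, 0.4) == pytest.approx(25.0)
        assert percent_improvement(0.4, 0.4) == 0.0
        # a 0.59 mean PA over a 0.36 baseline rounds to a reported "63%"
        assert percent_improvement(0.59, 0.36) == pytest.approx(63.9, abs=0.1)

    def test_nonpositive_baseline_is_missing(self):
        with pytest.warns(UserWarning):
            assert np.isnan(percent_improvement(0.5, 0.0))


def _noise_blues(n=150, seed=4, envs=("E1",), trait="T"):
    rng = np.random.default_rng(seed)
    ids = [f"l{i:03d}" for i in range(n)]
    rows = [(l, e, trait, rng.normal()) for e in envs for l in ids]
    return BlueTable(pd.DataFrame(rows, columns=["line", "env", "trait", "value"]))


class TestStCv1:
    def test_result_shape(self, small_single_trait):
        res = run_st_cv1(small_single_trait["blues"], small_single_trait["G"],
                         ["YLD"], ["E1"], reps=3, seed=0)
        assert len(res.records) == 3
        assert set(res.records["model"]) == {"st_cv1"}
        summ = res.summary()
        assert summ["n_rep"].iloc[0] == 3
        assert summ["mean_pa"].iloc[0] == pytest.approx(res.records["pa"].mean())

    def test_null_phenotype_has_no_predictive_ability(self, small_single_trait):
        """Mean PA under a pure-noise phenotype is zero.  Repetitions on one
        noise vector are correlated, so average over independent draws."""
        G = small_single_trait["G"]
        means = []
        for seed in range(6):
            rng = np.random.default_rng(100 + seed)
            bt = BlueTable(pd.DataFrame({
                "line": G.ids, "env": "E1", "trait": "T",
                "value": rng.normal(size=G.n)}))
            res = run_st_cv1(bt, G, ["T"], ["E1"], reps=12, seed=seed)
            means.append(res.mean_pa())
        assert abs(np.mean(means)) < 0.1

    def test_noiseless_eigenvector_phenotype_predicted_almost_perfectly(
            self, small_single_trait):
        G = small_single_trait["G"]
        w, V = np.linalg.eigh(G.values)
        bt = BlueTable(pd.DataFrame({
            "line": G.ids, "env": "E1", "trait": "T", "value": 10 * V[:, -1]}))
        res = run_st_cv1(bt, G, ["T"], ["E1"], reps=15, seed=2)
        assert res.mean_pa() > 0.9


class TestLeakage:
    def test_st_cv1_fitting_input_excludes_test_lines(self, small_single_trait):
        captured = []
        run_st_cv1(small_single_trait["blues"], small_single_trait["G"],
                   ["YLD"], ["E1"], reps=2, seed=3,
                   audit=lambda *a: captured.append(a))
        parts = make_cv1_partitions(
            sorted(set(small_single_trait["blues"].df["line"])), reps=2, seed=3)
        for (tag, rep, env, trait, y_train), part in zip(captured, parts):
            assert tag == "st_cv1"
            assert not set(y_train.index) & set(part.test_ids)

    def test_perturbing_heldout_phenotypes_leaves_predictions_unchanged(
            self, small_single_trait):
        G = small_single_trait["G"]
        y = small_single_trait["blues"].series("E1", "YLD")
        test = list(y.index[:20])
        y2 = y.copy()
        y2.loc[test] += 100.0  # arbitrary corruption of held-out data
        f1 = fit_gblup(y.drop(test), G)
        f2 = fit_gblup(y2.drop(test), G)
        pd.testing.assert_series_equal(predict_st(f1, test), predict_st(f2, test))

    def test_mt_cv_masks_follow_the_scheme(self, small_two_trait, quick_chain):
        captured = {}

        def audit(tag, rep, env, trait, Ymask):
            captured.setdefault(tag, []).append(Ymask.copy())

        for scheme in ("cv1", "cv2"):
            run_mt_cv(small_two_trait["blues"], small_two_trait["G"],
                      ["A", "B"], ["E1"], scheme, "A", reps=1, seed=5,
                      cfg=quick_chain, audit=audit)
        lines = sorted(set(small_two_trait["blues"].df["line"]))
        part = make_cv1_partitions(lines, reps=1, seed=5)[0]
        cv1_mask = captured["mt_cv1"][0]
        cv2_mask = captured["mt_cv2"][0]
        in_test = cv1_mask.index.isin(part.test_ids)
        assert cv1_mask.loc[in_test].isna().all().all()
        assert cv2_mask.loc[in_test, "A"].isna().all()
        assert cv2_mask.loc[in_test, "B"].notna().any()
        assert cv2_mask.loc[~in_test, "A"].notna().all()


class TestMtmeCv:
    def test_result_covers_all_cells(self, tiny_two_env):
        bt, G, cfg = tiny_two_env
        res = run_mtme_cv(bt, G, ["A", "B"], cfg.env_ids, reps=2, seed=6,
                          cfg=GibbsConfig(150, 600, 2, seed=0))
        assert len(res.records) == 2 * 2 * 2
        assert res.records["pa"].notna().all()

    def test_masks_cover_every_environment(self, tiny_two_env):
        bt, G, cfg = tiny_two_env
        captured = []
        run_mtme_cv(bt, G, ["A", "B"], cfg.env_ids, reps=1, seed=7,
                    cfg=GibbsConfig(150, 600, 2, seed=0),
                    audit=lambda *a: captured.append(a[4]))
        lines = sorted(set(bt.df["line"]) & set(G.ids))
        part = make_cv1_partitions(lines, reps=1, seed=7)[0]
        Ymask = captured[0]
        n = len(lines)
        for l in part.test_ids:
            i = lines.index(l)
            assert np.isnan(Ymask[[i, n + i], :]).all()


@pytest.fixture(scope="module")
def tiny_two_env():
    from mtgp import (SimConfig, fit_env_blues, grm_vanraden, make_psd,
                      simulate_genotypes, simulate_phenotypes)

    cfg = SimConfig(n_lines=40, n_markers=300, n_families=4, n_envs=2,
                    trait_names=("A", "B"), h2={"A": 0.6, "B": 0.6},
                    genetic_sd={"A": 1.0, "B": 1.0},
                    Sigma_t_corr=np.array([[1.0, 0.5], [0.5, 1.0]]),
                    Sigma_E_corr=np.array([[1.0, 0.6], [0.6, 1.0]]),
                    seed=15)
    g = simulate_genotypes(cfg)
    plot, _ = simulate_phenotypes(g, cfg)
    G = make_psd(grm_vanraden(g))
    bt = BlueTable.concat([fit_env_blues(plot, e, t)[0]
                           for e in cfg.env_ids for t in cfg.trait_names])
    return bt, G, cfg


class TestSparseDesign:
    def test_mask_size(self):
        d = build_sparse_design(
            [f"e{i}" for i in range(40)], [f"a{i}" for i in range(110)],
            [f"E{i}" for i in range(1, 6)], ["E1", "E2", "E3"])
        assert len(d.mask) == 220
        assert d.test_envs == ["E4", "E5"]

    def test_single_test_environment(self):
        d = build_sparse_design(["e1"], ["a1", "a2"],
                                ["E1", "E2", "E3"], ["E1", "E2"])
        assert {env for _, env in d.mask} == {"E3"}

    def test_empty_advanced_set_warns(self):
        with pytest.warns(UserWarning, match="empty advanced"):
            d = build_sparse_design(["e1"], [], ["E1", "E2"], ["E1"])
        assert d.mask == set()

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError, match="held-out"):
            build_sparse_design(["e1"], ["a1"], ["E1"], ["E1"])
        with pytest.raises(ValueError, match="overlap"):
            build_sparse_design(["x"], ["x"], ["E1", "E2"], ["E1"])
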