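"""BLUEs, REML variance components, heritability and correlations."""
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mtgp import (
    BlueTable,
    PlotTable,
    VarComp,
    env_correlations,
    fit_across_env,
    fit_env_blues,
    genetic_correlations_from_fit,
    heritability,
    reml_two_component,
    trait_correlations,
)


class TestEnvBlues:
    def test_balanced_blues_are_line_means(self, balanced_plot_table):
        bt, vc = fit_env_blues(balanced_plot_table, "E1", "T")
        s = bt.series("E1", "T")
        assert s["g1"] == pytest.approx(5.0, abs=1e-7)
        assert s["g2"] == pytest.approx(9.0, abs=1e-7)
        assert vc.available and vc.n_rep == 2

    def test_single_replicate_returns_observed_values(self):
        df = pd.DataFrame({"line": ["g1", "g2"], "env": "E1", "rep": "R1",
                           "trait": "T", "value": [3.0, 7.0]})
        bt, vc = fit_env_blues(PlotTable(df), "E1", "T")
        assert bt.series("E1", "T").to_dict() == {"g1": 3.0, "g2": 7.0}
        assert not vc.available and np.isnan(heritability(vc))

    def test_constant_phenotype_gives_zero_genetic_variance(self):
        df = pd.DataFrame({
            "line": ["g1", "g1", "g2", "g2"], "env": "E1",
            "rep": ["R1", "R2", "R1", "R2"], "trait": "T", "value": 4.0,
        })
        bt, vc = fit_env_blues(PlotTable(df), "E1", "T")
        assert np.allclose(bt.series("E1", "T"), 4.0)
        assert vc.sigma_g2 == 0.0

    def test_line_without_observations_omitted_with_warning(self):
        df = pd.DataFrame({
            "line": ["g1", "g1", "g2", "g2", "g3"],
            "env": ["E1", "E1", "E1", "E1", "E2"],
            "rep": ["R1", "R2", "R1", "R2", "R1"],
            "trait": "T", "value": [4.0, 6.0, 8.0, 10.0, 5.0],
        })
        with pytest.warns(UserWarning, match="omitted"):
            bt, _ = fit_env_blues(PlotTable(df), "E1", "T")
        assert "g3" not in set(bt.df["line"])


class TestAcrossEnv:
    def _pt(self, gxe=0.0):
        rows = []
        for li, base in (("g1", 5.0), ("g2", 9.0)):
            for e, off in (("E1", 0.0), ("E2", 2.0)):
                for r in ("R1", "R2"):
                    inter = gxe if (li, e) == ("g2", "E2") else 0.0
                    rows.append((li, e, r, "T", base + off + inter))
        return PlotTable(pd.DataFrame(
            rows, columns=["line", "env", "rep", "trait", "value"]))

    def test_balanced_noiseless_blues_are_line_means(self):
        bt, _ = fit_across_env(self._pt(), "T", "blue")
        s = bt.series("ALL", "T")
        assert s["g1"] == pytest.approx(6.0, abs=1e-6)
        assert s["g2"] == pytest.approx(10.0, abs=1e-6)

    def test_identical_envs_match_per_env_blues(self):
        rows = []
        for li, base in (("g1", 4.0), ("g2", 8.0)):
            for e in ("E1", "E2"):
                for r, off in (("R1", -1.0), ("R2", 1.0)):
                    rows.append((li, e, r, "T", base + off))
        pt = PlotTable(pd.DataFrame(
            rows, columns=["line", "env", "rep", "trait", "value"]))
        across, _ = fit_across_env(pt, "T", "blue")
        per_env, _ = fit_env_blues(pt, "E1", "T")
        np.testing.assert_allclose(
            across.series("ALL", "T").sort_index(),
            per_env.series("E1", "T").sort_index(), atol=1e-6,
        )

    def test_blup_full_shrinkage_without_genetic_variance(self):
        rows = []
        rng = np.random.default_rng(0)
        for li in ("g1", "g2", "g3", "g4"):
            for e in ("E1", "E2"):
                for r in ("R1", "R2"):
                    rows.append((li, e, r, "T", 10.0 + rng.normal(0, 1e-12)))
        pt = PlotTable(pd.DataFrame(
            rows, columns=["line", "env", "rep", "trait", "value"]))
        bt, vc = fit_across_env(pt, "T", "blup")
        assert np.allclose(bt.series("ALL", "T"), 10.0, atol=1e-6)

    def test_absent_trait_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            fit_across_env(self._pt(), "NOPE", "blue")


class TestRemlTwoComponent:
    def test_balanced_anova_closed_form(self):
        vc = reml_two_component([1.0, 3.0, 5.0, 7.0], ["g1", "g1", "g2", "g2"])
        assert vc.sigma_e2 == pytest.approx(2.0, rel=1e-4)
        assert vc.sigma_g2 == pytest.approx(7.0, rel=1e-4)

    def test_matches_lme4_on_unbalanced_data(self, tmp_path):
        """Independent REML oracle: lme4's lmer on the one-way model."""
        rng = np.random.default_rng(42)
        groups, values = [], []
        for i, k in enumerate([2, 3, 2, 4, 3, 2, 3, 2]):
            eff = rng.normal(0, 2.0)
            for _ in range(k):
                groups.append(f"g{i}")
                values.append(10 + eff + rng.normal(0, 1.0))
        df = pd.DataFrame({"g": groups, "y": values})
        df.to_csv(tmp_path / "d.csv", index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{tmp_path / 'd.csv'}")
            m <- lmer(y ~ 1 + (1|g), data=d, REML=TRUE)
            vc <- as.data.frame(VarCorr(m))
            cat(vc$vcov[1], vc$vcov[2], sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        sg_r, se_r = map(float, out.stdout.split())
        vc = reml_two_component(values, groups)
        assert vc.sigma_g2 == pytest.approx(sg_r, rel=1e-3, abs=1e-6)
        assert vc.sigma_e2 == pytest.approx(se_r, rel=1e-3, abs=1e-6)

    def test_internally_identical_groups_give_zero_residual(self):
        vc = reml_two_component([1.0, 1.0, 5.0, 5.0], ["a", "a", "b", "b"])
        assert vc.sigma_e2 == pytest.approx(0.0, abs=1e-8)

    def test_all_equal_gives_zero_components(self):
        vc = reml_two_component([2.0] * 6, ["a", "a", "b", "b", "c", "c"])
        assert vc.sigma_g2 == 0.0 and vc.sigma_e2 == 0.0

    def test_no_replication_rejected(self):
        with pytest.raises(ValueError):
            reml_two_component([1.0, 2.0, 3.0], ["a", "b", "c"])


class TestHeritability:
    def test_direct_substitution(self):
        assert heritability(VarComp(7.0, 2.0, n_rep=2)) == pytest.approx(0.875)

    def test_limits(self):
        assert heritability(VarComp(3.0, 0.0, n_rep=2)) == 1.0
        assert heritability(VarComp(0.0, 3.0, n_rep=2)) == 0.0

    def test_undefined_when_degenerate(self):
        with pytest.warns(UserWarning):
            assert np.isnan(heritability(VarComp(0.0, 0.0, n_rep=2)))

    def test_monotone_in_replication_and_genetic_variance(self):
        h = [heritability(VarComp(2.0, 4.0, n_rep=r)) for r in (1, 2, 4, 8)]
        assert all(a < b for a, b in zip(h, h[1:]))
        h2 = [heritability(VarComp(s, 4.0, n_rep=2)) for s in (1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(h2, h2[1:]))


def _blue_table(values: dict, env="E1"):
    rows = []
    for trait, series in values.items():
        for line, v in series.items():
            rows.append((line, env, trait, v))
    return BlueTable(pd.DataFrame(rows, columns=["line", "env", "trait", "value"]))


class TestCorrelations:
    def test_affine_traits_perfectly_correlated(self):
        a = {f"l{i}": float(i) for i in range(10)}
        bt = _blue_table({"A": a, "B": {k: 2 * v + 1 for k, v in a.items()},
                          "C": {k: -v for k, v in a.items()}})
        m = trait_correlations(bt, ["A", "B", "C"]).to_frame()
        assert m.loc["A", "B"] == pytest.approx(1.0)
        assert m.loc["A", "C"] == pytest.approx(-1.0)

    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(1)
        lines = [f"l{i}" for i in range(1000)]
        bt = _blue_table({
            "A": dict(zip(lines, rng.normal(size=1000))),
            "B": dict(zip(lines, rng.normal(size=1000))),
        })
        r = trait_correlations(bt, ["A", "B"]).values[0, 1]
        assert abs(r) < 0.1

    def test_zero_variance_trait_flagged(self):
        a = {f"l{i}": float(i) for i in range(5)}
        bt = _blue_table({"A": a, "B": {k: 1.0 for k in a}})
        with pytest.warns(UserWarning, match="zero-variance"):
            m = trait_correlations(bt, ["A", "B"])
        assert np.isnan(m.values[0, 1])

    def test_env_correlations(self):
        rng = np.random.default_rng(2)
        lines = [f"l{i}" for i in range(500)]
        rho = 0.7
        L = np.linalg.cholesky([[1, rho], [rho, 1]])
        z = rng.standard_normal((500, 2)) @ L.T
        rows = [(l, env, "T", z[i, e]) for i, l in enumerate(lines)
                for e, env in enumerate(["E1", "E2"])]
        bt = BlueTable(pd.DataFrame(rows, columns=["line", "env", "trait", "value"]))
        m = env_correlations(bt, "T")
        assert m.values[0, 1] == pytest.approx(rho, abs=0.1)
        # a duplicated environment correlates perfectly
        rows_dup = rows + [(l, "E3", "T", z[i, 1]) for i, l in enumerate(lines)]
        m2 = env_correlations(
            BlueTable(pd.DataFrame(rows_dup, columns=["line", "env", "trait", "value"])),
            "T")
        assert m2.to_frame().loc["E2", "E3"] == pytest.approx(1.0)


class TestGeneticCorrelations:
    class FakeFit:
        def __init__(self, S, names):
            self.Sigma_t = S
            self.trait_names = names

    def test_identity_and_diagonal(self):
        m = genetic_correlations_from_fit(self.FakeFit(np.eye(2), ["A", "B"]))
        np.testing.assert_allclose(m.values, np.eye(2))
        m2 = genetic_correlations_from_fit(
            self.FakeFit(np.diag([4.0, 9.0]), ["A", "B"]))
        assert m2.values[0, 1] == pytest.approx(0.0)

    def test_off_diagonal_scaling(self):
        S = np.array([[4.0, 2.0], [2.0, 4.0]])
        m = genetic_correlations_from_fit(self.FakeFit(S, ["A", "B"]))
        assert m.values[0, 1] == pytest.approx(0.5)

    def test_non_psd_repaired_with_warning(self):
        S = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.warns(UserWarning, match="repair"):
            m = genetic_correlations_from_fit(self.FakeFit(S, ["A", "B"]))
        assert np.all(np.abs(m.values) <= 1.0 + 1e-9)
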