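import numpy as np
import pandas as pd
import pytest

from wetlandflux.attribution import (
    build_unit_summaries,
    fit_path_model,
    hurricane_damage_ratio,
    pca,
    prune_variables,
    significance_stars,
)
from wetlandflux.synth import HABITATS, HabitatMap


def _unit_table(n=200, seed=0, a=0.5, b=0.6, c=-0.3):
    """Synthetic standardized unit table with known path structure
    x1 -> m -> y, x2 -> y; all variables unit variance in population."""
    rng = np.random.default_rng(seed)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    m = a * x1 + np.sqrt(1 - a**2) * rng.standard_normal(n)
    noise_var = 1 - b**2 - c**2 - 2 * b * c * 0.0
    y = b * m + c * x2 + np.sqrt(noise_var) * rng.standard_normal(n)
    return pd.DataFrame({"x1": x1, "x2": x2, "m": m, "y": y})


class TestUnitSummaries:
    def _hab(self):
        labels = np.zeros((4, 4), dtype=int)
        labels[:, 2:] = HABITATS.index("freshwater_marsh")
        return HabitatMap(labels=labels)  # west half mangrove, east half marsh

    def test_pure_unit_is_100_percent(self):
        units = np.zeros((4, 4), dtype=int)
        units[:, 2:] = 1
        out = build_unit_summaries(units, self._hab(), {})
        assert out.loc[out.unit_id == 0, "pct_mangrove"].iloc[0] == 100.0
        assert out.loc[out.unit_id == 1, "pct_freshwater_marsh"].iloc[0] == 100.0

    def test_even_split_is_50_50(self):
        units = np.zeros((4, 4), dtype=int)  # one unit spanning both habitats
        out = build_unit_summaries(units, self._hab(), {})
        assert out.loc[0, "pct_mangrove"] == 50.0
        assert out.loc[0, "pct_freshwater_marsh"] == 50.0

    def test_zonal_statistics_match_hand_computation(self):
        rng = np.random.default_rng(1)
        units = (np.arange(16) % 4).reshape(4, 4)
        mass = {"CO2": {2021: rng.normal(size=(4, 4))}}
        ind = {"wetness": rng.random((4, 4))}
        out = build_unit_summaries(units, self._hab(), mass, indicator_rasters=ind)
        for unit in (0, 2, 3):
            sel = units == unit
            row = out[out.unit_id == unit].iloc[0]
            assert row["mean_co2"] == pytest.approx(mass["CO2"][2021][sel].sum())
            assert row["wetness"] == pytest.approx(ind["wetness"][sel].mean())


class TestPCA:
    def test_two_perfectly_correlated_variables(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"a": x, "b": 2.0 * x + 1.0})
        res = pca(df, ["a", "b"])
        assert res.percent_variance[0] == pytest.approx(100.0)
        np.testing.assert_allclose(res.loadings["PC1"].to_numpy(),
                                   [1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        res = pca(df, list("abcde"))
        Z = (df - df.mean()) / df.std(ddof=1)
        _, sing, vt = np.linalg.svd(Z.to_numpy() / np.sqrt(len(df) - 1),
                                    full_matrices=False)
        np.testing.assert_allclose(res.eigenvalues, sing**2, atol=1e-8)
        np.testing.assert_allclose(np.abs(res.loadings.to_numpy()),
                                   np.abs(vt.T), atol=1e-8)

    def test_percent_variance_and_reconstruction(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        res = pca(df, list("abcd"))
        assert res.percent_variance.sum() == pytest.approx(100.0)
        Z = ((df - df.mean()) / df.std(ddof=1)).to_numpy()
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, Z, atol=1e-8)

    def test_constant_variable_named_in_error(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="b"):
            pca(df, ["a", "b"])

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        res1 = pca(df, list("abc"))
        res2 = pca(df.sample(frac=1.0, random_state=0).reset_index(drop=True),
                   list("abc"))
        np.testing.assert_allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)
        np.testing.assert_allclose(res1.loadings.to_numpy(),
                                   res2.loadings.to_numpy(), atol=1e-10)


class TestPrune:
    def test_zero_threshold_prunes_nothing(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        kept, _ = prune_variables(df, list("abcd"), threshold=0.0)
        assert kept == list("abcd")

    def test_noise_variable_pruned_first(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(100)
        df = pd.DataFrame({
            "s1": x + 0.05 * rng.standard_normal(100),
            "s2": -x + 0.05 * rng.standard_normal(100),
            "s3": 2 * x + 0.05 * rng.standard_normal(100),
            "noise": rng.standard_normal(100),
        })
        kept, _ = prune_variables(df, ["s1", "s2", "s3", "noise"], threshold=0.5)
        assert "noise" not in kept
        assert {"s1", "s2", "s3"} <= set(kept)

    def test_pruning_is_idempotent_at_convergence(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(60)
        df = pd.DataFrame({"a": x, "b": x + 0.1 * rng.standard_normal(60),
                           "c": rng.standard_normal(60)})
        kept, _ = prune_variables(df, ["a", "b", "c"], threshold=0.5)
        kept2, _ = prune_variables(df, kept, threshold=0.5)
        assert kept == kept2


class TestPathModel:
    def test_single_edge_equals_pearson_correlation(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(100)
        y = 0.5 * x + rng.standard_normal(100)
        df = pd.DataFrame({"x": x, "y": y})
        model = fit_path_model([("x", "y")], df)
        assert model.edges.iloc[0]["coef"] == pytest.approx(
            np.corrcoef(x, y)[0, 1], abs=1e-10)

    def test_null_coefficient_near_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.standard_normal(200),
                           "y": rng.standard_normal(200)})
        model = fit_path_model([("x", "y")], df)
        assert abs(model.edges.iloc[0]["coef"]) < 0.2

    def test_chain_indirect_effect_is_product_of_paths(self):
        df = _unit_table()
        model = fit_path_model([("x1", "m"), ("m", "y"), ("x2", "y")], df)
        coefs = {(r["from"], r["to"]): r["coef"] for _, r in model.edges.iterrows()}
        ind = model.indirect
        effect = ind[(ind.source == "x1") & (ind.target == "y")]["effect"].iloc[0]
        assert effect == pytest.approx(coefs[("x1", "m")] * coefs[("m", "y")], abs=1e-12)

    def test_known_coefficients_recovered_within_2_se(self):
        df = _unit_table(n=200, seed=0)
        model = fit_path_model([("x1", "m"), ("m", "y"), ("x2", "y")], df)
        truth = {("x1", "m"): 0.5, ("m", "y"): 0.6, ("x2", "y"): -0.3}
        for _, row in model.edges.iterrows():
            true_coef = truth[(row["from"], row["to"])]
            assert abs(row["coef"] - true_coef) < 2 * row["se"]

    def test_cyclic_spec_rejected(self):
        df = _unit_table()
        with pytest.raises(ValueError, match="cycle"):
            fit_path_model([("x1", "y"), ("y", "x1")], df)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(50)
        df = pd.DataFrame({"x1": x, "x2": x * (1 + 1e-12),
                           "y": rng.standard_normal(50)})
        with pytest.raises(ValueError, match="collinear"):
            fit_path_model([("x1", "y"), ("x2", "y")], df)

    def test_row_order_invariance(self):
        df = _unit_table(n=80, seed=11)
        a = fit_path_model([("x1", "m"), ("m", "y")], df)
        b = fit_path_model([("x1", "m"), ("m", "y")],
                           df.sample(frac=1.0, random_state=1).reset_index(drop=True))
        np.testing.assert_allclose(a.edges["coef"].to_numpy(),
                                   b.edges["coef"].to_numpy(), atol=1e-10)


def test_significance_star_levels():
    assert significance_stars(0.04) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(0.00005) == "***"
    assert significance_stars(0.2) == ""


def test_hurricane_damage_ratio():
    mangrove = np.zeros((4, 4), dtype=bool)
    mangrove[:2] = True
    ghost = np.zeros((4, 4), dtype=bool)
    ghost[0] = True
    assert hurricane_damage_ratio(ghost, mangrove) == pytest.approx(0.5)
    assert np.isnan(hurricane_damage_ratio(ghost, np.zeros((4, 4), dtype=bool)))
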