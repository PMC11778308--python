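import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nichepart.genome_features import GenomeTable
from nichepart.synthetic import (
    BinaryFeatureModel,
    ContinuousFeatureModel,
    GenomeSimConfig,
    scaled_design,
    simulate_genomes,
)
from nichepart.variance_partition import (
    batch_partition,
    fit_logistic_partition,
    fit_type3_anova,
    significance_tier,
    tukey_hsd,
)


def _random_complete_design(rng, n_classes=3, n_habitats=3, max_cell=8):
    """Unbalanced two-factor design with every cell occupied."""
    cls, hab, y = [], [], []
    for c in range(n_classes):
        for h in range(n_habitats):
            n = int(rng.integers(2, max_cell))
            cls += [f"c{c}"] * n
            hab += [f"h{h}"] * n
            y += list(rng.normal(c * 0.5 + h * 0.2, 1.0, n))
    return np.array(y), np.array(cls), np.array(hab)


def _brute_force_type3(y, cls, hab):
    """Independent oracle: explicit pseudo-inverse least squares, full vs
    reduced residual SS per term under sum-to-zero contrasts."""
    def sum_code(labels):
        levels = sorted(pd.unique(labels))
        X = np.zeros((len(labels), len(levels) - 1))
        for j, lev in enumerate(levels[:-1]):
            X[labels == lev, j] = 1.0
            X[labels == levels[-1], j] = -1.0
        return X

    def rss(X):
        P = X @ np.linalg.pinv(X)
        r = y - P @ y
        return float(r @ r)

    Xc, Xh = sum_code(cls), sum_code(hab)
    Xi = np.column_stack(
        [Xc[:, i] * Xh[:, j] for i in range(Xc.shape[1]) for j in range(Xh.shape[1])]
    )
    one = np.ones((len(y), 1))
    full = rss(np.column_stack([one, Xc, Xh, Xi]))
    return {
        "class": rss(np.column_stack([one, Xh, Xi])) - full,
        "habitat": rss(np.column_stack([one, Xc, Xi])) - full,
        "interaction": rss(np.column_stack([one, Xc, Xh])) - full,
        "residual": full,
    }


class TestType3Anova:
    def test_balanced_closed_form(self):
        """Balanced 2x2 with a pure class effect: class SS equals the
        between-group formula; habitat and interaction SS are zero."""
        y, cls, hab = [], [], []
        for c, eff in (("a", -1.0), ("b", 1.0)):
            for h in ("x", "y"):
                for v in (-0.5, 0.5):  # symmetric within-cell noise
                    y.append(eff + v)
                    cls.append(c)
                    hab.append(h)
        y = np.array(y)
        res = fit_type3_anova(y, cls, hab)
        grand = y.mean()
        closed = sum(
            4 * (y[np.array(cls) == g].mean() - grand) ** 2 for g in ("a", "b")
        )
        assert res.term("class")["ss"] == pytest.approx(closed)
        assert res.term("habitat")["ss"] == pytest.approx(0.0, abs=1e-12)
        assert res.term("interaction")["ss"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            y, cls, hab = _random_complete_design(rng)
            res = fit_type3_anova(y, cls, hab)
            oracle = _brute_force_type3(y, cls, hab)
            for term in ("class", "habitat", "interaction", "residual"):
                got = float(res.term(term)["ss"])
                assert got == pytest.approx(oracle[term], rel=1e-8, abs=1e-10)

    def test_matches_statsmodels_car_convention(self):
        """Cross-check against the reference type III implementation."""
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(3)
        y, cls, hab = _random_complete_design(rng)
        df = pd.DataFrame({"y": y, "c": cls, "h": hab})
        ref = anova_lm(smf.ols("y ~ C(c, Sum)*C(h, Sum)", df).fit(), typ=3)
        res = fit_type3_anova(y, cls, hab)
        assert res.term("class")["ss"] == pytest.approx(ref.loc["C(c, Sum)", "sum_sq"])
        assert res.term("habitat")["ss"] == pytest.approx(ref.loc["C(h, Sum)", "sum_sq"])
        assert res.term("interaction")["ss"] == pytest.approx(
            ref.loc["C(c, Sum):C(h, Sum)", "sum_sq"]
        )

    def test_balanced_design_equals_sequential_ss(self):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(5)
        cls = np.repeat(["a", "b", "c"], 12)
        hab = np.tile(np.repeat(["x", "y"], 6), 3)
        y = rng.normal(0, 1, 36) + (cls == "a") * 1.0
        df = pd.DataFrame({"y": y, "c": cls, "h": hab})
        seq = anova_lm(smf.ols("y ~ C(c, Sum)*C(h, Sum)", df).fit(), typ=1)
        res = fit_type3_anova(y, cls, hab)
        assert res.term("class")["ss"] == pytest.approx(seq.loc["C(c, Sum)", "sum_sq"])
        assert res.term("habitat")["ss"] == pytest.approx(seq.loc["C(h, Sum)", "sum_sq"])

    def test_pct_contributions_sum_to_100_and_nonnegative(self, genome_sim):
        table, _ = genome_sim
        res = fit_type3_anova(
            table.records["gc_pct"], table.records["class_"], table.records["habitat"]
        )
        assert sum(res.pct_contribution.values()) == pytest.approx(100.0, abs=1e-6)
        assert all(v >= 0 for v in res.pct_contribution.values())

    def test_empty_cells_drop_interaction_df(self, genome_sim):
        table, _ = genome_sim
        res = fit_type3_anova(
            table.records["genome_size"],
            table.records["class_"],
            table.records["habitat"],
        )
        assert res.dropped_interaction_df == 9  # nine empty cells in the design
        assert res.term("habitat")["df"] == 6

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError):
            fit_type3_anova([1.0, 2.0], ["a", "a"], ["x", "y"])

    def test_saturated_model_rejected(self):
        with pytest.raises(ValueError, match="saturated"):
            fit_type3_anova(
                [1.0, 2.0, 3.0, 4.0], ["a", "a", "b", "b"], ["x", "y", "x", "y"]
            )


class TestTukey:
    def test_identical_groups_p_one(self):
        y = np.ones(12)
        g = np.repeat(["a", "b", "c"], 4)
        tk = tukey_hsd(y, g)
        assert (tk["p_adj"] == 1.0).all()

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(11)
        y = np.concatenate(
            [rng.normal(0, 1, 30), rng.normal(0, 1, 30), rng.normal(10, 1, 30)]
        )
        g = np.repeat(["a", "b", "c"], 30)
        tk = tukey_hsd(y, g).set_index(["group_a", "group_b"])
        assert tk.loc[("a", "c"), "p_adj"] < 1e-5
        assert tk.loc[("b", "c"), "p_adj"] < 1e-5
        assert tk.loc[("a", "b"), "p_adj"] > 0.05

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1, 10) for m in (0.0, 0.5, 2.0)]
        y = np.concatenate(groups)
        g = np.repeat(["a", "b", "c"], 10)
        ours = tukey_hsd(y, g)
        ref = stats.tukey_hsd(*groups)
        expected = [ref.pvalue[0, 1], ref.pvalue[0, 2], ref.pvalue[1, 2]]
        assert np.allclose(ours["p_adj"], expected, atol=1e-9)

    def test_adjusted_p_not_below_unadjusted_for_k3(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            y = rng.normal(0, 1, 24)
            g = np.repeat(["a", "b", "c"], 8)
            tk = tukey_hsd(y, g)
            for _, row in tk.iterrows():
                ya, yb = y[g == row["group_a"]], y[g == row["group_b"]]
                _, p_raw = stats.ttest_ind(ya, yb, equal_var=True)
                assert row["p_adj"] >= p_raw - 1e-12


class TestLogisticPartition:
    def test_null_trait_near_zero_contributions(self):
        rng = np.random.default_rng(0)
        n = 600
        cls = rng.choice(["a", "b", "c"], n)
        hab = rng.choice(["x", "y"], n)
        trait = rng.integers(0, 2, n)
        res = fit_logistic_partition(trait, cls, hab, include_interaction=False)
        assert abs(res.pseudo_r2_full) < 0.02
        assert abs(res.contribution["class"]) < 0.02
        assert abs(res.contribution["habitat"]) < 0.02

    def test_two_by_two_matches_hand_computed_likelihoods(self):
        """Saturated 2x2 fit: McFadden R^2 from cell/overall binomial
        log-likelihoods computed directly."""
        # cells: (class, habitat) -> (n, k successes)
        cells = {
            ("a", "x"): (40, 30),
            ("a", "y"): (40, 28),
            ("b", "x"): (40, 10),
            ("b", "y"): (40, 6),
        }
        trait, cls, hab = [], [], []
        for (c, h), (n, k) in cells.items():
            trait += [1] * k + [0] * (n - k)
            cls += [c] * n
            hab += [h] * n
        trait = np.array(trait)

        def bin_ll(k, n):
            p = k / n
            if p in (0, 1):
                return 0.0
            return k * np.log(p) + (n - k) * np.log(1 - p)

        ll_full = sum(bin_ll(k, n) for (n, k) in cells.values())
        ll_null = bin_ll(trait.sum(), len(trait))
        expected_r2 = 1 - ll_full / ll_null
        res = fit_logistic_partition(trait, cls, hab)
        assert res.pseudo_r2_full == pytest.approx(expected_r2, rel=1e-6)

    def test_planted_class_driven_trait_recovered(self):
        rng = np.random.default_rng(21)
        n = 400
        cls = rng.choice(["spl1", "spl2", "other"], n)
        hab = rng.choice(["soil", "marine"], n)
        p = np.where(np.char.startswith(cls.astype(str), "spl"), 0.9, 0.1)
        trait = (rng.random(n) < p).astype(int)
        res = fit_logistic_partition(trait, cls, hab, include_interaction=False)
        assert res.contribution["class"] > 10 * max(res.contribution["habitat"], 1e-9)
        assert res.term_p["class"] < 1e-5

    def test_requires_both_outcomes(self):
        with pytest.raises(ValueError):
            fit_logistic_partition([1, 1, 1], ["a", "a", "b"], ["x", "y", "x"])

    def test_separation_flagged(self):
        cls = np.repeat(["a", "b"], 30)
        hab = np.tile(["x", "y"], 30)
        trait = (cls == "a").astype(int)  # perfectly separated by class
        res = fit_logistic_partition(trait, cls, hab, include_interaction=False)
        assert res.flagged


class TestBatchPartition:
    def test_planted_lineage_only_effects_flagged_lineage_specific(self):
        design = scaled_design(0.25)
        classes = sorted(design)
        feature_models = {
            f"f{i}": ContinuousFeatureModel(
                0.0,
                class_effects={c: (2.0 if j % 2 else -2.0) for j, c in enumerate(classes)},
                noise_sd=1.0,
            )
            for i in range(10)
        }
        cfg = GenomeSimConfig(design=design, feature_models=feature_models, seed=4)
        table, _ = simulate_genomes(cfg)
        result = batch_partition(table)
        spec = result.specificity.set_index("name")
        for i in range(10):
            assert spec.loc[f"f{i}", "category"] == "lineage-specific"
        assert result.tallies["habitat-specific"] == 0

    def test_habitat_only_trait_identified(self):
        design = scaled_design(0.3)
        trait_models = {"habitat_trait": BinaryFeatureModel(0.0, habitat_terms={"soil": 3.0})}
        trait_models |= {
            f"noise{i}": BinaryFeatureModel(0.0) for i in range(5)
        }
        cfg = GenomeSimConfig(design=design, trait_models=trait_models, seed=8)
        table, _ = simulate_genomes(cfg)
        result = batch_partition(table, include_interaction=False)
        spec = result.specificity.set_index("name")
        assert spec.loc["habitat_trait", "category"] == "habitat-specific"
        noise_cats = [spec.loc[f"noise{i}", "category"] for i in range(5)]
        assert noise_cats.count("neither") >= 4

    def test_constant_feature_reported_ns_batch_completes(self):
        design = scaled_design(0.2)
        cfg = GenomeSimConfig(
            design=design,
            feature_models={"ok": ContinuousFeatureModel(0.0, noise_sd=1.0)},
            seed=1,
        )
        table, _ = simulate_genomes(cfg)
        table.records["gc_pct"] = 50.0  # constant column
        result = batch_partition(table)
        spec = result.specificity.set_index("name")
        assert spec.loc["gc_pct", "category"] == "neither"
        assert "ok" in result.anova


class TestTiers:
    @pytest.mark.parametrize(
        "p,tier",
        [(1e-6, "strong"), (1e-5, "weak"), (0.049, "weak"), (0.05, "ns"), (np.nan, "ns")],
    )
    def test_tier_boundaries(self, p, tier):
        assert significance_tier(p) == tier
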