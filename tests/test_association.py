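import numpy as np
import pandas as pd
import pytest

from indelssr import (
    GeneRecord,
    PlantedQTL,
    SimConfig,
    candidate_gene_window,
    effect_for_variance_fraction,
    glm_assoc,
    marker_dosage,
    mlm_assoc,
    significant_markers,
    simulate_cohort,
    simulate_traits,
    trait_correlations,
    trait_summaries,
)
from indelssr.association import association_counts, fit_null_mlm
from indelssr.band_matrix import BandMatrix
from indelssr.diversity import KinshipMatrix


def long_traits(values: dict[str, list[float]], year=2021) -> pd.DataFrame:
    rows = []
    for trait, vals in values.items():
        for i, v in enumerate(vals):
            rows.append({"individual_id": f"i{i}", "trait": trait,
                         "year": year, "value": v})
    return pd.DataFrame(rows)


def subset_markers(matrix: BandMatrix, markers: list[str]) -> BandMatrix:
    scores = matrix.scores.loc[markers]
    return BandMatrix(scores=scores, _marker_order=markers)


class TestTraitSummaries:
    def test_mean_sd_cv(self):
        df = trait_summaries(long_traits({"t": [2.0, 4.0, 6.0]}))
        row = df.iloc[0]
        assert row["mean"] == 4 and row["sd"] == 2
        assert row["cv_pct"] == pytest.approx(50.0)
        assert row["range"] == 4

    def test_identical_year_distributions_f_near_zero(self):
        vals = list(np.random.default_rng(0).normal(10, 2, 30))
        t = pd.concat([
            long_traits({"t": vals}, year=2021),
            long_traits({"t": vals}, year=2022),
        ])
        df = trait_summaries(t)
        assert df["anova_between_years_p"].iloc[0] == pytest.approx(1.0)

    def test_shapiro_and_matches_scipy(self):
        from scipy import stats as ss

        vals = list(np.random.default_rng(1).normal(0, 1, 50))
        df = trait_summaries(long_traits({"t": vals}))
        w, p = ss.shapiro(np.array(vals))
        assert df["shapiro_w"].iloc[0] == pytest.approx(w)
        assert df["shapiro_p"].iloc[0] == pytest.approx(p)

    def test_collinear_traits_correlate_perfectly(self):
        vals = list(np.random.default_rng(2).normal(0, 1, 25))
        t = long_traits({"a": vals, "b": [3 * v + 1 for v in vals]})
        r, p = trait_correlations(t, 2021)
        assert r.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(r), 1.0)


@pytest.fixture(scope="module")
def qtl_cohort():
    """121 individuals, planted additive QTL explaining ~15% of variance."""
    cfg = SimConfig(
        seed=21, n_markers=25, missing_rate=0.0,
        planted_qtl=(PlantedQTL("m001", "leaf_area",
                                effect_for_variance_fraction(0.15)),),
        years=(2021,),
        trait_names=("leaf_area", "cormel_number"),
    )
    cohort = simulate_cohort(cfg)
    traits = simulate_traits(cfg, cohort)
    return cfg, cohort, traits


class TestGLM:
    def test_planted_effect_detected(self, qtl_cohort):
        cfg, cohort, traits = qtl_cohort
        res = glm_assoc(cohort.band_matrix, traits)
        hit = res[(res.marker_id == "m001") & (res.trait == "leaf_area")]
        assert hit["p_value"].iloc[0] < 1e-4
        assert 0 < hit["r2"].iloc[0] <= 1

    def test_strong_effect_is_very_significant(self):
        cfg = SimConfig(
            seed=22, n_individuals=200, n_markers=10, missing_rate=0.0,
            planted_qtl=(PlantedQTL("m001", "leaf_area", 1.0),),
            years=(2021,), trait_names=("leaf_area",), h2_polygenic=0.0,
        )
        cohort = simulate_cohort(cfg)
        traits = simulate_traits(cfg, cohort)
        res = glm_assoc(cohort.band_matrix, traits)
        assert res[res.marker_id == "m001"]["p_value"].iloc[0] < 1e-6

    def test_null_p_values_roughly_uniform(self):
        from scipy import stats as ss

        cfg = SimConfig(seed=23, n_individuals=120, n_markers=150,
                        missing_rate=0.0, years=(2021,),
                        trait_names=("t1",), h2_polygenic=0.0)
        cohort = simulate_cohort(cfg)
        rng = np.random.default_rng(24)
        traits = long_traits({"t1": list(rng.normal(0, 1, 120))})
        traits["individual_id"] = list(cohort.q_truth.index)
        res = glm_assoc(cohort.band_matrix, traits)
        ks = ss.kstest(res["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_matches_statsmodels_anova(self, qtl_cohort):
        import statsmodels.api as sm

        cfg, cohort, traits = qtl_cohort
        res = glm_assoc(subset_markers(cohort.band_matrix, ["m002"]), traits)
        dose = marker_dosage(cohort.band_matrix, "m002").iloc[:, :-1]
        y = traits[(traits.trait == "leaf_area")].set_index("individual_id")["value"]
        joint = dose.join(y.rename("y")).dropna()
        X = sm.add_constant(joint.drop(columns="y"))
        fit = sm.OLS(joint["y"], X).fit()
        p_ref = float(fit.f_pvalue)  # all non-intercept terms = the marker block
        assert res[res.trait == "leaf_area"]["p_value"].iloc[0] == pytest.approx(
            p_ref, rel=1e-6
        )

    def test_q_covariate_requires_two_columns(self, qtl_cohort):
        cfg, cohort, traits = qtl_cohort
        bad_q = cohort.q_truth.iloc[:, :1].assign(pop1=1.0)
        with pytest.raises(ValueError):
            glm_assoc(cohort.band_matrix, traits, q=bad_q)


class TestMLM:
    def test_identity_kinship_collapses_to_glm(self, qtl_cohort):
        cfg, cohort, traits = qtl_cohort
        ids = tuple(cohort.q_truth.index)
        eye = KinshipMatrix(ids=ids, values=np.eye(len(ids)), estimator="identity")
        glm = glm_assoc(cohort.band_matrix, traits).set_index(["marker_id", "trait"])
        mlm = mlm_assoc(cohort.band_matrix, traits, eye).set_index(["marker_id", "trait"])
        joined = glm.join(mlm, lsuffix="_glm", rsuffix="_mlm")
        assert np.allclose(joined["p_value_glm"], joined["p_value_mlm"], atol=1e-6)

    def test_heritability_recovery(self):
        h2_hats = []
        for rep in range(6):
            cfg = SimConfig(seed=100 + rep, n_individuals=200, n_markers=60,
                            missing_rate=0.0, years=(2021,),
                            trait_names=("t",), h2_polygenic=0.5)
            cohort = simulate_cohort(cfg)
            traits = simulate_traits(cfg, cohort)
            y = traits.set_index("individual_id")["value"].to_numpy(dtype=float)
            X0 = np.ones((len(y), 1))
            fit, _, _ = fit_null_mlm(y, X0, cohort.kinship_truth.values)
            h2_hats.append(fit.heritability)
        assert abs(np.mean(h2_hats) - 0.5) < 0.15

    def test_structure_confounding_reduced_by_k_and_q(self):
        # trait driven purely by subpopulation membership: GLM sees many
        # false marker hits, MLM(K+Q) sees fewer
        cfg = SimConfig(seed=31, n_individuals=100, n_markers=60,
                        missing_rate=0.0, years=(2021,), trait_names=("t",),
                        h2_polygenic=0.0)
        cohort = simulate_cohort(cfg)
        rng = np.random.default_rng(32)
        group_effect = cohort.q_truth.to_numpy() @ np.array([0.0, 1.5, 3.0])
        vals = group_effect + rng.normal(0, 0.5, 100)
        traits = pd.DataFrame({
            "individual_id": list(cohort.q_truth.index), "trait": "t",
            "year": 2021, "value": vals,
        })
        glm_n = (glm_assoc(cohort.band_matrix, traits)["p_value"] < 0.05).sum()
        mlm = mlm_assoc(cohort.band_matrix, traits, cohort.kinship_truth,
                        q=cohort.q_truth)
        mlm_n = (mlm["p_value"] < 0.05).sum()
        assert mlm_n < glm_n

    def test_p3d_close_to_exact(self, qtl_cohort):
        cfg, cohort, traits = qtl_cohort
        sub = subset_markers(cohort.band_matrix, ["m001", "m002", "m003"])
        fast = mlm_assoc(sub, traits, cohort.kinship_truth, p3d=True)
        exact = mlm_assoc(sub, traits, cohort.kinship_truth, p3d=False)
        merged = fast.merge(exact, on=["marker_id", "trait", "year"])
        assert np.allclose(
            np.log10(merged["p_value_x"]), np.log10(merged["p_value_y"]), atol=1.0
        )
        # P3D must never change which associations are (non-)significant here
        assert ((merged["p_value_x"] < 0.05) == (merged["p_value_y"] < 0.05)).all()

    def test_non_psd_kinship_rejected(self, qtl_cohort):
        cfg, cohort, traits = qtl_cohort
        ids = tuple(cohort.q_truth.index)
        bad = -np.eye(len(ids))
        with pytest.raises(ValueError, match="not PSD"):
            mlm_assoc(cohort.band_matrix, traits,
                      KinshipMatrix(ids=ids, values=bad, estimator="bad"))


class TestSignificantMarkers:
    def _results(self):
        return pd.DataFrame([
            dict(marker_id="mA", trait="t", year=2021, model="GLM",
                 p_value=0.001, r2=0.1, effects=(1.0,)),
            dict(marker_id="mA", trait="t", year=2021, model="MLM_K",
                 p_value=0.02, r2=0.1, effects=(1.0,)),
            dict(marker_id="mB", trait="t", year=2021, model="GLM",
                 p_value=0.01, r2=0.1, effects=(1.0,)),
            dict(marker_id="mB", trait="t", year=2021, model="MLM_K",
                 p_value=0.5, r2=0.0, effects=(0.0,)),
        ])

    def test_two_model_rule(self):
        stable = significant_markers(self._results(), min_models=2)
        assert list(stable["marker_id"]) == ["mA"]
        assert stable["models"].iloc[0] == ("GLM", "MLM_K")

    def test_single_model_marker_excluded(self):
        stable = significant_markers(self._results(), min_models=2)
        assert "mB" not in set(stable["marker_id"])

    def test_empty_results(self):
        assert significant_markers(pd.DataFrame(
            columns=["marker_id", "trait", "year", "model", "p_value"]
        )).empty

    def test_counts_table_layout(self):
        tab = association_counts(self._results())
        assert tab.loc["t", ("GLM", 2021)] == 2
        assert tab.loc["SUM", ("MLM_K", 2021)] == 1


class TestCandidateGeneWindow:
    def mk_gene(self, gid, start, end, chrom="c1"):
        return GeneRecord(gid, chrom, start, end, "+")

    def test_total_window_reading(self):
        genes = [self.mk_gene("near", 1_400_000, 1_401_000),
                 self.mk_gene("far", 1_600_000, 1_601_000)]
        hits = candidate_gene_window("c1", 1_000_000, genes)
        assert [g.gene_id for g in hits] == ["near"]

    def test_each_side_option_widens(self):
        genes = [self.mk_gene("far", 1_600_000, 1_601_000)]
        hits = candidate_gene_window("c1", 1_000_000, genes,
                                     full_width_each_side=True)
        assert [g.gene_id for g in hits] == ["far"]

    def test_planted_count_recovered_and_sorted(self):
        rng = np.random.default_rng(40)
        anchor = 2_000_000
        inside = [
            self.mk_gene(f"g{i}", s, s + 500)
            for i, s in enumerate(
                rng.integers(anchor - 499_000, anchor + 498_000, size=63)
            )
        ]
        outside = [self.mk_gene("o1", anchor + 600_000, anchor + 601_000),
                   self.mk_gene("o2", 1, 1000),
                   self.mk_gene("other_chrom", anchor, anchor + 500, chrom="c2")]
        hits = candidate_gene_window("c1", anchor, inside + outside)
        assert len(hits) == 63
        dists = [min(abs(g.start - anchor), abs(g.end - anchor))
                 if not g.start <= anchor <= g.end else 0 for g in hits]
        assert dists == sorted(dists)

    def test_window_clipped_at_chromosome_start(self):
        genes = [self.mk_gene("g", 1, 100)]
        assert candidate_gene_window("c1", 100_000, genes)
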