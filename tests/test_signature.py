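import numpy as np
import pandas as pd
import pytest

from m6apattern import (
    ClinicalTable,
    CohortSimulationParams,
    ExpressionMatrix,
    generate_cohort,
)
from m6apattern.signature import (
    cox_screen,
    m6sig_score,
    moderated_dge,
    optimal_cutpoint,
    phenotype_signature,
    rfe_select,
)


def expr_from(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(
            arr,
            index=genes or [f"G{i:03d}" for i in range(arr.shape[0])],
            columns=samples or [f"S{i:03d}" for i in range(arr.shape[1])],
        )
    )


class TestModeratedDge:
    def test_duplicated_groups_are_null(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=(30, 10))
        mat = expr_from(np.hstack([half, half]))
        labels = ["a"] * 10 + ["b"] * 10
        table = moderated_dge(mat, labels, ("a", "b")).table
        np.testing.assert_allclose(table["lfc"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["t_moderated"], 0.0, atol=1e-12)
        np.testing.assert_allclose(table["q"], 1.0, atol=1e-12)

    def test_homogeneous_variances_shrink_strongly(self):
        # equal true variances => large d0, moderated t ~ ordinary t with
        # more df; heterogeneous => small d0 keeps them distinct
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, size=(200, 20))
        mat = expr_from(X)
        labels = ["a"] * 10 + ["b"] * 10
        res = moderated_dge(mat, labels, ("a", "b"))
        assert res.d0 > 5.0
        # moderated and ordinary t agree in sign everywhere
        tt = res.table
        assert (np.sign(tt["t_moderated"]) == np.sign(tt["t_ordinary"])).all()

    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(2)
        mat = expr_from(rng.normal(size=(50, 12)))
        labels = ["a"] * 6 + ["b"] * 6
        table = moderated_dge(mat, labels, ("a", "b")).table
        assert (table["q"] >= table["p"] - 1e-15).all()

    def test_planted_effects_detected_at_stringent_threshold(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 100))
        X[:20, :50] += 2.0  # 20 true effects of 2 SD, n=50/group
        mat = expr_from(X)
        labels = ["a"] * 50 + ["b"] * 50
        res = moderated_dge(mat, labels, ("a", "b"))
        hits = set(res.significant(0.001))
        truth = {f"G{i:03d}" for i in range(20)}
        assert len(hits & truth) >= 16  # >= 80% power
        assert len(hits - truth) <= 2


class TestPhenotypeSignature:
    def test_definition_on_constructed_patterns(self):
        rng = np.random.default_rng(4)
        n = 30  # per cluster
        X = rng.normal(size=(4, 3 * n)) * 0.3
        X[0, :n] += 5.0        # pan-differential (up in cluster 0 only)
        X[1, :n] += 5.0
        X[1, n : 2 * n] += 5.0  # differential only between cluster 2 and rest
        mat = expr_from(X)
        labels = [0] * n + [1] * n + [2] * n
        sig = phenotype_signature(mat, labels, alpha=0.001)
        assert "G000" in sig
        assert "G003" not in sig  # pure noise gene excluded

    def test_planted_pan_differential_genes_recovered(self, default_cohort):
        c = default_cohort
        sig = phenotype_signature(c.expression, c.pattern_labels)
        truth = set(c.signature_genes)
        background = {g for g in c.expression.gene_ids if g.startswith("BG_")}
        assert len(set(sig) & truth) >= 0.9 * len(truth)
        assert len(set(sig) & background) <= 0.1 * max(len(sig), 1)

    def test_single_cluster_rejected(self, small_expr):
        with pytest.raises(ValueError, match="two clusters"):
            phenotype_signature(small_expr, [0] * 12)


class TestCoxScreen:
    def test_null_genes_kept_at_nominal_rate(self):
        rng = np.random.default_rng(5)
        n, g = 150, 100
        mat = expr_from(rng.normal(size=(g, n)))
        clin = ClinicalTable(
            pd.DataFrame(
                {"time": rng.exponential(20, n), "event": 1},
                index=mat.sample_ids,
            )
        )
        table = cox_screen(mat, clin)
        keep_rate = table["keep"].mean()
        assert 0.0 <= keep_rate <= 0.12  # ~5% nominal

    def test_binary_expression_hr_recovered(self):
        rng = np.random.default_rng(6)
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        time = rng.exponential(1.0 / (0.05 * np.exp(np.log(2) * x)))
        mat = expr_from(x[None, :], genes=["GX"])
        clin = ClinicalTable(
            pd.DataFrame({"time": time, "event": 1}, index=mat.sample_ids)
        )
        table = cox_screen(mat, clin, ["GX"])
        assert 1.6 <= np.exp(table.loc["GX", "coef"]) <= 2.5
        assert table.loc["GX", "keep"]


class TestRfeSelect:
    @staticmethod
    def informative_data(seed, n_per=40, informative=5, noise=95):
        rng = np.random.default_rng(seed)
        n = 3 * n_per
        labels = np.repeat([0, 1, 2], n_per)
        X = rng.normal(size=(informative + noise, n))
        for i in range(informative):
            X[i, labels == i % 3] += 3.0
        return expr_from(X), labels

    def test_informative_genes_survive_elimination(self):
        mat, labels = self.informative_data(seed=7)
        selected = rfe_select(mat, labels, fold_count=5, seed=1)
        informative = {f"G{i:03d}" for i in range(5)}
        assert len(set(selected) & informative) >= 4

    def test_all_noise_collapses_to_grid_minimum(self):
        rng = np.random.default_rng(8)
        mat = expr_from(rng.normal(size=(40, 60)))
        labels = np.repeat([0, 1, 2], 20)
        selected = rfe_select(mat, labels, fold_count=5, seed=2)
        assert len(selected) <= 10  # one-SE rule prefers the small end

    def test_fixed_seed_is_deterministic(self):
        mat, labels = self.informative_data(seed=9, noise=45)
        a = rfe_select(mat, labels, fold_count=5, seed=3)
        b = rfe_select(mat, labels, fold_count=5, seed=3)
        assert a == b

    def test_single_class_rejected(self, small_expr):
        with pytest.raises(ValueError, match="two classes"):
            rfe_select(small_expr, [1] * 12)


class TestM6sigScore:
    def test_identical_samples_score_zero(self):
        mat = expr_from(np.tile([[1.0], [2.0], [3.0], [4.0]], (1, 6)))
        model = m6sig_score(mat, mat.gene_ids)
        np.testing.assert_allclose(model.scores.to_numpy(), 0.0, atol=1e-12)

    def test_one_dimensional_geometry_uses_only_pc1(self):
        # all genes perfectly collinear: PC2 is degenerate, so the score
        # equals the PC1 coordinate alone
        t = np.linspace(-2, 2, 10)
        X = np.vstack([t, 2 * t, -t])
        mat = expr_from(X)
        model = m6sig_score(mat, mat.gene_ids)
        np.testing.assert_allclose(model.pc_scores["PC2"], 0.0, atol=1e-8)
        np.testing.assert_allclose(
            model.scores.to_numpy(), model.pc_scores["PC1"].to_numpy()
        )

    def test_invariant_to_gene_order_and_affine_rescaling(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(6, 30))
        X[0] += np.linspace(0, 3, 30)  # give PC1 a definite direction
        mat = expr_from(X)
        # survival orientation pins the otherwise-arbitrary component signs
        clin = ClinicalTable(
            pd.DataFrame(
                {"time": rng.exponential(20, 30), "event": 1},
                index=mat.sample_ids,
            )
        )
        base = m6sig_score(mat, mat.gene_ids, clinical=clin).scores
        shuffled = list(reversed(mat.gene_ids))
        rescaled = mat.data.copy().loc[shuffled]
        rescaled.iloc[2] = rescaled.iloc[2] * 7.0 - 100.0
        alt = m6sig_score(ExpressionMatrix(rescaled), shuffled, clinical=clin).scores
        np.testing.assert_allclose(base, alt, atol=1e-8)

    def test_recovers_planted_program_contrast(self):
        rng = np.random.default_rng(11)
        n = 200
        program = rng.normal(size=n)  # latent per-sample program level
        X = np.outer(rng.uniform(0.5, 1.5, 12), program) + rng.normal(
            scale=0.3, size=(12, n)
        )
        mat = expr_from(X)
        model = m6sig_score(mat, mat.gene_ids)
        r = np.corrcoef(model.scores, program)[0, 1]
        assert abs(r) >= 0.9

    def test_orientation_follows_survival_direction(self):
        rng = np.random.default_rng(12)
        n = 200
        program = rng.normal(size=n)
        X = np.outer(np.ones(5), program) + rng.normal(scale=0.2, size=(5, n))
        mat = expr_from(X)
        time = rng.exponential(1.0 / (0.05 * np.exp(0.7 * program)))
        clin = ClinicalTable(
            pd.DataFrame({"time": time, "event": 1}, index=mat.sample_ids)
        )
        model = m6sig_score(mat, mat.gene_ids, clinical=clin)
        assert np.corrcoef(model.scores, program)[0, 1] > 0.9

    def test_too_few_genes_rejected(self, small_expr):
        with pytest.raises(ValueError, match="at least 3"):
            m6sig_score(small_expr, ["G00", "G01"])


class TestOptimalCutpoint:
    def test_cutpoint_falls_between_separated_clusters(self):
        rng = np.random.default_rng(13)
        n = 60
        scores = np.concatenate([rng.normal(0, 0.3, n), rng.normal(5, 0.3, n)])
        time = np.concatenate(
            [rng.exponential(50, n), rng.exponential(10, n)]
        )
        ids = [f"S{i:03d}" for i in range(2 * n)]
        clin = ClinicalTable(
            pd.DataFrame({"time": time, "event": 1}, index=ids)
        )
        cut = optimal_cutpoint(pd.Series(scores, index=ids), clin)
        # the chosen split separates the two planted score clusters (up to
        # a few samples whose random survival times blur the boundary)
        high = cut.groups == "high"
        truth = np.array([False] * n + [True] * n)
        assert (high.to_numpy() == truth).mean() >= 0.95
        assert cut.cutpoint < 4.0

    def test_all_identical_scores_rejected(self, simple_clinical):
        s = pd.Series(1.0, index=simple_clinical.sample_ids)
        with pytest.raises(ValueError, match="identical"):
            optimal_cutpoint(s, simple_clinical)

    def test_impossible_minprop_band_rejected(self, simple_clinical):
        rng = np.random.default_rng(14)
        s = pd.Series(rng.normal(size=40), index=simple_clinical.sample_ids)
        with pytest.raises(ValueError, match="minprop"):
            optimal_cutpoint(s, simple_clinical, minprop=0.5)

    def test_null_score_selection_is_not_prognostic_out_of_sample(self):
        # the cutpoint maximizes in-sample separation even under the null;
        # applying it to fresh replicate data must give null log-rank p
        from m6apattern.survival_stats import km_logrank

        rng = np.random.default_rng(15)
        ps = []
        for rep in range(20):
            n = 100
            scores = rng.normal(size=n)
            ids = [f"S{i}" for i in range(n)]
            clin = ClinicalTable(
                pd.DataFrame(
                    {"time": rng.exponential(20, n), "event": 1}, index=ids
                )
            )
            cut = optimal_cutpoint(pd.Series(scores, index=ids), clin)
            fresh = ClinicalTable(
                pd.DataFrame(
                    {"time": rng.exponential(20, n), "event": 1}, index=ids
                )
            )
            fit = km_logrank(fresh, cut.groups)
            ps.append(fit.p)
        # held-out p-values behave like uniforms, not like the selected ones
        assert np.mean(np.array(ps) < 0.05) <= 0.2
        assert np.median(ps) > 0.15


class TestEndToEndRecovery:
    def test_low_score_group_has_lower_true_hazard(self):
        from m6apattern.pipeline import run_m6sig_pipeline

        params = CohortSimulationParams(seed=42)
        cohort = generate_cohort(params)
        res = run_m6sig_pipeline(
            cohort.expression, cohort.clinical, k=3, nruns=20, seed=0
        )
        hazard_by_group = cohort.true_log_hazard.groupby(res.cutpoint.groups).mean()
        assert hazard_by_group["low"] < hazard_by_group["high"]
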