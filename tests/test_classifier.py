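"""Swarm-optimized SVM pipeline: stage contracts, locking, end-to-end AUC."""

import numpy as np
import pandas as pd
import pytest

from tepseq import classifier as cl
from tepseq import performance as pf
from tepseq.core_io import CountMatrix
from tepseq.pso import PSOConfig
from tepseq.synthetic_data import simulate_counts


@pytest.fixture(scope="module")
def cohort():
    m, ann, truth = simulate_counts(
        n_genes=400, n_samples=120, frac_de=0.15, logfc=1.2, seed=42
    )
    return m, ann, truth


@pytest.fixture(scope="module")
def trained(cohort):
    m, ann, _ = cohort
    train = ann.role_samples("training")
    model = cl.train_classifier(
        m.subset_samples(train), ann.subset(train),
        theta=(0.8, 0.05, 0.9, 25), seed=1, anova_dispersion=0.2, grid_step=4,
    )
    return model


class TestRankGenes:
    def _inputs(self, cohort):
        m, ann, truth = cohort
        train = ann.role_samples("training")
        sub = m.subset_samples(train)
        return sub.counts, ann.group(train), sub.lib_size.astype(float), truth

    def test_threshold_one_returns_all_converged_genes_ordered(self, cohort):
        counts, group, off, _ = self._inputs(cohort)
        panel = cl.rank_genes_anova(counts, group, off, 1.01, dispersion=0.2)
        assert len(panel) == counts.shape[0]
        assert (np.diff(panel.scores.to_numpy()) <= 1e-12).all()

    def test_planted_genes_recovered(self, cohort):
        counts, group, off, truth = self._inputs(cohort)
        panel = cl.rank_genes_anova(counts, group, off, 0.05, dispersion=0.2)
        planted = set(truth["de_genes"])
        recall = len(set(panel.genes) & planted) / len(planted)
        assert recall >= 0.8

    def test_empty_panel_errors(self, cohort):
        counts, group, off, _ = self._inputs(cohort)
        with pytest.raises(cl.TrainingError, match="raise the threshold"):
            cl.rank_genes_anova(counts, group, off, 1e-300, dispersion=0.2)


class TestCorrelationFilter:
    def _panel(self, genes):
        return cl.GenePanel(
            genes=list(genes),
            scores=pd.Series(range(len(genes), 0, -1), index=genes, dtype=float),
        )

    def test_cutoff_one_without_duplicates_is_identity(self):
        rng = np.random.default_rng(0)
        feats = pd.DataFrame(
            rng.normal(size=(5, 30)), index=[f"g{i}" for i in range(5)]
        )
        panel = self._panel(feats.index)
        out = cl.remove_correlated_genes(feats, panel, 1.0)
        assert out.genes == panel.genes

    def test_duplicated_gene_removed_independent_kept(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=30)
        c = rng.normal(size=30)
        feats = pd.DataFrame([a, a.copy(), c], index=["A", "B", "C"])
        out = cl.remove_correlated_genes(feats, self._panel(["A", "B", "C"]), 0.9)
        assert "C" in out.genes
        assert sorted(set(out.genes) & {"A", "B"}).__len__() == 1

    def test_survivors_satisfy_cutoff(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=40)
        feats = pd.DataFrame(
            [base + rng.normal(0, s, 40) for s in (0.1, 0.2, 0.5, 1, 2, 5)],
            index=[f"g{i}" for i in range(6)],
        )
        out = cl.remove_correlated_genes(feats, self._panel(feats.index), 0.7)
        R = np.abs(np.corrcoef(feats.loc[out.genes].to_numpy()))
        np.fill_diagonal(R, 0)
        assert R.max() <= 0.7 + 1e-12


class TestRFE:
    def _data(self):
        rng = np.random.default_rng(3)
        n = 60
        y = np.array([0, 1] * (n // 2))
        informative = rng.normal(size=(5, n)) + 1.5 * y
        noise = rng.normal(size=(50, n))
        feats = pd.DataFrame(
            np.vstack([informative, noise]),
            index=[f"i{k}" for k in range(5)] + [f"n{k}" for k in range(50)],
            columns=[f"s{j}" for j in range(n)],
        )
        return feats, y

    def test_target_equal_to_panel_size_keeps_all(self):
        feats, y = self._data()
        panel = cl.GenePanel(list(feats.index),
                             pd.Series(1.0, index=feats.index))
        out = cl.svm_rfe(feats, y, panel, len(panel))
        assert set(out.genes) == set(panel.genes)

    def test_informative_genes_survive(self):
        feats, y = self._data()
        panel = cl.GenePanel(list(feats.index),
                             pd.Series(1.0, index=feats.index))
        out = cl.svm_rfe(feats, y, panel, 10)
        kept_informative = sum(g.startswith("i") for g in out.genes)
        assert kept_informative >= 4

    def test_elimination_path_containment(self):
        feats, y = self._data()
        panel = cl.GenePanel(list(feats.index),
                             pd.Series(1.0, index=feats.index))
        small = cl.svm_rfe(feats, y, panel, 10)
        large = cl.svm_rfe(feats, y, panel, 20)
        assert set(small.genes) <= set(large.genes)

    def test_bad_target_errors(self):
        feats, y = self._data()
        panel = cl.GenePanel(list(feats.index),
                             pd.Series(1.0, index=feats.index))
        with pytest.raises(cl.TrainingError):
            cl.svm_rfe(feats, y, panel, len(panel) + 1)


class TestSVMSearch:
    def _separable(self):
        rng = np.random.default_rng(4)
        n = 40
        y = np.array([0, 1] * (n // 2))
        feats = pd.DataFrame(
            rng.normal(size=(6, n)) + 2.5 * y,
            index=[f"g{i}" for i in range(6)],
            columns=[f"s{j}" for j in range(n)],
        )
        return feats, y

    def test_separable_reaches_auc_one(self):
        feats, y = self._separable()
        cfg = cl.grid_search_svm(
            feats, y, seed=0,
            log2_c_grid=np.arange(0, 21, 5), log2_gamma_grid=-np.arange(0, 21, 5),
        )
        assert cfg.cv_auc == 1.0

    def test_matches_exhaustive_scan_on_reduced_grid(self):
        rng = np.random.default_rng(5)
        n = 30
        y = np.array([0, 1] * (n // 2))
        feats = pd.DataFrame(
            rng.normal(size=(4, n)) + 0.8 * y,
            index=[f"g{i}" for i in range(4)],
            columns=[f"s{j}" for j in range(n)],
        )
        c_grid, g_grid = np.arange(0, 21, 5), -np.arange(0, 21, 5)
        cfg = cl.grid_search_svm(feats, y, seed=1,
                                 log2_c_grid=c_grid, log2_gamma_grid=g_grid)
        Z, _, _ = cl._standardize(feats)
        best = None
        for lc in sorted(c_grid):
            for lg in sorted(g_grid, reverse=True):
                auc = cl._cv_auc(Z, y, 2.0 ** lc, 2.0 ** lg, 2, 1)
                if best is None or auc > best[0]:
                    best = (auc, lc, lg)
        assert cfg.C == 2.0 ** best[1] and cfg.gamma == 2.0 ** best[2]

    def test_deterministic_given_seed(self):
        feats, y = self._separable()
        kw = dict(seed=2, log2_c_grid=np.arange(0, 21, 10),
                  log2_gamma_grid=-np.arange(0, 21, 10))
        c1 = cl.grid_search_svm(feats, y, **kw)
        c2 = cl.grid_search_svm(feats, y, **kw)
        assert (c1.C, c1.gamma) == (c2.C, c2.gamma)

    def test_pso_refine_never_worse_than_grid(self):
        feats, y = self._separable()
        cfg = cl.grid_search_svm(
            feats, y, seed=3,
            log2_c_grid=np.arange(0, 21, 10), log2_gamma_grid=-np.arange(0, 21, 10),
        )
        refined = cl.pso_refine_svm(feats, y, cfg, seed=3,
                                    n_particles=5, n_iterations=4)
        assert refined.cv_auc >= cfg.cv_auc - 1e-12


class TestImputation:
    def test_trigger_zero_replaces_only_exact_zeros(self, trained):
        model = trained
        genes = model.panel.genes[:3]
        counts = pd.DataFrame(
            {"v0": [0, 1, 5]}, index=genes
        )
        out = cl.impute_undetected_genes(counts, model, trigger=0)
        med = model.imputation_medians
        assert out.loc[genes[0], "v0"] == med.loc[genes[0]]
        assert out.loc[genes[1], "v0"] == 1
        assert out.loc[genes[2], "v0"] == 5

    def test_trigger_two_boundary(self, trained):
        model = trained
        g = model.panel.genes[0]
        counts = pd.DataFrame({"v0": [1], "v1": [3]}, index=[g])
        out = cl.impute_undetected_genes(counts, model, trigger=2)
        assert out.loc[g, "v0"] == model.imputation_medians.loc[g]
        assert out.loc[g, "v1"] == 3

    def test_missing_panel_gene_treated_as_zero_with_warning(self, trained):
        model = trained
        counts = pd.DataFrame({"v0": [7]}, index=["not_a_panel_gene"])
        with pytest.warns(UserWarning, match="absent"):
            out = cl.impute_undetected_genes(counts, model, trigger=2)
        g = model.panel.genes[0]
        assert out.loc[g, "v0"] == model.imputation_medians.loc[g]


class TestTrainPredict:
    def test_validation_auc_high_on_separable_cohort(self, cohort, trained):
        m, ann, _ = cohort
        val = ann.role_samples("validation")
        preds = cl.predict(m.subset_samples(val), trained)
        y = (ann.group(val) == trained.labels_order[1]).astype(int).to_numpy()
        assert pf.roc_auc(preds["score"].to_numpy(), y) >= 0.95

    def test_training_samples_score_on_correct_side(self, cohort, trained):
        m, ann, _ = cohort
        train = ann.role_samples("training")
        preds = cl.predict(m.subset_samples(train), trained)
        y = (ann.group(train) == trained.labels_order[1]).astype(int).to_numpy()
        assert (((preds["score"] >= 0.5).astype(int).to_numpy()) == y).all()

    def test_score_monotone_in_decision_value(self, cohort, trained):
        m, ann, _ = cohort
        val = ann.role_samples("validation")
        preds = cl.predict(m.subset_samples(val), trained)
        order = np.argsort(preds["decision"].to_numpy())
        assert (np.diff(preds["score"].to_numpy()[order]) >= -1e-15).all()

    def test_sample_order_equivariance(self, cohort, trained):
        m, ann, _ = cohort
        val = ann.role_samples("validation")
        preds = cl.predict(m.subset_samples(val), trained)
        rev = cl.predict(m.subset_samples(val[::-1]), trained)
        assert np.allclose(
            rev.loc[val, "score"].to_numpy(), preds["score"].to_numpy()
        )

    def test_leakage_guard_validation_edits_do_not_change_model(self, cohort):
        m, ann, _ = cohort
        train = ann.role_samples("training")
        kw = dict(theta=(0.8, 0.05, 0.9, 25), seed=1,
                  anova_dispersion=0.2, grid_step=4)
        base = cl.train_classifier(m.subset_samples(train), ann.subset(train), **kw)
        edited = m.counts.copy()
        edited.iloc[:, -5:] = 0  # clobber five validation samples
        again = cl.train_classifier(
            CountMatrix(edited).subset_samples(train), ann.subset(train), **kw
        )
        assert base.serialized_bytes() == again.serialized_bytes()

    def test_save_load_round_trip_scores_identical(self, cohort, trained, tmp_path):
        m, ann, _ = cohort
        val = ann.role_samples("validation")
        path = tmp_path / "model.json"
        trained.save(path)
        back = cl.ClassifierModel.load(path)
        p1 = cl.predict(m.subset_samples(val), trained)["score"].to_numpy()
        p2 = cl.predict(m.subset_samples(val), back)["score"].to_numpy()
        assert np.array_equal(p1, p2)

    def test_permuted_labels_destroy_signal(self, cohort):
        m, ann, _ = cohort
        train = ann.role_samples("training")
        val = ann.role_samples("validation")
        model = cl.train_classifier(
            m.subset_samples(train), ann.subset(train),
            theta=(0.8, 0.05, 0.9, 25), seed=1,
            anova_dispersion=0.2, grid_step=4,
        )
        rng = np.random.default_rng(13)
        feats_train = model._train_features
        feats_val = (
            cl.predict(m.subset_samples(val), model)  # warm the path
        )
        fit_predict = cl.svm_fit_predict_factory(model)
        # validation features through the locked normalization
        from tepseq import normalize
        adj = cl.impute_undetected_genes(
            m.subset_samples(val).counts.copy(), model
        )
        adjusted = CountMatrix(
            adj.loc[model.norm_model.gene_ids].round().astype(np.int64)
        )
        _, log_val = normalize.apply_correction(adjusted, model.norm_model)
        Xval = log_val.loc[model.panel.genes]
        yval = (ann.group(val) == model.labels_order[1]).astype(int)
        aucs = []
        ytr = pd.Series(model._train_y, index=feats_train.columns)
        for _ in range(40):
            perm = pd.Series(rng.permutation(ytr.to_numpy()), index=ytr.index)
            scores = fit_predict(feats_train, perm, Xval)
            aucs.append(pf.roc_auc(scores, yval.to_numpy()))
        assert 0.35 <= float(np.median(aucs)) <= 0.65


class TestOuterPSO:
    def test_one_particle_one_iteration_single_evaluation(self, cohort):
        m, ann, _ = cohort
        train = ann.role_samples("training")
        ev = ann.role_samples("evaluation")
        theta, model, trace = cl.outer_pso_optimize(
            m, ann, train, ev,
            PSOConfig(n_particles=1, n_iterations=1, seed=5),
            anova_dispersion=0.2, grid_step=6,
        )
        assert len(trace) == 1

    def test_global_best_trace_monotone(self, cohort):
        m, ann, _ = cohort
        train = ann.role_samples("training")
        ev = ann.role_samples("evaluation")
        theta, model, trace = cl.outer_pso_optimize(
            m, ann, train, ev,
            PSOConfig(n_particles=3, n_iterations=3, seed=6),
            anova_dispersion=0.2, grid_step=6,
        )
        assert (np.diff(np.asarray(trace)) <= 1e-15).all()

    def test_overlapping_cohorts_rejected(self, cohort):
        m, ann, _ = cohort
        train = ann.role_samples("training")
        with pytest.raises(cl.TrainingError, match="disjoint"):
            cl.outer_pso_optimize(
                m, ann, train, train[:2], PSOConfig(n_particles=1, n_iterations=1)
            )
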