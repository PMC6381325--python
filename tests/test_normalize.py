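"""Normalization: TMM vs independent oracle, stable genes, RUV recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tepseq import normalize as nz
from tepseq.core_io import CountMatrix
from tepseq.synthetic_data import ConfounderSpec, simulate_counts

from conftest import annotation_for, tiny_matrix


# --------------------------------------------------------------------------
# Independent TMM oracle: a deliberately naive re-implementation of the
# doubly trimmed weighted mean, written from the definition.
# --------------------------------------------------------------------------


def tmm_oracle(y_s, y_r, trim_m=0.3, trim_a=0.05):
    y_s, y_r = np.asarray(y_s, float), np.asarray(y_r, float)
    n_s, n_r = y_s.sum(), y_r.sum()
    keep = (y_s > 0) & (y_r > 0)
    ps, pr = y_s[keep] / n_s, y_r[keep] / n_r
    M = np.log2(ps / pr)
    A = 0.5 * np.log2(ps * pr)
    if np.allclose(M, 0):
        return 1.0
    n = len(M)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = stats.rankdata(M), stats.rankdata(A)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    w = 1.0 / ((1 - ps[sel]) / y_s[keep][sel] + (1 - pr[sel]) / y_r[keep][sel])
    return float(2 ** (np.average(M[sel], weights=w)))


class TestTMM:
    def test_identical_sample_gives_factor_one(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, 50).astype(float)
        assert nz.tmm_factor(col, col) == pytest.approx(1.0)

    def test_doubled_sample_gives_factor_one(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 500, 50).astype(float)
        assert nz.tmm_factor(2 * col, col) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_oracle_on_20_gene_toys(self, seed):
        rng = np.random.default_rng(seed)
        y_s = rng.integers(0, 300, 20).astype(float)
        y_r = rng.integers(1, 300, 20).astype(float)
        y_s[0] = max(y_s[0], 1)  # keep library sizes positive
        assert nz.tmm_factor(y_s, y_r) == pytest.approx(
            tmm_oracle(y_s, y_r), abs=1e-8
        )

    def test_factors_geometric_mean_one(self, small_cohort):
        m, _, _ = small_cohort
        ref = nz.select_tmm_reference(m, list(m.sample_ids))
        factors, _ = nz.tmm_factors(m.counts.astype(float), ref)
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-9)
        assert (factors > 0).all()


class TestReferenceSelection:
    def test_single_candidate(self, small_cohort):
        m, _, _ = small_cohort
        s = str(m.sample_ids[3])
        assert nz.select_tmm_reference(m, [s]) == s

    def test_identical_columns_tie_breaks_to_first(self):
        col = np.arange(1, 41)
        m = tiny_matrix(np.column_stack([col] * 4))
        assert nz.select_tmm_reference(m, list(m.sample_ids)) == "s0"

    def test_matches_exhaustive_argmin(self):
        rng = np.random.default_rng(5)
        m = tiny_matrix(rng.integers(0, 400, size=(60, 5)))
        cpm = m.cpm().to_numpy()
        q75 = np.quantile(cpm, 0.75, axis=0)
        expected = m.sample_ids[int(np.argmin(np.abs(q75 - q75.mean())))]
        assert nz.select_tmm_reference(m, list(m.sample_ids)) == expected

    def test_empty_candidates_error(self, small_cohort):
        m, _, _ = small_cohort
        with pytest.raises(nz.NormalizationError):
            nz.select_tmm_reference(m, [])


class TestLogCPM:
    def test_closed_form_zero_count(self):
        counts = pd.DataFrame({"s": [0]}, index=["g"])
        eff = pd.Series({"s": 1e6})
        val = nz.logcpm(counts, eff).iloc[0, 0]
        assert val == pytest.approx(np.log2(0.5 * 1e6 / (1e6 + 1)))

    def test_monotone_in_counts(self):
        counts = pd.DataFrame({"s": [10, 20, 40]}, index=list("abc"))
        eff = pd.Series({"s": 1e5})
        col = nz.logcpm(counts, eff)["s"]
        assert col.is_monotonic_increasing


class TestStableGenes:
    def test_libsize_proportional_gene_is_stable(self, small_cohort):
        m, ann, truth = small_cohort
        stable, r_lib, r_age = nz.stable_gene_selection(m, ann.age())
        # planted depth-tracking genes recovered at high rate
        planted = set(truth["stable_genes"])
        recall = len(set(stable) & planted) / len(planted)
        assert recall >= 0.9

    def test_age_tracking_gene_excluded(self):
        rng = np.random.default_rng(2)
        n = 80
        age = pd.Series(rng.normal(60, 10, n), index=[f"s{j}" for j in range(n)])
        lib_driver = rng.lognormal(10, 0.3, n)
        good = rng.poisson(lib_driver / 50.0)
        bad = np.round(10 * age.to_numpy()).astype(int)
        filler = rng.poisson(np.outer(np.full(30, 1.0), lib_driver / 100.0))
        m = tiny_matrix(
            np.vstack([good, bad, filler]), genes=["good", "agegene"] + [f"f{i}" for i in range(30)]
        )
        stable, r_lib, r_age = nz.stable_gene_selection(m, age)
        assert "agegene" not in stable
        assert abs(r_age.loc["agegene"]) > 0.9

    def test_zero_variance_gene_warned_and_excluded(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(8, 0.3, 40)
        rows = [rng.poisson(base / 10), np.full(40, 7)]
        m = tiny_matrix(np.vstack([rows[0], rows[1]]), genes=["var", "flat"])
        age = pd.Series(60.0, index=m.sample_ids)
        with pytest.warns(UserWarning, match="zero-variance"):
            stable, _, _ = nz.stable_gene_selection(m, age)
        assert "flat" not in stable


class TestRUV:
    def test_recovers_planted_batch_factor(self):
        m, ann, truth = simulate_counts(
            n_genes=400, n_samples=100, frac_de=0.0,
            confounders=ConfounderSpec(batch_strength=0.8), seed=21,
        )
        controls = truth["stable_genes"]
        W, mu, loadings = nz.ruv_estimate(m, controls, k=1)
        r = np.corrcoef(W[0], truth["batch_scores"])[0, 1]
        assert abs(r) > 0.9

    def test_constant_controls_error(self):
        m = tiny_matrix(np.tile([[7], [9]], (1, 10)))
        with pytest.raises(nz.NormalizationError, match="constant"):
            nz.ruv_estimate(m, ["g0", "g1"], k=1)

    def test_scores_ordered_by_singular_value(self, small_cohort):
        m, _, truth = small_cohort
        W, _, _ = nz.ruv_estimate(m, truth["stable_genes"], k=3)
        norms = np.linalg.norm(W.to_numpy(), axis=0)
        assert norms[0] >= norms[1] >= norms[2]

    def test_k_beyond_rank_errors(self):
        rng = np.random.default_rng(4)
        m = tiny_matrix(rng.integers(1, 50, size=(5, 3)))
        with pytest.raises(nz.NormalizationError):
            nz.ruv_estimate(m, list(m.gene_ids), k=4)


class TestAssignFactors:
    def _frame(self, cols):
        idx = [f"s{j}" for j in range(len(next(iter(cols.values()))))]
        return pd.DataFrame(cols, index=idx)

    def test_group_aligned_factor_protected(self):
        n = 60
        group = pd.Series(
            ["a"] * (n // 2) + ["b"] * (n // 2), index=[f"s{j}" for j in range(n)]
        )
        rng = np.random.default_rng(5)
        w_group = np.where(group == "a", -1.0, 1.0) + rng.normal(0, 0.1, n)
        lib = pd.Series(rng.lognormal(10, 0.3, n), index=group.index)
        W = self._frame({0: w_group})
        removed, _ = nz.assign_factors(W, group, {"lib_size": lib})
        assert removed == []

    def test_libsize_factor_removed_with_match(self):
        n = 60
        rng = np.random.default_rng(6)
        group = pd.Series(
            ["a", "b"] * (n // 2), index=[f"s{j}" for j in range(n)]
        )
        lib = pd.Series(rng.lognormal(10, 0.3, n), index=group.index)
        w = (lib - lib.mean()) / lib.std() + rng.normal(0, 0.05, n)
        W = self._frame({0: w.to_numpy()})
        removed, matches = nz.assign_factors(W, group, {"lib_size": lib})
        assert removed == [0]
        assert matches[0] == ["lib_size"]

    def test_pure_noise_factor_not_removed(self):
        n = 200
        rng = np.random.default_rng(7)
        group = pd.Series(["a", "b"] * (n // 2), index=[f"s{j}" for j in range(n)])
        lib = pd.Series(rng.lognormal(10, 0.3, n), index=group.index)
        W = self._frame({0: rng.normal(0, 1, n)})
        removed, _ = nz.assign_factors(W, group, {"lib_size": lib})
        assert removed == []


class TestRUVCorrect:
    def test_no_removed_factors_is_identity(self, small_cohort):
        m, _, truth = small_cohort
        W, _, _ = nz.ruv_estimate(m, truth["stable_genes"], k=2)
        corrected, lib, _ = nz.ruv_correct(m, W, [])
        assert np.array_equal(corrected.to_numpy(), m.counts.to_numpy().astype(float))
        assert np.array_equal(lib.to_numpy(), m.lib_size.to_numpy().astype(float))

    def test_planted_batch_removed_from_log_expression(self):
        m, ann, truth = simulate_counts(
            n_genes=400, n_samples=120, frac_de=0.0,
            confounders=ConfounderSpec(batch_strength=0.8), seed=22,
        )
        batch = truth["batch_scores"].to_numpy()
        # two factors: the controls carry both a depth direction and the
        # planted batch; removing both wipes the batch out of expression
        W, _, _ = nz.ruv_estimate(m, truth["stable_genes"], k=2)
        corrected, _, _ = nz.ruv_correct(m, W, [0, 1])

        def gene_batch_corr(mat):
            X = np.log2(mat + 1.0)
            Xc = X - X.mean(axis=1, keepdims=True)
            bc = batch - batch.mean()
            denom = np.sqrt((Xc**2).sum(axis=1) * (bc**2).sum())
            return np.abs(Xc @ bc / np.maximum(denom, 1e-12))

        pre = gene_batch_corr(m.counts.to_numpy(dtype=float))
        post = gene_batch_corr(corrected.to_numpy())
        assert np.median(pre) > 0.6
        assert (post < 0.1).mean() >= 0.95

    def test_corrected_values_nonnegative(self, small_cohort):
        m, _, truth = small_cohort
        W, _, _ = nz.ruv_estimate(m, truth["stable_genes"], k=2)
        corrected, _, _ = nz.ruv_correct(m, W, [0, 1])
        assert (corrected.to_numpy() >= 0).all()


class TestIterativeCorrection:
    def test_k0_degenerates_to_tmm_logcpm(self, small_cohort):
        m, ann, _ = small_cohort
        model, corrected, log_mat = nz.iterative_correction(
            m, ann, list(m.sample_ids), k=0
        )
        assert model.stable_genes == [] and model.removed_factors == []
        eff = m.lib_size.astype(float) * model.tmm_factors
        expected = nz.logcpm(m.counts.astype(float), eff)
        assert np.allclose(log_mat.to_numpy(), expected.to_numpy())

    def test_held_out_labels_never_used(self, small_cohort):
        m, ann, _ = small_cohort
        training = list(m.sample_ids[:50])
        model1, _, log1 = nz.iterative_correction(m, ann, training, k=2)
        shuffled = ann.table.copy()
        held = [s for s in m.sample_ids if s not in training]
        shuffled.loc[held, "group"] = (
            shuffled.loc[held, "group"].sample(frac=1, random_state=1).to_numpy()
        )
        from tepseq.core_io import SampleAnnotation

        model2, _, log2 = nz.iterative_correction(
            m, SampleAnnotation(shuffled), training, k=2
        )
        assert np.array_equal(log1.to_numpy(), log2.to_numpy())

    def test_corrected_lib_size_is_column_sum(self, small_cohort):
        m, ann, _ = small_cohort
        model, corrected, _ = nz.iterative_correction(
            m, ann, list(m.sample_ids), k=2
        )
        assert np.allclose(
            model.corrected_lib_size.to_numpy(), corrected.sum(axis=0).to_numpy()
        )

    def test_serialization_round_trip(self, small_cohort, tmp_path):
        m, ann, _ = small_cohort
        model, _, _ = nz.iterative_correction(m, ann, list(m.sample_ids), k=2)
        path = tmp_path / "norm.json"
        model.save(path)
        back = nz.NormalizationModel.load(path)
        assert back.ref_sample == model.ref_sample
        assert back.removed_factors == model.removed_factors
        assert np.allclose(
            back.tmm_factors.to_numpy(), model.tmm_factors.to_numpy(), atol=1e-12
        )
        assert np.allclose(back.W.to_numpy(), model.W.to_numpy(), atol=1e-12)


class TestRLE:
    def test_identical_inputs_give_unit_p(self, small_cohort):
        m, ann, _ = small_cohort
        _, _, log_mat = nz.iterative_correction(m, ann, list(m.sample_ids), k=0)
        d1, d2, p = nz.rle_stats(log_mat, log_mat)
        assert p == 1.0
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_rle_rows_have_zero_median(self, small_cohort):
        m, ann, _ = small_cohort
        _, _, log_mat = nz.iterative_correction(m, ann, list(m.sample_ids), k=0)
        rle = nz.rle_matrix(log_mat)
        assert np.allclose(rle.median(axis=1).to_numpy(), 0.0, atol=1e-12)

    def test_planted_offsets_reduced_significantly(self):
        rng = np.random.default_rng(31)
        base = rng.normal(5, 2, size=(300, 1))
        clean = base + rng.normal(0, 0.2, size=(300, 100))
        offsets = rng.normal(0, 1.5, 100)
        dirty = clean + offsets
        cols = [f"s{j}" for j in range(100)]
        idx = [f"g{i}" for i in range(300)]
        before = pd.DataFrame(dirty, index=idx, columns=cols)
        after = pd.DataFrame(clean, index=idx, columns=cols)
        _, _, p = nz.rle_stats(before, after)
        assert p < 0.01
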