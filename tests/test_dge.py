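"""Time-course DGE, BH adjustment, profile classification, phase clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import grntrace as gt
from grntrace.datasets import ExpressionDataset, make_sample_sheet
from grntrace.synth import PROFILE_ACTIVATOR, PROFILE_NONE, PROFILE_REPRESSOR


def two_genotype_dataset(values: np.ndarray, genes) -> ExpressionDataset:
    sheet = make_sample_sheet(["gA", "gB"], (3, 5, 9, 12, 14), 3)
    frame = pd.DataFrame(values, index=genes, columns=sheet.index)
    return ExpressionDataset(frame, sheet)


class TestNormalize:
    def _sheet(self, n):
        sheet = make_sample_sheet(["gA", "gB"], (3, 5, 9, 12, 14), 3)
        return sheet.iloc[:n]

    def test_log2_of_scaled_values(self):
        raw = pd.DataFrame(
            np.tile([[0.0], [7.0]], (1, 30)),
            index=["zero", "seven"],
            columns=self._sheet(30).index,
        )
        out = gt.normalize(raw, self._sheet(30))
        assert (out.values.loc["zero"] == 0.0).all()
        assert np.allclose(out.values.loc["seven"], 3.0)

    def test_depth_invariance(self):
        rng = np.random.default_rng(0)
        raw = pd.DataFrame(
            rng.poisson(20, size=(10, 30)).astype(float),
            index=[f"G{i}" for i in range(10)],
            columns=self._sheet(30).index,
        )
        doubled = raw.copy()
        doubled.iloc[:, 0] *= 2
        a = gt.normalize(raw, self._sheet(30)).values
        b = gt.normalize(doubled, self._sheet(30)).values
        np.testing.assert_allclose(a.iloc[:, 0], b.iloc[:, 0], rtol=1e-9)

    def test_all_zero_sample_rejected(self):
        raw = pd.DataFrame(
            np.ones((3, 30)), index=list("abc"), columns=self._sheet(30).index
        )
        raw.iloc[:, 5] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            gt.normalize(raw, self._sheet(30))


class TestTimecourseDGE:
    def test_noise_free_shift_recovered_exactly(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        sheet = make_sample_sheet(["gA", "gB"], (3, 5, 9, 12, 14), 3)
        day = sheet["day"].to_numpy()
        trend = 0.3 * day  # inside the smooth-trend span
        shifted = trend + 2.0 * (sheet["genotype"] == "gB").to_numpy()
        expr = two_genotype_dataset(np.vstack([trend, shifted]), ["null", "hit"])
        res = gt.timecourse_dge(expr, ("gA", "gB"))
        assert res.loc["hit", "b"] == pytest.approx(2.0, abs=1e-9)
        assert res.loc["hit", "p"] < 1e-12
        assert res.loc["null", "lrt_stat"] == pytest.approx(0.0, abs=1e-9)
        assert res.loc["null", "p"] == pytest.approx(1.0)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(1000, 30))
        expr = two_genotype_dataset(values, [f"G{i}" for i in range(1000)])
        res = gt.timecourse_dge(expr, ("gA", "gB"))
        assert stats.kstest(res["p"], "uniform").pvalue > 0.01
        assert (res["q"] < 0.1).mean() <= 0.12

    def test_constant_gene_is_null(self):
        values = np.vstack([np.full(30, 5.0), np.random.default_rng(2).normal(size=30)])
        expr = two_genotype_dataset(values, ["flat", "noisy"])
        res = gt.timecourse_dge(expr, ("gA", "gB"))
        assert res.loc["flat", "lrt_stat"] == 0.0
        assert res.loc["flat", "p"] == 1.0

    def test_sign_convention_b_positive_in_second_genotype(self):
        sheet = make_sample_sheet(["gA", "gB"], (3, 5, 9, 12, 14), 3)
        up_in_b = 1.0 + (sheet["genotype"] == "gB").to_numpy() * 3.0
        expr = two_genotype_dataset(up_in_b[None, :], ["g"])
        res = gt.timecourse_dge(expr, ("gA", "gB"))
        assert res.loc["g", "b"] > 0
        res_flipped = gt.timecourse_dge(expr, ("gB", "gA"))
        assert res_flipped.loc["g", "b"] < 0

    def test_missing_timepoints_rejected(self, expr):
        sub = expr.subset_samples(
            [s for s in expr.sample_ids if not s.startswith("WT_d3")
             and not s.startswith("WT_d5") and not s.startswith("WT_d9")
             and not s.startswith("WT_d12")]
        )
        with pytest.raises(ValueError, match="fewer than 2 timepoints"):
            gt.timecourse_dge(sub, ("WT", "dek1"))


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert gt.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            gt.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        assert (gt.bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_matches_hand_stepup_on_random_vectors(self):
        def hand_bh(p):
            p = np.asarray(p)
            m = len(p)
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank_from_top, i in enumerate(order[::-1]):
                rank = m - rank_from_top
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        rng = np.random.default_rng(3)
        for _ in range(10):
            p = rng.uniform(size=25)
            np.testing.assert_allclose(gt.bh_adjust(p), hand_bh(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            gt.bh_adjust([0.5, 1.5])


class TestClassifyProfiles:
    def _mk(self, b_sign, q, contrast):
        res = pd.DataFrame(
            {"lrt_stat": [5.0], "p": [q], "q": [q], "b": [b_sign * 1.0]},
            index=["g"],
        )
        res.attrs["contrast"] = contrast
        return res

    def test_activator_pattern(self):
        # dek1 up vs WT, oex1 down vs WT, dek1 up vs oex1
        out = gt.classify_profiles(
            self._mk(+1, 0.01, ("WT", "dek1")),
            self._mk(-1, 0.01, ("WT", "oex1")),
            self._mk(+1, 0.01, ("oex1", "dek1")),
        )
        assert out.loc["g", "profile"] == PROFILE_ACTIVATOR

    def test_repressor_pattern(self):
        out = gt.classify_profiles(
            self._mk(-1, 0.01, ("WT", "dek1")),
            self._mk(+1, 0.01, ("WT", "oex1")),
            self._mk(-1, 0.01, ("oex1", "dek1")),
        )
        assert out.loc["g", "profile"] == PROFILE_REPRESSOR

    def test_insignificant_contrast_gates_to_none(self):
        out = gt.classify_profiles(
            self._mk(+1, 0.01, ("WT", "dek1")),
            self._mk(-1, 0.5, ("WT", "oex1")),
            self._mk(+1, 0.01, ("oex1", "dek1")),
        )
        assert out.loc["g", "profile"] == PROFILE_NONE

    def test_orientation_is_contrast_aware(self):
        # same biology expressed with flipped contrast tuples
        out = gt.classify_profiles(
            self._mk(-1, 0.01, ("dek1", "WT")),   # WT lower... dek1 higher
            self._mk(+1, 0.01, ("oex1", "WT")),   # WT higher than oex1
            self._mk(-1, 0.01, ("dek1", "oex1")),  # oex1 lower than dek1
        )
        assert out.loc["g", "profile"] == PROFILE_ACTIVATOR

    def test_missing_gene_flagged_none(self):
        a = self._mk(+1, 0.01, ("WT", "dek1"))
        b = self._mk(-1, 0.01, ("WT", "oex1"))
        c = self._mk(+1, 0.01, ("oex1", "dek1"))
        c = c.rename(index={"g": "other"})
        out = gt.classify_profiles(a, b, c)
        assert out.loc["g", "profile"] == PROFILE_NONE
        assert bool(out.loc["g", "missing"])


class TestCumulativeMisregulation:
    def _res(self, lrt):
        return pd.DataFrame({"lrt_stat": [lrt], "p": [0.5], "q": [0.5], "b": [0.0]}, index=["g"])

    def test_sum_and_symmetry(self):
        r = [self._res(2.5), self._res(3.5), self._res(4.0)]
        total = gt.cumulative_misregulation(*r)
        assert total["g"] == pytest.approx(10.0)
        total_perm = gt.cumulative_misregulation(r[2], r[0], r[1])
        assert total_perm["g"] == pytest.approx(10.0)

    def test_zero(self):
        assert gt.cumulative_misregulation(self._res(0.0))["g"] == 0.0

    def test_planted_targets_exceed_nontargets_noise_free(self, noise_free):
        _, tr, ex, _ = noise_free
        d1 = gt.timecourse_dge(ex, ("WT", "dek1"))
        d2 = gt.timecourse_dge(ex, ("WT", "oex1"))
        d3 = gt.timecourse_dge(ex, ("oex1", "dek1"))
        total = gt.cumulative_misregulation(d1, d2, d3)
        planted = [g for g, p in tr.planted_profile.items() if p != PROFILE_NONE]
        nones = [g for g in tr.target_ids if tr.planted_profile[g] == PROFILE_NONE]
        assert total[planted].min() > total[nones].max()


class TestClusterPhases:
    def test_peak_classes_separate(self):
        sheet = make_sample_sheet(["WT"], (3, 5, 9, 12, 14), 3)
        day = sheet["day"].to_numpy()
        early = (day <= 5).astype(float)
        late = (day >= 12).astype(float)
        values = np.vstack([early] * 5 + [late] * 5)
        genes = [f"E{i}" for i in range(5)] + [f"L{i}" for i in range(5)]
        expr = ExpressionDataset(
            pd.DataFrame(values, index=genes, columns=sheet.index), sheet
        )
        labels = gt.cluster_phases(expr, genes, k=2, seed=0)
        assert len(set(labels[:5])) == 1
        assert len(set(labels[5:])) == 1
        assert labels["E0"] != labels["L0"]

    def test_degenerate_profiles_reduce_k(self):
        sheet = make_sample_sheet(["WT"], (3, 5, 9, 12, 14), 3)
        values = np.tile(np.linspace(0, 1, 15), (4, 1))
        genes = list("abcd")
        expr = ExpressionDataset(
            pd.DataFrame(values, index=genes, columns=sheet.index), sheet
        )
        with pytest.warns(UserWarning, match="reducing phase clusters"):
            labels = gt.cluster_phases(expr, genes, k=3, seed=0)
        assert len(set(labels)) == 1
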