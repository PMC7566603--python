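import numpy as np
import pandas as pd
import pytest
from scipy import stats
from hypothesis import given, settings
from hypothesis import strategies as st

from overlayde import (
    DataError,
    KdeModel,
    apply_cutoffs,
    build_kde_model,
    build_replicate_cloud,
    call_de,
    build_condition_points,
    de_pvalues,
    estimate_bandwidth,
    kde_cdf,
    kde_pdf,
    log2_fold_changes,
)
from overlayde.kde import DEReport
from overlayde.io import SampleDesign, log10_transform

from conftest import make_expression


def _design():
    return SampleDesign(pd.DataFrame(
        {"condition": ["c1", "c1", "c2", "c2"],
         "replicate": ["r1", "r2", "r1", "r2"]},
        index=["c1_r1", "c1_r2", "c2_r1", "c2_r2"]))


def _random_model(seed, n=40):
    rng = np.random.default_rng(seed)
    x1 = rng.normal(0, 1, n)
    x2 = x1 + rng.normal(0, 0.2, n)
    h1, h2 = estimate_bandwidth(np.column_stack([x1, x2]))
    return KdeModel(x1=x1, x2=x2, h1=h1, h2=h2)


class TestBandwidth:
    def test_silverman_closed_form_n64(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(0, 1, size=(64, 2))
        pts = (pts - pts.mean(axis=0)) / pts.std(axis=0, ddof=1)  # sd exactly 1
        h1, h2 = estimate_bandwidth(pts, "silverman")
        assert h1 == pytest.approx(0.5, abs=1e-12)  # 64 ** (-1/6) = 1/2
        assert h2 == pytest.approx(0.5, abs=1e-12)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 1, size=(50, 2))
        h = np.array(estimate_bandwidth(pts))
        hc = np.array(estimate_bandwidth(pts * 3.5))
        np.testing.assert_allclose(hc, 3.5 * h)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DataError):
            estimate_bandwidth(np.zeros((1, 2)))
        pts = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(DataError, match="zero variance"):
            estimate_bandwidth(pts)

    def test_plugin_bandwidth_reasonable_on_gaussian(self):
        # Sheather-Jones on normal data should land near the optimal
        # Gaussian-reference bandwidth 1.06 * sd * n^(-1/5)
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, size=(500, 2))
        h1, h2 = estimate_bandwidth(pts, "plugin")
        ref = 1.06 * 500 ** (-1 / 5)
        assert 0.5 * ref < h1 < 1.5 * ref
        assert 0.5 * ref < h2 < 1.5 * ref


class TestKdeCdf:
    def test_single_kernel_at_center_is_quarter(self):
        model = KdeModel(x1=np.array([1.0]), x2=np.array([2.0]), h1=0.3, h2=0.7)
        assert kde_cdf((1.0, 2.0), model) == pytest.approx(0.25, abs=1e-12)

    def test_cdf_limits(self):
        model = _random_model(3)
        assert kde_cdf((1e6, 1e6), model) == pytest.approx(1.0)
        assert kde_cdf((-1e6, -1e6), model) == pytest.approx(0.0)

    def test_two_kernel_hand_evaluation(self):
        model = KdeModel(x1=np.array([0.0, 1.0]), x2=np.array([0.0, -1.0]),
                         h1=1.0, h2=1.0)
        p = (0.5, 0.5)
        expected = 0.5 * (
            stats.norm.cdf(0.5) * stats.norm.cdf(0.5)
            + stats.norm.cdf(-0.5) * stats.norm.cdf(1.5)
        )
        assert kde_cdf(p, model) == pytest.approx(expected, abs=1e-12)

    def test_single_kernel_matches_product_of_normal_cdfs(self):
        model = KdeModel(x1=np.array([0.3]), x2=np.array([-0.2]), h1=0.5, h2=1.5)
        for p in [(-1.0, 0.0), (0.3, -0.2), (2.0, 1.0)]:
            expected = stats.norm.cdf((p[0] - 0.3) / 0.5) * stats.norm.cdf(
                (p[1] + 0.2) / 1.5)
            assert kde_cdf(p, model) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounded_and_coordinate_monotone(self, seed):
        model = _random_model(seed)
        rng = np.random.default_rng(seed + 1)
        pts = rng.normal(0, 2, size=(10, 2))
        vals = np.asarray(kde_cdf(pts, model))
        assert np.all((vals >= 0) & (vals <= 1))
        eps = 0.3
        for p, v in zip(pts, vals):
            assert kde_cdf((p[0] + eps, p[1]), model) >= v - 1e-12
            assert kde_cdf((p[0], p[1] + eps), model) >= v - 1e-12


class TestBuildKdeModel:
    def test_cloud_is_union_of_replicate_clouds(self, two_cond_design):
        rng = np.random.default_rng(5)
        em = make_expression(
            {k: rng.lognormal(2, 1, 25) for k in
             ["cond1_r1", "cond1_r2", "cond2_r1", "cond2_r2"]},
            design=two_cond_design)
        em_log = log10_transform(em)
        model = build_kde_model(em_log, ("cond1", "cond2"))
        assert model.n_points == 50  # 2m cloud points
        c1 = build_replicate_cloud(em_log, "cond1")
        c2 = build_replicate_cloud(em_log, "cond2")
        expected = np.vstack([c1.xy, c2.xy])
        np.testing.assert_allclose(
            np.sort(np.column_stack([model.x1, model.x2]), axis=0),
            np.sort(expected, axis=0))

    def test_identical_replicates_on_diagonal(self, two_cond_design):
        rng = np.random.default_rng(6)
        a = rng.lognormal(2, 1, 30)
        b = rng.lognormal(2, 1, 30)
        em = make_expression(
            {"cond1_r1": a, "cond1_r2": a, "cond2_r1": b, "cond2_r2": b},
            design=two_cond_design)
        model = build_kde_model(log10_transform(em), ("cond1", "cond2"))
        np.testing.assert_allclose(model.x1, model.x2)


class TestDePvalues:
    def _setup(self, seed=7, m=60):
        rng = np.random.default_rng(seed)
        mean = rng.lognormal(2, 1, m)
        noise = lambda: rng.lognormal(0, 0.05, m)
        em = make_expression(
            {"c1_r1": mean * noise(), "c1_r2": mean * noise(),
             "c2_r1": mean * noise(), "c2_r2": mean * noise()},
            design=_design())
        em_log = log10_transform(em)
        rep = (build_replicate_cloud(em_log, "c1"),
               build_replicate_cloud(em_log, "c2"))
        combos = build_condition_points(em_log, "c1", "c2")
        result = call_de(combos, rep, 0.004)
        report = DEReport.from_overlay(result, em, ("c1", "c2"))
        model = build_kde_model(em_log, ("c1", "c2"))
        return em, em_log, report, model

    def test_hdr_deep_point_near_one_outlier_near_zero(self):
        em, em_log, report, model = self._setup()
        # probe a central cloud point and a far outlier directly
        center = (np.median(model.x1), np.median(model.x2))
        outlier = (model.x1.max() + 5, model.x2.min() - 5)
        from overlayde.kde import _hdr_pvalues

        p = _hdr_pvalues(np.array([center, outlier]), model, n_mc=4000, seed=0)
        assert p[0] > 0.5
        assert p[1] < 0.02

    def test_cdf_mode_lower_left_tail(self):
        em, em_log, report, model = self._setup()
        out = de_pvalues(report, model, em_log, ("c1", "c2"), mode="cdf")
        # gene with the lowest expression has the smallest CDF p
        low_gene = em.values.mean(axis=1).idxmin()
        assert out.table.loc[low_gene, "p"] < 0.1

    def test_hdr_matches_grid_integration_oracle(self):
        em, em_log, report, model = self._setup(seed=8, m=40)
        pts = np.column_stack([
            em_log.values["c1_r1"].to_numpy(), em_log.values["c2_r1"].to_numpy()
        ])[:5]
        from overlayde.kde import _hdr_pvalues

        mc = _hdr_pvalues(pts, model, n_mc=20_000, seed=1)
        # dense-grid numerical integration of the mixture density
        lo1, hi1 = model.x1.min() - 5 * model.h1, model.x1.max() + 5 * model.h1
        lo2, hi2 = model.x2.min() - 5 * model.h2, model.x2.max() + 5 * model.h2
        g1 = np.linspace(lo1, hi1, 400)
        g2 = np.linspace(lo2, hi2, 400)
        gg = np.column_stack([np.repeat(g1, 400), np.tile(g2, 400)])
        dens = np.asarray(kde_pdf(gg, model))
        cell = (g1[1] - g1[0]) * (g2[1] - g2[0])
        f0 = np.asarray(kde_pdf(pts, model))
        oracle = np.array([(dens[dens <= f] * cell).sum() * 1 for f in f0])
        se = np.sqrt(mc * (1 - mc) / 20_000) + 1e-3
        np.testing.assert_array_less(np.abs(mc - oracle), 3 * se + 0.02)

    def test_two_sided_mode_and_unknown_mode(self):
        em, em_log, report, model = self._setup()
        cdf = de_pvalues(report, model, em_log, ("c1", "c2"), mode="cdf")
        two = de_pvalues(report, model, em_log, ("c1", "c2"), mode="two_sided")
        f = cdf.table["p"].to_numpy()
        np.testing.assert_allclose(
            two.table["p"].to_numpy(), 2 * np.minimum(f, 1 - f))
        with pytest.raises(DataError, match="mode"):
            de_pvalues(report, model, em_log, ("c1", "c2"), mode="bogus")

    def test_all_combo_maximum_is_conservative(self):
        em, em_log, report, model = self._setup()
        first = de_pvalues(report, model, em_log, ("c1", "c2"), combo="first")
        allc = de_pvalues(report, model, em_log, ("c1", "c2"), combo="all")
        assert (allc.table["p"].to_numpy()
                >= first.table["p"].to_numpy() - 1e-12).all()


class TestCutoffs:
    def _report(self):
        table = pd.DataFrame(
            {
                "de_overlay": [True, True, True, False],
                "p": [0.01, 0.20, 0.01, 0.01],
                "log2_fold_change": [2.0, 2.0, 0.5, 3.0],
                "de_final": [True, True, True, False],
            },
            index=["g1", "g2", "g3", "g4"],
        )
        return DEReport(table)

    def test_no_cutoffs_is_identity(self):
        out = apply_cutoffs(self._report())
        assert out.de_final_genes == ["g1", "g2", "g3"]

    def test_fold_cutoff_on_mean_tpm(self, two_cond_design):
        em = make_expression(
            {"cond1_r1": [10.0, 10.0], "cond1_r2": [10.0, 10.0],
             "cond2_r1": [40.0, 15.0], "cond2_r2": [40.0, 15.0]},
            design=two_cond_design)
        fc = log2_fold_changes(em, ("cond1", "cond2"))
        assert fc.iloc[0] == pytest.approx(2.0)  # 10 -> 40 is 2 doublings
        report = DEReport(pd.DataFrame(
            {"de_overlay": [True, True], "p": [0.0, 0.0],
             "log2_fold_change": fc.to_numpy(), "de_final": [True, True]},
            index=fc.index))
        out = apply_cutoffs(report, fold_cutoff=2.0)
        assert out.table["de_final"].tolist() == [True, False]

    def test_p_cutoff_filters_and_zero_excludes_all(self):
        out = apply_cutoffs(self._report(), p_cutoff=0.05)
        assert out.de_final_genes == ["g1", "g3"]
        none = apply_cutoffs(self._report(), p_cutoff=0.0)
        assert none.de_final_genes == []

    def test_cutoffs_never_add_genes(self):
        report = self._report()
        for p_cut in (None, 0.5, 0.05):
            for f_cut in (None, 1.5, 4.0):
                out = apply_cutoffs(report, p_cutoff=p_cut, fold_cutoff=f_cut)
                assert set(out.de_final_genes) <= {"g1", "g2", "g3"}

    def test_tightening_is_monotone(self):
        report = self._report()
        n_loose = len(apply_cutoffs(report, p_cutoff=0.5, fold_cutoff=1.5).de_final_genes)
        n_tight = len(apply_cutoffs(report, p_cutoff=0.05, fold_cutoff=4.0).de_final_genes)
        assert n_tight <= n_loose

    def test_out_of_range_cutoffs_rejected(self):
        with pytest.raises(DataError):
            apply_cutoffs(self._report(), p_cutoff=1.5)
        with pytest.raises(DataError):
            apply_cutoffs(self._report(), fold_cutoff=0.5)
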