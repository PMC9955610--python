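"""Broken-line model: GLM engine, breakpoint recovery, class assignment."""

import numpy as np
import pytest

from bcivalidate.datatypes import DegenerateInputError
from bcivalidate.regression import fit_ols
from bcivalidate.segmentation import (
    assign_size_classes,
    binned_mass_table,
    compare_models_plot,
    fit_glm,
    fit_segmented,
    select_breakpoints,
)
from bcivalidate.synthetic_data import (
    generate_mass_segmented,
    intercept_for_anchor,
    segmented_mean_mass,
)

from conftest import records_from_arrays

PSI = (20.2, 30.0)
SLOPES = (30.0, 90.0, 180.0)
ICPT = intercept_for_anchor(PSI, SLOPES, 17.0, 158.2)


class TestGlm:
    def test_gamma_intercept_only_fits_mean(self):
        g = fit_glm(np.ones((3, 1)), [2.0, 2.0, 2.0], "gamma_neg_inverse")
        np.testing.assert_allclose(g.fitted, 2.0, rtol=1e-8)

    def test_gaussian_identity_equals_ols(self, rng):
        x = rng.normal(3, 0.3, 80)
        y = 1.5 * x + rng.normal(0, 0.2, 80)
        g = fit_glm(np.column_stack([np.ones_like(x), x]), y, "gaussian_identity")
        f = fit_ols(x, y)
        assert g.coefficients[0] == pytest.approx(f.intercept, abs=1e-9)
        assert g.coefficients[1] == pytest.approx(f.slope, abs=1e-9)

    def test_gamma_recovery_within_3_se(self, rng):
        x = rng.uniform(1, 5, 10_000)
        truth = np.array([-0.3, -0.05])
        mu = -1.0 / (truth[0] + truth[1] * x)
        y = rng.gamma(50.0, mu / 50.0)
        g = fit_glm(np.column_stack([np.ones_like(x), x]), y, "gamma_neg_inverse")
        se = np.sqrt(np.diag(g.cov))
        assert np.all(np.abs(g.coefficients - truth) < 3 * se)
        assert g.dispersion == pytest.approx(1 / 50.0, rel=0.15)

    def test_gamma_rejects_nonpositive(self):
        with pytest.raises(DegenerateInputError):
            fit_glm(np.ones((5, 1)), [1.0, 2.0, 0.0, 1.0, 1.0], "gamma_neg_inverse")


class TestFitSegmented:
    def test_noiseless_kink_recovered_exactly(self):
        x = np.linspace(10, 40, 200)
        y = np.where(x < 20, x, 20 + 5 * (x - 20))
        m = fit_segmented(x, y, 1)
        assert m.converged
        assert m.psi[0] == pytest.approx(20.0, abs=1e-3)

    def test_noiseless_residuals_zero(self, rng):
        svl = rng.uniform(12, 46, 200)
        mass = generate_mass_segmented(svl, PSI, SLOPES, ICPT, 0.0, seed=1)
        m = fit_segmented(svl, mass, 2, psi0=PSI)
        resid = mass - m.predict_mean(svl)
        assert np.max(np.abs(resid)) < 1e-6 * mass.mean()

    def test_recovery_within_3_se(self):
        r = np.random.default_rng(42)
        svl = r.uniform(10, 46.4, 883)
        mass = generate_mass_segmented(svl, PSI, SLOPES, ICPT, 0.10, r)
        m = fit_segmented(svl, mass, 2)
        assert m.converged
        for est, se, truth in zip(m.psi, m.psi_se, PSI):
            assert abs(est - truth) < 3 * se

    def test_null_slope_change_rarely_significant(self):
        """On straight-line data the k=1 slope change passes a 0.05 screen
        in at least 90% of runs."""
        r = np.random.default_rng(77)
        ok = 0
        runs = 200
        for _ in range(runs):
            x = r.uniform(0, 10, 300)
            y = 2 + 3 * x + r.normal(0, 1, 300)
            m = fit_segmented(x, y, 1)
            ok += (not m.converged) or m.slope_change_p[0] > 0.05
        assert ok >= 0.9 * runs

    def test_precondition_on_n(self):
        with pytest.raises(DegenerateInputError):
            fit_segmented(np.arange(15.0), np.arange(15.0), 1)

    def test_fixed_point_refit(self):
        r = np.random.default_rng(3)
        svl = r.uniform(10, 46.4, 883)
        mass = generate_mass_segmented(svl, PSI, SLOPES, ICPT, 0.10, r)
        m = fit_segmented(svl, mass, 2)
        m2 = fit_segmented(svl, mass, 2, psi0=m.psi)
        np.testing.assert_allclose(m2.psi, m.psi, atol=2e-4)
        np.testing.assert_allclose(m2.coefficients, m.coefficients, rtol=1e-4)


class TestSelection:
    def test_straight_line_selects_zero_breakpoints(self):
        hits = 0
        runs = 200
        for i in range(runs):
            r = np.random.default_rng(i)
            x = r.uniform(0, 10, 300)
            y = 2 + 3 * x + r.normal(0, 1, 300)
            hits += select_breakpoints(x, y, k_max=5).k == 0
        assert hits >= 0.9 * runs

    def test_three_segment_data_selects_two_breakpoints(self):
        hits = 0
        runs = 25
        for i in range(runs):
            r = np.random.default_rng(500 + i)
            svl = r.uniform(10, 46.4, 883)
            mass = generate_mass_segmented(svl, PSI, SLOPES, ICPT, 0.10, r)
            m = select_breakpoints(svl, mass, k_max=10)
            hits += m.k == 2
        assert hits >= 0.8 * runs  # the full 200-run experiment lives in acceptance

    def test_selected_bic_not_worse_than_plain_glm(self):
        r = np.random.default_rng(8)
        svl = r.uniform(10, 46.4, 883)
        mass = generate_mass_segmented(svl, PSI, SLOPES, ICPT, 0.10, r)
        m = select_breakpoints(svl, mass, k_max=6)
        assert m.bic <= m.bic_trace[0]

    def test_small_n_raises(self):
        with pytest.raises(DegenerateInputError):
            select_breakpoints(np.arange(8.0), np.arange(8.0), k_max=2)


class TestSizeClasses:
    @pytest.mark.parametrize(
        "svl,expected",
        [(17.0, 1), (20.1, 1), (20.2, 2), (24.8, 2), (29.9, 2), (30.0, 3), (34.0, 3)],
    )
    def test_half_open_boundaries(self, svl, expected):
        recs = records_from_arrays([svl], [500.0])
        out = assign_size_classes(recs, PSI)
        assert out[0].size_class == expected

    def test_original_records_untouched(self):
        recs = records_from_arrays([15.0, 25.0], [100.0, 500.0])
        assign_size_classes(recs, PSI)
        assert all(r.size_class is None for r in recs)


class TestBinnedComparison:
    def test_bin_structure(self, rng):
        svl = rng.uniform(10, 46.4, 400)
        mass = segmented_mean_mass(svl, PSI, SLOPES, ICPT)
        recs = records_from_arrays(svl, mass)
        table = binned_mass_table(recs, bin_width=2.0, svl_range=(10.0, 46.4))
        assert len(table) <= 19
        assert table["svl_lo"].iloc[0] == pytest.approx(10.0)
        assert table["svl_hi"].iloc[0] == pytest.approx(12.0)

    def test_noiseless_bin_means_on_curve(self, rng):
        svl = rng.uniform(10, 46.4, 600)
        mass = segmented_mean_mass(svl, PSI, SLOPES, ICPT)
        recs = records_from_arrays(svl, mass)
        table = binned_mass_table(recs)
        for _, row in table.iterrows():
            sel = (svl >= row["svl_lo"]) & (svl < row["svl_hi"])
            assert row["mean_mass_g"] == pytest.approx(mass[sel].mean())

    def test_compare_models_plot_returns_table_and_axes(self, rng):
        import matplotlib

        matplotlib.use("Agg")
        svl = rng.uniform(10, 46.4, 300)
        mass = generate_mass_segmented(svl, PSI, SLOPES, ICPT, 0.1, seed=4)
        recs = records_from_arrays(svl, mass)
        from bcivalidate.regression import fit_sma

        basic = fit_sma(np.log(svl), np.log(mass))
        model = fit_segmented(svl, mass, 2)
        table, ax = compare_models_plot(recs, basic, model)
        assert len(table) > 0
        assert ax.get_xlabel() == "SVL (cm)"
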