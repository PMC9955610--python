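"""Index arithmetic, identities on constructed data, grouping semantics."""

import math

import numpy as np
import pytest

from bcivalidate.condition_indices import (
    BCI_COLUMNS,
    compute_bci_table,
    log_ratio_index,
    log_relative_index,
    percent_fat,
    ratio_index,
    relative_index,
    residual_fat,
    residual_index,
    scaled_fat,
    scaled_mass_index,
)
from bcivalidate.datatypes import DegenerateInputError, SmiParams
from bcivalidate.regression import fit_sma
from bcivalidate.segmentation import assign_size_classes
from bcivalidate.diagnostics import kendall_tau

from conftest import make_clean_config, records_from_arrays
from bcivalidate.synthetic_data import generate_dataset


class TestScalarArithmetic:
    def test_ratio_indices(self):
        assert ratio_index(1000.0, 10.0, 1) == pytest.approx(100.0)
        # group-3 style means: 1301.1 g at 34.0 cm
        assert ratio_index(1301.1, 34.0, 3) == pytest.approx(0.03311, abs=5e-5)
        with pytest.raises(DegenerateInputError):
            ratio_index(-5.0, 10.0, 3)

    def test_isometric_data_gives_constant_fulton(self, rng):
        svl = rng.uniform(10, 40, 50)
        mass = 0.03 * svl**3
        k = ratio_index(mass, svl, 3)
        np.testing.assert_allclose(k, 0.03)

    def test_log_ratio(self):
        assert log_ratio_index(math.e**2, math.e) == pytest.approx(2.0)
        # female-mean style values: 531.9 g, 24.4 cm
        assert log_ratio_index(531.9, 24.4) == pytest.approx(1.965, abs=1e-3)
        assert log_ratio_index(1.0, 5.0) == pytest.approx(0.0)
        with pytest.raises(DegenerateInputError):
            log_ratio_index(100.0, 1.0)

    def test_smi(self):
        p = SmiParams(l0=24.65, b_sma=3.13)
        assert scaled_mass_index(500.0, 24.65, p) == pytest.approx(500.0)
        assert scaled_mass_index(500.0, 25.0, SmiParams(24.65, 3.13)) == pytest.approx(
            478.4, abs=0.5
        )

    def test_percent_fat(self):
        assert percent_fat(10.3, 531.9) == pytest.approx(1.937, abs=1e-3)
        assert percent_fat(50.0, 100.0) == pytest.approx(50.0)


class TestRegressionIndices:
    def test_relative_index_on_and_off_the_line(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0])
        fit = fit_sma(x, y)  # slope 1, intercept 0 in ln-ln space
        svl = np.exp(x)
        on_line = np.exp(fit.predict(x))
        assert relative_index(on_line, svl, fit) == pytest.approx([1.0, 1.0, 1.0])
        assert relative_index(2 * on_line, svl, fit) == pytest.approx([2.0, 2.0, 2.0])
        # record (svl=e, mass=2e): relative = 2, log-relative = ln(2e)/1
        lr = log_relative_index(np.array([2 * math.e]), np.array([math.e]), fit)
        assert lr[0] == pytest.approx(math.log(2 * math.e))

    def test_residuals_zero_on_fitted_line(self, rng):
        svl = rng.uniform(10, 40, 30)
        mass = 0.03 * svl**3.13
        for method in ("ols", "ma", "sma"):
            np.testing.assert_allclose(
                residual_index(mass, svl, method), 0.0, atol=1e-10
            )

    def test_doubling_mass_raises_own_residual(self, rng):
        svl = rng.uniform(10, 40, 25)
        mass = 0.03 * svl**3.13 * np.exp(rng.normal(0, 0.05, 25))
        for method in ("ols", "ma", "sma"):
            before = residual_index(mass, svl, method)[0]
            mass2 = mass.copy()
            mass2[0] *= 2.0
            after = residual_index(mass2, svl, method)[0]
            assert after > before

    def test_residual_fat_sums_to_zero(self, rng):
        svl = rng.uniform(10, 40, 40)
        fat = 1e-4 * svl**6.9 * np.exp(rng.normal(0, 0.8, 40))
        r = residual_fat(fat, svl)
        assert abs(r.sum()) < 1e-9 * np.abs(np.log(fat)).sum()

    def test_zero_fat_rejected_by_ln_measures(self):
        with pytest.raises(DegenerateInputError):
            residual_fat([0.0, 1.0, 2.0], [10.0, 20.0, 30.0])
        with pytest.raises(DegenerateInputError):
            scaled_fat([0.0, 1.0], [10.0, 20.0], SmiParams(20.0, 6.9))


class TestBciTable:
    def test_columns_and_residual_sums(self, clean_records):
        table = compute_bci_table(clean_records, grouping="all")
        assert list(table.columns) == ["id", "group", *BCI_COLUMNS,
                                       "percent_fat", "scaled_fat", "residual_fat"]
        for col in ("OLSres", "MAres", "SMAres", "res(M~L^3)", "residual_fat"):
            assert abs(table[col].sum()) < 1e-7
        assert ((table["percent_fat"] > 0) & (table["percent_fat"] < 100)).all()

    def test_single_group_matches_all(self, clean_records):
        labelled = assign_size_classes(clean_records, psi=[5.0])  # everyone class 2
        t_all = compute_bci_table(labelled, "all")
        t_grp = compute_bci_table(labelled, "by_size_class")
        for col in BCI_COLUMNS:
            np.testing.assert_allclose(t_all[col], t_grp[col])

    def test_ratio_columns_grouping_independent(self, clean_records):
        labelled = assign_size_classes(clean_records, psi=[24.0])
        t_all = compute_bci_table(labelled, "all")
        t_grp = compute_bci_table(labelled, "by_size_class")
        for col in ("M/L", "M/L^2", "M/L^3", "logM/logL", "percent_fat"):
            np.testing.assert_allclose(t_all[col], t_grp[col])

    def test_smi_and_smares_perfectly_rank_correlated(self, clean_records):
        labelled = assign_size_classes(clean_records, psi=[24.0])
        table = compute_bci_table(labelled, "by_size_class")
        for g in table["group"].unique():
            sub = table[table["group"] == g]
            t = kendall_tau(sub["SMI"].to_numpy(), sub["SMAres"].to_numpy())
            assert t.statistic == pytest.approx(1.0)

    def test_smares_and_olsres_positively_associated(self):
        recs = generate_dataset(make_clean_config(n=1000, seed=17))
        table = compute_bci_table(recs, "all")
        t = kendall_tau(table["SMAres"].to_numpy(), table["OLSres"].to_numpy())
        assert t.statistic > 0

    def test_isometric_identities(self):
        rng = np.random.default_rng(5)
        svl = rng.uniform(10, 40, 60)
        mass = 0.03 * svl**3
        recs = records_from_arrays(svl, mass)
        table = compute_bci_table(recs, "all")
        np.testing.assert_allclose(table["M/L^3"], 0.03)
        np.testing.assert_allclose(table["SMAres"], 0.0, atol=1e-12)
        l0 = svl.mean()
        np.testing.assert_allclose(table["SMI"], 0.03 * l0**3, rtol=1e-9)

    def test_tiny_group_skipped_with_warning(self):
        svl = np.array([12.0, 13.0, 25.0, 26.0, 27.0, 28.0])
        recs = records_from_arrays(svl, 0.03 * svl**3.1)
        labelled = assign_size_classes(recs, psi=[20.0])
        with pytest.warns(UserWarning, match="fewer than 3"):
            table = compute_bci_table(labelled, "by_size_class")
        sub = table[table["group"] == 1]
        assert sub["SMAres"].isna().all()
        assert sub["M/L^3"].notna().all()
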