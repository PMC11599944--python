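"""Referencing: shielding-to-shift conversion, fitting, averaging, regression."""

import numpy as np
import pandas as pd
import pytest

from nmrxtal import (
    PiecewiseReference,
    ReferencingScheme,
    ShiftTable,
    SingleReference,
    apply_reference,
    average_equivalent,
    fit_reference,
    regression_slope,
)
from nmrxtal.errors import ConfigurationError, DegenerateFitError


class TestApplyReference:
    def test_single_reference(self):
        scheme = ReferencingScheme.default()
        assert apply_reference(31.0, "1H", scheme) == pytest.approx(0.0)
        assert apply_reference(-160.0, "15N", scheme) == pytest.approx(0.0)

    def test_piecewise_keeps_first_pass_above_threshold(self):
        """sigma = 120.9: first pass 172 - 120.9 = 51.1 >= 45, kept."""
        scheme = ReferencingScheme.default()
        assert apply_reference(120.9, "13C", scheme) == pytest.approx(51.1)

    def test_piecewise_switches_below_threshold(self):
        """sigma = 150: first pass 22 < 45, recomputed as 175 - 150 = 25."""
        scheme = ReferencingScheme.default()
        assert apply_reference(150.0, "13C", scheme) == pytest.approx(25.0)

    def test_missing_nucleus(self):
        with pytest.raises(ConfigurationError):
            apply_reference(100.0, "19F", ReferencingScheme.default())

    def test_inverse_identity_single_reference(self):
        scheme = ReferencingScheme({"1H": SingleReference(31.0)})
        for sigma in (12.3, 28.0, 31.0):
            delta = apply_reference(sigma, "1H", scheme)
            assert 31.0 - delta == pytest.approx(sigma)

    def test_boundary_band_warning(self, caplog):
        scheme = ReferencingScheme(
            {"13C": PiecewiseReference(172.0, 175.0, 45.0)})
        with caplog.at_level("WARNING", logger="nmrxtal.referencing"):
            apply_reference(172.0 - 46.0, "13C", scheme)
        assert any("ambiguous" in r.message for r in caplog.records)


class TestFitReference:
    def test_single_pair(self):
        assert fit_reference([(100.0, 70.0)]) == pytest.approx(170.0)

    def test_linearity_in_experimental_offset(self):
        rng = np.random.default_rng(2)
        pairs = [(float(s), float(d)) for s, d in rng.normal(100, 10, (8, 2))]
        base = fit_reference(pairs)
        shifted = fit_reference([(s, d + 3.7) for s, d in pairs])
        assert shifted - base == pytest.approx(3.7, abs=1e-12)

    def test_matches_grid_search_oracle(self):
        """Closed form equals a 1e-4 ppm grid search of the RMSD objective."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = rng.integers(3, 12)
            sigma = rng.uniform(20, 180, n)
            delta = rng.uniform(0, 160, n)
            pairs = list(zip(sigma, delta))
            fitted = fit_reference(pairs)
            grid = np.arange(fitted - 0.05, fitted + 0.05, 1e-4)
            rmsds = [np.sqrt(np.mean([(d - (g - s)) ** 2 for s, d in pairs]))
                     for g in grid]
            assert abs(grid[int(np.argmin(rmsds))] - fitted) <= 1e-4

    def test_is_rmsd_minimum(self):
        """Perturbing the fitted reference by +-0.1 ppm never reduces RMSD."""
        rng = np.random.default_rng(8)
        pairs = [(float(s), float(d)) for s, d in rng.uniform(10, 170, (15, 2))]
        fitted = fit_reference(pairs)

        def rmsd(ref):
            return np.sqrt(np.mean([(d - (ref - s)) ** 2 for s, d in pairs]))

        assert rmsd(fitted) <= rmsd(fitted + 0.1)
        assert rmsd(fitted) <= rmsd(fitted - 0.1)

    def test_empty_input(self):
        with pytest.raises(DegenerateFitError):
            fit_reference([])

    def test_recovers_true_reference_under_noise(self):
        """|fitted - true| <= 4 sigma/sqrt(n) in >= 95% of 200 seeded trials."""
        true_ref, sigma_n, n = 172.0, 0.5, 25
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            shifts = rng.uniform(10, 180, n)
            sigma_calc = true_ref - shifts
            delta_exp = shifts + rng.normal(0, sigma_n, n)
            fitted = fit_reference(list(zip(sigma_calc, delta_exp)))
            if abs(fitted - true_ref) <= 4 * sigma_n / np.sqrt(n):
                hits += 1
        assert hits >= 190


class TestAveragingAndRegression:
    def test_methyl_average(self):
        out = average_equivalent({"Ha": 2.4, "Hb": 2.5, "Hc": 2.6},
                                 {"Ha": "Me", "Hb": "Me", "Hc": "Me"})
        assert out == {"Me": pytest.approx(2.5)}

    def test_singleton_group_and_passthrough(self):
        out = average_equivalent({"H1": 7.0, "H2": 3.0}, {"H1": "g"})
        assert out == {"g": 7.0, "H2": 3.0}

    def test_no_groups_identity(self):
        shifts = {"H1": 1.0, "H2": 2.0}
        assert average_equivalent(shifts) == shifts

    def test_exact_line(self):
        pairs = [(s, -s + 170.0) for s in (20.0, 80.0, 150.0)]
        slope, intercept = regression_slope(pairs)
        assert slope == pytest.approx(-1.0)
        assert intercept == pytest.approx(170.0)

    def test_two_points_define_line(self):
        slope, intercept = regression_slope([(0.0, 5.0), (10.0, 25.0)])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(5.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 200, 30)
        y = -0.97 * x + 168 + rng.normal(0, 2, 30)
        slope, intercept = regression_slope(list(zip(x, y)))
        want = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert slope == pytest.approx(want, abs=1e-10)
        assert intercept == pytest.approx(np.mean(y) - want * np.mean(x), abs=1e-9)

    def test_degenerate_abscissa(self):
        with pytest.raises(DegenerateFitError):
            regression_slope([(5.0, 1.0), (5.0, 2.0)])


class TestShiftTable:
    def test_duplicate_site_rejected(self):
        df = pd.DataFrame({"site": ["C1", "C1"], "nucleus": ["13C", "13C"],
                           "exp": [1.0, 2.0]})
        with pytest.raises(ValueError, match="duplicate"):
            ShiftTable(df)

    def test_all_empty_row_rejected(self):
        df = pd.DataFrame({"site": ["C1"], "nucleus": ["13C"], "exp": [np.nan]})
        with pytest.raises(ValueError, match="at least one shift"):
            ShiftTable(df)

    def test_csv_round_trip_and_column_map(self):
        df = pd.DataFrame({"site": ["C1", "H1"], "nucleus": ["13C", "1H"],
                           "exp": [105.6, np.nan], "calc": [106.6, 8.6]})
        t = ShiftTable(df)
        t2 = ShiftTable.from_csv(__import__("io").StringIO(t.to_csv()))
        assert t2.column_map("13C", "exp") == {"C1": 105.6}
        assert t2.column_map("1H", "exp") == {}
        assert t2.column_map("1H", "calc") == {"H1": 8.6}
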