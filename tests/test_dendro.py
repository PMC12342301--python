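"""Ring-width I/O, detrending and chronology signal statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from budwormsync import dendro
from budwormsync.dendro import (
    RwiSeries,
    TreeRingSeries,
    biweight_mean,
    build_chronology,
    composite_rwi,
    detrend_spline,
    eps,
    interseries_correlation,
    read_rwl,
    sss,
    strip_chronology,
    write_rwl,
)


class TestRwlFormat:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        series = [
            TreeRingSeries("TRE01A", 1903, rng.uniform(0.2, 3.0, 117)),
            TreeRingSeries("TRE02B", 1891, rng.uniform(0.2, 3.0, 129)),
        ]
        p = tmp_path / "x.rwl"
        write_rwl(p, series, unit=0.001)
        back = read_rwl(p)
        for a, b in zip(series, back):
            assert a.tree_id == b.tree_id
            assert a.first_year == b.first_year
            np.testing.assert_allclose(a.widths, b.widths, atol=5e-4)
        # second round trip is byte-identical (values already quantized)
        p2 = tmp_path / "y.rwl"
        write_rwl(p2, back, unit=0.001)
        assert p.read_bytes() == p2.read_bytes()

    def test_fifteen_years_starting_1991_spans_two_decadal_rows(self, tmp_path):
        s = TreeRingSeries("SHORT1", 1991, np.full(15, 1.0))
        p = tmp_path / "s.rwl"
        write_rwl(p, [s])
        rows = [ln for ln in p.read_text().splitlines() if ln.strip()]
        assert len(rows) == 2
        assert int(rows[0][8:12]) == 1991 and int(rows[1][8:12]) == 2000

    def test_unit_flag_scales_to_mm(self, tmp_path):
        # hand-built fixture: 0.01 mm units signalled by the 999 terminator
        p = tmp_path / "unit.rwl"
        p.write_text(
            "HND01A  1990   100   150   200   250   300   350   400   450   500   550\n"
            "HND01A  2000   600   999\n"
        )
        (s,) = read_rwl(p)
        np.testing.assert_allclose(s.widths[:3], [1.00, 1.50, 2.00])
        assert s.widths.size == 11

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.rwl"
        p.write_text("BAD01A  19xx   100   999\n")
        with pytest.raises(ValueError, match="bad.rwl:1"):
            read_rwl(p)


class TestDetrend:
    def test_constant_series_gives_unit_index(self):
        s = TreeRingSeries("C1", 1900, np.full(120, 1.7))
        np.testing.assert_allclose(detrend_spline(s).index, 1.0, atol=1e-9)

    def test_negative_exponential_fully_captured(self):
        t = np.arange(150.0)
        s = TreeRingSeries("N1", 1870, 2.5 * np.exp(-t / 80.0) + 0.4)
        rwi = detrend_spline(s).index
        assert np.abs(rwi - 1.0).max() < 1e-2

    def test_fifty_percent_response_at_cutoff_wavelength(self):
        # interior projection of the fitted curve onto the input sinusoid
        t = np.arange(600.0)
        w = 2 * np.pi / 60.0
        s = TreeRingSeries("S1", 1400, 1.0 + 0.3 * np.sin(w * t))
        rwi = detrend_spline(s, wavelength=60.0).index
        sl = slice(100, 500)
        # RWI keeps the fraction the spline does not absorb
        kept = 2 * np.mean((rwi[sl] - 1.0) * np.sin(w * t[sl])) / 0.3
        assert kept == pytest.approx(0.5, abs=0.08)

    def test_short_series_uses_negexp_fallback(self):
        t = np.arange(25.0)
        s = TreeRingSeries("F1", 2000, 2.0 * np.exp(-t / 40.0) + 0.5)
        rwi = detrend_spline(s)
        assert np.abs(rwi.index - 1.0).max() < 0.05


class TestSignalStatistics:
    def test_eps_closed_form(self):
        assert eps(0.3, 23) == pytest.approx(0.9078947368, abs=1e-9)
        assert eps(1.0, 7) == pytest.approx(1.0)
        assert eps(0.0, 10) == 0.0

    def test_sss_closed_form(self):
        assert sss(0.3, 5, 25) == pytest.approx(41.0 / 55.0, abs=1e-12)
        assert sss(0.4, 9, 9) == 1.0
        assert sss(1.0, 3, 25) == pytest.approx(1.0)

    @given(
        rbar=st.floats(0.0, 1.0),
        n_sub=st.integers(1, 40),
        extra=st.integers(0, 40),
    )
    @settings(max_examples=60, deadline=None)
    def test_eps_sss_bounded_in_unit_interval(self, rbar, n_sub, extra):
        n_total = n_sub + extra
        v = sss(rbar, n_sub, n_total)
        assert 0.0 <= v <= 1.0 + 1e-12
        if n_total >= 2:
            assert 0.0 <= eps(rbar, n_total) <= 1.0 + 1e-12

    def test_negative_rbar_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert eps(-0.2, 10) == 0.0

    def test_biweight_resists_outlier(self):
        x = np.array([1.0, 1.02, 0.98, 1.01, 0.99, 5.0])
        assert abs(biweight_mean(x) - 1.0) < abs(np.mean(x) - 1.0)
        assert abs(biweight_mean(x) - 1.0) < 0.05


class TestChronology:
    def _coherent_set(self, n=8, years=120, seed=0, noise=0.3):
        rng = np.random.default_rng(seed)
        signal = rng.standard_normal(years)
        return [
            RwiSeries(f"T{i}", 1900, 1.0 + 0.2 * signal + noise * 0.2 * rng.standard_normal(years))
            for i in range(n)
        ]

    def test_identical_series_give_unit_rbar_and_same_index(self):
        base = RwiSeries("A", 1900, 1.0 + 0.1 * np.sin(np.arange(100.0)))
        twin = RwiSeries("B", 1900, base.index.copy())
        chron = build_chronology([base, twin])
        assert chron.rbar == pytest.approx(1.0)
        np.testing.assert_allclose(chron.index, base.index, atol=1e-12)

    def test_biweight_mean_chronology_downweights_outlier_year(self):
        rng = np.random.default_rng(2)
        series = self._coherent_set(n=6, seed=2)
        series[0].index[50] += 3.0  # one wild year in one tree
        robust = build_chronology(series, robust=True)
        plain = build_chronology(series, robust=False)
        clean = np.mean([s.index[50] for s in series[1:]])
        assert abs(robust.index[50] - clean) < abs(plain.index[50] - clean)

    def test_synthetic_default_rbar_exceeds_common_signal_floor(self, default_rwi):
        assert interseries_correlation(default_rwi) > 0.3

    def test_no_overlap_raises(self):
        a = RwiSeries("A", 1900, np.ones(30))
        b = RwiSeries("B", 2000, np.ones(30))
        with pytest.raises(ValueError):
            build_chronology([a, b])


class TestStripping:
    def test_identical_series_nothing_removed(self):
        base = 1.0 + 0.15 * np.sin(np.arange(120.0) / 3.0)
        series = [RwiSeries(f"S{i}", 1900, base.copy()) for i in range(5)]
        chron = strip_chronology(series, period=(1900, 2019))
        assert len(chron.tree_ids) == 5

    def test_noise_series_removed_first_and_eps_never_decreases(self):
        rng = np.random.default_rng(7)
        sig = rng.standard_normal(120)
        series = [
            RwiSeries(f"G{i}", 1900, 1 + 0.2 * sig + 0.05 * rng.standard_normal(120))
            for i in range(9)
        ]
        series.append(RwiSeries("NOISE", 1900, 1 + 0.2 * rng.standard_normal(120)))
        full = build_chronology(series)
        chron = strip_chronology(series, period=(1900, 2019))
        assert "NOISE" not in chron.tree_ids
        assert chron.eps >= full.eps


class TestComposite:
    def test_single_site_equals_site_chronology(self, default_rwi):
        solo = build_chronology(default_rwi)
        comp = composite_rwi({"s1": default_rwi}, species=dendro.WHITE_SPRUCE)
        np.testing.assert_allclose(comp.index, solo.index)

    def test_pooled_depth_is_sum_of_site_depths(self, default_rwi):
        half = len(default_rwi) // 2
        sites = {"a": default_rwi[:half], "b": default_rwi[half:]}
        comp = composite_rwi(sites, species=dendro.WHITE_SPRUCE)
        a = build_chronology(sites["a"])
        b = build_chronology(sites["b"])
        years = comp.years
        da = np.zeros(years.size)
        db = np.zeros(years.size)
        da[np.isin(years, a.years)] = a.sample_depth
        db[np.isin(years, b.years)] = b.sample_depth
        np.testing.assert_array_equal(comp.sample_depth, da + db)

    def test_mixed_species_rejected(self, default_rwi):
        other = RwiSeries("BS1", 1900, np.ones(120), species=dendro.BLACK_SPRUCE)
        with pytest.raises(ValueError, match="composite"):
            composite_rwi({"a": default_rwi, "b": [other]}, species=dendro.WHITE_SPRUCE)
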