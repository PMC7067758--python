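import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from traitvar.scan import (ScanEligibility, bin_and_interval,
                           eligible_sites, fit_breakpoint, haversine_km,
                           scan_all_sites, scan_from_site,
                           test_bin_significance)

KM_PER_DEG = 6371.0 * np.pi / 180.0


class TestHaversine:
    def test_identical_points(self):
        assert haversine_km((10.0, 20.0), (10.0, 20.0)) == 0.0

    def test_one_degree_of_longitude_at_equator(self):
        assert haversine_km((0.0, 0.0), (0.0, 1.0)) == pytest.approx(
            111.195, abs=1e-3)

    def test_antipodal(self):
        assert haversine_km((0.0, 0.0), (0.0, 180.0)) == pytest.approx(
            20015.09, abs=1e-2)

    def test_invalid_coordinates(self):
        with pytest.raises(ValueError):
            haversine_km((91.0, 0.0), (0.0, 0.0))

    @given(st.floats(-90, 90), st.floats(-180, 180),
           st.floats(-90, 90), st.floats(-180, 180))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_and_bounded(self, a, b, c, d):
        d1 = haversine_km((a, b), (c, d))
        d2 = haversine_km((c, d), (a, b))
        assert d1 == pytest.approx(d2, abs=1e-9)
        assert 0.0 <= d1 <= np.pi * 6371.0 + 1e-6


def collinear_fixture(spacing_deg=1.0, n_species=3, obs=2):
    """Three sites on the equator, equally spaced in longitude."""
    sites = pd.DataFrame({
        "site_id": ["sA", "sB", "sC"],
        "latitude": [0.0, 0.0, 0.0],
        "longitude": [0.0, spacing_deg, 2 * spacing_deg],
        "mean_annual_temperature": [-2.0] * 3,
        "class_temperature": [0.0] * 3,
    })
    rows = []
    rng = np.random.default_rng(0)
    for s in sites["site_id"]:
        for k in range(n_species):
            for o in range(obs):
                rows.append({
                    "record_id": f"{s}-{k}-{o}",
                    "species": f"sp{k}", "genus": "G",
                    "functional_group": "forb", "dataset_id": "d0",
                    "site_id": s, "trait": "plant height",
                    "value": float(np.exp(rng.normal(k, 0.1))),
                })
    return pd.DataFrame(rows), sites


class TestScan:
    def test_collinear_inclusion_order_and_scales(self):
        records, sites = collinear_fixture()
        steps = scan_from_site(records, sites, "sA")
        d = KM_PER_DEG  # one degree of longitude on the equator
        assert steps["scale_km"].tolist() == pytest.approx([0.0, d, 2 * d],
                                                           abs=1e-6)
        assert steps["step_index"].tolist() == [0, 1, 2]

    def test_single_eligible_site(self):
        records, sites = collinear_fixture()
        records = records[records["site_id"] == "sA"]
        steps = scan_from_site(records, sites, "sA")
        assert len(steps) == 1 and steps["scale_km"].iloc[0] == 0.0

    def test_ineligible_start_rejected(self):
        records, sites = collinear_fixture()
        few = records[records["species"] != "sp0"]
        few = few[few["site_id"] != "sA"]
        with pytest.raises(ValueError):
            scan_from_site(few, sites, "sA")

    def test_all_sites_row_count_identity(self):
        records, sites = collinear_fixture()
        steps = scan_all_sites(records, sites)
        n_elig = len(eligible_sites(records))
        # one trait: rows = sum over starts of number of eligible sites
        assert len(steps) == n_elig * n_elig

    def test_fractions_sum_and_monotone_scale(self, small_db):
        records, sites, _ = small_db
        start = eligible_sites(records)[0]
        steps = scan_from_site(records, sites, start)
        assert np.allclose(steps["f_within"] + steps["f_among"], 1.0,
                           atol=1e-9)
        for _, sub in steps.groupby("trait"):
            assert (np.diff(sub["scale_km"]) >= -1e-9).all()
            assert (np.diff(sub["richness"]) >= 0).all()

    def test_row_order_invariance(self):
        records, sites = collinear_fixture()
        s1 = scan_all_sites(records, sites)
        s2 = scan_all_sites(records.sample(frac=1, random_state=3), sites)
        pd.testing.assert_frame_equal(
            s1.reset_index(drop=True), s2.reset_index(drop=True),
            check_exact=False, atol=1e-9)

    def test_final_richness_is_total_species_pool(self, small_db):
        records, sites, _ = small_db
        elig = eligible_sites(records)
        steps = scan_from_site(records, sites, elig[0])
        pool = records[records["site_id"].isin(elig)]["species"].nunique()
        assert steps["richness"].iloc[-1] == pool


class TestBinning:
    @staticmethod
    def steps_frame(x, fw):
        return pd.DataFrame({"scale_km": x, "richness": 1,
                             "f_within": fw, "f_among": 1 - np.asarray(fw)})

    def test_single_bin_spans_data(self):
        s = self.steps_frame([1.0, 2.0, 3.0], [0.2, 0.4, 0.6])
        out = bin_and_interval(s, width=5.0)
        w = out[out["source"] == "f_within"].iloc[0]
        assert w["n_steps"] == 3
        assert w["lower95"] >= 0.2 and w["upper95"] <= 0.6

    def test_constant_fractions_collapse_interval(self):
        s = self.steps_frame([1.0, 2.0, 3.0, 7.0], [0.3] * 4)
        out = bin_and_interval(s, width=5.0)
        w = out[out["source"] == "f_within"]
        assert (w["lower95"] == 0.3).all() and (w["upper95"] == 0.3).all()

    def test_percentiles_match_sort_oracle(self):
        rng = np.random.default_rng(1)
        fw = rng.uniform(0, 1, 1000)
        s = self.steps_frame(rng.uniform(0, 4.9, 1000), fw)
        out = bin_and_interval(s, width=5.0)
        w = out[out["source"] == "f_within"].iloc[0]
        srt = np.sort(fw)

        def pct(q):  # linear interpolation on the sorted sample
            h = q / 100 * (len(srt) - 1)
            lo = int(np.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert w["lower95"] == pytest.approx(pct(2.5), abs=1e-12)
        assert w["upper95"] == pytest.approx(pct(97.5), abs=1e-12)

    def test_small_bins_flagged(self):
        s = self.steps_frame([0.0, 10.0], [0.1, 0.9])
        out = bin_and_interval(s, width=5.0)
        assert not out["interval_defined"].any()


class TestBinSignificance:
    @staticmethod
    def steps_frame(x, fw):
        fw = np.asarray(fw)
        return pd.DataFrame({"scale_km": x, "richness": 1,
                             "f_within": fw, "f_among": 1 - fw})

    def test_equal_sources_not_significant(self):
        s = self.steps_frame(np.linspace(1, 100, 30), [0.5] * 30)
        out = test_bin_significance(s)
        assert not out["significant"].any()

    def test_separated_sources_significant_and_match_t_oracle(self):
        rng = np.random.default_rng(2)
        fw = 0.9 + rng.normal(0, 0.01, 20)
        s = self.steps_frame(np.full(20, 10.0), fw)
        out = test_bin_significance(s)
        tested = out[out["testable"]]
        assert len(tested) == 1 and tested["significant"].all()
        t = stats.ttest_ind(fw, 1 - fw, equal_var=True)
        assert tested["p_value"].iloc[0] == pytest.approx(t.pvalue, rel=1e-9)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        fw = 0.7 + rng.normal(0, 0.05, 25)
        s = self.steps_frame(np.full(25, 3.0), fw)
        p1 = test_bin_significance(s, sources=("f_within", "f_among"))
        p2 = test_bin_significance(s, sources=("f_among", "f_within"))
        t1, t2 = p1[p1["testable"]], p2[p2["testable"]]
        assert np.allclose(t1["p_value"], t2["p_value"])
        assert np.allclose(t1["coef"], -t2["coef"])


class TestBreakpoint:
    def test_noiseless_recovery_exact(self):
        x = np.linspace(0, 20, 200)
        y = np.where(x < 10, 1.0 - 0.02 * x, 1.0 - 0.2)
        fit = fit_breakpoint(x, y)
        assert fit.converged
        assert fit.psi == pytest.approx(10.0, abs=1e-6)
        assert fit.slope_left == pytest.approx(-0.02, abs=1e-9)
        assert fit.slope_right == pytest.approx(0.0, abs=1e-9)

    def test_continuous_at_break(self):
        x = np.linspace(0, 20, 100)
        rng = np.random.default_rng(4)
        y = np.where(x < 8, x, 8 + 0.5 * (x - 8)) + rng.normal(0, 0.1, 100)
        fit = fit_breakpoint(x, y)
        left = fit.predict(fit.psi - 1e-9)
        right = fit.predict(fit.psi + 1e-9)
        assert left == pytest.approx(right, abs=1e-6)

    def test_pure_line_not_converged_and_rss_matches(self):
        x = np.linspace(0, 10, 50)
        y = 0.5 + 0.1 * x
        fit = fit_breakpoint(x, y)
        A = np.column_stack([np.ones_like(x), x])
        beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
        rss_line = float(((y - A @ beta) ** 2).sum())
        assert not fit.converged
        assert fit.rss <= rss_line + 1e-9

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(0, 20, 80))
        y = np.where(x < 12, 2 - 0.1 * x, 0.8) + rng.normal(0, 0.05, 80)
        f1, f2 = fit_breakpoint(x, y), fit_breakpoint(x, y)
        assert f1 == f2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_breakpoint([1, 2, 3], [1, 2, 3])
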