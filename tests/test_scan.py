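import numpy as np
import pandas as pd
import pytest

import sweepscan as ss
from sweepscan.scan import (
    FLAG_HIGH, FLAG_NORMAL, SmoothingConfig, classify_peaks, control_chart,
)


def oracle_lowess(x, y, window, degree=1):
    """Independent tricube weighted-least-squares smoother (matrix route)."""
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argsort(d, kind="stable")[:window]
        dmax = d[idx].max() or 1.0
        w = (1 - (d[idx] / dmax) ** 3) ** 3
        X = np.vander(x[idx] - x[i], degree + 1, increasing=True)
        W = np.diag(np.sqrt(w))  # ||sqrt(w)(Xb - y)||^2 minimises the WLS loss
        beta, *_ = np.linalg.lstsq(W @ X, W @ y[idx], rcond=None)
        out[i] = beta[0]
    return out


class TestSmoothingFraction:
    def test_division(self):
        assert ss.smoothing_fraction(2000, 20) == 0.01

    def test_reported_chromosome_value(self):
        # 909 SNPs with a 20-SNP window gives S ~ 0.022
        assert ss.smoothing_fraction(909, 20) == pytest.approx(0.022, abs=5e-4)

    def test_boundary_global_regression(self):
        assert ss.smoothing_fraction(20, 20) == 1.0

    def test_fallback_to_one(self):
        assert ss.smoothing_fraction(10, 20) == 1.0


class TestLowess:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.x = np.sort(rng.uniform(0, 1e6, 50))
        self.y = np.sin(self.x / 2e5) + rng.normal(0, 0.1, 50)

    def test_linear_reproduction(self):
        y = 0.7 + 3e-6 * self.x
        sm = ss.lowess_smooth(self.x, y)
        assert np.abs(sm - y).max() < 1e-9

    def test_constant_reproduction(self):
        sm = ss.lowess_smooth(self.x, np.full(50, 0.25))
        assert np.abs(sm - 0.25).max() < 1e-12

    def test_seven_point_fixture_matches_oracle(self):
        x = np.array([0.0, 1.0, 2.5, 3.0, 5.5, 7.0, 10.0])
        y = np.array([1.0, 0.5, 2.0, 1.5, 3.0, 2.2, 4.0])
        sm = ss.lowess_smooth(x, y, SmoothingConfig(window_snps=5))
        assert np.abs(sm - oracle_lowess(x, y, 5)).max() < 1e-9

    @pytest.mark.parametrize("window", [5, 13, 20, 50])
    def test_matches_oracle_random(self, window):
        sm = ss.lowess_smooth(self.x, self.y, SmoothingConfig(window_snps=window))
        assert np.abs(sm - oracle_lowess(self.x, self.y, window)).max() < 1e-9

    def test_matches_statsmodels(self):
        from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess
        sm = ss.lowess_smooth(self.x, self.y, SmoothingConfig(window_snps=20))
        ref = sm_lowess(self.y, self.x, frac=20 / 50, it=0, delta=0.0,
                        return_sorted=False)
        assert np.abs(sm - ref).max() < 1e-8

    def test_shift_scale_equivariance(self):
        sm = ss.lowess_smooth(self.x, self.y)
        sm2 = ss.lowess_smooth(self.x, 2.0 + 3.0 * self.y)
        assert np.allclose(sm2, 2.0 + 3.0 * sm, atol=1e-9)

    def test_duplicate_positions_jittered(self):
        x = np.array([0.0, 100.0, 100.0, 200.0, 300.0, 400.0])
        y = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        sm = ss.lowess_smooth(x, y, SmoothingConfig(window_snps=4))
        assert np.isfinite(sm).all()

    def test_degree2_reproduces_quadratic(self):
        y = 1.0 + 2e-6 * self.x + 3e-12 * self.x**2
        sm = ss.lowess_smooth(self.x, y, SmoothingConfig(window_snps=10, degree=2))
        assert np.abs(sm - y).max() < 1e-6 * np.abs(y).max()

    def test_nan_rejected(self):
        y = self.y.copy()
        y[3] = np.nan
        with pytest.raises(ValueError):
            ss.lowess_smooth(self.x, y)


class TestControlChart:
    def test_all_equal_no_outliers(self):
        ch = control_chart(np.full(10, 0.3))
        assert ch["sd"] == 0
        assert (ch["flags"] == FLAG_NORMAL).all()

    def test_ninety_nine_zeros_one_hundred(self):
        """mean 1, SD 10, UCL 31: the single large value is the only outlier."""
        v = np.array([0.0] * 99 + [100.0])
        ch = control_chart(v, k=3)
        assert ch["mean"] == pytest.approx(1.0)
        assert ch["sd"] == pytest.approx(10.0)
        assert ch["ucl"] == pytest.approx(31.0)
        assert (ch["flags"] == FLAG_HIGH).sum() == 1
        assert ch["flags"][-1] == FLAG_HIGH

    def test_value_exactly_on_limit_is_normal(self):
        # values [0, 2, 4]: mean 2, sample SD exactly 2 -> UCL = 4 with k = 1
        ch = control_chart(np.array([0.0, 2.0, 4.0]), k=1)
        assert ch["ucl"] == 4.0
        assert ch["flags"][2] == FLAG_NORMAL
        assert ch["flags"][0] == FLAG_NORMAL  # == LCL

    def test_limits_symmetric(self):
        rng = np.random.default_rng(1)
        ch = control_chart(rng.normal(size=100), k=3)
        assert ch["ucl"] - ch["mean"] == pytest.approx(ch["mean"] - ch["lcl"])


def frame(values, start_pos=1000):
    return pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(len(values))],
        "position_bp": np.arange(start_pos, start_pos + 1000 * len(values), 1000),
        "smoothed_fst": values,
    })


class TestClassifyPeaks:
    def test_run_collapsing(self):
        v = [0.0] * 40 + [10.0] * 5 + [0.0] * 40
        f = frame(v)
        ch = control_chart(np.array(v))
        peaks = classify_peaks(f, ch)
        out = peaks[peaks["kind"] == "outlier"]
        assert len(out) == 1
        assert out.iloc[0]["n_snps"] == 5
        assert out.iloc[0]["start_bp"] == f.loc[40, "position_bp"]
        assert out.iloc[0]["end_bp"] == f.loc[44, "position_bp"]

    def test_borderline_local_maximum(self):
        """An isolated maximum at mean + 2.8 SD (k=3, fraction 0.9 -> threshold
        2.7 SD) is borderline, not an outlier."""
        rng = np.random.default_rng(5)
        v = rng.normal(0, 1e-3, 101)
        ch = control_chart(v)
        target = ch["mean"] + 2.8 * ch["sd"]
        v2 = v.copy()
        v2[50] = target
        ch2 = control_chart(v2)
        assert ch2["mean"] + 2.7 * ch2["sd"] < target <= ch2["ucl"]
        peaks = classify_peaks(frame(v2), ch2)
        assert (peaks["kind"] == "borderline").sum() >= 1
        assert peaks.loc[peaks["kind"] == "borderline", "summit_bp"].iloc[0] \
            == frame(v2).loc[50, "position_bp"]
        assert (peaks["kind"] == "outlier").sum() == 0

    def test_empty_when_nothing_high(self):
        v = np.linspace(0, 1e-4, 60)
        ch = control_chart(v)
        ch["ucl"] = ch["mean"] + 10  # nothing close
        peaks = classify_peaks(frame(v), ch)
        assert len(peaks) == 0


class TestFstScanModel:
    def test_flags_match_brute_force(self, small_sim):
        ds, _ = small_sim
        qcd, _ = ss.run_qc(ds)
        res = ss.FstScanModel(qcd).fit()
        for chrom, grp in res.track.groupby("chromosome"):
            v = grp["smoothed_fst"].to_numpy()
            mean, sd = v.mean(), v.std(ddof=1)
            expected = np.where(v > mean + 3 * sd, FLAG_HIGH,
                                np.where(v < mean - 3 * sd, "outlier_low",
                                         FLAG_NORMAL))
            assert (grp["flag"].to_numpy() == expected).all()

    def test_genome_scope_single_limits(self, small_sim):
        ds, _ = small_sim
        qcd, _ = ss.run_qc(ds)
        res = ss.FstScanModel(qcd, chart_scope="genome").fit()
        assert res.limits["ucl"].nunique() == 1

    def test_nan_loci_dropped(self):
        from tests.conftest import build_dataset
        cols = [[0, 1, 1, 2]] * 30
        cols[7] = [0, 0, 0, 0]  # pooled-monomorphic -> NaN fst
        ds = build_dataset(cols, pop_sizes=(2, 2))
        res = ss.FstScanModel(ds).fit()
        assert res.n_dropped_na == 1
        assert len(res.track) == 29

    def test_summary_mentions_counts(self, small_sim):
        ds, _ = small_sim
        qcd, _ = ss.run_qc(ds)
        s = ss.FstScanModel(qcd).fit().summary()
        assert "mean Fst" in s and "outlier" in s


def test_null_gaussian_outlier_rate_is_nominal():
    """On iid Gaussian noise the chromosome-wise 3-SD chart flags close to the
    nominal two-sided rate (0.27%); smoothing does not inflate it."""
    rng = np.random.default_rng(0)
    n_out = n_tot = 0
    for _ in range(25):
        x = np.sort(rng.uniform(0, 1e8, 2000))
        y = rng.normal(size=2000)
        ch = control_chart(ss.lowess_smooth(x, y))
        n_out += int((ch["flags"] != FLAG_NORMAL).sum())
        n_tot += 2000
    assert n_out / n_tot < 0.006
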