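"""Sliding-kernel aggregation, bootstrap peak estimation, peak comparison."""

import numpy as np
import pandas as pd
import pytest

from neuralwave import (
    GeneratorConfig,
    KernelSpec,
    TuningDataset,
    bootstrap_peak,
    compare_peaks,
    gen_tuning_dataset,
    sliding_kernel_curves,
)
from scipy import stats


def small_dataset(rates_fn, sf=(0.1, 0.2, 0.4), tf=(1.0, 2.0), contrast=(10.0,), n_trials=3):
    rows = []
    for s in sf:
        for t in tf:
            for c in contrast:
                for tr in range(n_trials):
                    rows.append((s, t, c, tr, rates_fn(s, t, c, tr)))
    return TuningDataset(pd.DataFrame(rows, columns=["sf", "tf", "contrast", "trial", "rate"]))


class TestSlidingKernel:
    def test_identity_kernel_returns_raw_condition_means(self):
        d = small_dataset(lambda s, t, c, tr: 10 * s + t + tr)
        out = sliding_kernel_curves(d, KernelSpec(slide="tf"))
        for _, row in out.iterrows():
            expected = d.data[
                np.isclose(d.data.tf, row.tf_center)
                & np.isclose(d.data.sf, 0.1)
            ].rate.mean()
            assert row.mean_rate == pytest.approx(expected)

    def test_constant_rates_give_flat_curves(self):
        d = small_dataset(lambda *a: 7.0)
        out = sliding_kernel_curves(d, KernelSpec(sf_window=3, tf_window=2, slide="tf"))
        assert np.allclose(out.mean_rate, 7.0)

    def test_window_centers_are_geometric_means(self):
        d = small_dataset(lambda *a: 1.0)
        out = sliding_kernel_curves(d, KernelSpec(tf_window=2, slide="tf"))
        assert out.tf_center.iloc[0] == pytest.approx(stats.gmean([1.0, 2.0]))

    def test_full_width_windows_preserve_global_mean(self):
        d = small_dataset(lambda s, t, c, tr: 3 * s + 2 * t + tr)
        out = sliding_kernel_curves(
            d, KernelSpec(sf_window=3, tf_window=1, contrast_window=1, slide="tf")
        )
        # size-1 slide windows with full-extent fixed windows tile the grid
        assert out.mean_rate.mean() == pytest.approx(d.data.rate.mean())

    def test_planted_peak_recovered_within_one_grid_step(self):
        g = GeneratorConfig(seed=7, dispersion=0.5)
        d, truth = gen_tuning_dataset(g)
        out = sliding_kernel_curves(
            d, KernelSpec(sf_window=2, tf_window=1, contrast_window=2, slide="tf")
        )
        peak_center = out.tf_center.iloc[int(np.argmax(out.mean_rate))]
        tf_grid = np.array(g.tf_grid)
        planted_idx = np.argmin(np.abs(tf_grid - truth["peak_tf"]))
        peak_idx = np.argmin(np.abs(tf_grid - peak_center))
        assert abs(int(peak_idx) - int(planted_idx)) <= 1

    def test_oversized_window_rejected(self):
        d = small_dataset(lambda *a: 1.0)
        with pytest.raises(ValueError, match="exceeds grid"):
            sliding_kernel_curves(d, KernelSpec(tf_window=5, slide="tf"))

    def test_missing_condition_raises_named_placement(self):
        d = small_dataset(lambda *a: 1.0)
        trimmed = TuningDataset(d.data[~np.isclose(d.data.tf, 2.0) | ~np.isclose(d.data.sf, 0.1)])
        with pytest.raises(ValueError, match="empty kernel window"):
            sliding_kernel_curves(trimmed, KernelSpec(slide="tf"))


class TestBootstrapPeak:
    AXIS = np.array([0.05, 0.1, 0.2, 0.4, 0.8])

    def peaked_rates(self, peak, noise_sd, rng, n_trials=10):
        means = 30 * np.exp(-np.log(self.AXIS / peak) ** 2 / (2 * 0.6**2))
        return np.clip(means[:, None] + rng.normal(0, noise_sd, (self.AXIS.size, n_trials)), 0, None)

    def test_noiseless_curve_gives_zero_spread_at_true_peak(self):
        rng = np.random.default_rng(0)
        rates = self.peaked_rates(0.2, 0.0, rng)
        est = bootstrap_peak(self.AXIS, rates, n_iter=50, rng=1)
        assert est.sd == pytest.approx(0.0, abs=1e-12)
        assert est.peak == pytest.approx(0.2, rel=0.1)
        assert not est.flagged

    def test_seeded_estimate_is_bit_identical_on_rerun(self):
        rng = np.random.default_rng(0)
        rates = self.peaked_rates(0.2, 4.0, rng)
        e1 = bootstrap_peak(self.AXIS, rates, n_iter=60, rng=42)
        e2 = bootstrap_peak(self.AXIS, rates, n_iter=60, rng=42)
        assert e1.peak == e2.peak and e1.sd == e2.sd
        np.testing.assert_array_equal(e1.samples, e2.samples)

    def test_interval_coverage_consistent_with_nominal_rates(self):
        # the resampling SD is an honest (roughly Gaussian) uncertainty:
        # ~68% of replicates should land within 1 SD and ~95% within 2 SD,
        # up to binomial noise at 20 replicates
        rng = np.random.default_rng(5)
        errs, sds = [], []
        n_rep = 20
        for _ in range(n_rep):
            rates = self.peaked_rates(0.2, 5.0, rng)
            est = bootstrap_peak(self.AXIS, rates, n_iter=120, rng=rng)
            errs.append(abs(est.peak - 0.2))
            sds.append(est.sd)
        errs, sds = np.array(errs), np.array(sds)
        assert np.mean(errs <= sds) >= 0.45
        assert np.mean(errs <= 2 * sds) >= 0.75

    def test_flat_data_flagged_degenerate(self):
        rates = np.full((self.AXIS.size, 10), 5.0)
        est = bootstrap_peak(self.AXIS, rates, n_iter=40, rng=0)
        assert est.flagged
        assert est.n_degenerate == 40

    def test_monotone_data_flagged_boundary(self):
        rates = np.tile(np.linspace(1, 50, self.AXIS.size)[:, None], (1, 10))
        est = bootstrap_peak(self.AXIS, rates, n_iter=40, rng=0)
        assert est.boundary_fraction > 0.5
        assert est.flagged


class TestComparePeaks:
    def _est(self, center, spread, rng, n=200):
        from neuralwave.tuning import PeakEstimate
        samples = rng.normal(center, spread, n)
        return PeakEstimate(peak=center, sd=spread, n_resamples=n, samples=samples,
                            n_degenerate=0, flagged=False, boundary_fraction=0.0)

    def test_identical_distributions_show_no_change(self, rng):
        samples = rng.normal(0.2, 0.01, 200)
        from neuralwave.tuning import PeakEstimate
        a = PeakEstimate(0.2, 0.01, 200, samples, 0, False, 0.0)
        b = PeakEstimate(0.2, 0.01, 200, samples.copy(), 0, False, 0.0)
        assert compare_peaks(a, b)["direction"] == "no_change"

    def test_separated_peaks_classified_by_planted_order(self, rng):
        lo = self._est(0.1, 0.01, rng)
        hi = self._est(0.3, 0.01, rng)
        assert compare_peaks(lo, hi)["direction"] == "increased"
        assert compare_peaks(hi, lo)["direction"] == "decreased"

    def test_threshold_is_strict_at_alpha(self, rng):
        lo = self._est(0.1, 0.01, rng)
        hi = self._est(0.3, 0.01, rng)
        out = compare_peaks(lo, hi, alpha=0.0)  # p < 0 never true
        assert out["direction"] == "no_change"

    def test_insufficient_samples_rejected(self, rng):
        a = self._est(0.1, 0.01, rng, n=1)
        b = self._est(0.2, 0.01, rng, n=200)
        with pytest.raises(ValueError):
            compare_peaks(a, b)
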