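"""Neurocorrelation maps, threshold ladder, collinearity and residualization."""

import numpy as np
import pandas as pd
import pytest

from neurolex.neurocorr import (
    CorrelationMap,
    ThresholdLadder,
    bonferroni_test,
    ladder_test,
    neurocorrelate,
    parameter_correlation_matrix,
    residualize,
    restrict_window,
)
from neurolex.spectral import TrialSpectra


def make_spectra(rng, n_trials=40, n_ch=2, n_f=6, n_t=10):
    return TrialSpectra(
        log_rsm=rng.standard_normal((n_trials, n_ch, n_f, n_t)),
        freqs=np.linspace(10, 10 + 5 * (n_f - 1), n_f),
        times=np.linspace(-0.5, 0.5, n_t),
        trial_ids=np.arange(n_trials),
        channel_names=[f"ch{i}" for i in range(n_ch)],
    )


def make_map(p, r=None, freqs=None, times=None):
    p = np.asarray(p, dtype=float)
    return CorrelationMap(
        r=np.zeros_like(p) if r is None else np.asarray(r, float),
        p=p,
        parameter="x",
        n=100,
        freqs=np.arange(p.shape[1]) if freqs is None else freqs,
        times=np.arange(p.shape[2]) * 0.02 if times is None else times,
        channel_names=[f"ch{i}" for i in range(p.shape[0])],
    )


class TestParameterCorrelationMatrix:
    def test_duplicated_column_fully_correlated(self, rng):
        x = rng.standard_normal(50)
        res = parameter_correlation_matrix(pd.DataFrame({"a": x, "b": x.copy()}))
        assert res.r.loc["a", "b"] == pytest.approx(1.0)
        assert res.significant.loc["a", "b"]
        assert res.strong.loc["a", "b"]

    def test_independent_columns_rarely_look_strong(self):
        hits = 0
        for seed in range(200):
            g = np.random.default_rng(seed)
            df = pd.DataFrame(g.standard_normal((1000, 2)), columns=["a", "b"])
            res = parameter_correlation_matrix(df)
            hits += abs(res.r.loc["a", "b"]) < 0.1
        assert hits >= 190  # |r| < 0.1 in >= 95% of null runs

    def test_constant_column_flagged_undefined(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(30), "b": np.ones(30)})
        res = parameter_correlation_matrix(df)
        assert np.isnan(res.r.loc["a", "b"])
        assert not res.significant.loc["a", "b"]

    def test_complete_cases_only(self, rng):
        a = rng.standard_normal(40)
        b = 0.9 * a + 0.1 * rng.standard_normal(40)
        a[:5] = np.nan
        res = parameter_correlation_matrix(pd.DataFrame({"a": a, "b": b}))
        assert res.n.loc["a", "b"] == 35
        assert res.r.loc["a", "b"] > 0.8


class TestNeurocorrelate:
    def test_parameter_equal_to_one_bin_gives_r_one(self, rng):
        sp = make_spectra(rng)
        values = sp.log_rsm[:, 1, 2, 3].copy()
        cmap = neurocorrelate(sp, values, "probe")
        assert cmap.r[1, 2, 3] == pytest.approx(1.0)
        assert cmap.p[1, 2, 3] == 0.0

    def test_length_mismatch_rejected(self, rng):
        sp = make_spectra(rng)
        with pytest.raises(ValueError):
            neurocorrelate(sp, np.ones(sp.n_trials - 1))

    def test_affine_rescaling_invariance(self, rng):
        sp = make_spectra(rng)
        v = rng.standard_normal(sp.n_trials)
        a = neurocorrelate(sp, v)
        b = neurocorrelate(sp, 3.7 * v + 11.0)
        assert np.allclose(a.r, b.r, atol=1e-12)

    def test_zero_variance_bin_flagged(self, rng):
        sp = make_spectra(rng)
        sp.log_rsm[:, 0, 0, 0] = 2.5
        cmap = neurocorrelate(sp, rng.standard_normal(sp.n_trials))
        assert np.isnan(cmap.r[0, 0, 0])

    def test_missing_parameter_trials_dropped_pairwise(self, rng):
        sp = make_spectra(rng, n_trials=30)
        v = rng.standard_normal(30)
        v[:4] = np.nan
        cmap = neurocorrelate(sp, v)
        assert cmap.n == 26
        assert np.isfinite(cmap.r).all()


class TestBonferroni:
    def test_threshold_arithmetic(self):
        p = np.full((1, 100, 100), 1.0)
        p[0, 0, 0] = 1e-6  # below 0.05/10000 = 5e-6
        p[0, 0, 1] = 1e-5  # above
        mask = bonferroni_test(make_map(p), q=0.05)
        assert mask[0, 0, 0] and not mask[0, 0, 1]

    def test_empty_map(self):
        mask = bonferroni_test(make_map(np.ones((1, 2, 2))))
        assert not mask.any()

    def test_contained_in_ladder_cap_mask(self, rng):
        ladder = ThresholdLadder()
        for _ in range(20):
            p = 10 ** rng.uniform(-9, 0, size=(2, 10, 10))
            cmap = make_map(p)
            bonf = bonferroni_test(cmap, q=0.05, m=100_000)  # q/m = 5e-7 < 5e-6
            cap_mask = cmap.p <= ladder.cap
            assert not np.any(bonf & ~cap_mask)


class TestLadder:
    def test_reports_most_conservative_passing_rung(self):
        ladder = ThresholdLadder(thresholds=(5e-6, 5e-7, 5e-8))
        p = np.full((1, 3, 3), 0.5)
        p[0, 1, 1] = 1e-7
        # 1e-7 passes 5e-7 but not 5e-8, so 5e-7 is the last passing rung
        thr, mask = ladder_test(make_map(p), ladder)
        assert thr == 5e-7 and mask[0, 1, 1]

    def test_nothing_below_cap_reports_no_effect(self):
        p = np.full((1, 3, 3), 1e-4)
        thr, mask = ladder_test(make_map(p))
        assert thr is None and not mask.any()

    def test_cap_boundary_inclusive(self):
        p = np.full((1, 2, 2), 0.9)
        p[0, 0, 0] = 5e-6
        thr, mask = ladder_test(make_map(p))
        assert thr == 5e-6 and mask[0, 0, 0]

    def test_adding_smaller_p_only_lowers_threshold(self, rng):
        p = 10 ** rng.uniform(-8, -3, size=(1, 5, 5))
        thr1, _ = ladder_test(make_map(p))
        p2 = p.copy()
        p2[0, 0, 0] = p.min() / 10
        thr2, _ = ladder_test(make_map(p2))
        assert thr2 <= thr1

    def test_invalid_ladder_rejected(self):
        with pytest.raises(ValueError):
            ThresholdLadder(thresholds=(5e-6, 5e-6))
        with pytest.raises(ValueError):
            ThresholdLadder(thresholds=(1e-3, 1e-4))


class TestResidualize:
    def make_table(self, rng, n=200):
        x = rng.standard_normal(n)
        return pd.DataFrame(
            {
                "a": x,
                "b": 0.7 * x + 0.7 * rng.standard_normal(n),
                "c": rng.standard_normal(n),
            }
        )

    def test_residual_orthogonal_to_predictors(self, rng):
        df = self.make_table(rng)
        resid, used = residualize(df, "a")
        for col in used:
            r = np.corrcoef(resid, df[col])[0, 1]
            assert abs(r) < 1e-10

    def test_no_confounds_gives_mean_centered_target(self, rng):
        df = pd.DataFrame(
            {"a": rng.standard_normal(100), "b": rng.standard_normal(100)}
        )
        corr = parameter_correlation_matrix(df, alpha=1e-9)  # nothing significant
        resid, used = residualize(df, "a", alpha=1e-9, corr=corr)
        assert used == []
        assert np.allclose(resid, df["a"] - df["a"].mean())

    def test_collinear_predictors_pruned_in_column_order(self, rng):
        x = rng.standard_normal(120)
        df = pd.DataFrame(
            {"t": 0.8 * x + 0.3 * rng.standard_normal(120), "p1": x, "p2": x.copy()}
        )
        resid, used = residualize(df, "t")
        assert used == ["p1"]

    def test_orthogonal_parameter_map_unchanged_by_residualization(self, rng):
        sp = make_spectra(rng, n_trials=80)
        v = rng.standard_normal(80)
        df = pd.DataFrame({"v": v, "other": rng.standard_normal(80)})
        corr = parameter_correlation_matrix(df, alpha=1e-9)
        resid, _ = residualize(df, "v", alpha=1e-9, corr=corr)
        a = neurocorrelate(sp, v)
        b = neurocorrelate(sp, resid.to_numpy())
        assert np.allclose(a.r, b.r, atol=1e-10)


class TestRestrictWindow:
    def test_frequency_cap(self, rng):
        sp = make_spectra(rng, n_f=40)  # freqs 10..205 Hz
        out = restrict_window(sp, (-0.2, 0.2), margin=0.5, f_max=150.0)
        assert out.freqs.max() <= 150.0

    def test_zero_margin_starts_at_speech_start(self, rng):
        sp = make_spectra(rng)
        out = restrict_window(sp, (0.0, 0.3), margin=0.0, f_max=1000.0)
        assert out.times.min() >= 0.0

    def test_identity_configuration(self, rng):
        sp = make_spectra(rng)
        out = restrict_window(sp, (0.0, 0.0), margin=np.inf, f_max=300.0)
        assert out.log_rsm.shape == sp.log_rsm.shape

    def test_per_trial_bounds_are_averaged(self, rng):
        sp = make_spectra(rng)
        ss = [-0.1, -0.3]  # mean -0.2
        se = [0.1, 0.3]
        out = restrict_window(sp, (ss, se), margin=0.0, f_max=1000.0)
        assert out.times.min() >= -0.2 - 1e-9
        assert out.times.max() <= 0.2 + 1e-9
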