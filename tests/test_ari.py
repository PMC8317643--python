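import numpy as np
import pandas as pd
import pytest

from restforge.ari import (
    LogRestitutionRegressor,
    build_apdr,
    compare_cohorts,
    fit_cohort_curves,
    fit_log_robust,
    wyatt_ari,
)
from restforge.cohorts import cohort_table
from restforge.egm import CohortSpec, NoiseSpec, synth_cohort


def _clean_cohort(n_pat=1, n_el=2, cohort="snlv", seed=5, noise=None, spread=False):
    spec = CohortSpec.from_cohort(cohort, ari_noise_sd=0.0)
    spec.anchor_offsets = None  # electrodes follow their log curve exactly
    if not spread:
        spec.between_sd = 0.0
        spec.within_sd = 0.0
    return synth_cohort(spec, n_pat, n_el, noise=noise, rng_seed=seed)


class TestWyatt:
    def test_clean_recovery_within_one_sample(self):
        rec = _clean_cohort()[0]
        one_sample = 1000.0 / rec.fs
        for ch in range(rec.n_channels):
            m = wyatt_ari(rec, ch)
            assert m["detected"].all()
            truth = rec.truth[(rec.truth["electrode"] == ch) & rec.truth["captured"]]
            merged = m.merge(truth, on=["burst", "beat"], suffixes=("_est", "_true"))
            err = np.abs(merged["ari_est"] - merged["ari_true"])
            assert (err <= one_sample + 1e-9).all()

    def test_constant_offset_invariance(self):
        rec = _clean_cohort()[0]
        m1 = wyatt_ari(rec, 0)
        rec.samples = rec.samples + 3.7  # derivative unchanged
        m2 = wyatt_ari(rec, 0)
        pd.testing.assert_frame_equal(m1, m2)


class TestExclusionRule:
    @pytest.mark.parametrize("n_beats,expected", [(20, 16), (5, 1)])
    def test_retained_count(self, n_beats, expected):
        meas = pd.DataFrame(
            dict(
                burst=0,
                cl=500.0,
                beat=np.arange(n_beats),
                di=np.linspace(200, 250, n_beats),
                ari=np.full(n_beats, 240.0),
                detected=True,
            )
        )
        pts = build_apdr(meas)
        assert len(pts) == expected

    def test_four_beat_burst_is_degenerate(self):
        meas = pd.DataFrame(
            dict(burst=0, cl=500.0, beat=np.arange(4), di=1.0, ari=1.0, detected=True)
        )
        with pytest.raises(ValueError):
            build_apdr(meas)


class TestRobustLogFit:
    def test_noiseless_machine_precision_recovery(self):
        di = np.linspace(120, 340, 30)
        ari = 100.0 + 50.0 * np.log(di)
        c = fit_log_robust(di, ari)
        assert c.alpha == pytest.approx(100.0, abs=1e-7)
        assert c.beta == pytest.approx(50.0, abs=1e-8)
        assert c.r_squared == pytest.approx(100.0, abs=1e-8)
        assert c.accepted

    def test_bisquare_reduces_to_ols_for_small_residuals(self, rng):
        # when residuals are small relative to the tuning constant the
        # bisquare weights are ~1 and the fit collapses to OLS
        di = np.linspace(120, 340, 80)
        ari = -20.0 + 55.0 * np.log(di) + rng.normal(0, 1.5, di.size)
        c = fit_log_robust(di, ari)
        beta_ols, alpha_ols = np.polyfit(np.log(di), ari, 1)
        assert c.beta == pytest.approx(beta_ols, rel=0.02)
        assert c.alpha == pytest.approx(alpha_ols, abs=0.05 * abs(alpha_ols) + 1.0)

    @pytest.mark.parametrize("cohort", ["snlv", "icmp"])
    def test_anchor_mean_fit_tracks_the_published_points(self, cohort):
        tab = cohort_table(cohort)
        di = tab["di_mean"].to_numpy()
        ari = tab["ari_mean"].to_numpy()
        c = fit_log_robust(di, ari)
        assert np.max(np.abs(c(di) - ari)) < 12.0  # log model residual scale
        assert c.accepted

    def test_resists_gross_outliers_where_ols_does_not(self, rng):
        di = np.linspace(100, 340, 60)
        ari = -20.0 + 55.0 * np.log(di) + rng.normal(0, 1.0, di.size)
        spoiled = ari.copy()
        idx = rng.choice(di.size, size=12, replace=False)  # 20% gross outliers
        spoiled[idx] += rng.choice([-100.0, 100.0], size=12)
        robust = fit_log_robust(di, spoiled)
        beta_ols, _ = np.polyfit(np.log(di), spoiled, 1)
        assert abs(robust.beta - 55.0) / 55.0 < 0.05
        assert abs(beta_ols - 55.0) > abs(robust.beta - 55.0)

    def test_r2_filter_rejects_noise_dominated_fit(self, rng):
        di = np.linspace(100, 340, 48)
        ari = 230.0 + rng.normal(0, 30.0, di.size)  # no restitution signal
        c = fit_log_robust(di, ari)
        assert not c.accepted

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_log_robust([200.0] * 10, np.linspace(200, 250, 10))

    def test_sklearn_estimator_interface(self):
        di = np.linspace(120, 340, 20)
        reg = LogRestitutionRegressor().fit(di, 10 + 40 * np.log(di))
        assert reg.get_params()["c"] == 4.685
        assert np.allclose(reg.predict(di), 10 + 40 * np.log(di), atol=1e-6)


class TestEndToEnd:
    def test_slope_recovery_within_2_percent_for_95_percent_of_electrodes(self):
        recs = _clean_cohort(n_pat=3, n_el=4, spread=True, seed=21)
        ok = 0
        total = 0
        for rec in recs:
            for ch in range(rec.n_channels):
                m = wyatt_ari(rec, ch)
                pts = build_apdr(m)
                c = fit_log_robust(pts["di"], pts["ari"])
                beta_true = rec.truth[rec.truth["electrode"] == ch]["beta_true"].iloc[0]
                total += 1
                if abs(c.beta - beta_true) / abs(beta_true) < 0.02:
                    ok += 1
        assert ok / total >= 0.95


class TestCompareCohorts:
    def _curves(self, rng, delta=0.0, n_pat=5, n_el=3):
        rows = []
        for cohort, off in (("snlv", 0.0), ("icmp", delta)):
            for p in range(n_pat):
                pslope = 50.0 + off + rng.normal(0, 5)
                for e in range(n_el):
                    rows.append(
                        dict(cohort=cohort, patient=f"{cohort}{p}", electrode=e,
                             beta=pslope + rng.normal(0, 2))
                    )
        return pd.DataFrame(rows)

    def test_identical_cohorts_ci_covers_zero(self, rng):
        res = compare_cohorts(self._curves(rng, 0.0), seed=0, n_boot=500)
        assert res["ci_low"] < 0.0 < res["ci_high"]

    def test_known_offset_recovered(self, rng):
        res = compare_cohorts(self._curves(rng, 30.0, n_pat=8), seed=0, n_boot=500)
        assert res["ci_low"] < 30.0 < res["ci_high"]
        assert res["estimate"] == pytest.approx(30.0, abs=8.0)

    def test_electrode_shuffling_within_patient_leaves_estimate(self, rng):
        df = self._curves(rng, 10.0)
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = compare_cohorts(df, seed=3, n_boot=200)
        b = compare_cohorts(shuffled, seed=3, n_boot=200)
        assert a["estimate"] == pytest.approx(b["estimate"], abs=1e-12)

    def test_single_patient_cohort_rejected(self, rng):
        df = self._curves(rng)
        df = df[(df["cohort"] == "snlv") | (df["patient"] == "icmp0")]
        with pytest.raises(ValueError):
            compare_cohorts(df)


def test_fit_cohort_curves_shapes():
    recs = _clean_cohort(n_pat=2, n_el=2)
    curves = fit_cohort_curves(recs, cohort="snlv")
    assert set(curves.columns) >= {"patient", "electrode", "alpha", "beta", "r2", "accepted"}
    assert len(curves) == 4
    assert curves["accepted"].all()
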