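import numpy as np
import pytest

from restforge.cohorts import cohort_table
from restforge.egm import (
    CohortSpec,
    NoiseSpec,
    PacingProtocol,
    synth_cohort,
    synth_truth,
    synth_unieg,
)


def _clean_spec(cohort="snlv"):
    # idealized cohort: pure log curve, no variability, no anchor offsets
    spec = CohortSpec.from_cohort(cohort, ari_noise_sd=0.0)
    spec.between_sd = 0.0
    spec.within_sd = 0.0
    spec.anchor_offsets = None
    return spec


class TestSynthTruth:
    def test_zero_variance_points_lie_exactly_on_curve(self):
        spec = _clean_spec()
        truth = synth_truth(spec, 1, 1, rng_seed=0)
        cap = truth[truth["captured"]]
        pred = spec.alpha + spec.beta * np.log(cap["di"])
        assert np.allclose(cap["ari"], pred, atol=1e-9)

    def test_deterministic_under_seed(self):
        spec = CohortSpec.from_cohort("icmp")
        a = synth_truth(spec, 2, 2, rng_seed=7)
        b = synth_truth(spec, 2, 2, rng_seed=7)
        assert a.equals(b)

    def test_loss_of_capture_flagged_not_emitted(self):
        # a curve so long that ARI exceeds the shortest CL loses capture
        spec = _clean_spec()
        spec.alpha += 250.0
        truth = synth_truth(spec, 1, 1, rng_seed=0)
        lost = truth[~truth["captured"]]
        assert len(lost) > 0
        assert lost["ari"].isna().all()

    def test_cohort_means_match_anchors_within_2_sem(self):
        # statistical calibration of the generator against the published
        # per-CL cohort anchors
        for cohort in ("snlv", "icmp"):
            spec = CohortSpec.from_cohort(cohort)
            truth = synth_truth(spec, 30, 8, rng_seed=3)  # 240 electrodes
            cap = truth[truth["captured"] & (truth["beat"] >= 3)]
            tab = cohort_table(cohort).set_index("cl")
            for cl, g in cap.groupby("cl"):
                per_el = g.groupby(["patient", "electrode"])[["di", "ari"]].mean()
                for col, anchor in (("di", "di_mean"), ("ari", "ari_mean")):
                    m = per_el[col].mean()
                    sem = per_el[col].std() / np.sqrt(len(per_el))
                    tol = 2.0 * max(sem, 1.0) + 3.0  # 2 SEM plus curve-fit residual
                    assert abs(m - tab.loc[cl, anchor]) < tol, (cohort, cl, col)

    def test_icmp_short_cl_spread_exceeds_snlv(self):
        t_s = synth_truth(CohortSpec.from_cohort("snlv"), 25, 8, rng_seed=11)
        t_i = synth_truth(CohortSpec.from_cohort("icmp"), 25, 8, rng_seed=11)

        def sd350(t):
            g = t[t["captured"] & (t["cl"] == 350) & (t["beat"] >= 3)]
            return g.groupby(["patient", "electrode"])["ari"].mean().std()

        assert sd350(t_i) > 1.5 * sd350(t_s)


class TestSynthUnieg:
    def test_derivative_extrema_at_truth_times(self):
        spec = _clean_spec()
        rec = synth_cohort(spec, 1, 1, rng_seed=2)[0]
        sig = rec.samples[0]
        t = rec.time_ms
        deriv = np.gradient(sig, 1000.0 / rec.fs)
        one_sample = 1000.0 / rec.fs
        truth = rec.truth[rec.truth["captured"]]
        for _, row in truth.head(30).iterrows():
            at, rt = row["at"], row["rt"]
            win = (t > at - 25) & (t < at + 25)
            t_min = t[win][np.argmin(deriv[win])]
            assert abs(t_min - at) <= one_sample + 1e-9
            win = (t > rt - 60) & (t < rt + 60)
            t_max = t[win][np.argmax(deriv[win])]
            assert abs(t_max - rt) <= one_sample + 1e-9

    def test_amplitude_scaling_leaves_extrema_fixed(self):
        spec = _clean_spec()
        truth = synth_truth(spec, 1, 1, rng_seed=4)
        r1 = synth_unieg(truth, rng_seed=0, act_amp_mv=1.5)
        r2 = synth_unieg(truth, rng_seed=0, act_amp_mv=3.0)
        d1 = np.gradient(r1.samples[0])
        d2 = np.gradient(r2.samples[0])
        assert np.argmin(d1) == np.argmin(d2)

    def test_bit_identical_under_seed(self):
        spec = CohortSpec.from_cohort("icmp")
        r1 = synth_cohort(spec, 2, 2, noise=NoiseSpec(white_sd=0.05), rng_seed=9)
        r2 = synth_cohort(spec, 2, 2, noise=NoiseSpec(white_sd=0.05), rng_seed=9)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.samples, b.samples)

    def test_zero_noise_spec_is_clean(self):
        ns = NoiseSpec()
        assert ns.white_sd == 0 and ns.line_amp == 0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(white_sd=-1.0)


def test_protocol_validation():
    with pytest.raises(ValueError):
        PacingProtocol(cls=(350, 600))
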