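"""Signal-model forward evaluation and map-fit round trips.

Frozen expected values were computed independently with high-precision
arithmetic of the closed forms (mpmath-style evaluation of exp/sin/cos).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import qmrecon as q
from qmrecon.signal_models import fit_t2_msme_map, qdess_f_factor


class TestMSME:
    def test_single_echo_value(self):
        # 1000 * exp(-100/100) = 1000 * exp(-1)
        s = q.msme_signal(1000.0, 100.0, [100.0])
        assert s[0] == pytest.approx(367.8794411714423, rel=1e-12)

    def test_small_te_limit_approaches_i0(self):
        s = q.msme_signal(5.0, 1e9, [1e-9])
        assert s[0] == pytest.approx(5.0, rel=1e-9)

    def test_default_protocol_strictly_decreasing(self):
        seq = q.msme_params()
        assert seq.te_list == tuple(float(t) for t in range(10, 170, 10))
        s = q.msme_signal(100.0, 77.0, seq.te_list)
        assert np.all(np.diff(s) < 0)

    def test_nonpositive_t2_rejected(self):
        with pytest.raises(ValueError):
            q.msme_signal(1.0, 0.0, [10.0])

    def test_noiseless_fit_recovers_parameters(self):
        te = tuple(range(10, 170, 10))
        s = q.msme_signal(500.0, 80.0, te)
        i0, t2, valid = q.fit_t2_msme(s, te)
        assert valid
        assert i0 == pytest.approx(500.0, rel=1e-6)
        assert t2 == pytest.approx(80.0, rel=1e-6)

    def test_flat_signal_is_invalid(self):
        _, t2, valid = q.fit_t2_msme(np.full(8, 3.0), tuple(range(10, 90, 10)))
        assert not valid
        assert t2 == pytest.approx(5000.0)

    def test_single_echo_rejected(self):
        with pytest.raises(ValueError):
            q.fit_t2_msme([1.0], [10.0])

    def test_noisy_fit_median_bias_below_two_percent(self):
        te = tuple(range(10, 170, 10))
        clean = q.msme_signal(1000.0, 80.0, te)
        rng = np.random.default_rng(123)
        snr = 50.0
        sigma = 1000.0 / snr
        fits = []
        sig = np.abs(clean + rng.normal(scale=sigma, size=(1000, len(te))))
        i0, t2, valid = fit_t2_msme_map(sig, te)
        fits = t2[valid]
        assert abs(np.median(fits) - 80.0) / 80.0 < 0.02

    def test_map_fit_matches_scalar_fit_on_clean_decay(self):
        te = tuple(range(10, 170, 10))
        i0s = np.array([200.0, 900.0])
        t2s = np.array([35.0, 140.0])
        sig = q.msme_signal(i0s, t2s, te)
        i0m, t2m, validm = fit_t2_msme_map(sig, te)
        assert validm.all()
        np.testing.assert_allclose(t2m, t2s, rtol=1e-8)
        np.testing.assert_allclose(i0m, i0s, rtol=1e-8)


class TestSPGR:
    def test_reference_value(self):
        # I0=1000, T1=1000, TR=18, alpha=24 deg; frozen from an
        # arbitrary-precision evaluation of the closed form (sympy)
        s = q.spgr_signal(1000.0, 1000.0, 18.0, 24.0)
        assert s == pytest.approx(70.61482755007470, rel=1e-12)

    def test_zero_flip_angle_limit(self):
        s = q.spgr_signal(1000.0, 800.0, 18.0, 1e-7)
        assert abs(s) < 1e-5

    def test_saturation_limit_is_i0_sin_alpha(self):
        s = q.spgr_signal(100.0, 1.0, 1e5, 30.0)
        assert s == pytest.approx(100.0 * np.sin(np.deg2rad(30.0)), rel=1e-9)

    def test_as_printed_form_omits_sin(self):
        s_sin = q.spgr_signal(1.0, 1000.0, 18.0, 24.0, include_sin=True)
        s_raw = q.spgr_signal(1.0, 1000.0, 18.0, 24.0, include_sin=False)
        assert s_sin == pytest.approx(s_raw * np.sin(np.deg2rad(24.0)), rel=1e-12)

    @pytest.mark.parametrize("include_sin", [True, False])
    def test_vfa_round_trip(self, include_sin):
        angles = (4.0, 24.0)  # default two-angle protocol
        s = np.array([q.spgr_signal(800.0, 1200.0, 18.0, a, include_sin)
                      for a in angles])
        i0, t1, valid = q.fit_t1_vfa(s, angles, 18.0, include_sin=include_sin)
        assert valid
        assert t1 == pytest.approx(1200.0, rel=1e-6)
        assert i0 == pytest.approx(800.0, rel=1e-6)

    def test_nonphysical_slope_invalid(self):
        # a decay with angle steeper than any T1 allows puts the linearized
        # slope at >= 1 -> flagged invalid
        _, t1, valid = q.fit_t1_vfa(np.array([1.0, 0.05]), (4.0, 24.0), 18.0)
        assert not valid

    def test_identical_angles_rejected(self):
        with pytest.raises(ValueError):
            q.fit_t1_vfa(np.array([1.0, 2.0]), (10.0, 10.0), 18.0)


class TestQDESS:
    def test_uncorrected_half_ratio(self):
        seq = q.qdess_params()
        # exp(-2*(17.9-5.7)/T2) = 0.5 at T2 = 24.4/ln 2
        t2 = 24.4 / np.log(2.0)
        r = q.qdess_ratio(t2, seq, corrected=False)
        assert r == pytest.approx(0.5, rel=1e-12)

    def test_f_factor_reference_value(self):
        seq = q.qdess_params(d=0.0, flip=20.0, assumed_t1=1000.0, tr=17.9)
        assert qdess_f_factor(seq) == pytest.approx(0.7765, abs=2e-4)

    def test_infinite_t2_limit_uncorrected(self):
        seq = q.qdess_params()
        assert q.qdess_ratio(1e12, seq, corrected=False) == pytest.approx(1.0, rel=1e-9)

    def test_ratio_increasing_in_t2(self):
        seq = q.qdess_params()
        t2 = np.linspace(10, 400, 50)
        r = q.qdess_ratio(t2, seq)
        assert np.all(np.diff(r) > 0)

    def test_closed_form_inversion(self):
        seq = q.qdess_params()
        fid = np.ones((3, 3))
        echo = fid * q.qdess_ratio(45.0, seq)
        t2, valid = q.fit_t2_qdess(fid, echo, seq)
        assert valid.all()
        np.testing.assert_allclose(t2, 45.0, rtol=1e-6)

    def test_non_decaying_ratio_invalid(self):
        seq = q.qdess_params()
        t2, valid = q.fit_t2_qdess(np.ones((2,)), np.full((2,), 2.0), seq)
        assert not valid.any()

    def test_zero_fid_invalid(self):
        seq = q.qdess_params()
        _, valid = q.fit_t2_qdess(np.zeros(2), np.ones(2), seq)
        assert not valid.any()

    def test_uncorrected_fit_inverts_plain_exponential_exactly(self):
        seq = q.qdess_params(d=0.0)
        t2_true = 123.0
        r = np.exp(-2.0 * (seq.tr - seq.te_list[0]) / t2_true)
        t2, valid = q.fit_t2_qdess(np.ones(1), np.full(1, r), seq, corrected=False)
        assert valid.all()
        assert t2[0] == pytest.approx(t2_true, rel=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10**6))
def test_round_trip_property_all_sequences(seed):
    """Noiseless fit(signal(params)) recovers the parameters, all models."""
    rng = np.random.default_rng(seed)
    i0 = float(rng.uniform(10.0, 2000.0))
    t2 = float(rng.uniform(20.0, 300.0))
    t1 = float(rng.uniform(300.0, 3000.0))
    te = tuple(range(10, 170, 10))
    s = q.msme_signal(i0, t2, te)
    fi0, ft2, valid = q.fit_t2_msme(s, te)
    assert valid and abs(ft2 - t2) / t2 < 1e-6 and abs(fi0 - i0) / i0 < 1e-6
    angles = (4.0, 24.0)
    sv = np.array([q.spgr_signal(i0, t1, 18.0, a) for a in angles])
    _, ft1, validv = q.fit_t1_vfa(sv, angles, 18.0)
    assert validv and abs(ft1 - t1) / t1 < 1e-6
    seq = q.qdess_params()
    t2q = float(rng.uniform(10.0, 400.0))
    echo = q.qdess_ratio(t2q, seq)
    ft2q, validq = q.fit_t2_qdess(np.ones(1), np.full(1, echo), seq)
    assert validq.all() and abs(ft2q[0] - t2q) / t2q < 1e-6


class TestSequenceParams:
    def test_te_must_increase(self):
        with pytest.raises(ValueError):
            q.SequenceParams("MSME", te_list=(20.0, 10.0), tr=4000.0,
                             flip_angles=(90.0,))

    def test_tr_must_exceed_te(self):
        with pytest.raises(ValueError):
            q.SequenceParams("MSME", te_list=(10.0, 20.0), tr=15.0,
                             flip_angles=(90.0,))

    def test_flip_angle_range(self):
        with pytest.raises(ValueError):
            q.SequenceParams("VFA_SPGR", te_list=(8.0,), tr=18.0,
                             flip_angles=(0.0, 24.0))

    def test_default_protocols_match_study_settings(self):
        msme = q.msme_params()
        assert msme.tr == 4000.0 and len(msme.te_list) == 16
        vfa = q.vfa_params()
        assert vfa.flip_angles == (4.0, 24.0) and vfa.tr == 18.0
        qd = q.qdess_params()
        assert qd.te_list == (5.7, 30.1) and qd.tr == 17.9 and qd.flip_angles == (20.0,)
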