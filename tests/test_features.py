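"""The 40-feature descriptor: oracles and invariants per group."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from beatguard.features import (
    FEATURE_GROUPS,
    FEATURE_NAMES,
    extract_features,
    fiducial_features,
    hrv_nonlinear_features,
    locate_fiducials,
    poincare_descriptors,
    sample_entropy,
    statistical_features,
    wavelet_features,
)
from beatguard.records import BeatSegment, RRContext
from beatguard.synth import (
    NORMAL_TEMPLATE,
    PVC_TEMPLATE,
    WaveParams,
    synth_beat,
)

RR32 = RRContext(rr_pre=820.0, rr_post=850.0,
                 rr_history=np.full(32, 840.0))


def _segment(samples):
    return BeatSegment(np.asarray(samples, dtype=float), 360.0)


# ---------------------------------------------------------------------------
# statistical
# ---------------------------------------------------------------------------

def _naive_statistics(x):
    """Loop-based re-implementation straight from the moment definitions."""
    n = len(x)
    mu = sum(x) / n
    var = sum((v - mu) ** 2 for v in x) / n
    sd = math.sqrt(var)
    ptp = max(x) - min(x)
    if sd == 0:
        skew = kurt = 0.0
    else:
        skew = sum(((v - mu) / sd) ** 3 for v in x) / n
        kurt = sum(((v - mu) / sd) ** 4 for v in x) / n - 3.0
    rms = math.sqrt(sum(v * v for v in x) / n)
    return [mu, sd, ptp, skew, kurt, rms]


def test_statistical_small_example():
    seg = _segment(np.resize([1.0, 2.0, 3.0, 4.0], 256))
    # direct arithmetic on the first four values, replicated to 256:
    vals = statistical_features(_segment([1.0, 2.0, 3.0, 4.0] * 64))
    assert vals[0] == pytest.approx(2.5)
    assert vals[2] == pytest.approx(3.0)
    assert vals[1] == pytest.approx(math.sqrt(1.25))


def test_statistical_constant_segment_degenerate():
    vals = statistical_features(_segment(np.full(256, -0.4)))
    mu, sd, ptp, skew, kurt, rms = vals
    assert sd == 0 and ptp == 0 and skew == 0 and kurt == 0
    assert rms == pytest.approx(0.4)


@settings(max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_statistical_matches_naive_oracle(seed):
    x = np.random.default_rng(seed).normal(size=256)
    np.testing.assert_allclose(
        statistical_features(_segment(x)), _naive_statistics(list(x)),
        rtol=1e-10, atol=1e-12)


# ---------------------------------------------------------------------------
# fiducial
# ---------------------------------------------------------------------------

class TestFiducials:
    def test_clean_beat_recovers_generator_truth(self):
        seg, truth = synth_beat(NORMAL_TEMPLATE)
        fid = locate_fiducials(seg)
        assert abs(fid.q_trough - (truth.q_trough + seg.r_index / 360)) \
            < 0.010
        assert abs(fid.s_trough - (truth.s_trough + seg.r_index / 360)) \
            < 0.010

    def test_flat_segment_all_absent(self):
        fid = locate_fiducials(_segment(np.zeros(256)))
        assert fid.r_amplitude is None and fid.q_trough is None
        assert fid.t_peak is None and fid.p_peak is None

    def test_inverted_t_measured_negative(self):
        _, truth = synth_beat(PVC_TEMPLATE)
        seg, _ = synth_beat(PVC_TEMPLATE)
        fid = locate_fiducials(seg)
        assert fid.t_amplitude < 0
        assert truth.t_amplitude < 0

    def test_qrs_subtraction(self):
        """T_Q at 0.26 s, T_S at 0.34 s gives an 80 ms QRS duration."""
        from beatguard.features import FiducialPoints

        fid = FiducialPoints(baseline=0.0, q_onset=0.26, s_offset=0.34)
        vals, mask = fiducial_features(fid, RR32)
        assert not mask[2]
        assert vals[2] == pytest.approx(80.0)

    def test_ratio_convention(self):
        from beatguard.features import FiducialPoints

        fid = FiducialPoints(baseline=0.0, r_amplitude=1.0,
                             s_amplitude=-0.25)
        vals, mask = fiducial_features(fid, RR32)
        assert vals[FEATURE_NAMES.index("rs_ratio") - 6] == pytest.approx(4.0)

    def test_absent_wave_masked_not_fabricated(self):
        from beatguard.features import FiducialPoints

        fid = FiducialPoints(baseline=0.0, r_amplitude=1.0)
        vals, mask = fiducial_features(fid, RR32)
        # p-derived entries masked
        for name in ("p_duration", "p_amplitude", "pr_ratio"):
            assert mask[FEATURE_NAMES.index(name) - 6]

    def test_recovery_on_fifty_clean_beats(self):
        """QRS within 10 ms of truth, T polarity always matches."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(50):
            waves = {}
            for n, (a, c, w) in NORMAL_TEMPLATE.waves.items():
                g = float(rng.uniform(0.8, 1.2))
                waves[n] = (a * g, c, w)
            if rng.random() < 0.5:
                a, c, w = waves["T"]
                waves["T"] = (-a, c, w)
            seg, truth = synth_beat(WaveParams(waves))
            fid = locate_fiducials(seg)
            if truth.qrs_duration_ms is not None:
                meas = fiducial_features(fid, RR32)[0][2]
                assert abs(meas - truth.qrs_duration_ms) <= 10.0
                checked += 1
            assert np.sign(fid.t_amplitude) == np.sign(truth.t_amplitude)
        assert checked >= 40


# ---------------------------------------------------------------------------
# wavelet
# ---------------------------------------------------------------------------

DB4_LO = np.array([
    -0.010597401785069032, 0.0328830116668852, 0.030841381835560764,
    -0.18703481171909309, -0.027983769416859854, 0.6308807679298589,
    0.7148465705529157, 0.2303778133088965,
])  # decomposition low-pass, standard db4 coefficients


def _independent_dwt_energies(x):
    """Direct circular convolution/decimation pyramid (periodized DWT),
    written from the filter-bank definition, independent of pywt."""
    lo = DB4_LO
    hi = np.array([(-1) ** k * lo[::-1][k] for k in range(len(lo))])
    L = len(lo)
    energies = []
    a = np.asarray(x, dtype=float)
    for _ in range(4):
        n = len(a)
        idx = (2 * np.arange(n // 2)[:, None] + L // 2
               - np.arange(L)[None, :]) % n
        ca = (a[idx] * lo[None, :]).sum(axis=1)
        cd = (a[idx] * hi[None, :]).sum(axis=1)
        energies.append(float(np.sum(cd**2)))
        a = ca
    return energies, float(np.sum(a**2))


def test_wavelet_zero_signal_all_zero():
    vals = wavelet_features(_segment(np.zeros(256)))
    np.testing.assert_array_equal(vals, np.zeros(12))


def test_wavelet_single_nonzero_coefficient_entropy_zero():
    from beatguard.features import _shannon_entropy

    assert _shannon_entropy(np.array([0.0, 3.0, 0.0])) == 0.0


def test_wavelet_parseval_and_entropy_bounds():
    """Energy conservation within 1e-6 relative on 100 random beats,
    verified against the independent filter-bank pyramid."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        x = rng.normal(size=256)
        vals = wavelet_features(_segment(x))
        energies = vals[0::3]
        entropies = vals[1::3]
        ref_details, ref_approx = _independent_dwt_energies(x)
        sig = float(np.sum(x**2))
        # detail energies match the oracle, and together with the
        # approximation they account for the whole signal energy
        np.testing.assert_allclose(energies, ref_details, rtol=1e-8)
        assert abs(sum(ref_details) + ref_approx - sig) / sig < 1e-6
        assert np.all(energies >= 0)
        for h, n in zip(entropies, (128, 64, 32, 16)):  # cD1..cD4 lengths
            assert 0.0 <= h <= np.log2(n) + 1e-12


def test_wavelet_energies_match_independent_pyramid():
    rng = np.random.default_rng(13)
    x = rng.normal(size=256)
    vals = wavelet_features(_segment(x))
    ref, _ = _independent_dwt_energies(x)
    np.testing.assert_allclose(vals[0::3], ref, rtol=1e-8)


# ---------------------------------------------------------------------------
# HRV / non-linear
# ---------------------------------------------------------------------------

def _brute_force_sampen(x, m, r):
    x = np.asarray(x, dtype=float)
    n = len(x)

    def count(mm):
        tpl = np.array([x[i:i + mm] for i in range(n - mm + 1)])
        d = cdist(tpl, tpl, metric="chebyshev")
        iu = np.triu_indices(len(tpl), k=1)
        return int(np.sum(d[iu] <= r))

    # templates of length m drawn from the first n-m positions only,
    # matching the definition where each m-template extends to m+1
    def count_restricted(mm, limit):
        tpl = np.array([x[i:i + mm] for i in range(limit)])
        d = cdist(tpl, tpl, metric="chebyshev")
        iu = np.triu_indices(len(tpl), k=1)
        return int(np.sum(d[iu] <= r))

    b = count_restricted(m, n - m)
    a = count_restricted(m + 1, n - m)
    if a == 0 or b == 0:
        return None
    return -math.log(a / b)


def test_sampen_constant_series_zero():
    assert sample_entropy(np.full(20, 800.0)) == 0.0


@pytest.mark.parametrize("seed", range(10))
def test_sampen_matches_bruteforce_on_short_series(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(8, 31))
    x = rng.normal(800, 50, size=n)
    r = 0.15 * float(np.std(x))
    ours = sample_entropy(x, m=2, r=r)
    ref = _brute_force_sampen(x, 2, r)
    if ref is None:
        assert ours is None
    else:
        assert ours == pytest.approx(ref, rel=1e-12)


def test_poincare_hand_oracle():
    """RR = [800, 810, 800, 810]: SD1/SD2 from the lagged-pair variances."""
    rr = np.array([800.0, 810.0, 800.0, 810.0])
    d = rr[1:] - rr[:-1]          # [10, -10, 10]
    s = rr[1:] + rr[:-1]          # [1610, 1610, 1610]
    sd1_ref = math.sqrt(0.5 * np.var(d))
    sd2_ref = math.sqrt(0.5 * np.var(s))
    sd1, sd2 = poincare_descriptors(rr)
    assert sd1 == pytest.approx(sd1_ref)
    assert sd2 == pytest.approx(sd2_ref) == 0.0


@pytest.mark.parametrize("seed", range(20))
def test_poincare_identity(seed):
    """SD1^2 + SD2^2 = 2 * SDNN_lag^2 with population variances."""
    rng = np.random.default_rng(seed)
    rr = rng.normal(850, 40, size=int(rng.integers(8, 64)))
    sd1, sd2 = poincare_descriptors(rr)
    a, b = rr[1:], rr[:-1]
    sdnn_lag_sq = 0.5 * (np.var(a) + np.var(b))
    assert sd1**2 + sd2**2 == pytest.approx(2 * sdnn_lag_sq, abs=1e-9)


def test_hrv_constant_history():
    rr = RRContext(rr_pre=800.0, rr_post=800.0,
                   rr_history=np.full(32, 800.0))
    vals, mask = hrv_nonlinear_features(rr)
    names = FEATURE_GROUPS["hrv_nonlinear"]
    d = dict(zip(names, vals))
    for key in ("sdnn", "rmssd", "sd1", "sd2", "sampen"):
        assert not mask[names.index(key)]
        assert d[key] == 0.0


def test_hrv_short_history_masked():
    rr = RRContext(rr_pre=800.0, rr_post=800.0,
                   rr_history=np.full(5, 800.0))
    _, mask = hrv_nonlinear_features(rr)
    assert mask.all()


# ---------------------------------------------------------------------------
# full descriptor
# ---------------------------------------------------------------------------

class TestExtract:
    def test_length_and_group_sizes(self):
        seg, _ = synth_beat(NORMAL_TEMPLATE)
        fv = extract_features(seg, RR32)
        assert fv.values.size == 40
        sizes = {g: len(n) for g, n in FEATURE_GROUPS.items()}
        assert sizes == {"statistical": 6, "fiducial": 13, "wavelet": 12,
                         "hrv_nonlinear": 9}

    def test_determinism(self):
        seg, _ = synth_beat(NORMAL_TEMPLATE)
        a = extract_features(seg, RR32)
        b = extract_features(seg, RR32)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_absent_p_masks_only_p_entries(self):
        seg, _ = synth_beat(PVC_TEMPLATE)  # P amplitude is 0
        fv = extract_features(seg, RR32)
        d = fv.as_dict()
        for name in ("p_duration", "p_amplitude", "pr_ratio"):
            assert d[name] is None
        assert d["qrs_duration"] is not None
        finite = [v for v in d.values() if v is not None]
        assert all(np.isfinite(v) for v in finite)

    def test_canonical_order(self):
        assert FEATURE_NAMES[:6] == FEATURE_GROUPS["statistical"]
        assert FEATURE_NAMES[6:19] == FEATURE_GROUPS["fiducial"]
        assert FEATURE_NAMES[19:31] == FEATURE_GROUPS["wavelet"]
        assert FEATURE_NAMES[31:] == FEATURE_GROUPS["hrv_nonlinear"]
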