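import numpy as np
import pytest
from scipy import signal

from isletnet import (
    ExclusionRules,
    IsletConfig,
    Protocol,
    Segment,
    TraceSet,
    bandpass_zero_lag,
    correct_bleaching,
    exclude_artifacts,
    generate_islet,
    normalize_f0,
    preprocess_traces,
)

FS = 10.0


def _simple_protocol(pre=120.0, stim=480.0, post=120.0):
    return Protocol(
        [
            Segment("low", 0.0, pre),
            Segment("high", pre, pre + stim, True, 0.033, 10.7),
            Segment("washout", pre + stim, pre + stim + post),
        ]
    )


def _traceset(F, prot=None):
    F = np.asarray(F, dtype=float)
    n = F.shape[1]
    return TraceSet(
        F=F, fs=FS, positions=np.zeros((n, 2)),
        protocol=prot or _simple_protocol(),
    )


# ----------------------------------------------------------------- F/F0

def test_normalize_constant_trace_gives_unity():
    ts = _traceset(np.full((7200, 2), 37.5))
    out = normalize_f0(ts)
    np.testing.assert_allclose(out.F, 1.0)


def test_normalize_recovers_relative_signal_exactly():
    t = np.arange(7200) / FS
    s = 0.4 * np.sin(2 * np.pi * t / 60.0)
    s[: int(120 * FS)] = 0.0  # quiet baseline window
    ts = _traceset((123.0 * (1.0 + s))[:, None])
    out = normalize_f0(ts, baseline_window=(0.0, 60.0))
    np.testing.assert_allclose(out.F[:, 0], 1.0 + s, rtol=1e-12)


def test_normalize_rejects_window_overlapping_active_segment():
    ts = _traceset(np.ones((7200, 1)))
    with pytest.raises(ValueError):
        normalize_f0(ts, baseline_window=(100.0, 200.0))  # crosses 120 s
    with pytest.raises(ValueError):
        normalize_f0(ts, baseline_window=(200.0, 260.0))  # inside active


def test_normalize_rejects_nonpositive_baseline():
    F = np.ones((7200, 1))
    F[:, 0] = -1.0
    with pytest.raises(ValueError):
        normalize_f0(_traceset(F))


# ------------------------------------------------------------- bleaching

def test_bleach_correction_leaves_driftfree_trace_unchanged():
    ts = _traceset(np.full((7200, 1), 2.0))
    out, report = correct_bleaching(ts)
    np.testing.assert_allclose(out.F, ts.F, rtol=1e-6)
    assert report.loc[0, "method"] == "exp+linear"


def test_bleach_correction_flattens_known_exponential_plus_linear_drift(fast_protocol):
    cfg = IsletConfig(
        n_cells=4, seed=4, noise_sd=0.0, bleach_tau_s=1200.0,
        bleach_slope_per_s=-5e-5, deact_delay_median_s=60.0,
    )
    traces, _ = generate_islet(cfg, fast_protocol)
    out, _ = correct_bleaching(normalize_f0(traces))
    t = out.time
    for j in range(out.n_cells):
        x = out.F[:, j]
        start = x[t < 110.0].mean()
        end = np.percentile(x[t > fast_protocol.end - 100.0], 10)
        # raw baseline decays to ~45% of start; corrected stays flat
        assert abs(end - start) < 0.01 * start


def test_bleach_correction_preserves_oscillation_amplitudes(fast_protocol):
    cfg = IsletConfig(
        n_cells=4, seed=4, noise_sd=0.0, bleach_tau_s=np.inf,
        bleach_slope_per_s=0.0, deact_delay_median_s=60.0,
    )
    traces, _ = generate_islet(cfg, fast_protocol)
    ts = normalize_f0(traces)
    out, _ = correct_bleaching(ts)
    for j in range(out.n_cells):
        a_in = ts.F[:, j].max() - ts.F[:, j].min()
        a_out = out.F[:, j].max() - out.F[:, j].min()
        assert abs(a_out - a_in) / a_in < 0.02


# ------------------------------------------------------------- exclusion

def _trapezoid_train(t, period=30.0, plateau=10.0, ramp=3.0):
    """Smooth oscillation train: 3 s rise, 10 s plateau, 3 s fall."""
    ph = np.mod(t, period)
    up = np.clip(ph / ramp, 0, 1)
    down = np.clip((plateau + ramp - ph) / ramp, 0, 1)
    return np.minimum(up, down)


def _quiet_then_active(n_cells=4, seed=0):
    """Noisy beta-like cells: quiet in low glucose, oscillating in high."""
    rng = np.random.default_rng(seed)
    prot = _simple_protocol()
    n = int(prot.end * FS)
    t = np.arange(n) / FS
    F = 1.0 + 0.01 * rng.standard_normal((n, n_cells))
    # phase-aligned so the train starts and stops at zero (no step edges)
    window = (t >= 127.0) & (t < 590.0)
    F += 0.8 * (_trapezoid_train(t - 127.0) * window)[:, None]
    return _traceset(F, prot)


def test_beta_like_cells_are_kept():
    kept, excluded = exclude_artifacts(_quiet_then_active())
    assert kept.n_cells == 4
    assert excluded == []


def test_low_glucose_active_cell_is_excluded():
    ts = _quiet_then_active()
    t = ts.time
    ts.F[:, 1] += 0.8 * _trapezoid_train(t) * (t < 115.0)  # active early
    kept, excluded = exclude_artifacts(ts)
    assert ("cell001", "low-glucose-active") in excluded
    assert kept.n_cells == 3


def test_high_glucose_inactive_cell_is_excluded():
    ts = _quiet_then_active()
    rng = np.random.default_rng(1)
    ts.F[:, 2] = 1.0 + 0.01 * rng.standard_normal(ts.n_samples)  # never active
    _, excluded = exclude_artifacts(ts)
    assert ("cell002", "high-glucose-inactive") in excluded


def test_single_frame_jump_is_excluded_as_artifact():
    ts = _quiet_then_active()
    noise_sd = 0.01
    ts.F[2050, 3] += 10.0 * noise_sd  # 10-sd single-frame spike (t=205 s,
    # between oscillations)
    _, excluded = exclude_artifacts(ts)
    assert ("cell003", "artifact") in excluded


def test_all_cells_excluded_raises():
    rng = np.random.default_rng(0)
    F = 1.0 + 0.01 * rng.standard_normal((int(720 * FS), 3))  # nobody responds
    with pytest.raises(ValueError, match="empty islet"):
        exclude_artifacts(_traceset(F))


# ---------------------------------------------------------------- filter

def test_dc_input_is_removed():
    x = np.full((6000, 1), 5.0)
    y = bandpass_zero_lag(x, FS, 0.03, 1.5)
    assert np.abs(y.mean()) < 1e-3 * 5.0


def test_inband_sinusoid_preserved_with_zero_lag():
    t = np.arange(60000) / FS
    x = np.sin(2 * np.pi * 0.5 * t)[:, None]
    y = bandpass_zero_lag(x, FS, 0.03, 1.5)[:, 0]
    mid = slice(5000, 55000)
    amp = (y[mid].max() - y[mid].min()) / 2
    assert abs(amp - 1.0) < 0.05
    # zero phase: cross-correlation peaks at lag 0
    xc = signal.correlate(y[mid], x[mid, 0], mode="same")
    assert abs(int(np.argmax(xc)) - len(xc) // 2) == 0


def test_out_of_band_sinusoid_attenuated():
    t = np.arange(120000) / FS
    x = np.sin(2 * np.pi * 0.005 * t)[:, None]
    y = bandpass_zero_lag(x, FS, 0.03, 1.5)[:, 0]
    assert np.abs(y[20000:-20000]).max() < 0.10


@pytest.mark.parametrize("freq", [0.1, 0.3, 0.5, 1.0])
def test_zero_phase_holds_across_inband_grid(freq):
    t = np.arange(40000) / FS
    x = np.sin(2 * np.pi * freq * t)[:, None]
    y = bandpass_zero_lag(x, FS, 0.03, 1.5)[:, 0]
    mid = slice(5000, 35000)
    xc = signal.correlate(y[mid], x[mid, 0], mode="same")
    assert abs(int(np.argmax(xc)) - len(xc) // 2) <= 1


def test_nyquist_violation_rejected():
    with pytest.raises(ValueError):
        bandpass_zero_lag(np.zeros((100, 1)), fs=2.0, f_lo=0.03, f_hi=1.5)


def test_filter_is_idempotent_for_inband_signal():
    t = np.arange(60000) / FS
    x = np.sin(2 * np.pi * 0.3 * t)[:, None]
    once = bandpass_zero_lag(x, FS, 0.03, 1.5)
    twice = bandpass_zero_lag(once, FS, 0.03, 1.5)
    mid = slice(5000, 55000)
    rms = np.sqrt(np.mean((twice[mid] - once[mid]) ** 2))
    assert rms < 0.01 * np.sqrt(np.mean(once[mid] ** 2))


# ------------------------------------------------------------- assembled

def test_preprocess_chain_outputs_are_consistent(fast_islet):
    traces, _ = fast_islet
    clean = preprocess_traces(traces, band=(0.02, 1.5))
    assert clean.f_norm.shape == clean.f_filt.shape
    assert clean.n_cells + len(clean.excluded) == traces.n_cells
    # band-passed output is zero-mean per cell
    assert np.abs(clean.f_filt.mean(axis=0)).max() < 1e-2
    # kept F/F0 traces average ~1 over the baseline window
    w = clean.f_norm[: int(60 * clean.fs)].mean(axis=0)
    assert np.abs(w - 1.0).max() < 0.05
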