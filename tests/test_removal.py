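"""Two-stage rational-function artifact removal."""

import numpy as np
import pytest

import skincap as sc


def _trace_from(fn, rate=8192.0, dur_ms=300.0, pulse=0):
    t = (np.arange(int(dur_ms * rate / 1000.0)) - pulse) * 1000.0 / rate
    y = np.zeros_like(t)
    m = t > 0
    y[m] = fn(t[m])
    return t, y


@pytest.mark.parametrize(
    "rate, expected",
    [
        (1024.0, (8.0, 28.0)),
        (512.0, (8.0, 28.0)),
        (8192.0, (1.5, 25.0)),
        (16384.0, (1.5, 25.0)),
    ],
)
def test_default_fit_window_anchors(rate, expected):
    assert sc.default_fit_window(rate) == pytest.approx(expected)


def test_default_fit_window_interpolates_between_anchors():
    t0, t1 = sc.default_fit_window(4096.0)
    assert 1.5 < t0 < 8.0
    assert 25.0 < t1 < 28.0
    with pytest.raises(ValueError):
        sc.default_fit_window(0.0)


def _deflection_recording(deflections, rate=8192.0):
    n = int(0.1 * rate)
    data = np.zeros((len(deflections), n))
    peak = int(0.010 * rate)  # 10 ms after pulse at sample 0
    for i, d in enumerate(deflections):
        data[i, peak] = d
    return sc.Recording(data, rate, 0, [f"c{i}" for i in range(len(deflections))])


def test_select_subset_sorts_by_signed_extremum():
    rec = _deflection_recording([9, 7, 5, 1, -2, -6, -8, -10])
    subset = sc.select_subset(rec)
    assert subset == ["c0", "c1", "c2", "c7", "c6", "c5"]


def test_select_subset_fills_from_opposite_pool_with_warning():
    rec = _deflection_recording([9, 8, 7, 6, 5, 4, 3, 2])
    with pytest.warns(UserWarning, match="opposite-signed"):
        subset = sc.select_subset(rec)
    assert subset[:3] == ["c0", "c1", "c2"]
    assert len(subset) == 6 and len(set(subset)) == 6
    # the fill takes the least-extreme leftovers
    assert set(subset[3:]) == {"c5", "c6", "c7"}


def test_select_subset_tie_break_deterministic():
    rec = _deflection_recording([5, 5, 5, 5, -5, -5, -5, -5])
    assert sc.select_subset(rec) == sc.select_subset(rec)
    assert sc.select_subset(rec) == ["c0", "c1", "c2", "c4", "c5", "c6"]


def test_select_subset_needs_enough_channels():
    rec = _deflection_recording([1, -1])
    with pytest.raises(ValueError):
        sc.select_subset(rec)


@pytest.mark.parametrize(
    "fn",
    [
        lambda t: 1.0 / (t + 3.0) ** 2,
        lambda t: 5.0 / (t + 3.0) ** 2 - 2.0 / (t + 3.0) ** 3,
        lambda t: 0.3 / (t + 0.8) ** 2 + 4.0 / (t + 0.8) ** 3,
    ],
)
def test_fit_rational_exact_class_recovery(fn):
    """Any combination of 1/(t+sigma)^2 and 1/(t+sigma)^3 is inside the
    rational model class and is recovered to machine precision."""
    t, y = _trace_from(fn)
    art = sc.fit_rational(y, (1.5, 25.0), 8192.0)
    peak = np.max(np.abs(y))
    assert art.residual_rms < 1e-9 * peak
    assert min(art.beta0, art.beta1, art.beta2) >= 0


def test_fit_rational_time_shift_invariance():
    """Shifting the trace in time keeps it inside the model class: the
    shifted fit is as good as the original."""
    t, y = _trace_from(lambda t: 2.0 / (t + 4.0) ** 2)
    art0 = sc.fit_rational(y, (1.5, 25.0), 8192.0)
    t2, y2 = _trace_from(lambda t: 2.0 / (t + 4.0 + 2.5) ** 2)  # shift b = 2.5 ms
    art1 = sc.fit_rational(y2, (1.5, 25.0), 8192.0)
    assert art1.residual_rms < 1e-9 * np.max(np.abs(y2))
    assert art0.residual_rms == pytest.approx(art1.residual_rms, abs=1e-12)


def test_fit_rational_recovers_model_artifact_in_noise(head_params):
    """Fitting a model-generated referenced artifact plus white noise leaves
    a residual within 2x the noise SD."""
    rate = 8192.0
    rng = np.random.default_rng(11)
    p = sc.LayerParams.from_constants(1.0, 1e4)
    t, clean = _trace_from(
        lambda tt: 50.0
        * sc.referenced_difference(
            tt, sc.ElectrodeModel(sigma=2.0), sc.ElectrodeModel(sigma=3.0), p
        ),
        rate=rate,
    )
    y = clean + rng.normal(0, 1.0, clean.size)
    art = sc.fit_rational(y, (1.5, 25.0), rate)
    assert art.residual_rms < 2.0


def test_fit_rational_window_too_short():
    t, y = _trace_from(lambda t: 1.0 / (t + 3.0) ** 2, rate=1024.0)
    with pytest.raises(ValueError):
        sc.fit_rational(y, (8.0, 8.5), 1024.0)


def _basis_pair():
    a = sc.RationalArtifact(1.0, 0.5, 8.0, 6.0, 3.0, window=(1.5, 25.0))
    b = sc.RationalArtifact(0.2, 2.0, 60.0, 20.0, 9.0, window=(1.5, 25.0))
    return [a, b]


def test_project_exact_span_membership():
    basis = _basis_pair()
    rate = 8192.0
    n = int(0.05 * rate)
    t = np.arange(n) * 1000.0 / rate
    data = np.zeros((1, n))
    m = t >= 1.0
    data[0, m] = 0.4 * basis[0](t[m]) - 0.2 * basis[1](t[m])
    rec = sc.Recording(data, rate, 0, ["a"])
    proj = sc.project_electrodes(rec, basis, (1.5, 25.0))
    assert proj.coefficients[0] == pytest.approx([0.4, -0.2], abs=1e-10)


def test_project_orthogonal_background_near_zero():
    """A trace orthogonalized against the basis projects to ~zero with the
    residual carrying the full input RMS."""
    basis = _basis_pair()
    rate = 8192.0
    n = int(0.05 * rate)
    t = np.arange(n) * 1000.0 / rate
    rng = np.random.default_rng(5)
    noise = rng.normal(0, 10.0, n)
    m = (t >= 1.5) & (t <= 25.0)
    B = np.column_stack([f(t[m]) for f in basis])
    coef, *_ = np.linalg.lstsq(B, noise[m], rcond=None)
    noise[m] -= B @ coef
    rec = sc.Recording(noise[None, :], rate, 0, ["a"])
    proj = sc.project_electrodes(rec, basis, (1.5, 25.0))
    in_rms = float(np.sqrt(np.mean(noise[m] ** 2)))
    assert np.all(np.abs(proj.coefficients) < 1e-8)
    assert proj.residual_rms[0] == pytest.approx(in_rms, rel=1e-6)


def test_project_rank_deficient_warns():
    a = _basis_pair()[0]
    twin = sc.RationalArtifact(2 * a.alpha0, 2 * a.alpha1, a.beta0, a.beta1, a.beta2, a.window)
    rate = 8192.0
    n = int(0.05 * rate)
    rec = sc.Recording(np.ones((1, n)), rate, 0, ["a"])
    with pytest.warns(UserWarning, match="rank deficient"):
        sc.project_electrodes(rec, [a, twin], (1.5, 25.0))


def test_subtract_zero_coefficient_channel_unchanged(referenced_scene):
    _, _, pre, _ = referenced_scene
    basis = _basis_pair()
    proj = sc.ProjectionResult(
        coefficients=np.zeros((pre.n_channels, 2)),
        residual_rms=np.zeros(pre.n_channels),
        basis=basis,
        window=(1.5, 25.0),
    )
    out = sc.subtract_artifacts(pre, proj)
    np.testing.assert_array_equal(out.data, pre.data)
    assert out.metadata["unreconstructable_ms"] == [0.0, 1.5]


def test_removal_preserves_line_noise(head_params):
    """A 50 Hz sine riding on the artifacts survives removal with < 5%
    amplitude error (the subtraction reconstructs the line signal)."""
    cfg = sc.SceneConfig(
        seed=3, reference="reference-electrode", background_sd=0.0,
        blip_amplitude=0.0, drift_slope=0.0, line_amplitude=15.0,
    )
    rec, comp = sc.generate_recording(cfg)
    cleaned, _ = sc.remove_artifacts(rec)
    t = rec.times_ms
    m = (t >= 30) & (t <= 2000)
    w = 2 * np.pi * 50 / 1000.0
    B = np.column_stack([np.sin(w * t[m]), np.cos(w * t[m])])
    for ch in range(0, rec.n_channels, 4):
        a_true = np.hypot(*np.linalg.lstsq(B, comp["line"][ch, m], rcond=None)[0])
        a_got = np.hypot(*np.linalg.lstsq(B, cleaned.data[ch, m], rcond=None)[0])
        assert a_got == pytest.approx(a_true, rel=0.05)


def test_end_to_end_removal_residual(referenced_scene):
    """After 50 Hz subtraction and removal, the residual against the
    known non-discharge ground truth stays within 2x the background SD on
    at least 90% of channels over [window start, 150 ms]."""
    cfg, rec, pre, comp = referenced_scene
    cleaned, report = sc.remove_artifacts(pre)
    t = rec.times_ms
    truth = pre.data - comp["discharge"]
    m = (t >= report["window_ms"][0]) & (t <= 150.0)
    rms = np.sqrt(np.mean((cleaned.data[:, m] - truth[:, m]) ** 2, axis=1))
    assert np.mean(rms <= 2.0 * cfg.background_sd) >= 0.9


def test_removal_idempotent_in_noiseless_limit():
    """Once the discharge is removed there is nothing left to fit: a second
    pass changes the channels by less than 5% of the default background SD."""
    cfg = sc.SceneConfig(
        seed=5, reference="reference-electrode", background_sd=0.0,
        blip_amplitude=0.0, drift_slope=0.0, line_amplitude=0.0,
    )
    rec, _ = sc.generate_recording(cfg)
    c1, _ = sc.remove_artifacts(rec)
    c2, _ = sc.remove_artifacts(c1)
    t = rec.times_ms
    m = (t >= 1.5) & (t <= 150.0)
    assert np.max(np.abs(c2.data[:, m] - c1.data[:, m])) < 0.05 * 10.0


def test_interpolate_gap_linear_and_constant():
    rate = 8192.0
    n = int(0.05 * rate)
    t = (np.arange(n) - 100) * 1000.0 / rate
    ramp = 3.0 + 0.5 * t
    rec = sc.Recording(np.vstack([ramp, np.full(n, 7.0)]), rate, 100, ["r", "c"])
    out = sc.interpolate_gap(rec, gap=(0.0, 1.5))
    np.testing.assert_allclose(out.data[0], ramp, atol=1e-9)
    np.testing.assert_allclose(out.data[1], 7.0, atol=1e-9)


def test_interpolate_gap_sine_accuracy():
    """A 10 Hz sine bridged over a 3 ms gap at 8192 Hz is reproduced to
    < 1% of its amplitude."""
    rate = 8192.0
    n = int(0.2 * rate)
    t = (np.arange(n) - 500) * 1000.0 / rate
    y = 50.0 * np.sin(2 * np.pi * 10.0 * t / 1000.0)
    rec = sc.Recording(y[None, :], rate, 500, ["s"])
    out = sc.interpolate_gap(rec, gap=(0.0, 3.0))
    assert np.max(np.abs(out.data[0] - y)) < 0.01 * 50.0


def test_interpolate_gap_edge_error():
    rate = 1024.0
    rec = sc.Recording(np.zeros((1, 50)), rate, 1, ["a"])
    with pytest.raises(ValueError):
        sc.interpolate_gap(rec, gap=(-2.0, 5.0))


def test_muscle_guard_shifts_window():
    """With the guard on, the fit window starts after the last +-500 uV
    muscle excursion."""
    cfg = sc.SceneConfig(
        seed=9, reference="reference-electrode", muscle_amplitude=2000.0,
        muscle_onset_ms=2.0, muscle_duration_ms=8.0,
    )
    rec, _ = sc.generate_recording(cfg)
    _, report = sc.remove_artifacts(rec, sc.RemovalConfig(muscle_guard=True))
    assert report["window_ms"][0] > 1.5
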