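"""Preprocessing primitives: offset correction, re-referencing, line-noise
subtraction, and post-removal band-pass/notch filtering."""

from __future__ import annotations

import numpy as np
from scipy import signal

from .recording import Recording

__all__ = ["offset_correct", "apply_reference", "subtract_line_noise", "bandpass_notch"]


def offset_correct(rec: Recording, span_ms: float = 1000.0) -> Recording:
    """Subtract each channel's time average over the ``span_ms`` immediately
    preceding the pulse (clipped to the available pre-pulse samples)."""
    n_span = min(int(round(span_ms * rec.rate / 1000.0)), rec.pulse_onset)
    if n_span < 1:
        raise ValueError("offset span contains no samples before the pulse")
    means = rec.data[:, rec.pulse_onset - n_span : rec.pulse_onset].mean(axis=1)
    out = rec.copy(data=rec.data - means[:, None])
    out.log("offset_correct", span_ms=span_ms)
    return out


def apply_reference(rec: Recording, mode="remote") -> Recording:
    """Re-reference a recording.

    ``mode`` is ``"remote"`` (identity: the reference is an unaffected,
    zero-potential site), ``"common-average"`` (subtract the per-sample mean
    of all channels), or ``("head", label)`` (subtract the designated
    channel's trace, as a scalp reference electrode does).
    """
    if mode == "remote":
        out = rec.copy()
    elif mode == "common-average":
        out = rec.copy(data=rec.data - rec.data.mean(axis=0, keepdims=True))
    elif isinstance(mode, (tuple, list)) and len(mode) == 2 and mode[0] == "head":
        ref = rec.channel(mode[1])  # KeyError if unknown
        out = rec.copy(data=rec.data - ref[None, :])
    else:
        raise ValueError(f"unknown reference mode {mode!r}")
    out.metadata["reference"] = list(mode) if isinstance(mode, tuple) else mode
    out.log("apply_reference", mode=str(mode))
    return out


def subtract_line_noise(rec: Recording, freq: float = 50.0) -> Recording:
    """Fit a sine at ``freq`` (least-squares amplitude and phase) to each
    channel's pre-pulse baseline and subtract it from the whole trace.

    The pre-pulse fit keeps post-pulse artifacts from biasing the line-noise
    estimate; the fitted sinusoid is extrapolated coherently over the full
    recording.
    """
    t_abs = np.arange(rec.n_samples) / rec.rate  # seconds
    n_pre = rec.pulse_onset
    if n_pre < rec.rate / freq:
        raise ValueError("pre-pulse baseline shorter than one line-noise period")
    w = 2.0 * np.pi * freq
    basis = np.column_stack([np.sin(w * t_abs), np.cos(w * t_abs)])
    coef, *_ = np.linalg.lstsq(basis[:n_pre], rec.data[:, :n_pre].T, rcond=None)
    out = rec.copy(data=rec.data - (basis @ coef).T)
    out.log("subtract_line_noise", freq=freq)
    return out


def bandpass_notch(
    rec: Recording,
    hp: float = 1.0,
    lp: float = 300.0,
    notch: float | None = 50.0,
    order: int = 4,
) -> Recording:
    """Zero-phase band-pass (Butterworth, forward-backward) plus optional
    notch.  Intended for use *after* artifact removal: filtering first would
    smear the discharge artifact across the trace."""
    nyq = rec.rate / 2.0
    if lp >= nyq or (notch is not None and notch >= nyq):
        raise ValueError("cutoff frequency at or above Nyquist")
    if not 0 < hp < lp:
        raise ValueError("need 0 < hp < lp")
    # cascaded high-pass + low-pass: numerically robust for very wide bands;
    # padding scaled to the high-pass time constant so the forward-backward
    # edge transient settles inside the padding, not inside the data
    sos_hp = signal.butter(order, hp, btype="highpass", fs=rec.rate, output="sos")
    sos_lp = signal.butter(order, lp, btype="lowpass", fs=rec.rate, output="sos")
    padlen = min(rec.n_samples - 1, int(3 * rec.rate / hp))
    data = signal.sosfiltfilt(sos_hp, rec.data, axis=1, padlen=padlen)
    data = signal.sosfiltfilt(sos_lp, data, axis=1)
    if notch is not None:
        b, a = signal.iirnotch(notch, Q=30.0, fs=rec.rate)
        data = signal.filtfilt(b, a, data, axis=1, padlen=padlen)
    out = rec.copy(data=data)
    out.log("bandpass_notch", hp=hp, lp=lp, notch=notch, order=order)
    return out
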