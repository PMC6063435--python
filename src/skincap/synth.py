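"""Synthetic multichannel TMS-EEG generator.

Composes, channel by channel, the signal classes a post-pulse recording
contains: the model's discharge artifacts (evaluated from the closed-form
Green's function per electrode), 1/f background EEG, 50 Hz line pickup,
stimulator recharge blips (two wavelets exactly 20 ms apart), biphasic
cranial-muscle waveforms, slow electrode drifts, and a clipped biphasic
pulse-artifact template during the pulse itself.  Ground-truth components
are returned separately so every processing stage can be scored against
what it should recover.

The default scene: 13 point electrodes (spreads sigma equally spaced in
0.1-0.7 ms, as on a head where the initial charge profile varies smoothly
across the cap), a shared initial-voltage amplitude, lambda = 1, tau =
1000 ms, 8192 Hz, 500 ms pre-pulse baseline and 2 s post-pulse.  Muscle
activation is off by default (amplitude 0); when enabled it follows the
reported ranges (7-13 ms duration, 1.2-4 mV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import ElectrodeModel, LayerParams, electrode_voltage
from .preprocess import apply_reference
from .recording import Recording

__all__ = ["SceneConfig", "generate_recording", "apply_reference", "skin_preparation_scale"]

_COMPONENTS = ("background", "line", "blips", "muscle", "drift", "pulse")


def default_electrodes(n: int = 13, amplitude: float = 200.0) -> list[ElectrodeModel]:
    sigmas = np.linspace(0.1, 0.7, n)
    return [ElectrodeModel(sigma=float(s), amplitude=amplitude) for s in sigmas]


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.  All voltages in uV, times in ms."""

    n_channels: int = 13
    sampling_rate: float = 8192.0
    duration_ms: float = 2500.0
    pulse_onset_ms: float = 500.0
    layer: LayerParams = field(default_factory=LayerParams.from_constants)
    electrodes: list[ElectrodeModel] | None = None
    reference: object = "remote"  # "remote" | "common-average" | ("head", label)
    reference_electrode: ElectrodeModel | None = field(
        default_factory=lambda: ElectrodeModel(sigma=0.5, amplitude=200.0)
    )
    background_sd: float = 10.0
    background_band: tuple[float, float] = (0.5, 100.0)
    line_amplitude: float = 10.0
    line_freq: float = 50.0
    blip_amplitude: float = 30.0
    blip_first_ms: tuple[float, float] = (10.0, 20.0)  # uniform window for the first blip
    blip_spacing_ms: float = 20.0  # the stimulator recharge spacing is exact
    muscle_amplitude: float = 0.0  # enable with 1200-4000 uV
    muscle_duration_ms: float = 10.0  # biphasic span, reported range 7-13 ms
    muscle_onset_ms: float = 2.0
    muscle_channels: tuple[int, ...] = ()
    drift_slope: float = 5.0  # per-channel slope scale, uV/s
    pulse_amplitude: float = 200000.0
    pulse_duration_ms: float = 0.33
    pulse_clip: float = 262000.0  # amplifier input range, uV
    seed: int = 0

    def electrode_list(self) -> list[ElectrodeModel]:
        if self.electrodes is not None:
            if len(self.electrodes) != self.n_channels:
                raise ValueError("number of electrodes must equal n_channels")
            return list(self.electrodes)
        return default_electrodes(self.n_channels)


def _rng_streams(seed: int) -> dict[str, np.random.Generator]:
    """One independent, reproducible stream per component.

    Streams are keyed by component name (not spawn order), so toggling one
    component off leaves every other component's samples unchanged.
    """
    return {
        name: np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))
        for k, name in enumerate(_COMPONENTS)
    }


def _background(rng, n_ch, n_s, rate, sd, band) -> np.ndarray:
    """1/f-shaped Gaussian noise band-limited to ``band``, per-channel SD ``sd``."""
    white = rng.standard_normal((n_ch, n_s))
    freqs = np.fft.rfftfreq(n_s, d=1.0 / rate)
    shape = np.zeros_like(freqs)
    m = (freqs >= band[0]) & (freqs <= band[1])
    shape[m] = 1.0 / np.sqrt(freqs[m])
    spec = np.fft.rfft(white, axis=1) * shape[None, :]
    x = np.fft.irfft(spec, n=n_s, axis=1)
    x_sd = x.std(axis=1, keepdims=True)
    x_sd[x_sd == 0] = 1.0
    return sd * x / x_sd


def _biphasic(t_ms: np.ndarray, onset: float, width: float) -> np.ndarray:
    """Raised-cosine biphasic wavelet of total span ``width`` ms starting at
    ``onset``: one positive and one negative half-sine lobe."""
    u = (t_ms - onset) / width
    out = np.zeros_like(t_ms)
    m = (u >= 0) & (u < 1)
    out[m] = np.sin(2.0 * np.pi * u[m]) * np.sin(np.pi * u[m])
    return out


def generate_recording(cfg: SceneConfig) -> tuple[Recording, dict[str, np.ndarray]]:
    """Generate a synthetic recording plus its ground-truth components.

    Returns ``(recording, components)`` where ``components`` maps each
    component name (``discharge``, ``background``, ``line``, ``blips``,
    ``muscle``, ``drift``, ``pulse``) to a channels x samples array and the
    recording data is exactly their sum.  A fixed seed gives bit-identical
    output.
    """
    electrodes = cfg.electrode_list()
    n_s = int(round(cfg.duration_ms * cfg.sampling_rate / 1000.0))
    pulse_idx = int(round(cfg.pulse_onset_ms * cfg.sampling_rate / 1000.0))
    n_ch = cfg.n_channels
    labels = [f"ch{i:02d}" for i in range(n_ch)]
    rng = _rng_streams(cfg.seed)
    t = (np.arange(n_s) - pulse_idx) * 1000.0 / cfg.sampling_rate

    comp: dict[str, np.ndarray] = {}

    # --- discharge artifacts from the physical model -----------------------
    discharge = np.zeros((n_ch, n_s))
    post = t > 0
    for i, e in enumerate(electrodes):
        if e.amplitude != 0:
            discharge[i, post] = electrode_voltage(t[post], e, cfg.layer)
    if cfg.reference == "common-average":
        discharge -= discharge.mean(axis=0, keepdims=True)
    elif cfg.reference == "reference-electrode":
        if cfg.reference_electrode is None:
            raise ValueError("reference-electrode mode needs reference_electrode")
        if cfg.reference_electrode.amplitude != 0:
            ref = np.zeros(n_s)
            ref[post] = electrode_voltage(t[post], cfg.reference_electrode, cfg.layer)
            discharge -= ref[None, :]
    elif cfg.reference != "remote":
        raise ValueError(f"unknown reference mode {cfg.reference!r}")
    comp["discharge"] = discharge

    # --- background EEG ----------------------------------------------------
    if cfg.background_sd > 0:
        comp["background"] = _background(
            rng["background"], n_ch, n_s, cfg.sampling_rate, cfg.background_sd, cfg.background_band
        )
    else:
        comp["background"] = np.zeros((n_ch, n_s))

    # --- 50 Hz line pickup, common phase, per-channel amplitude jitter -----
    line = np.zeros((n_ch, n_s))
    if cfg.line_amplitude > 0:
        phase = rng["line"].uniform(0, 2 * np.pi)
        amps = cfg.line_amplitude * (0.5 + rng["line"].random(n_ch))
        line = amps[:, None] * np.sin(2 * np.pi * cfg.line_freq * t[None, :] / 1000.0 + phase)
    comp["line"] = line

    # --- stimulator recharge blips: two wavelets exactly 20 ms apart -------
    blips = np.zeros((n_ch, n_s))
    if cfg.blip_amplitude > 0:
        first = rng["blips"].uniform(*cfg.blip_first_ms)
        for onset in (first, first + cfg.blip_spacing_ms):
            blips += cfg.blip_amplitude * _biphasic(t, onset, 2.0)[None, :]
    comp["blips"] = blips

    # --- cranial muscle activation (biphasic + exponential return tail) ----
    muscle = np.zeros((n_ch, n_s))
    if cfg.muscle_amplitude > 0:
        channels = cfg.muscle_channels or tuple(range(min(3, n_ch)))
        for ch in channels:
            a = cfg.muscle_amplitude * (0.6 + 0.4 * rng["muscle"].random())
            w = _biphasic(t, cfg.muscle_onset_ms, cfg.muscle_duration_ms)
            tail_start = cfg.muscle_onset_ms + cfg.muscle_duration_ms
            tail = np.where(
                t >= tail_start, 0.1 * np.exp(-(t - tail_start) / 10.0), 0.0
            )
            muscle[ch] += a * (w + tail)
    comp["muscle"] = muscle

    # --- slow per-channel drifts ------------------------------------------
    drift = np.zeros((n_ch, n_s))
    if cfg.drift_slope != 0:
        slopes = cfg.drift_slope * rng["drift"].standard_normal(n_ch)
        drift = slopes[:, None] * (t[None, :] / 1000.0)
    comp["drift"] = drift

    # --- pulse artifact: clipped biphasic template during the pulse --------
    pulse = np.zeros((n_ch, n_s))
    if cfg.pulse_amplitude > 0:
        gains = 0.5 + rng["pulse"].random(n_ch)
        template = cfg.pulse_amplitude * _biphasic(t, 0.0, cfg.pulse_duration_ms)
        pulse = np.clip(gains[:, None] * template[None, :], -cfg.pulse_clip, cfg.pulse_clip)
    comp["pulse"] = pulse

    data = sum(comp.values())
    rec = Recording(
        data=data,
        rate=cfg.sampling_rate,
        pulse_onset=pulse_idx,
        labels=labels,
        metadata={"scene_seed": cfg.seed, "reference": str(cfg.reference)},
    )
    return rec, comp


def skin_preparation_scale(cfg: SceneConfig, mode: str = "none") -> SceneConfig:
    """Scene after skin preparation.

    Puncturing (factor 0.1) and exfoliation (factor 0.4) reduce the charge
    the skin capacitor accumulates, scaling the discharge amplitudes down
    while leaving the pulse-artifact template and the power-law form of the
    decay unchanged.
    """
    factors = {"none": 1.0, "exfoliation": 0.4, "puncture": 0.1}
    if mode not in factors:
        raise ValueError(f"unknown skin preparation mode {mode!r}")
    f = factors[mode]
    if f == 1.0:
        return cfg
    electrodes = [replace(e, amplitude=e.amplitude * f) for e in cfg.electrode_list()]
    ref = cfg.reference_electrode
    if ref is not None:
        ref = replace(ref, amplitude=ref.amplitude * f)
    return replace(cfg, electrodes=electrodes, reference_electrode=ref)
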