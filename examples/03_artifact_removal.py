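"""End-to-end discharge-artifact removal on a synthetic recording.

Generates a 13-channel TMS-EEG scene (discharge artifacts, 1/f background,
50 Hz line noise, recharge blips, drifts, pulse template), subtracts the
line noise, runs the two-stage removal, and scores the residual against the
known ground truth.
"""

import numpy as np

import skincap as sc

cfg = sc.SceneConfig(seed=42, reference="reference-electrode")
rec, components = sc.generate_recording(cfg)
print(f"scene: {rec.n_channels} channels, {rec.n_samples} samples at {rec.rate:.0f} Hz")
peak = np.max(np.abs(components["discharge"]))
print(f"peak discharge artifact {peak/1000:.1f} mV, background SD {cfg.background_sd:.0f} uV")

pre = sc.subtract_line_noise(rec)
cleaned, report = sc.remove_artifacts(pre)
print(f"fit window {report['window_ms']} ms, basis electrodes {report['subset']}")

t = rec.times_ms
truth = pre.data - components["discharge"]  # everything except the artifact
m = (t >= report["window_ms"][0]) & (t <= 150.0)
rms = np.sqrt(np.mean((cleaned.data[:, m] - truth[:, m]) ** 2, axis=1))
print(f"residual RMS per channel (uV): {np.round(rms, 1)}")
print(f"channels within 2x background SD: {np.sum(rms <= 2*cfg.background_sd)}/{rec.n_channels}")
print()
print("Residuals at the background-noise level mean the reconstructed rational")
print("artifacts captured the discharge while leaving the physiological-like")
print("signal (and the 50 Hz and blip components) untouched.")
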