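# Methods

## The physical model

The electrode-gel-skin interface is treated as two laterally extended
resistive sheets — the conductive gel on top, the aqueous deep skin below —
separated by the stratum corneum, which acts as a leaky dielectric. On a
regular grid of edge resistors with per-node leaky capacitors, Kirchhoff and
Ohm relations homogenize (edge length → 0) to the coupled system for the
layer voltages `v_T`, `v_B`; their difference `v = v_T − v_B` obeys the
two-dimensional cable equation `τ ∂t v = λ²Δv − v` with
`λ² = r_m/(r_T + r_B)` and `τ = r_m c_m`. A localized initial voltage
splits between the layers in proportion to the sheet resistivities
(`v_T = r_T/(r_T+r_B)·v0·g`, `v_B = −r_B/(r_T+r_B)·v0·g`), so both surface
voltages inherit the dynamics of the impulse response

    g(t, x) = τ/(4πλ²t) · exp(−|x|²τ/(4λ²t) − t/τ).

Assumptions: both sheets are uniform and infinite (no per-node parameter
maps, no boundaries), the third dimension enters only through the local
leaky capacitor, and the initial charge profile under each electrode is a
Gaussian of spread `σ` (time units; spatial variance `λ²σ/τ`), optionally
displaced by `μ` and averaged over a disk electrode of radius `b`.
Volume conduction beneath the skin and the physics that set the exact
initial charge distribution (coil geometry, wire induction) are outside the
model; electrodes are parameterized directly by `(σ, μ, b, amplitude)`.

## Units and default parameters

| Parameter | Default | Meaning |
|---|---|---|
| time | ms, `t = 0` at pulse onset | all fit windows are quoted this way |
| space | units of `λ` | `λ = 1` unless circuit constants given |
| `τ` | 1000 ms | sets the power-law/exponential crossover; head-scale |
| `σ` per electrode | 0.1–0.7 ms | initial Gaussian spread; varies across the cap |
| `σ_R` (reference) | 0.5 ms, `μ_R = 0` | reference-electrode initial condition |
| `b` | 0 | disk radius; 0 = point electrode (results change little with `b`) |
| amplitude | 200 | common initial-voltage scale; gives few-mV referenced artifacts, matching real head recordings and making the 1.5 mV decay-comparison cutoff meaningful |
| pulse exclusion | 0.33 ms | measured pulse duration; excluded from every fit |

All electrodes share the amplitude by default because the differentiator
argument subtracts equal-mass Gaussians; unequal masses would reintroduce an
order-1 term into referenced differences that the model does not describe.

## Numerical choices

- **Disk averaging** reduces to a 1-D radial integral via the modified
  Bessel function (`i0e` for stability), integrated adaptively to relative
  tolerance 1e−10; `b = 0` short-circuits to point evaluation. A 2-D
  adaptive quadrature serves as the oracle in tests (agreement ~1e−16).
- **Field evolution** (`simulate_field`) uses FFT convolution on a periodic
  square domain with default half-width `max(10λ√(t_max/τ), 3λ)`, chosen so
  boundary wrap-around is below 1e−8 of the peak.
- **Leading-order expansion**: the first-order terms in `σ₂−σ₁` (time) and
  `μ₂−μ₁` (space) are evaluated on the pure heat kernel, i.e. without the
  `e^{−t/τ}` bookkeeping factor; they are therefore meaningful in the
  intermediate regime `t ≪ τ` where that factor is ≈ 1. The expansion is
  first-order accurate only when both differences are small — in particular,
  when `μ₂ = 0` and `μ₁` is itself the expansion increment, the "first
  order" space term is quadratic in the increment and no longer dominates
  its remainder.
- **Grid oracle**: with both layers grounded at the boundary, the layer
  constraint forces `V_T`, `V_B` to be exactly proportional to the
  cross-layer difference, so the double-grid system reduces *exactly* to one
  linear ODE for the difference, integrated by Crank–Nicolson with a sparse
  LU factorization (the network is stiff for small edge lengths). The
  grounded boundary sits ≥ 10λ from the source so the power-law window is
  not corrupted. A point charge on one node carries mass `v0·ε²`, and the
  lattice resolves the continuum kernel only beyond a few multiples of its
  own diffusion time `ε²τ/λ²`; comparisons against `g` start there.
- **Rational fitting** profiles the numerator out (it enters linearly) and
  solves the bounded 3-parameter denominator problem with a trust-region
  least-squares method, multi-started from `β = (σ³, 3σ², 3σ)` for
  `σ ∈ {0.5, 1, 2, 5, 10, 20}` ms — each start is an exactly representable
  `(t+σ)³` denominator. Any trace in the span of `1/(t+σ)²`, `1/(t+σ)³` is
  recovered to machine precision, and the class is invariant under time
  shifts.
- **Projection** is ordinary least squares over the fit window only (later
  physiology must not bias the coefficients), computed by a
  column-normalized truncated SVD (relative cutoff 1e−6): basis directions
  indistinguishable within the window are dropped instead of producing huge
  cancelling coefficients that extrapolate wildly outside it; an exactly
  collinear basis degrades to the minimum-norm solution with a warning.
- **Subset selection** measures deflection as the signed extremum of the raw
  trace between one sample after the pulse exclusion and the window end,
  with ties broken by channel order; if one sign is underpopulated the
  subset is filled from the opposite pool with a warning.
- **Fit windows** default to (8, 28) ms at rates ≤ 1024 Hz and (1.5, 25) ms
  at rates ≥ 8192 Hz, with both endpoints log-linearly interpolated in rate
  between the anchors. The earliest usable start can instead be derived
  from the data as the order-1 tangency point `t0` (the time from which all
  artifacts decay faster than `1/t`); both options are exposed.
- **Gap interpolation** uses natural cubic splines anchored on 10 samples on
  each side of the unreconstructable span.
- **Chi-square horizons** use one degree of freedom per residual sample (no
  reduction for the 5 fitted parameters): the test asks whether the fit *is*
  the truth, not whether a nested model improves it; this leans
  conservative.
- **Instantaneous log-log slopes** (for tangency detection) use centered
  differences on a log-resampled grid with a 5-point Savitzky–Golay smooth.
- **Cross-rate alignment** shifts on the 1000/16384 ms grid and evaluates
  the summed absolute difference at the coarse recording's own sample times
  against the densely interpolated reference, from 1.33 ms after the pulse
  to 50 ms; sampling the dense side makes integer-step shifts exactly
  recoverable regardless of trace curvature.
- **Filtering** (post-removal only) is zero-phase: cascaded Butterworth
  high-pass and low-pass plus an IIR notch, with the forward-backward
  padding scaled to the high-pass time constant so edge transients settle
  outside the data.

## The synthetic generator

`skincap.synth` emulates the statistical structure the method assumes:
model-generated discharge artifacts under a chosen reference scheme
(remote, common-average, or a physical reference electrode), 1/f-shaped
Gaussian background band-limited to 0.5–100 Hz (SD 10 μV), 50 Hz line
pickup with common phase, two stimulator recharge blips exactly 20 ms apart
(first one uniform in 10–20 ms post-pulse, ≤ 50 μV), biphasic cranial-muscle
waveforms (7–13 ms, 1.2–4 mV when enabled; disabled by default since the
reference validation scenario contains no muscle activation and such
amplitudes require manual window adaptation), per-channel linear drifts,
and a clipped biphasic pulse template over the 0.33 ms pulse. Components
are seeded through independent per-component streams, so toggling one
component leaves the others bit-identical, and the recording is exactly the
sum of the returned ground-truth components.

What it does **not** emulate: physiological TEPs, auditory/somatosensory
responses, amplifier electronics (bandwidth, slew rate, sample-and-hold),
nonstationary noise, or electrode-specific impedance spectra. Passing
end-to-end tests therefore show that the removal recovers everything except
the discharge component *under the model's own assumptions plus generic
noise* — they do not certify performance on real data, where the initial
charge profile need not be Gaussian and early non-Gaussian transients can
push the usable fit start later.

## Degenerate inputs and edge cases

Evaluation requires `t + σ > 0`; the singular instant `t = σ = 0` with a
point electrode is excluded. Traces that change sign inside a log-log
window have no slope and raise. Channels that never exceed the 1.5 mV
cutoff are excluded (reported, not fatal) from the decay comparison. A
two-exponential fit of an effectively single-exponential trace is flagged
degenerate and its time-constant ratio reported as 1.

## Known limitations

- The removal idempotence that holds exactly in the noiseless limit is
  fundamentally bounded in noise: re-running removal on cleaned data
  re-projects the background onto the basis and must change channels by
  about `σ·√(k/n)` (k basis functions, n window samples) — ~1.8 μV under
  the default scene. This is a property of least squares, not of the model.
- The grid oracle's point initial condition converges at first order or
  better, but its early-time values are lattice-limited; quantitative
  agreement with the continuum starts a few lattice diffusion times in.
- Recharge blips falling inside the fit window perturb the rational fits;
  the 50 Hz line component must be subtracted (pre-pulse sine fit) before
  removal, as done in the pipeline, or it biases the fitted tails.
- Electrode disk averaging assumes a filled disk; ring electrodes are only
  handled through the tangency-based window start, not through their true
  aperture function.
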