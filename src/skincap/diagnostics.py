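"""Evaluation statistics for discharge-artifact fits and decay tails.

Covers the chi-square fit-acceptance horizon, log-log slope estimation,
shifted-power-law versus exponential model comparison, the two-exponential
control fit, cross-sampling-rate alignment, the order-1 tangency start
point, trial envelopes, and drift-based trial exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

__all__ = [
    "ChiSquareReport",
    "DecayComparison",
    "AlignmentResult",
    "chi_square_acceptance",
    "loglog_slope",
    "compare_power_vs_exp",
    "fit_two_exponentials",
    "align_sampling_rates",
    "find_t0_order1_tangent",
    "trial_envelope",
    "drift_exclude",
]

REF_RATE = 16384.0  # the finest acquisition rate used; alignment grid = 1000/REF_RATE ms


@dataclass
class ChiSquareReport:
    """Per-channel longest fit-acceptance horizon.

    ``t2_max[i]`` is the largest tested end time for which the null
    hypothesis "the fit is correct on [t1, t2]" is accepted at level
    ``alpha``; ``nan`` if rejected at every horizon.
    """

    sigma: np.ndarray
    alpha: float
    t1: float
    t2_grid: np.ndarray
    accepted: np.ndarray  # (n_channels, n_horizons) boolean
    t2_max: np.ndarray  # (n_channels,), nan where rejected everywhere


def chi_square_acceptance(
    t: np.ndarray,
    residuals: np.ndarray,
    sigma,
    alpha: float = 0.05,
    t1: float = 1.65,
    t2_grid=None,
) -> ChiSquareReport:
    """Chi-square acceptance horizons of fit residuals.

    Under a correct fit the residuals are the channel's background noise, so
    the sum of squared residuals over ``[t1, t2]`` normalized by the
    pre-pulse noise variance ``sigma_i^2`` follows a chi-square distribution
    with one degree of freedom per sample.  For each ``t2`` on the grid the
    fit is accepted iff the statistic is at most the ``1 - alpha`` quantile.

    Parameters
    ----------
    t : array, ms
        Time axis of ``residuals`` (post-pulse).
    residuals : (n_channels, n_samples) array
    sigma : per-channel noise SD estimated from the 100 ms pre-pulse window.
    """
    residuals = np.atleast_2d(np.asarray(residuals, dtype=float))
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (residuals.shape[0],))
    if np.any(sigma <= 0):
        raise ValueError("degenerate noise estimate: sigma must be positive")
    t = np.asarray(t, dtype=float)
    if t2_grid is None:
        t2_grid = np.arange(2.0, min(100.0, t[-1]) + 1e-9, 1.0)
    t2_grid = np.asarray(t2_grid, dtype=float)

    base = t >= t1
    sq = residuals[:, base] ** 2 / sigma[:, None] ** 2
    csum = np.cumsum(sq, axis=1)
    tb = t[base]
    accepted = np.zeros((residuals.shape[0], t2_grid.size), dtype=bool)
    for j, t2 in enumerate(t2_grid):
        n = int(np.searchsorted(tb, t2, side="right"))
        if n == 0:
            accepted[:, j] = True
            continue
        crit = stats.chi2.ppf(1.0 - alpha, df=n)
        accepted[:, j] = csum[:, n - 1] <= crit
    t2_max = np.full(residuals.shape[0], np.nan)
    for i in range(residuals.shape[0]):
        ok = np.flatnonzero(accepted[i])
        if ok.size:
            t2_max[i] = t2_grid[ok[-1]]
    return ChiSquareReport(
        sigma=sigma.copy(), alpha=alpha, t1=t1, t2_grid=t2_grid, accepted=accepted,
        t2_max=t2_max,
    )


def loglog_slope(t: np.ndarray, v: np.ndarray, window: tuple[float, float] | None = None) -> float:
    """Ordinary least-squares slope of ``log|v|`` versus ``log t``.

    A power law ``v = A / t^k`` yields exactly ``-k``.  The trace must be
    strictly one-signed (and nonzero) inside the window: a sign change makes
    the log-scale slope undefined.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, v = t[m], v[m]
    if t.size < 2:
        raise ValueError("need at least two samples in the window")
    if np.any(t <= 0):
        raise ValueError("log-log slope requires positive times")
    if np.any(v > 0) and np.any(v < 0) or np.any(v == 0):
        raise ValueError("trace changes sign (or vanishes) inside the window")
    slope, _ = np.polyfit(np.log(t), np.log(np.abs(v)), 1)
    return float(slope)


@dataclass
class DecayComparison:
    """Shifted power law ``a/(t+b)^2`` versus exponential ``c exp(-d t)``."""

    power_params: tuple[float, float]
    exp_params: tuple[float, float]
    r2_power: float
    r2_exp: float
    v_cutoff: float
    t_fit: float
    t_start: float


def _r2(y, yhat) -> float:
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - np.mean(y)) ** 2)
    return 1.0 - ss_res / ss_tot


def compare_power_vs_exp(
    t: np.ndarray,
    v: np.ndarray,
    v_cutoff: float = 1500.0,
    t_fit: float = 24.2,
) -> DecayComparison | None:
    """Least-squares fit of both decay models to one trace and their R².

    The fit spans ``t_fit`` ms starting at the first sample where the trace
    amplitude drops to ``v_cutoff`` (default 1.5 mV in uV).  Returns ``None``
    (channel excluded) when the trace never reaches the cutoff from above or
    changes sign in the fit span.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    av = np.abs(v)
    above = np.flatnonzero(av >= v_cutoff)
    if above.size == 0:
        return None
    start = above[0] + np.argmax(av[above[0] :] <= v_cutoff)
    if av[start] > v_cutoff:  # never comes back below the cutoff
        return None
    m = (t >= t[start]) & (t <= t[start] + t_fit)
    ts, ys = t[m], v[m]
    if ts.size < 4 or (np.any(ys > 0) and np.any(ys < 0)):
        return None
    sgn = np.sign(ys[0])
    ys = ys * sgn  # fit the magnitude, reapply the sign in the params
    # shifted power law a/(t+b)^2, a profiled out
    def pow_resid(b):
        basis = 1.0 / (ts + b[0]) ** 2
        a = float(basis @ ys / (basis @ basis))
        return a * basis - ys

    sol_p = optimize.least_squares(pow_resid, x0=[1.0], bounds=([0.0], [np.inf]))
    bp = float(sol_p.x[0])
    basis = 1.0 / (ts + bp) ** 2
    ap = float(basis @ ys / (basis @ basis))
    fit_p = ap * basis

    # exponential c exp(-d t), c profiled out; init from the log-linear fit
    d0 = max(-np.polyfit(ts, np.log(np.maximum(ys, 1e-12)), 1)[0], 1e-6)

    def exp_resid(d):
        basis = np.exp(-d[0] * ts)
        c = float(basis @ ys / (basis @ basis))
        return c * basis - ys

    sol_e = optimize.least_squares(exp_resid, x0=[d0], bounds=([0.0], [np.inf]))
    de = float(sol_e.x[0])
    basis_e = np.exp(-de * ts)
    ce = float(basis_e @ ys / (basis_e @ basis_e))
    fit_e = ce * basis_e

    return DecayComparison(
        power_params=(sgn * ap, bp),
        exp_params=(sgn * ce, de),
        r2_power=_r2(ys, fit_p),
        r2_exp=_r2(ys, fit_e),
        v_cutoff=v_cutoff,
        t_fit=t_fit,
        t_start=float(ts[0]),
    )


def fit_two_exponentials(
    t: np.ndarray, v: np.ndarray, window: tuple[float, float] | None = None
) -> dict:
    """Fit ``c1 exp(-d1 t) + c2 exp(-d2 t)`` and report the time-constant
    ratio ``max(1/d) / min(1/d)``.

    This is the comparison model (the conventional description of capacitive
    discharge), never used for removal.  The amplitudes are profiled out;
    the rates are multi-started on a log grid.  A degenerate optimum
    (``d1 ~ d2`` or a vanishing amplitude) indicates the trace is effectively
    a single exponential; the ratio is then reported as 1.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    if window is not None:
        m = (t >= window[0]) & (t <= window[1])
        t, v = t[m], v[m]
    if t.size < 5:
        raise ValueError("window too short for a two-exponential fit")

    def profile(d):
        B = np.exp(np.outer(t, -np.abs(d)))
        c, *_ = np.linalg.lstsq(B, v, rcond=None)
        return c, B @ c - v

    def resid(d):
        return profile(d)[1]

    starts = []
    scale = max(t[-1], 1.0)
    for r1 in (0.3, 1.0, 3.0):
        for ratio in (3.0, 10.0, 30.0):
            starts.append([r1 / scale, r1 * ratio / scale])
    best, log = None, []
    for d0 in starts:
        try:
            sol = optimize.least_squares(resid, x0=d0, bounds=(0.0, np.inf), max_nfev=400)
        except Exception as exc:  # pragma: no cover
            log.append((d0, repr(exc)))
            continue
        log.append((d0, sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"two-exponential fit did not converge; starts: {log}")
    d = np.sort(np.abs(best.x))
    c, r = profile(d)
    vr = float(np.sqrt(np.mean(v**2)))
    degenerate = bool(
        d[0] == 0 or d[1] / max(d[0], 1e-300) < 1.05 or np.min(np.abs(c)) * 1e6 < vr
    )
    ratio = 1.0 if degenerate else float((1.0 / d[0]) / (1.0 / d[1]) if d[0] else np.inf)
    ratio = max(ratio, 1.0)
    return {
        "c": (float(c[0]), float(c[1])),
        "d": (float(d[0]), float(d[1])),
        "ratio": ratio,
        "degenerate": degenerate,
        "residual_rms": float(np.sqrt(np.mean(r**2))),
    }


@dataclass
class AlignmentResult:
    rate: float
    t_align: float  # ms, a multiple of 1000/REF_RATE
    steps: int
    objective: float


def align_sampling_rates(
    rec_s, rec_ref, *, window: tuple[float, float] = (1.33, 50.0), max_steps: int = 120
) -> AlignmentResult:
    """Alignment shift of a low-rate recording against the 16 kHz reference.

    Lower acquisition rates register the artifact with a progressive delay.
    The rate-S traces are shifted backwards on a grid of ``1000/16384`` ms
    steps and linearly resampled onto the reference grid; the shift
    minimizing the summed absolute difference over all channels in the
    objective window (directly after the pulse artifact) is returned.
    """
    if rec_s.labels != rec_ref.labels:
        raise ValueError("recordings must share the same channel set")
    step = 1000.0 / REF_RATE
    t_ref = rec_ref.times_ms
    t_s = rec_s.times_ms
    obj_mask = (t_s >= window[0]) & (t_s <= window[1])
    t_obj = t_s[obj_mask]
    if t_obj.size == 0:
        raise ValueError("objective window contains no samples of the rate-S recording")
    coarse = rec_s.data[:, obj_mask]

    # The delayed coarse trace satisfies s(t) ~ ref(t - t_align); evaluate the
    # dense reference at the backward-shifted coarse sample times (the dense
    # grid makes the resampling error negligible and integer-step shifts land
    # on reference samples exactly).
    best = None
    for k in range(max_steps + 1):
        t_query = t_obj - k * step
        if t_query[0] < t_ref[0]:
            break
        shifted_ref = np.vstack(
            [np.interp(t_query, t_ref, rec_ref.data[ch]) for ch in range(rec_ref.n_channels)]
        )
        obj = float(np.sum(np.abs(coarse - shifted_ref)))
        if best is None or obj < best[1]:
            best = (k, obj)
    if best is None:
        raise ValueError("no overlap between the recordings after shifting")
    return AlignmentResult(
        rate=rec_s.rate, t_align=best[0] * step, steps=best[0], objective=best[1]
    )


def find_t0_order1_tangent(
    t: np.ndarray,
    traces: np.ndarray,
    *,
    n_grid: int = 400,
    smooth: int = 5,
) -> float:
    """Earliest time from which every trace decays faster than ``1/t``.

    The instantaneous log-log slope of each |trace| is computed by centered
    differences on a log-resampled grid with a short Savitzky-Golay smooth;
    ``t0`` is the order-1 tangency point of the slowest-decaying trace (for
    ``A/(t+b)^2`` the slope is ``-2t/(t+b)``, so ``t0 = b``).  Raises when
    some trace never decays faster than order 1.
    """
    t = np.asarray(t, dtype=float)
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if np.any(t <= 0):
        raise ValueError("requires positive times")
    tg = np.geomspace(t[0], t[-1], n_grid)
    ltg = np.log(tg)
    t0 = tg[0]
    for y in traces:
        ly = np.log(np.interp(tg, t, np.abs(y)))
        slope = np.gradient(ly, ltg)
        if smooth and smooth >= 3:
            slope = signal.savgol_filter(slope, smooth, 2)
        if slope[-1] >= -1.0:
            raise ValueError("a trace never decays faster than a power law of order 1")
        late = np.flatnonzero(slope >= -1.0)
        if late.size == 0:
            continue  # always faster than order 1: tangency at the grid start
        j = late[-1]
        # linear interpolation of the -1 crossing between grid points j, j+1
        f = (-1.0 - slope[j]) / (slope[j + 1] - slope[j])
        cross = tg[j] * (tg[j + 1] / tg[j]) ** f
        t0 = max(t0, float(cross))
    return t0


def trial_envelope(trials, discard: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Pooled per-time-sample (discard, 1-discard) quantile bands.

    ``trials`` is a sequence of (channels x samples) arrays or Recordings;
    all trace values at each time sample are pooled before taking quantiles
    (``discard = 0``: min/max envelope).
    """
    if not 0 <= discard < 0.5:
        raise ValueError("discard fraction must be in [0, 0.5)")
    arrays = [tr.data if hasattr(tr, "data") else np.atleast_2d(np.asarray(tr)) for tr in trials]
    if not arrays:
        raise ValueError("no trials given")
    pooled = np.concatenate(arrays, axis=0)
    lo = np.quantile(pooled, discard, axis=0)
    hi = np.quantile(pooled, 1.0 - discard, axis=0)
    return lo, hi


def drift_exclude(trial, band: float = 40.0, window: tuple[float, float] = (1500.0, 2000.0)):
    """Per-channel keep flags for the drift-exclusion rule.

    A channel is kept iff all its samples within the window (default 1.5-2 s
    after the pulse) stay inside ``+-band`` uV (default 40).
    """
    t = trial.times_ms
    m = (t >= window[0]) & (t <= window[1])
    return np.all(np.abs(trial.data[:, m]) <= band, axis=1)
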