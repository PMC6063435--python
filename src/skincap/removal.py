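"""Model-based discharge-artifact reconstruction and removal.

The physical model predicts that every reference-subtracted discharge
artifact is, to leading order, a linear combination of ``1/(t + sigma)^2``
and ``1/(t + sigma)^3`` — i.e. a rational function

    V(t) = (alpha_1 t + alpha_0) / (t^3 + beta_2 t^2 + beta_1 t + beta_0)

with non-negative ``beta`` coefficients (which excludes denominator roots,
hence singularities, for t > 0).  Removal proceeds in two stages:

1. Fit the rational function to the ``N_p`` most-positive and ``N_n``
   most-negative deflecting electrodes (default 3 + 3) over a
   sampling-rate-dependent window.
2. Project every channel onto the span of the fitted artifacts (the model
   is linear in the initial voltage distribution) and subtract.

Samples before the fit window cannot be reconstructed and are spline
interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from scipy import optimize
from scipy.interpolate import CubicSpline

from .recording import Recording

__all__ = [
    "RationalArtifact",
    "RemovalConfig",
    "ProjectionResult",
    "default_fit_window",
    "select_subset",
    "fit_rational",
    "project_electrodes",
    "subtract_artifacts",
    "interpolate_gap",
    "remove_artifacts",
]

# printed anchors: (8, 28) ms at 1 kHz-class rates, (1.5, 25) ms at >= 8 kHz
_RATE_LO, _WINDOW_LO = 1024.0, (8.0, 28.0)
_RATE_HI, _WINDOW_HI = 8192.0, (1.5, 25.0)


def default_fit_window(sampling_rate: float) -> tuple[float, float]:
    """Default artifact-fit window (ms) for a given sampling rate.

    Low rates cannot resolve the early artifact, so the window starts later.
    Between the anchor rates both endpoints are log-linearly interpolated;
    outside them they clamp to the nearest anchor.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling rate must be positive")
    if sampling_rate <= _RATE_LO:
        return _WINDOW_LO
    if sampling_rate >= _RATE_HI:
        return _WINDOW_HI
    f = np.log(sampling_rate / _RATE_LO) / np.log(_RATE_HI / _RATE_LO)
    return (
        float(_WINDOW_LO[0] + f * (_WINDOW_HI[0] - _WINDOW_LO[0])),
        float(_WINDOW_LO[1] + f * (_WINDOW_HI[1] - _WINDOW_LO[1])),
    )


@dataclass
class RemovalConfig:
    """Configuration of the two-stage removal.

    ``n_pos``/``n_neg`` are the subset sizes of stage 1; ``window`` overrides
    the rate-dependent default; ``pulse_exclusion`` (ms) is the pulse-artifact
    span excluded from every fit; ``muscle_guard`` shifts the window start
    past the last |sample| > ``muscle_threshold`` crossing when enabled.
    """

    n_pos: int = 3
    n_neg: int = 3
    window: tuple[float, float] | None = None
    pulse_exclusion: float = 0.33
    interpolate: bool = True
    muscle_guard: bool = False
    muscle_threshold: float = 500.0

    @property
    def n_basis(self) -> int:
        return self.n_pos + self.n_neg


@dataclass
class RationalArtifact:
    """Fitted discharge artifact for one electrode."""

    alpha0: float
    alpha1: float
    beta0: float
    beta1: float
    beta2: float
    window: tuple[float, float]
    electrode: str = ""
    residual_rms: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.beta0, self.beta1, self.beta2) < 0:
            raise ValueError("beta coefficients must be non-negative")

    def __call__(self, t) -> np.ndarray:
        """Evaluate the artifact at times ``t`` (ms, > 0)."""
        t = np.asarray(t, dtype=float)
        den = ((t + self.beta2) * t + self.beta1) * t + self.beta0
        return (self.alpha1 * t + self.alpha0) / den


def _window_samples(rec: Recording, window: tuple[float, float]) -> np.ndarray:
    t = rec.times_ms
    return np.flatnonzero((t >= window[0]) & (t <= window[1]))


def select_subset(rec: Recording, cfg: RemovalConfig | None = None) -> list[str]:
    """Stage-1 electrode subset: the ``n_pos`` channels with the largest
    positive and the ``n_neg`` with the most negative post-pulse deflection.

    The deflection of a channel is its signed extremum (largest absolute
    sample) between one sample after the pulse exclusion and the window end;
    ties break by channel order.  If one sign is underpopulated the subset is
    filled from the other pool with a warning.
    """
    cfg = cfg or RemovalConfig()
    if rec.n_channels < cfg.n_basis:
        raise ValueError(
            f"need at least {cfg.n_basis} channels, recording has {rec.n_channels}"
        )
    window = cfg.window or default_fit_window(rec.rate)
    t = rec.times_ms
    mask = (t > cfg.pulse_exclusion) & (t <= window[1])
    seg = rec.data[:, mask]
    idx_ext = np.argmax(np.abs(seg), axis=1)
    deflection = seg[np.arange(rec.n_channels), idx_ext]

    order_desc = np.argsort(-deflection, kind="stable")
    order_asc = np.argsort(deflection, kind="stable")
    pos_pool = [i for i in order_desc if deflection[i] > 0]
    neg_pool = [i for i in order_asc if deflection[i] < 0]
    pos = pos_pool[: cfg.n_pos]
    neg = neg_pool[: cfg.n_neg]
    missing = (cfg.n_pos - len(pos)) + (cfg.n_neg - len(neg))
    if missing:
        warnings.warn(
            "fewer channels deflect in one direction than requested; "
            "filling the subset from the opposite-signed pool",
            stacklevel=2,
        )
        taken = set(pos) | set(neg)
        # least-extreme leftovers first, deterministic by channel order
        leftovers = [i for i in np.argsort(np.abs(deflection), kind="stable") if i not in taken]
        fill = leftovers[:missing]
        pos += [i for i in fill if deflection[i] >= 0]
        neg += [i for i in fill if deflection[i] < 0]
    return [rec.labels[i] for i in pos + neg]


def _denominator(t: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return ((t + beta[2]) * t + beta[1]) * t + beta[0]


def _profile_alpha(t, y, beta):
    """Optimal numerator for a fixed denominator (linear least squares)."""
    den = _denominator(t, beta)
    M = np.column_stack([np.ones_like(t), t]) / den[:, None]
    coef, *_ = np.linalg.lstsq(M, y, rcond=None)
    return coef, M @ coef - y


def fit_rational(
    trace: np.ndarray,
    window: tuple[float, float],
    sampling_rate: float,
    *,
    pulse_onset: int = 0,
    label: str = "",
    sigma_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0),
) -> RationalArtifact:
    """Constrained least-squares fit of the rational artifact model.

    Any trace that is exactly a combination of ``1/(t + sigma)^2`` and
    ``1/(t + sigma)^3`` lies in the model class (denominator
    ``(t + sigma)^3``) and is recovered to machine precision.

    The numerator is profiled out (it enters linearly), leaving a bounded
    3-parameter problem in the ``beta``'s solved by ``scipy.optimize
    .least_squares`` from multiple starts: each grid value of ``sigma``
    seeds the exactly-representable expansion ``beta = (sigma^3, 3 sigma^2,
    3 sigma)``.
    """
    trace = np.asarray(trace, dtype=float)
    t_all = (np.arange(trace.size) - pulse_onset) * 1000.0 / sampling_rate
    mask = (t_all >= window[0]) & (t_all <= window[1])
    if mask.sum() < 6:
        raise ValueError("fit window contains fewer samples than free parameters")
    t, y = t_all[mask], trace[mask]

    def beta_residual(logless_beta):
        _, r = _profile_alpha(t, y, logless_beta)
        return r

    best = None
    diagnostics = []
    for s in sigma_grid:
        beta0 = np.array([s**3, 3 * s**2, 3 * s])
        try:
            sol = optimize.least_squares(
                beta_residual,
                beta0,
                bounds=(np.zeros(3), np.full(3, np.inf)),
                xtol=1e-15,
                ftol=1e-15,
                gtol=1e-15,
                max_nfev=400,
            )
        except Exception as exc:  # pragma: no cover - optimizer hiccup
            diagnostics.append((s, repr(exc)))
            continue
        diagnostics.append((s, sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"rational fit did not converge; multi-start log: {diagnostics}")
    beta = best.x
    alpha, resid = _profile_alpha(t, y, beta)
    return RationalArtifact(
        alpha0=float(alpha[0]),
        alpha1=float(alpha[1]),
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        window=tuple(window),
        electrode=label,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


@dataclass
class ProjectionResult:
    """Stage-2 projection of every channel onto the fitted artifact basis."""

    coefficients: np.ndarray  # (n_channels, n_basis)
    residual_rms: np.ndarray  # (n_channels,)
    basis: list[RationalArtifact] = dataclass_field(default_factory=list)
    window: tuple[float, float] = (0.0, 0.0)


def project_electrodes(
    rec: Recording, basis: list[RationalArtifact], window: tuple[float, float]
) -> ProjectionResult:
    """Ordinary least-squares coefficients of every channel on the evaluated
    basis artifacts over the fit window.

    The projection uses the fit window only, so later physiology (TEPs) does
    not bias the coefficients.  A rank-deficient (collinear) basis triggers a
    warning; the minimum-norm solution is returned.
    """
    if not basis:
        raise ValueError("empty artifact basis")
    idx = _window_samples(rec, window)
    t = rec.times_ms[idx]
    B = np.column_stack([f(t) for f in basis])
    # Column-normalized truncated-SVD solve: basis directions that are
    # indistinguishable within the window (collinear artifacts, e.g. fits to
    # noise on an already-cleaned recording) are dropped rather than allowed
    # to produce huge cancelling coefficients that extrapolate wildly outside
    # the window.  Exactly collinear bases degrade to the minimum-norm
    # solution with a warning.
    norms = np.sqrt(np.mean(B**2, axis=0))
    norms[norms == 0] = 1.0
    Bn = B / norms
    rank = np.linalg.matrix_rank(Bn)
    if rank < B.shape[1]:
        warnings.warn(
            f"artifact basis is rank deficient (rank {rank} < {B.shape[1]}); "
            "returning the minimum-norm projection",
            stacklevel=2,
        )
    coef, *_ = np.linalg.lstsq(Bn, rec.data[:, idx].T, rcond=1e-6)
    coef /= norms[:, None]
    resid = rec.data[:, idx].T - B @ coef
    return ProjectionResult(
        coefficients=coef.T,
        residual_rms=np.sqrt(np.mean(resid**2, axis=0)),
        basis=list(basis),
        window=tuple(window),
    )


def subtract_artifacts(rec: Recording, fits: ProjectionResult) -> Recording:
    """Subtract the reconstructed artifacts from every channel.

    The artifact model is evaluated (and subtracted) from the fit-window
    start to the end of the recording; earlier post-pulse samples cannot be
    reconstructed and are flagged in ``metadata['unreconstructable_ms']``.
    """
    if fits.coefficients.shape[0] != rec.n_channels:
        raise ValueError("projection does not cover all channels")
    t = rec.times_ms
    sel = t >= fits.window[0]
    B = np.column_stack([f(t[sel]) for f in fits.basis])
    cleaned = rec.data.copy()
    cleaned[:, sel] -= fits.coefficients @ B.T
    out = rec.copy(data=cleaned, unreconstructable_ms=[0.0, fits.window[0]])
    out.log("subtract_artifacts", window=list(fits.window), n_basis=len(fits.basis))
    return out


def interpolate_gap(rec: Recording, gap: tuple[float, float] | None = None, n_anchor: int = 10) -> Recording:
    """Replace the unreconstructable gap by a natural cubic spline.

    The spline is anchored on ``n_anchor`` samples on each side of the gap
    (default 10).  The gap defaults to the span recorded by
    :func:`subtract_artifacts`.
    """
    if gap is None:
        gap = rec.metadata.get("unreconstructable_ms")
        if gap is None:
            raise ValueError("no gap given and none recorded in metadata")
    t = rec.times_ms
    inside = np.flatnonzero((t >= gap[0]) & (t < gap[1]))
    if inside.size == 0:
        return rec.copy()
    lo, hi = inside[0], inside[-1] + 1
    left = np.arange(max(lo - n_anchor, 0), lo)
    right = np.arange(hi, min(hi + n_anchor, rec.n_samples))
    if left.size < 2 or right.size < 2:
        raise ValueError("gap at recording edge: fewer than 2 anchor samples")
    anchors = np.concatenate([left, right])
    data = rec.data.copy()
    for ch in range(rec.n_channels):
        spline = CubicSpline(t[anchors], data[ch, anchors], bc_type="natural")
        data[ch, inside] = spline(t[inside])
    out = rec.copy(data=data, interpolated_ms=[float(t[lo]), float(t[hi - 1])])
    out.log("interpolate_gap", gap=list(gap), n_anchor=n_anchor)
    return out


def remove_artifacts(
    rec: Recording, cfg: RemovalConfig | None = None
) -> tuple[Recording, dict]:
    """Full two-stage removal pipeline.

    Returns the cleaned recording and a report with the fit window, the
    selected subset, the per-basis rational parameters, and per-channel
    projection coefficients and residuals.
    """
    cfg = cfg or RemovalConfig()
    window = cfg.window or default_fit_window(rec.rate)
    if cfg.muscle_guard:
        t = rec.times_ms
        m = (t > cfg.pulse_exclusion) & (t <= window[1])
        exceed = np.abs(rec.data[:, m]) > cfg.muscle_threshold
        if exceed.any():
            t_last = t[m][np.flatnonzero(exceed.any(axis=0))[-1]]
            if t_last > window[0]:
                window = (float(t_last + 1000.0 / rec.rate), window[1])
    cfg_used = RemovalConfig(**{**cfg.__dict__, "window": window})
    subset = select_subset(rec, cfg_used)
    basis = [
        fit_rational(
            rec.channel(lbl), window, rec.rate, pulse_onset=rec.pulse_onset, label=lbl
        )
        for lbl in subset
    ]
    proj = project_electrodes(rec, basis, window)
    cleaned = subtract_artifacts(rec, proj)
    if cfg.interpolate:
        cleaned = interpolate_gap(cleaned)
    report = {
        "window_ms": list(window),
        "subset": subset,
        "basis": [
            {
                "electrode": f.electrode,
                "alpha0": f.alpha0,
                "alpha1": f.alpha1,
                "beta0": f.beta0,
                "beta1": f.beta1,
                "beta2": f.beta2,
                "residual_rms": f.residual_rms,
            }
            for f in basis
        ],
        "coefficients": {
            lbl: proj.coefficients[i].tolist() for i, lbl in enumerate(rec.labels)
        },
        "projection_residual_rms": {
            lbl: float(proj.residual_rms[i]) for i, lbl in enumerate(rec.labels)
        },
    }
    return cleaned, report
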