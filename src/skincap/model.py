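"""Closed-form solution of the homogenized two-layer skin-capacitor model.

The electrode-gel-skin interface is modeled as two resistive sheets (gel on
top, deep skin below) coupled everywhere by leaky capacitors (the stratum
corneum).  The cross-layer voltage ``v = v_T - v_B`` obeys the
two-dimensional cable equation

    tau * dv/dt = lambda^2 * Laplacian(v) - v

with length constant ``lambda^2 = r_m / (r_T + r_B)`` and time constant
``tau = r_m * c_m``.  Its impulse response is the density

    g(t, x) = tau / (4 pi lambda^2 t) * exp(-|x|^2 tau / (4 lambda^2 t) - t / tau)

which decays as ``1/t`` in the intermediate regime
``|x|^2 tau / lambda^2 << t << tau`` and exponentially for ``t >> tau``.
Referencing (subtracting a second electrode with slightly different initial
spread) acts as a differentiator, turning the ``1/t`` tail into ``1/t^2``.

Units: time in ms with t = 0 at TMS pulse onset; space in units of
``lambda`` by default; voltages in uV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, special

__all__ = [
    "LayerParams",
    "ElectrodeModel",
    "VoltageField",
    "LeadingOrder",
    "green_function",
    "split_initial_pulse",
    "electrode_voltage",
    "referenced_difference",
    "leading_order_difference",
    "classify_regimes",
    "simulate_field",
]


@dataclass(frozen=True)
class LayerParams:
    """Homogenized constants of the two-layer skin capacitor.

    Parameters
    ----------
    r_T, r_B : float
        Edge resistivities of the top (gel) and bottom (deep skin) sheets.
    r_m : float
        Cross-layer membrane resistance (ohm * area).
    c_m : float
        Cross-layer capacitance per area (so that ``tau = r_m * c_m`` is
        in ms).
    """

    r_T: float
    r_B: float
    r_m: float
    c_m: float

    def __post_init__(self) -> None:
        for name in ("r_T", "r_B", "r_m", "c_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def lam(self) -> float:
        """Length constant, ``lambda = sqrt(r_m / (r_T + r_B))``."""
        return math.sqrt(self.r_m / (self.r_T + self.r_B))

    @property
    def tau(self) -> float:
        """Time constant in ms, ``tau = r_m * c_m``."""
        return self.r_m * self.c_m

    @property
    def diffusivity(self) -> float:
        """``D = lambda^2 / tau`` (length^2 / ms)."""
        return self.lam**2 / self.tau

    @classmethod
    def from_constants(cls, lam: float = 1.0, tau: float = 1000.0) -> "LayerParams":
        """Canonical circuit realization of given ``lambda`` (length units)
        and ``tau`` (ms), with symmetric sheets ``r_T = r_B = 1``."""
        if lam <= 0 or tau <= 0:
            raise ValueError("lam and tau must be strictly positive")
        r_m = 2.0 * lam**2
        return cls(r_T=1.0, r_B=1.0, r_m=r_m, c_m=tau / r_m)


@dataclass(frozen=True)
class ElectrodeModel:
    """Initial-condition parameters of one electrode.

    The post-pulse charge under electrode ``i`` is a Gaussian of spread
    parameter ``sigma`` (time units; spatial variance ``lambda^2 sigma/tau``)
    displaced by ``mu`` from the electrode center, averaged over a disk of
    radius ``b`` (``b = 0``: point electrode).
    """

    x: tuple[float, float] = (0.0, 0.0)
    sigma: float = 0.5
    mu: tuple[float, float] = (0.0, 0.0)
    b: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.b < 0:
            raise ValueError("b must be non-negative")


def green_function(t, x, params: LayerParams):
    """Impulse response ``g(t, x)`` of the two-dimensional cable equation.

    ``g(t, x) = tau/(4 pi lambda^2 t) exp(-|x|^2 tau/(4 lambda^2 t) - t/tau)``.
    Strictly positive and radially symmetric in ``x``; defined for ``t > 0``.

    Parameters
    ----------
    t : float or array
        Time in ms, strictly positive.
    x : array-like
        A 2-vector, or an array whose last axis has length 2.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("green_function requires t > 0")
    x = np.asarray(x, dtype=float)
    r2 = np.sum(x * x, axis=-1)
    lam2 = params.lam**2
    tau = params.tau
    return tau / (4.0 * np.pi * lam2 * t) * np.exp(-r2 * tau / (4.0 * lam2 * t) - t / tau)


def split_initial_pulse(v0: float, params: LayerParams) -> tuple[float, float]:
    """Split a localized cross-layer voltage pulse into layer voltages.

    The solution with initial difference ``v0`` at the origin has
    ``v_T = r_T/(r_T+r_B) v0 g`` and ``v_B = -r_B/(r_T+r_B) v0 g``; this
    returns the two amplitude fractions, which differ by ``v0``.
    """
    denom = params.r_T + params.r_B
    return (params.r_T / denom * v0, -params.r_B / denom * v0)


def _disk_average_g(t: float, mu: np.ndarray, b: float, params: LayerParams) -> float:
    # Radial reduction of (1/pi b^2) * int_{|y|<=b} g(t, mu - y) dy.
    # With s = 4 D_eff t (D_eff in the g parameterization) and m = |mu|,
    # the angular integral gives a modified Bessel I0; i0e keeps it stable.
    lam2 = params.lam**2
    tau = params.tau
    s = 4.0 * lam2 * t / tau  # = 4 D t
    m = float(np.hypot(mu[0], mu[1]))
    pref = tau / (4.0 * np.pi * lam2 * t) * math.exp(-t / tau)

    def radial(r: float) -> float:
        z = 2.0 * r * m / s
        return r * math.exp(-((r - m) ** 2) / s) * special.i0e(z)

    val, _ = integrate.quad(radial, 0.0, b, epsabs=0.0, epsrel=1e-10, limit=200)
    return pref * 2.0 * np.pi * val / (np.pi * b**2)


def electrode_voltage(t, e: ElectrodeModel, params: LayerParams):
    """Cross-layer voltage seen by electrode ``e`` at time ``t`` (ms).

    Evaluates ``amplitude * (1/pi b^2) int_{|y|<=b} g(t + sigma, mu - y) dy``;
    for a point electrode (``b = 0``) this is ``amplitude * g(t + sigma, mu)``.
    Requires ``t + sigma > 0``.
    """
    t_arr = np.asarray(t, dtype=float)
    ts = t_arr + e.sigma
    if np.any(ts <= 0):
        raise ValueError("electrode_voltage requires t + sigma > 0")
    mu = np.asarray(e.mu, dtype=float)
    if e.b == 0.0:
        return e.amplitude * green_function(ts, mu, params)
    vals = np.array([_disk_average_g(float(tv), mu, e.b, params) for tv in np.atleast_1d(ts)])
    out = e.amplitude * vals
    return out[0] if t_arr.ndim == 0 else out.reshape(t_arr.shape)


def referenced_difference(t, e1: ElectrodeModel, e2: ElectrodeModel, params: LayerParams):
    """Voltage difference ``v_1(t) - v_2(t)`` between two electrodes.

    This is what an EEG amplifier reports when ``e2`` is the reference.
    Subtraction acts as a differentiator: for small parameter differences
    the ``1/t`` tails of the individual electrodes cancel at leading order
    and the difference decays as ``1/t^2`` in the intermediate regime.
    """
    return electrode_voltage(t, e1, params) - electrode_voltage(t, e2, params)


@dataclass(frozen=True)
class LeadingOrder:
    """First-order expansion of a referenced difference.

    ``A1`` is the time-expansion term (vanishes when the spreads agree),
    ``A2`` the space-expansion term (vanishes when the displacements agree);
    the Taylor remainders are bounded by power laws of order 3 and 2.
    """

    A1: float
    A2: float

    @property
    def total(self) -> float:
        return self.A1 + self.A2


def _a1_integrand(t: float, w2, e1: ElectrodeModel, e2: ElectrodeModel, D: float):
    # A1 = (sigma1 - sigma2) d/dt Phi(t + sigma1, w), Phi the 2D heat kernel
    T = t + e1.sigma
    return (
        (e2.sigma - e1.sigma)
        / (16.0 * np.pi * D**2)
        * (4.0 * D / T**2 - w2 / T**3)
        * np.exp(-w2 / (4.0 * D * T))
    )


def _a2_integrand(t: float, w, e1: ElectrodeModel, e2: ElectrodeModel, D: float):
    # A2 = (mu1 - mu2)^T grad_x Phi(t + sigma2, w), evaluated at w = mu1 - y
    T = t + e2.sigma
    dmu = np.asarray(e2.mu, float) - np.asarray(e1.mu, float)
    w2 = np.sum(w * w, axis=-1)
    return (
        np.sum(dmu * w, axis=-1)
        / (8.0 * np.pi * D**2 * T**2)
        * np.exp(-w2 / (4.0 * D * T))
    )


def leading_order_difference(
    t: float, e1: ElectrodeModel, e2: ElectrodeModel, params: LayerParams
) -> LeadingOrder:
    """First-order (in ``sigma2 - sigma1`` and ``mu2 - mu1``) approximation
    of :func:`referenced_difference`, disk-averaged over the electrode.

    The expansion is taken around the pure heat kernel (the exponential
    ``exp(-t/tau)`` bookkeeping factor is dropped), so it is meaningful in
    the intermediate power-law regime ``t << tau``.  ``A1 + A2`` identifies
    power laws of order 2 and 3: the physical basis of the rational fitting
    class used for artifact removal.  Valid for small parameter differences
    (|sigma2 - sigma1| << sigma1, |mu2 - mu1| << lambda); not enforced.
    """
    D = params.diffusivity
    mu1 = np.asarray(e1.mu, float)
    amp = e1.amplitude
    if e1.b == 0.0:
        w = mu1
        a1 = float(_a1_integrand(t, float(w @ w), e1, e2, D))
        a2 = float(_a2_integrand(t, w, e1, e2, D))
        return LeadingOrder(A1=amp * a1, A2=amp * a2)

    b = e1.b

    def f1(r, th):
        y = np.array([r * math.cos(th), r * math.sin(th)])
        w = mu1 - y
        return r * _a1_integrand(t, float(w @ w), e1, e2, D)

    def f2(r, th):
        y = np.array([r * math.cos(th), r * math.sin(th)])
        w = mu1 - y
        return r * _a2_integrand(t, w, e1, e2, D)

    a1, _ = integrate.dblquad(f1, 0, 2 * np.pi, 0, b, epsabs=0.0, epsrel=1e-8)
    a2, _ = integrate.dblquad(f2, 0, 2 * np.pi, 0, b, epsabs=0.0, epsrel=1e-8)
    area = np.pi * b**2
    return LeadingOrder(A1=amp * a1 / area, A2=amp * a2 / area)


def classify_regimes(x, params: LayerParams) -> tuple[float, float]:
    """Boundaries of the three decay regimes of ``g(., x)``.

    Returns ``(x^2 tau / lambda^2, tau)``: below the first time the Gaussian
    factor suppresses ``g``; between the two, ``g ~ tau/(4 pi lambda^2 t)``
    (the 1/t power law); beyond ``tau`` the decay is exponential.  The
    bounds are order-of-magnitude markers ("<<" is conventionally a factor
    of 10).
    """
    x = np.asarray(x, dtype=float)
    r2 = float(np.sum(x * x))
    return (r2 * params.tau / params.lam**2, params.tau)


@dataclass
class VoltageField:
    """Sampled solution on a square grid.

    ``v`` has shape (n_times, n, n); ``v_T``/``v_B`` are the layer surface
    voltages given by the resistive split, satisfying ``v = v_T - v_B`` and
    ``v_T / v_B = -r_T / r_B`` wherever ``v_B != 0``.
    """

    times: np.ndarray
    coords: np.ndarray  # 1D grid coordinates, shared by both axes
    v: np.ndarray
    params: LayerParams
    dx: float = field(init=False)

    def __post_init__(self) -> None:
        self.dx = float(self.coords[1] - self.coords[0])

    @property
    def v_T(self) -> np.ndarray:
        return self.params.r_T / (self.params.r_T + self.params.r_B) * self.v

    @property
    def v_B(self) -> np.ndarray:
        return -self.params.r_B / (self.params.r_T + self.params.r_B) * self.v

    def mass(self) -> np.ndarray:
        """Plane integral of ``v(t, .)`` per time sample."""
        return self.v.sum(axis=(1, 2)) * self.dx**2


def simulate_field(
    v0_distribution,
    times,
    params: LayerParams,
    *,
    half_width: float | None = None,
    n: int = 256,
) -> VoltageField:
    """Evolve an initial cross-layer voltage map under the cable equation.

    ``v(t, .) = v0 * g(t, .)`` evaluated by FFT convolution on a periodic
    square domain wide enough that boundary wrap is negligible (default
    half-width ``max(10 lambda sqrt(t_max/tau), 3 lambda)``).  The plane
    integral of ``v(t, .)`` decays as ``exp(-t/tau)`` times the initial
    integral.

    Parameters
    ----------
    v0_distribution : callable
        Maps coordinate arrays ``(X, Y)`` to the initial voltage map;
        must be integrable with support well inside the domain.
    times : sequence of float
        Strictly positive evaluation times (ms).
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times <= 0):
        raise ValueError("simulate_field requires strictly positive times")
    if half_width is None:
        half_width = params.lam * max(10.0 * math.sqrt(times.max() / params.tau), 3.0)
    coords = (np.arange(n) - n // 2) * (2.0 * half_width / n)
    X, Y = np.meshgrid(coords, coords, indexing="ij")
    v0 = np.asarray(v0_distribution(X, Y), dtype=float)
    dx = coords[1] - coords[0]
    R2 = X**2 + Y**2
    lam2, tau = params.lam**2, params.tau
    V0 = np.fft.rfft2(np.fft.ifftshift(v0))
    out = np.empty((len(times), n, n))
    for k, t in enumerate(times):
        g = tau / (4.0 * np.pi * lam2 * t) * np.exp(-R2 * tau / (4.0 * lam2 * t) - t / tau)
        G = np.fft.rfft2(np.fft.ifftshift(g))
        out[k] = np.fft.fftshift(np.fft.irfft2(V0 * G, s=(n, n))) * dx**2
    return VoltageField(times=times, coords=coords, v=out, params=params)
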