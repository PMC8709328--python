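"""Late-phase CEUS washout quantification.

A region-of-interest time-intensity curve (TIC) from the late vascular phase
(>120 s after bolus) is summarised by fitting the mono-exponential washout
model

    F(t) = A * exp(-k * (t - t_start)) + B

where ``B`` is the asymptotic intensity at t -> infinity, ``A`` the excess of
the start-frame intercept over ``B``, and ``k >= 0`` the decay rate.  Derived
quantities:

* ``gradient0 = -A*k`` -- the initial slope of the fitted curve;
* ``t_to_peak`` -- time from the start frame to the observed maximum;
* ``AREA`` -- the time-averaged deviation of the fitted curve from its
  start-frame value over the analysis window (dB; negative when intensity
  falls, i.e. washout);
* ``mse`` -- mean squared residual of the fit.

A lesion AREA at or below the -19.3 dB operating cutoff flags washout, the
late-phase hallmark of malignancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq, curve_fit

#: Operating cutoff (dB) on the lesion AREA statistic; AREA <= cutoff flags
#: washout (malignancy-suggestive), boundary inclusive.
DEFAULT_WASHOUT_CUTOFF_DB = -19.3

#: Upper bound on the decay rate during fitting (1/s).  2D late-phase TICs
#: evolve over minutes; rates beyond this are indistinguishable from an
#: instantaneous drop on a >=1 s sampling grid.
K_MAX = 10.0


@dataclass(frozen=True)
class TICSeries:
    """Timestamped intensity samples (dB) for one ROI of one lesion.

    ``start_index``/``end_index`` bound the analysis window (half-open end,
    Python slice convention); by default the full series is the window.
    """

    lesion_id: str
    roi: str  # "lesion" | "parenchyma"
    times: np.ndarray
    intensities: np.ndarray
    start_index: int = 0
    end_index: Optional[int] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("times and intensities must be 1-D and the same length")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    @property
    def window_times(self) -> np.ndarray:
        return self.times[self.start_index : self.end_index]

    @property
    def window_intensities(self) -> np.ndarray:
        return self.intensities[self.start_index : self.end_index]

    @property
    def t_start(self) -> float:
        return float(self.window_times[0])

    @property
    def window_length(self) -> float:
        t = self.window_times
        return float(t[-1] - t[0])


@dataclass(frozen=True)
class WashoutFit:
    """Fitted washout-model parameters and derived TIC summary statistics."""

    A: float
    B: float
    k: float
    gradient0: float  # -A*k, dB/s
    t_to_peak: float  # s from start frame
    area: float  # dB (time-averaged) by default
    mse: float  # dB^2
    converged: bool

    def curve(self, tau: np.ndarray) -> np.ndarray:
        """Evaluate the fitted model on a window-relative time axis (tau = t - t_start)."""
        return self.A * np.exp(-self.k * np.asarray(tau, dtype=float)) + self.B


def _model(tau: np.ndarray, A: float, k: float, B: float) -> np.ndarray:
    return A * np.exp(-k * tau) + B


def area_factor(k: float, window_length: float) -> float:
    """Time-averaged deviation of exp(-k t) from its t=0 value, per unit amplitude.

    Equals (1 - e^{-kT})/(kT) - 1 for T = window_length; -> 0 as kT -> 0 and
    -> -1 as kT -> infinity.  AREA = A * area_factor(k, T).
    """
    x = k * window_length
    if x < 0:
        raise ValueError("k and window_length must be non-negative")
    if x < 1e-8:
        return -x / 2.0 + x * x / 6.0
    return -math.expm1(-x) / x - 1.0


def time_to_peak(series: TICSeries) -> float:
    """Seconds from the start frame to the (first) maximum observed intensity."""
    y = series.window_intensities
    if len(y) == 0:
        raise ValueError("empty analysis window")
    i = int(np.argmax(y))  # first occurrence on ties
    return float(series.window_times[i] - series.t_start)


def compute_area(
    fit: WashoutFit,
    series: TICSeries,
    source: str = "fit",
    normalize: bool = True,
) -> float:
    """AREA statistic: deviation from start-frame intensity over the window.

    AREA = (1/T) * integral over the window of (F(t) - F(t_start)) dt, with
    ``F`` the fitted curve (``source="fit"``, default) or the raw samples
    interpolated linearly (``source="samples"``).  ``normalize=False`` returns
    the raw integral in dB*s instead of the time-average in dB.
    """
    T = series.window_length
    if T <= 0:
        raise ValueError("zero-length analysis window")
    if source == "fit":
        a = fit.A * area_factor(fit.k, T)
    elif source == "samples":
        t = series.window_times
        y = series.window_intensities
        a = float(np.trapezoid(y - y[0], t)) / T
    else:
        raise ValueError(f"unknown AREA source {source!r}")
    return a * T if not normalize else a


def washout_flag(lesion_area: float, cutoff: float = DEFAULT_WASHOUT_CUTOFF_DB) -> bool:
    """True iff the lesion AREA is at or below the cutoff (washout present)."""
    if not (math.isfinite(lesion_area) and math.isfinite(cutoff)):
        raise ValueError("lesion_area and cutoff must be finite")
    return lesion_area <= cutoff


def fit_washout(series: TICSeries, k_max: float = K_MAX, area_source: str = "fit") -> WashoutFit:
    """Least-squares fit of the washout model to the windowed samples.

    Deterministic: a single trust-region run from the heuristic start
    (A0 = first - last, B0 = last, k0 = 2/T) with k constrained to
    [0, ``k_max``].  If the optimiser fails, the best-effort parameters are
    returned with ``converged=False``.  The nested constant model (A=0) is
    always evaluated and used whenever it is at least as good, so the fit MSE
    never exceeds the variance of the samples, and an exactly flat series
    yields A=0 with k tie-broken to 0.
    """
    tau_abs = series.window_times
    y = series.window_intensities
    if len(y) < 4:
        raise ValueError("need at least 4 samples in the analysis window")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensities in the analysis window")
    tau = tau_abs - tau_abs[0]
    T = float(tau[-1])

    B_const = float(np.mean(y))
    mse_const = float(np.mean((y - B_const) ** 2))

    converged = True
    if np.ptp(y) == 0.0:
        A, k, B, mse = 0.0, 0.0, float(y[0]), 0.0
    else:
        p0 = (float(y[0] - y[-1]), min(2.0 / T, 0.5 * k_max), float(y[-1]))
        try:
            popt, _ = curve_fit(
                _model,
                tau,
                y,
                p0=p0,
                bounds=([-np.inf, 0.0, -np.inf], [np.inf, k_max, np.inf]),
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
                maxfev=20000,
            )
            A, k, B = (float(v) for v in popt)
        except RuntimeError:
            A, k, B = p0
            converged = False
        mse = float(np.mean((_model(tau, A, k, B) - y) ** 2))
        if mse > mse_const:  # constant model is nested; never do worse
            A, k, B, mse = 0.0, 0.0, B_const, mse_const

    fit = WashoutFit(
        A=A,
        B=B,
        k=k,
        gradient0=-A * k,
        t_to_peak=time_to_peak(series),
        area=float("nan"),
        mse=mse,
        converged=converged,
    )
    area = compute_area(fit, series, source=area_source)
    return WashoutFit(
        A=A,
        B=B,
        k=k,
        gradient0=-A * k,
        t_to_peak=fit.t_to_peak,
        area=area,
        mse=mse,
        converged=converged,
    )


def find_crossing(
    lesion_fit: WashoutFit,
    parenchyma_fit: WashoutFit,
    window: tuple[float, float],
    n_grid: int = 513,
) -> Optional[float]:
    """First time (window-relative) at which the two fitted curves cross, or None.

    A crossing is a sign change of the curve difference, located by bisection.
    """
    lo, hi = window
    if not hi > lo:
        raise ValueError("window must have positive length")
    tau = np.linspace(lo, hi, n_grid)
    d = lesion_fit.curve(tau) - parenchyma_fit.curve(tau)
    sign = np.sign(d)
    for i in range(len(tau) - 1):
        if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
            f = lambda t: float(lesion_fit.curve(t) - parenchyma_fit.curve(t))
            return float(brentq(f, tau[i], tau[i + 1]))
        if sign[i] != 0 and sign[i + 1] == 0 and i + 2 < len(tau):
            # grazing zero: count as crossing only if the sign flips beyond it
            j = i + 1
            while j < len(tau) and sign[j] == 0:
                j += 1
            if j < len(tau) and sign[j] != sign[i]:
                return float(tau[i + 1])
    return None


def curves_intersect(
    lesion_fit: WashoutFit,
    parenchyma_fit: WashoutFit,
    window: tuple[float, float],
) -> bool:
    """Whether the fitted lesion and parenchyma curves cross within the window.

    A qualitative secondary washout indicator: a lesion that starts above the
    parenchyma and dips below it in the late phase is washing out.
    """
    return find_crossing(lesion_fit, parenchyma_fit, window) is not None
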