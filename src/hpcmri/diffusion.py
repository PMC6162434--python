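"""Mono-exponential ADC fitting for ¹H and hyperpolarized ¹³C DWI.

The apparent diffusion coefficient is estimated from the decay
S(b) = S₀·exp(−b·ADC).  Neither the ¹H b-set {25, 180, 323, 508} nor the
interleaved ¹³C set {50, 300, 600, 1500, 1000, 2000} s/mm² contains b = 0,
so S₀ is always a free fitted parameter, never the lowest-b signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin


@dataclass(frozen=True)
class DiffusionFit:
    """Result of a single mono-exponential fit."""

    b_values: np.ndarray
    signals: np.ndarray
    s0_hat: float
    adc_hat: float
    r_squared: float
    n_points: int
    clipped: bool  # fitted ADC was negative and clamped to 0


@dataclass(frozen=True)
class AdcMap:
    """Voxelwise ADC grid (mm²/s); NaN outside the mask or on failed fits."""

    values: np.ndarray
    mask: np.ndarray
    nucleus: str = "1H"
    b_values: tuple[float, ...] = ()


def _monoexp(b: np.ndarray, s0: float, adc: float) -> np.ndarray:
    return s0 * np.exp(-b * adc)


class MonoExponentialADC(BaseEstimator, RegressorMixin):
    """Mono-exponential diffusion decay regressor, S(b) = S₀·e^(−b·ADC).

    Parameters
    ----------
    method : {"nonlinear", "loglinear"}
        ``loglinear`` solves ordinary least squares on log S (requires all
        signals > 0); ``nonlinear`` (default) refines by Levenberg–Marquardt
        on the untransformed model, initialized from the log-linear
        solution.  On noiseless data both are exact.
    clip_negative : bool
        Clamp a negative fitted ADC (a noise artifact) to 0, refitting S₀,
        and set ``clipped_``.  Keeps ROI averages free of sign cancellation.

    Attributes (after :meth:`fit`)
    ------------------------------
    adc_ : float       fitted ADC, mm²/s (units of 1/b)
    s0_ : float        fitted zero-b signal
    r_squared_ : float coefficient of determination on the signal scale
    clipped_ : bool
    n_points_ : int
    """

    def __init__(self, method: str = "nonlinear", clip_negative: bool = True):
        self.method = method
        self.clip_negative = clip_negative

    def fit(self, X, y) -> "MonoExponentialADC":
        b = np.asarray(X, dtype=float).reshape(-1)
        s = np.asarray(y, dtype=float).reshape(-1)
        if b.shape != s.shape:
            raise ValueError("b_values and signals must have equal length")
        if np.unique(b).size < 2:
            raise ValueError("need at least 2 distinct b-values")
        if self.method not in ("nonlinear", "loglinear"):
            raise ValueError(f"unknown method {self.method!r}")

        if self.method == "loglinear" and np.any(s <= 0):
            raise ValueError("loglinear fit requires strictly positive signals")

        s0, adc = self._loglinear(b, s)
        if self.method == "nonlinear":
            try:
                (s0, adc), _ = curve_fit(
                    _monoexp, b, s, p0=[s0, adc], maxfev=10000
                )
            except RuntimeError:
                pass  # keep the log-linear solution
        clipped = False
        if adc < 0 and self.clip_negative:
            adc = 0.0
            s0 = float(np.mean(s))
            clipped = True

        resid = s - _monoexp(b, s0, adc)
        ss_tot = float(np.sum((s - s.mean()) ** 2))
        self.adc_ = float(adc)
        self.s0_ = float(s0)
        self.r_squared_ = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        self.clipped_ = clipped
        self.n_points_ = int(b.size)
        return self

    @staticmethod
    def _loglinear(b: np.ndarray, s: np.ndarray) -> tuple[float, float]:
        if np.any(s <= 0):
            # positive-signal subset fallback for nonlinear initialization
            ok = s > 0
            if ok.sum() < 2 or np.unique(b[ok]).size < 2:
                return float(np.max(np.abs(s)) or 1.0), 1e-3
            b, s = b[ok], s[ok]
        slope, intercept = np.polyfit(b, np.log(s), 1)
        return float(np.exp(intercept)), float(-slope)

    def predict(self, X) -> np.ndarray:
        b = np.asarray(X, dtype=float).reshape(-1)
        return _monoexp(b, self.s0_, self.adc_)


def fit_monoexp_adc(
    b_values, signals, method: str = "nonlinear", clip_negative: bool = True
) -> DiffusionFit:
    """Fit S(b) = S₀·e^(−b·ADC) to one signal vector.

    The b-values may be given in acquisition (interleaved, unsorted) order;
    least squares is permutation invariant.
    """
    est = MonoExponentialADC(method=method, clip_negative=clip_negative)
    est.fit(b_values, signals)
    b = np.asarray(b_values, dtype=float).reshape(-1)
    s = np.asarray(signals, dtype=float).reshape(-1)
    return DiffusionFit(
        b_values=b,
        signals=s,
        s0_hat=est.s0_,
        adc_hat=est.adc_,
        r_squared=est.r_squared_,
        n_points=est.n_points_,
        clipped=est.clipped_,
    )


def compute_adc_map(
    stack: np.ndarray,
    b_values,
    mask: np.ndarray,
    method: str = "nonlinear",
    nucleus: str = "1H",
) -> AdcMap:
    """Voxelwise mono-exponential fit inside a mask.

    ``stack`` has shape (n_b, H, W).  Voxels where the fit fails are NaN.
    """
    stack = np.asarray(stack, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    b = np.asarray(b_values, dtype=float).reshape(-1)
    if stack.ndim != 3 or stack.shape[0] != b.size:
        raise ValueError("stack must have shape (n_b, H, W) matching b_values")
    if mask.shape != stack.shape[1:]:
        raise ValueError("mask shape does not match stack grid")
    if not mask.any():
        raise ValueError("empty mask")
    values = np.full(mask.shape, np.nan)
    for i, j in zip(*np.nonzero(mask)):
        try:
            values[i, j] = fit_monoexp_adc(b, stack[:, i, j], method=method).adc_hat
        except (ValueError, RuntimeError):
            pass  # leave NaN
    return AdcMap(values=values, mask=mask, nucleus=nucleus, b_values=tuple(b))


def roi_mean_adc(adc_map: AdcMap, roi: np.ndarray) -> float:
    """Arithmetic mean ADC over the defined voxels of an ROI (map-then-mean)."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != adc_map.values.shape:
        raise ValueError("ROI shape does not match map")
    if np.any(roi & ~adc_map.mask):
        raise ValueError("ROI extends outside the fitted mask")
    vals = adc_map.values[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no fitted voxels")
    return float(vals.mean())


def roi_mean_then_fit(
    stack: np.ndarray, b_values, roi: np.ndarray, method: str = "nonlinear"
) -> DiffusionFit:
    """Low-SNR alternative: average the ROI signal per b-value, then fit once."""
    stack = np.asarray(stack, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    signals = stack[:, roi].mean(axis=1)
    return fit_monoexp_adc(b_values, signals, method=method)
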