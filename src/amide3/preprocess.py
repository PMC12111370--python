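"""Spectral pre-treatment: Savitzky-Golay smoothing, asymmetric least squares
baseline correction and band cropping.

The processing chain mirrors standard FTIR practice for biofluid spectra:
smooth with a local polynomial, track the underside of the trace with an
asymmetrically weighted penalized smoother to estimate the baseline, subtract
it and restrict the result to the Amide III band.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.signal import savgol_filter

from .spectrum import Spectrum

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessParams:
    """Tunable parameters of the pre-treatment chain.

    sg_window/sg_order: Savitzky-Golay window (points, odd) and polynomial
    order.  als_lambda: smoothness penalty of the baseline (larger = stiffer;
    10^6 suits cm^-1-gridded FTIR).  als_p: asymmetry factor -- points above
    the baseline get weight p, points below 1-p; p << 0.5 makes the smoother
    hug the underside of peaks.  als_threshold: relative-change convergence
    criterion.  band: retained wavenumber range, cm^-1.
    """

    sg_window: int = 25
    sg_order: int = 2
    als_lambda: float = 1e6
    als_p: float = 0.001
    als_threshold: float = 0.01
    als_max_iter: int = 50
    band: tuple[float, float] = (1185.0, 1330.0)

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and greater than sg_order")
        if not 0.0 < self.als_p < 1.0:
            raise ValueError("als_p must lie in (0, 1)")
        if self.als_lambda <= 0:
            raise ValueError("als_lambda must be positive")
        if self.band[0] >= self.band[1]:
            raise ValueError("band must satisfy low < high")


def savitzky_golay(
    spectrum: Spectrum,
    window: int = 25,
    order: int = 2,
    deriv: int = 0,
) -> Spectrum:
    """Least-squares local-polynomial smoothing (optionally a derivative).

    Boundary points are handled by fitting the polynomial to the truncated
    window (no reflection), so cropped-band analysis is unaffected by
    out-of-band content.  For `deriv` > 0 the trace is differentiated with
    respect to wavenumber (requires a uniform grid).
    """
    if len(spectrum) < window:
        raise ValueError(
            f"spectrum has {len(spectrum)} points, shorter than window {window}"
        )
    if deriv > 0 and not spectrum.is_uniform():
        raise ValueError("derivative smoothing requires a uniform wavenumber grid")
    delta = spectrum.step if deriv > 0 else 1.0
    y = savgol_filter(
        spectrum.absorbance, window, order, deriv=deriv, delta=delta, mode="interp"
    )
    return spectrum.with_absorbance(y)


class ALSResult(NamedTuple):
    """Baseline-correction output; unpacks as (baseline, corrected)."""

    baseline: Spectrum
    corrected: Spectrum
    n_iter: int
    converged: bool
    objective: tuple[float, ...]


def als_baseline(spectrum: Spectrum, params: PreprocessParams | None = None) -> ALSResult:
    """Asymmetric least squares baseline estimate.

    The baseline z minimizes sum_i w_i (y_i - z_i)^2 + lambda * sum (d2 z)^2
    with w_i = p where y_i > z_i and 1 - p otherwise, iterating the weights
    until the relative change in z (or an unchanged weight vector) falls
    below `als_threshold`.  Non-convergence within `als_max_iter` produces a
    warning and returns the last iterate.
    """
    params = params or PreprocessParams()
    y = spectrum.absorbance
    n = y.size
    if n < 4:
        raise ValueError("baseline correction needs at least 4 points")
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n)).tocsc()
    penalty = params.als_lambda * (D.T @ D)
    w = np.ones(n)
    z = np.zeros(n)
    objective: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.als_max_iter + 1):
        W = sparse.diags(w)
        z_new = spsolve((W + penalty).tocsc(), w * y)
        objective.append(
            float(np.sum(w * (y - z_new) ** 2) + params.als_lambda * np.sum(np.diff(z_new, 2) ** 2))
        )
        w_new = np.where(y > z_new, params.als_p, 1.0 - params.als_p)
        z = z_new
        # converged when the asymmetric weights have stabilized: fewer than
        # a `als_threshold` fraction of points switch side of the baseline
        flip_frac = float(np.mean(w_new != w))
        if it >= 2 and flip_frac < params.als_threshold:
            w = w_new
            converged = True
            break
        w = w_new
    if not converged:
        warnings.warn(
            f"ALS baseline did not converge within {params.als_max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
        log.warning("ALS non-convergence after %d iterations; returning last iterate", it)
    baseline = spectrum.with_absorbance(z)
    corrected = spectrum.with_absorbance(y - z)
    return ALSResult(baseline, corrected, it, converged, tuple(objective))


def crop_band(
    spectrum: Spectrum,
    low: float = 1185.0,
    high: float = 1330.0,
) -> Spectrum:
    """Restrict a spectrum to [low, high] cm^-1 (inclusive, order preserved)."""
    if low > high:
        raise ValueError("crop bounds must satisfy low <= high")
    mask = (spectrum.wavenumbers >= low) & (spectrum.wavenumbers <= high)
    if not mask.any():
        raise ValueError(
            f"band [{low}, {high}] does not overlap spectrum support "
            f"[{spectrum.wavenumbers[0]}, {spectrum.wavenumbers[-1]}]"
        )
    return Spectrum(
        spectrum.wavenumbers[mask],
        spectrum.absorbance[mask],
        sample_id=spectrum.sample_id,
        portion_id=spectrum.portion_id,
    )


def preprocess(spectrum: Spectrum, params: PreprocessParams | None = None) -> Spectrum:
    """Full chain: smooth, baseline-correct over the full range, then crop."""
    params = params or PreprocessParams()
    smoothed = savitzky_golay(spectrum, params.sg_window, params.sg_order)
    _, corrected, *_ = als_baseline(smoothed, params)
    return crop_band(corrected, *params.band)
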