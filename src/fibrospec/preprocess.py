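"""Spectral preprocessing chain.

The chain applied before any modelling is: truncation to the
biofingerprint region (900-1,800 cm^-1), Savitzky-Golay smoothing,
automatic weighted least squares (AWLS) baseline correction, and vector
normalisation — in exactly that order.  Truncation discards regions
dominated by water; smoothing removes random detector noise; the
iteratively reweighted polynomial baseline removes drift common in
biological ATR measurements; normalising each spectrum to unit Euclidean
norm cancels multiplicative effects of sample thickness / contact
pressure.  The full chain is exactly invariant to multiplying any input
row by a positive constant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .dataset import SpectrumSet
from .exceptions import ConfigurationError, DegenerateSpectrumError

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain (all configurable; the
    smoothing window/order and baseline order are package defaults chosen
    for mild smoothing at 4 cm^-1 spacing)."""

    lo: float = 900.0
    hi: float = 1800.0
    sg_window: int = 9
    sg_order: int = 2
    awls_order: int = 2
    awls_max_iter: int = 50
    awls_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ConfigurationError("lo/hi: require lo < hi")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ConfigurationError("sg_window: must be odd and > sg_order")
        if self.awls_order < 0:
            raise ConfigurationError("awls_order: must be >= 0")
        if self.awls_tol <= 0:
            raise ConfigurationError("awls_tol: must be > 0")


def truncate(spectra: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Retain the columns with lo <= wavenumber <= hi (closed interval)."""
    mask = (spectra.axis >= lo) & (spectra.axis <= hi)
    if not mask.any():
        raise ValueError(f"truncation [{lo}, {hi}] does not overlap the axis")
    return spectra.with_absorbance(spectra.absorbance[:, mask], axis=spectra.axis[mask])


def savitzky_golay(spectra: SpectrumSet, window: int, order: int) -> SpectrumSet:
    """Savitzky-Golay least-squares smoothing along the wavenumber axis.

    Edge points are handled by evaluating the polynomial fitted over the
    window anchored at the spectrum end (asymmetric about the evaluated
    point), not by padding.
    """
    if window % 2 == 0 or window <= order:
        raise ValueError("window must be odd and > order")
    if window > spectra.n_points:
        raise ValueError(f"window {window} exceeds row length {spectra.n_points}")
    steps = np.diff(spectra.axis)
    if steps.size and (steps.max() - steps.min()) > 1e-6 * steps.mean():
        raise ValueError("Savitzky-Golay requires a uniformly spaced axis")
    if spectra.n_rows == 0:
        return spectra.with_absorbance(spectra.absorbance)
    smoothed = savgol_filter(spectra.absorbance, window, order, axis=1, mode="interp")
    return spectra.with_absorbance(smoothed)


def awls_baseline(
    spectra: SpectrumSet,
    order: int = 2,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> SpectrumSet:
    """Automatic weighted least squares baseline correction.

    Per row, a degree-`order` polynomial is fitted by iteratively
    reweighted least squares: points above the current fit (peaks) have
    their weight driven to a small floor (1e-3, kept for conditioning)
    while points at or below keep weight 1, so the fit settles under the
    peaks; iteration stops when the baseline's maximum relative change
    falls below `tol` or after `max_iter` iterations (a warning is issued
    and the last iterate used).  The final baseline is subtracted.
    """
    if spectra.n_points <= order + 1:
        raise ValueError(f"row length {spectra.n_points} must exceed order+1 = {order + 1}")
    t = np.linspace(-1.0, 1.0, spectra.n_points)
    V = np.polynomial.polynomial.polyvander(t, order)
    out = np.empty_like(spectra.absorbance)
    for i in range(spectra.n_rows):
        y = spectra.absorbance[i]
        out[i] = y - _awls_single(y, V, max_iter, tol)
    return spectra.with_absorbance(out)


_WEIGHT_FLOOR = 1e-3


def _awls_single(y: np.ndarray, V: np.ndarray, max_iter: int, tol: float) -> np.ndarray:
    w = np.ones_like(y)
    baseline = np.zeros_like(y)
    for _ in range(max_iter):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(V * sw[:, None], y * sw, rcond=None)
        new_baseline = V @ coef
        delta = np.abs(new_baseline - baseline).max()
        scale = np.abs(new_baseline).max()
        baseline = new_baseline
        if delta <= tol * max(scale, np.finfo(float).tiny):
            break
        w = np.where(y > baseline, _WEIGHT_FLOOR, 1.0)
    else:
        warnings.warn(
            f"AWLS baseline did not converge within {max_iter} iterations; "
            "using last iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return baseline


def vector_normalize(spectra: SpectrumSet) -> SpectrumSet:
    """Scale each row to unit Euclidean norm."""
    norms = np.linalg.norm(spectra.absorbance, axis=1)
    zero = np.nonzero(norms == 0)[0]
    if zero.size:
        sid = spectra.sample_id[zero[0]]
        raise DegenerateSpectrumError(f"sample {sid} has an all-zero spectrum")
    return spectra.with_absorbance(spectra.absorbance / norms[:, None])


def preprocess_pipeline(spectra: SpectrumSet, config: PreprocessConfig | None = None) -> SpectrumSet:
    """Full chain: truncate -> Savitzky-Golay -> AWLS baseline -> vector norm."""
    config = config or PreprocessConfig()
    logger.info("truncating to [%g, %g] cm^-1", config.lo, config.hi)
    out = truncate(spectra, config.lo, config.hi)
    logger.info("Savitzky-Golay smoothing (window=%d, order=%d)", config.sg_window, config.sg_order)
    out = savitzky_golay(out, config.sg_window, config.sg_order)
    logger.info("AWLS baseline correction (order=%d)", config.awls_order)
    out = awls_baseline(out, config.awls_order, config.awls_max_iter, config.awls_tol)
    if out.n_rows == 0:
        logger.info("empty spectrum set; skipping normalisation")
        return out
    logger.info("vector normalisation")
    return vector_normalize(out)
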