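"""Multitaper spectral estimation, normalization, and aperiodic modelling.

Power spectral densities use Thomson's multitaper method with 1-second
consecutive non-overlapping windows, a +/- 2 Hz half-bandwidth and three
Slepian tapers (NW = 2, 2NW - 1 = 3), evaluated on a 1-Hz grid from 4 to
110 Hz.  Spectra are normalized to total power excluding line-noise bins,
then the aperiodic 1/f-with-knee background

    log10 P(f) = b - log10(k + f**chi)

is fitted in semi-log space and subtracted, leaving aperiodic-adjusted
spectra on which band powers and downstream maps are computed.
Magnitude-squared coherence is estimated from taper- and window-averaged
auto- and cross-spectra with the same settings.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import optimize
from scipy.signal.windows import dpss

from .types import AperiodicFit, BipolarRecording, CoherenceSpectrum, Spectrum, band_bins

#: line-noise exclusion bands for normalization / fitting (Hz, closed)
LINE_EXCLUDE = [(58.0, 62.0)]


def _window_taper_ffts(x: np.ndarray, rate_hz: float, win_s: float,
                       half_bw_hz: float, n_tapers: int) -> tuple[np.ndarray, np.ndarray]:
    """Tapered FFTs of all complete windows: (n_windows, n_tapers, n_freqs)."""
    n_win_samp = int(round(win_s * rate_hz))
    n_windows = x.shape[-1] // n_win_samp
    if n_windows < 1:
        raise ValueError("recording shorter than one analysis window")
    nw = win_s * half_bw_hz
    tapers = dpss(n_win_samp, nw, Kmax=n_tapers)  # (n_tapers, n_win_samp), unit energy
    segs = x[..., :n_windows * n_win_samp].reshape(*x.shape[:-1], n_windows, n_win_samp)
    tapered = segs[..., None, :] * tapers  # (..., n_windows, n_tapers, n_win_samp)
    fft = np.fft.rfft(tapered, axis=-1)
    freqs = np.fft.rfftfreq(n_win_samp, 1.0 / rate_hz)
    return fft, freqs


def _grid_indices(freqs_full: np.ndarray, f_lo: float, f_hi: float) -> tuple[np.ndarray, np.ndarray]:
    grid = np.arange(float(np.ceil(f_lo)), float(np.floor(f_hi)) + 1.0)
    idx = np.array([int(np.argmin(np.abs(freqs_full - f))) for f in grid])
    return idx, grid


def multitaper_psd(rec: BipolarRecording | np.ndarray, channel: int | None = None,
                   rate_hz: float | None = None, win_s: float = 1.0,
                   half_bw_hz: float = 2.0, n_tapers: int = 3,
                   f_lo: float = 4.0, f_hi: float = 110.0) -> Spectrum:
    """Multitaper PSD of one channel on the 1-Hz analysis grid.

    Accepts either a :class:`BipolarRecording` plus channel index, or a 1-D
    sample array plus ``rate_hz``.  Incomplete trailing windows are dropped.
    """
    if isinstance(rec, BipolarRecording):
        if channel is None:
            raise ValueError("channel index required for a BipolarRecording")
        x = rec.samples[channel]
        fs = rec.rate_hz
    else:
        x = np.asarray(rec, dtype=float)
        if rate_hz is None:
            raise ValueError("rate_hz required for a plain array")
        fs = float(rate_hz)
    if fs < 2 * f_hi:
        raise ValueError("sampling rate below twice the highest analysis frequency")
    fft, freqs_full = _window_taper_ffts(x, fs, win_s, half_bw_hz, n_tapers)
    # one-sided PSD, unit-energy tapers: S = 2|X|^2 / fs
    psd = (2.0 / fs) * (np.abs(fft) ** 2)
    psd = psd.mean(axis=(0, 1))  # average tapers and windows
    idx, grid = _grid_indices(freqs_full, f_lo, f_hi)
    return Spectrum(grid, psd[idx], normalized=False, aperiodic_adjusted=False,
                    n_windows=fft.shape[0])


def normalize_spectrum(spec: Spectrum, exclude: list[tuple[float, float]] | None = None
                       ) -> Spectrum:
    """Normalize to total power over the grid, excluding line-noise bins.

    The returned values sum to 1 over the non-excluded bins.
    """
    if spec.normalized:
        raise ValueError("spectrum already normalized")
    exclude = LINE_EXCLUDE if exclude is None else exclude
    keep = np.ones(spec.freqs.size, dtype=bool)
    for lo, hi in exclude:
        keep &= ~((spec.freqs >= lo) & (spec.freqs <= hi))
    total = spec.values[keep].sum()
    if total <= 0:
        raise ValueError("total includable power is zero")
    return Spectrum(spec.freqs, spec.values / total, normalized=True,
                    aperiodic_adjusted=spec.aperiodic_adjusted, n_windows=spec.n_windows)


def _model_log10(freqs: np.ndarray, b: float, k: float, chi: float,
                 knee_form: str) -> np.ndarray:
    if knee_form == "kchi_plus_fchi":
        return b - np.log10(k ** chi + freqs ** chi)
    return b - np.log10(k + freqs ** chi)


def fit_aperiodic(spec: Spectrum, exclude: list[tuple[float, float]] | None = None,
                  knee_form: str = "k_plus_fchi") -> AperiodicFit:
    """Fit the aperiodic model ``log10 P = b - log10(k + f**chi)``.

    Least squares in semi-log space over the non-excluded grid bins, with
    bounds k >= 0 and 0 < chi <= 10, from a small grid of knee/exponent
    starting points.  A second robust pass masks bins whose positive
    residual exceeds one SD of the first-pass residuals (narrowband peaks)
    and refits on the rest.
    """
    exclude = LINE_EXCLUDE if exclude is None else exclude
    keep = np.ones(spec.freqs.size, dtype=bool)
    for lo, hi in exclude:
        keep &= ~((spec.freqs >= lo) & (spec.freqs <= hi))
    f = spec.freqs[keep]
    if f.size < 10:
        raise ValueError("need >= 10 non-excluded bins to fit the aperiodic model")
    P = spec.values[keep]
    if np.any(P <= 0):
        raise ValueError("power must be positive at fitted bins")
    logP = np.log10(P)

    # slope in log-log space as exponent guess
    chi0 = (logP[0] - logP[-1]) / (np.log10(f[-1]) - np.log10(f[0]))
    chi0 = float(np.clip(chi0, 0.2, 8.0))

    lb = np.array([-np.inf, 0.0, 1e-3])
    ub = np.array([np.inf, np.inf, 10.0])

    def resid(theta: np.ndarray, ff: np.ndarray, yy: np.ndarray) -> np.ndarray:
        return yy - _model_log10(ff, theta[0], theta[1], theta[2], knee_form)

    def solve(ff: np.ndarray, yy: np.ndarray, starts: list[tuple[float, float]]
              ) -> tuple[np.ndarray, float, bool]:
        best, best_cost, ok = None, np.inf, False
        for k0, c0 in starts:
            b0 = float(np.mean(yy + np.log10(k0 + ff ** c0))) if knee_form == "k_plus_fchi" \
                else float(np.mean(yy + np.log10(k0 ** c0 + ff ** c0)))
            try:
                sol = optimize.least_squares(resid, x0=[b0, k0, c0], args=(ff, yy),
                                             bounds=(lb, ub), method="trf",
                                             xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            if sol.cost < best_cost:
                best, best_cost, ok = sol.x, sol.cost, sol.success
        if best is None:
            return np.array([np.mean(yy), 0.0, 1.0]), np.inf, False
        return best, best_cost, ok

    starts = [(k0, c0) for k0 in (1e-6, 5.0, 30.0, 150.0)
              for c0 in (0.6 * chi0, chi0, 1.6 * chi0)]
    theta, _, ok = solve(f, logP, starts)

    # second pass: mask positive-residual outliers (oscillatory peaks)
    r = resid(theta, f, logP)
    sd = r.std()
    if sd > 0:
        keep2 = r <= sd
        if keep2.sum() >= 10:
            theta2, _, ok2 = solve(f[keep2], logP[keep2],
                                   [(max(theta[1], 1e-6), theta[2])] + starts[:4])
            theta, ok = theta2, ok2
            r = resid(theta, f, logP)
    if not ok:
        warnings.warn("aperiodic fit did not fully converge; returning best effort")
    return AperiodicFit(b=float(theta[0]), k=float(theta[1]), chi=float(theta[2]),
                        fit_range=(float(f[0]), float(f[-1])),
                        residual_rms=float(np.sqrt(np.mean(r ** 2))),
                        converged=bool(ok), knee_form=knee_form)


def remove_aperiodic(spec: Spectrum, fit: AperiodicFit) -> Spectrum:
    """Subtract the fitted aperiodic curve in log10 space.

    Returns ``log10(power) - (b - log10(k + f**chi))`` per bin; values may
    be negative and the ``aperiodic_adjusted`` flag is set.
    """
    if spec.aperiodic_adjusted:
        raise ValueError("spectrum already aperiodic-adjusted")
    if np.any(spec.values <= 0):
        raise ValueError("power must be positive to take log10")
    vals = np.log10(spec.values) - fit.curve(spec.freqs)
    return Spectrum(spec.freqs, vals, normalized=spec.normalized,
                    aperiodic_adjusted=True, n_windows=spec.n_windows)


def restore_aperiodic(spec: Spectrum, fit: AperiodicFit) -> Spectrum:
    """Inverse of :func:`remove_aperiodic` (back to linear power units)."""
    if not spec.aperiodic_adjusted:
        raise ValueError("spectrum is not aperiodic-adjusted")
    vals = 10.0 ** (spec.values + fit.curve(spec.freqs))
    return Spectrum(spec.freqs, vals, normalized=spec.normalized,
                    aperiodic_adjusted=False, n_windows=spec.n_windows)


def band_power(spec: Spectrum, band: str | tuple[float, float]) -> float:
    """Arithmetic mean of spectrum values over the closed band."""
    mask = band_bins(spec.freqs, band)
    return float(spec.values[mask].mean())


def msc_coherence(a: np.ndarray, b: np.ndarray, rate_hz: float, win_s: float = 1.0,
                  half_bw_hz: float = 2.0, n_tapers: int = 3,
                  f_lo: float = 4.0, f_hi: float = 110.0,
                  pair: tuple[str, str] = ("a", "b")) -> CoherenceSpectrum:
    """Magnitude-squared coherence from multitaper cross-spectra.

    msc(f) = |Sxy|^2 / (Sxx Syy) with auto-/cross-spectra averaged over all
    tapers and complete windows; a warning is issued below 30 windows, where
    the estimator bias is substantial.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channels must have equal length")
    fa, freqs_full = _window_taper_ffts(a, rate_hz, win_s, half_bw_hz, n_tapers)
    fb, _ = _window_taper_ffts(b, rate_hz, win_s, half_bw_hz, n_tapers)
    n_windows = fa.shape[0]
    if n_windows < 30:
        warnings.warn(f"only {n_windows} windows; coherence estimates will be biased high")
    sxx = (np.abs(fa) ** 2).mean(axis=(0, 1))
    syy = (np.abs(fb) ** 2).mean(axis=(0, 1))
    sxy = (fa * np.conj(fb)).mean(axis=(0, 1))
    idx, grid = _grid_indices(freqs_full, f_lo, f_hi)
    sxx, syy, sxy = sxx[idx], syy[idx], sxy[idx]
    if np.any(sxx == 0) or np.any(syy == 0):
        raise ValueError("zero auto-spectrum at some analysis bin")
    msc = (np.abs(sxy) ** 2) / (sxx * syy)
    return CoherenceSpectrum(grid, np.clip(msc, 0.0, 1.0), pair=pair, n_windows=n_windows)


def coherence_matrix(primary: BipolarRecording, partner: BipolarRecording,
                     **kw) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs msc array (n_primary, n_partner, n_freqs) plus the grid."""
    if primary.rate_hz != partner.rate_hz:
        raise ValueError("rate mismatch between montages")
    first = None
    out = None
    for i in range(primary.n_channels):
        for j in range(partner.n_channels):
            cs = msc_coherence(primary.samples[i], partner.samples[j], primary.rate_hz,
                               pair=(primary.labels[i], partner.labels[j]), **kw)
            if out is None:
                first = cs.freqs
                out = np.empty((primary.n_channels, partner.n_channels, cs.freqs.size))
            out[i, j] = cs.msc
    return out, first
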