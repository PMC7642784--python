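"""Spectral SNR estimation and signal/bias/noise decomposition.

Half-pair cross-correlation estimators. Writing each noisy half as
x = s + n with noise independent between halves, the ring-averaged real
cross spectrum of the two halves estimates the signal power S(k), and the
half power spectrum minus that cross term estimates the noise power N(k).
The Fourier ring correlation relates to the spectral SNR through
SSNR = FRC/(1 − FRC).

For denoised halves y = f(x) produced by applying the SAME operator
independently to each half, three cross spectra separate three components:

* C_nn = ⟨Re X_e X̄_o⟩      — signal power in the noisy halves,
* C_dn = ½⟨Re Y_e X̄_o + Re Y_o X̄_e⟩ — covariance of denoised output with
  the signal (only signal survives: the denoised half shares nothing else
  with the opposite noisy half),
* C_dd = ⟨Re Y_e Ȳ_o⟩      — everything the two denoised halves share:
  retained signal plus the correlated "false signal" (bias) the operator
  invents.

From these, retained signal power = C_dn²/C_nn (the part of the shared
denoised power explained by the true signal), bias = C_dd − C_dn²/C_nn, and
residual noise = P_y − C_dd. Scalar SNR and SNBR are ring-population-weighted
sums excluding the DC ring; SNBR = signal/(noise + bias) measures the power
of true signal against everything else in the denoised image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HalfPair, Micrograph
from .spectral import RingGrid, SpectralCurve

__all__ = [
    "frc",
    "ssnr_from_frc",
    "cross_corr_snr",
    "decompose",
    "snr_report",
    "SpectralDecomposition",
]

_EPS = 1e-6


def frc(a: Micrograph, b: Micrograph, grid: RingGrid | None = None) -> SpectralCurve:
    """Fourier ring correlation between two images.

    Per ring: Σ Re(A·conj(B)) / sqrt(Σ|A|² · Σ|B|²) over independent
    coefficients. Values lie in [−1, 1]; the DC ring is reported but carries
    only the (always fully correlated) mean term.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if grid is None:
        grid = RingGrid(a.shape, a.pixel_size)
    fa = np.fft.rfft2(a.pixels)
    fb = np.fft.rfft2(b.pixels)
    num = grid.ring_sum(np.real(fa * np.conj(fb)))
    pa = grid.ring_sum(np.abs(fa) ** 2)
    pb = grid.ring_sum(np.abs(fb) ** 2)
    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(denom > 0, num / np.maximum(denom, 1e-300), np.nan)
    return SpectralCurve(grid.freq, vals, grid.counts)


def ssnr_from_frc(c: SpectralCurve) -> SpectralCurve:
    """Spectral SNR from an FRC curve: SSNR = FRC/(1 − FRC).

    FRC is clamped to [0, 1 − 1e−6] first, so negative correlations map to
    SSNR 0 and perfect correlation to a large finite value.
    """
    f = np.clip(c.value, 0.0, 1.0 - _EPS)
    return SpectralCurve(c.freq, f / (1.0 - f), c.n)


def cross_corr_snr(a: Micrograph, b: Micrograph) -> float:
    """Real-space cross-correlation SNR estimate from one image pair.

    SNR = ρ/(1 − ρ) with ρ the Pearson correlation of the mean-subtracted
    images; the classical whole-image estimator for two noisy copies of one
    signal. Returns +inf when ρ reaches the clamp boundary (e.g. a == b).
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    x = a.pixels.astype(np.float64).ravel()
    y = b.pixels.astype(np.float64).ravel()
    x = x - x.mean()
    y = y - y.mean()
    sx, sy = np.linalg.norm(x), np.linalg.norm(y)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    rho = float(np.dot(x, y) / (sx * sy))
    if rho >= 1.0 - _EPS:
        return float("inf")
    return max(rho, 0.0) / (1.0 - max(rho, 0.0))


@dataclass
class SpectralDecomposition:
    """Per-ring signal/bias/noise powers and scalar summaries.

    All powers are ring means of Fourier power (clamped at 0); scalars are
    ring-population-weighted ratios excluding the DC ring.
    """

    signal_noisy: SpectralCurve
    noise_noisy: SpectralCurve
    signal_denoised: SpectralCurve
    bias: SpectralCurve
    noise_denoised: SpectralCurve
    snr_noisy: float
    snr_denoised: float
    snbr: float
    name: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "freq_invA": self.signal_noisy.freq,
                "signal_noisy": self.signal_noisy.value,
                "noise_noisy": self.noise_noisy.value,
                "signal_denoised": self.signal_denoised.value,
                "bias": self.bias.value,
                "noise_denoised": self.noise_denoised.value,
                "n_coeffs": self.signal_noisy.n,
            }
        )


def decompose(
    noisy: HalfPair, denoised: HalfPair, grid: RingGrid | None = None
) -> SpectralDecomposition:
    """Separate signal, bias and residual noise of a denoised half-pair.

    ``denoised`` must be the same operator applied independently to each
    member of ``noisy``. Per-ring estimates follow the extended
    cross-correlation scheme described in the module docstring; negative
    power estimates are clamped to zero before the scalar sums.
    """
    shapes = {noisy.even.shape, noisy.odd.shape, denoised.even.shape, denoised.odd.shape}
    if len(shapes) != 1:
        raise ValueError(f"all four images must share one shape, got {shapes}")
    if grid is None:
        grid = RingGrid(noisy.even.shape, noisy.even.pixel_size)
    xe = np.fft.rfft2(noisy.even.pixels)
    xo = np.fft.rfft2(noisy.odd.pixels)
    ye = np.fft.rfft2(denoised.even.pixels)
    yo = np.fft.rfft2(denoised.odd.pixels)

    c_nn = grid.ring_mean(np.real(xe * np.conj(xo)))
    c_dn = 0.5 * (
        grid.ring_mean(np.real(ye * np.conj(xo))) + grid.ring_mean(np.real(yo * np.conj(xe)))
    )
    c_dd = grid.ring_mean(np.real(ye * np.conj(yo)))
    p_x = 0.5 * (grid.ring_mean(np.abs(xe) ** 2) + grid.ring_mean(np.abs(xo) ** 2))
    p_y = 0.5 * (grid.ring_mean(np.abs(ye) ** 2) + grid.ring_mean(np.abs(yo) ** 2))

    # raw (unclamped) per-ring estimates; the estimators are unbiased only in
    # this form, so the scalar ratios are computed from them. The reported
    # curves are clamped at 0 afterwards (powers are non-negative).
    signal_noisy = c_nn
    noise_noisy = p_x - c_nn
    denom = np.maximum(c_nn, _EPS * p_x)
    with np.errstate(invalid="ignore", divide="ignore"):
        signal_denoised = np.where(denom > 0, c_dn**2 / np.maximum(denom, 1e-300), 0.0)
    bias = c_dd - signal_denoised
    noise_denoised = p_y - c_dd

    counts = grid.counts
    w = counts.astype(float).copy()
    w[0] = 0.0  # DC ring excluded from all scalar summaries
    sum_w = lambda v: float(np.nansum(w * v))  # noqa: E731
    s_n, n_n = max(sum_w(signal_noisy), 0.0), max(sum_w(noise_noisy), 0.0)
    s_d, n_d = max(sum_w(signal_denoised), 0.0), max(sum_w(noise_denoised), 0.0)
    b_d = max(sum_w(bias), 0.0)
    ratio = lambda a, b: a / b if b > 0 else (float("inf") if a > 0 else 0.0)  # noqa: E731
    snr_noisy = ratio(s_n, n_n)
    snr_denoised = ratio(s_d, n_d)
    snbr = ratio(s_d, b_d + n_d)
    clip = lambda v: np.clip(v, 0.0, None)  # noqa: E731
    return SpectralDecomposition(
        signal_noisy=SpectralCurve(grid.freq, clip(signal_noisy), counts),
        noise_noisy=SpectralCurve(grid.freq, clip(noise_noisy), counts),
        signal_denoised=SpectralCurve(grid.freq, clip(signal_denoised), counts),
        bias=SpectralCurve(grid.freq, clip(bias), counts),
        noise_denoised=SpectralCurve(grid.freq, clip(noise_denoised), counts),
        snr_noisy=snr_noisy,
        snr_denoised=snr_denoised,
        snbr=snbr,
        name=noisy.name,
    )


def snr_report(
    decomps: list[SpectralDecomposition],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize decompositions across a data set.

    Returns ``(scalars, curves)``: per-micrograph scalar SNR/SNBR rows with a
    mean/std footer, and mean per-ring power curves with their standard
    deviations across micrographs.
    """
    if not decomps:
        raise ValueError("at least one decomposition is required")
    scalars = pd.DataFrame(
        {
            "micrograph": [d.name for d in decomps],
            "snr_noisy": [d.snr_noisy for d in decomps],
            "snr_denoised": [d.snr_denoised for d in decomps],
            "snbr": [d.snbr for d in decomps],
        }
    )
    stats = scalars[["snr_noisy", "snr_denoised", "snbr"]]
    summary = pd.DataFrame(
        {
            "micrograph": ["mean", "std"],
            "snr_noisy": [stats["snr_noisy"].mean(), stats["snr_noisy"].std(ddof=0)],
            "snr_denoised": [stats["snr_denoised"].mean(), stats["snr_denoised"].std(ddof=0)],
            "snbr": [stats["snbr"].mean(), stats["snbr"].std(ddof=0)],
        }
    )
    scalars = pd.concat([scalars, summary], ignore_index=True)

    freq = decomps[0].signal_noisy.freq
    curves = {"freq_invA": freq}
    for field in ("signal_noisy", "noise_noisy", "signal_denoised", "bias", "noise_denoised"):
        stack = np.stack([getattr(d, field).value for d in decomps])
        curves[f"{field}_mean"] = np.nanmean(stack, axis=0)
        curves[f"{field}_std"] = np.nanstd(stack, axis=0)
    return scalars, pd.DataFrame(curves)
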