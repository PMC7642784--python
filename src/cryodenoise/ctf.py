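"""Contrast transfer function evaluation and phase flipping.

The CTF of a defocused bright-field electron image is an oscillatory,
sine-like function of spatial frequency. Its sign alternates between zeros,
so frequency bands of a micrograph carry alternately inverted contrast.
Phase flipping multiplies the image's Fourier transform by the sign of the
CTF, giving every band consistently signed contrast without touching
amplitudes.

Conventions (CTFFIND-style): positive defocus means underfocus, and the
overall sign is chosen so that low-frequency contrast is negative,

    CTF(k, θ) = −[ (1 − A²)^{1/2} sin χ + A cos χ ],
    χ(k, θ)  = π λ k² Δf(θ) − (π/2) Cs λ³ k⁴ + φ,
    Δf(θ)    = ½ [df_u + df_v + (df_u − df_v) cos 2(θ − α)],

with k in 1/Å, λ the relativistic electron wavelength in Å, Δf in Å, Cs in Å
(converted from mm), A the amplitude contrast fraction and φ an additional
phase shift (e.g. from a phase plate). Coherence envelopes and detector MTF
are deliberately not modelled: only the sign of the oscillation is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # avoid a circular import at runtime
    from .io import Micrograph

__all__ = ["CtfParams", "electron_wavelength", "ctf_2d", "phase_flip"]

_MM_TO_A = 1.0e7


@dataclass(frozen=True)
class CtfParams:
    """Microscope and defocus parameters defining a 2-D CTF.

    defocus_u/defocus_v are the defocus along the major/minor astigmatism
    axes in Å (positive = underfocus); astig_angle is the azimuth of the
    major axis in radians; voltage in kV; cs (spherical aberration) in mm;
    amplitude_contrast is a dimensionless fraction in [0, 1); phase_shift is
    an additional phase in radians.

    On construction defocus_u >= defocus_v is normalized by swapping the two
    values and rotating the angle by π/2 when violated.
    """

    defocus_u: float
    defocus_v: float
    astig_angle: float = 0.0
    voltage: float = 300.0
    cs: float = 2.7
    amplitude_contrast: float = 0.07
    phase_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.defocus_u < self.defocus_v:
            du, dv = self.defocus_v, self.defocus_u
            object.__setattr__(self, "defocus_u", du)
            object.__setattr__(self, "defocus_v", dv)
            object.__setattr__(self, "astig_angle", self.astig_angle + math.pi / 2)
        if not self.voltage > 0:
            raise ValueError(f"voltage must be positive, got {self.voltage}")
        if self.cs < 0:
            raise ValueError(f"cs must be non-negative, got {self.cs}")
        if not 0 <= self.amplitude_contrast < 1:
            raise ValueError(
                f"amplitude_contrast must be in [0, 1), got {self.amplitude_contrast}"
            )


def electron_wavelength(voltage: float) -> float:
    """Relativistic electron wavelength in Å for an accelerating voltage in kV.

    λ = 12.2639 / sqrt(V + 0.97845e−6 V²) with V in volts; ≈0.0197 Å at 300 kV.
    """
    if not voltage > 0:
        raise ValueError(f"voltage must be positive, got {voltage}")
    v = voltage * 1.0e3
    return 12.2639 / math.sqrt(v + 0.97845e-6 * v * v)


def ctf_1d(params: CtfParams, k: np.ndarray, azimuth: float = 0.0) -> np.ndarray:
    """Evaluate the CTF along one azimuth for frequency magnitudes ``k`` (1/Å)."""
    k = np.asarray(k, dtype=float)
    lam = electron_wavelength(params.voltage)
    cs_a = params.cs * _MM_TO_A
    dfu, dfv = params.defocus_u, params.defocus_v
    df = 0.5 * (dfu + dfv + (dfu - dfv) * math.cos(2.0 * (azimuth - params.astig_angle)))
    chi = (
        math.pi * lam * df * k**2
        - 0.5 * math.pi * cs_a * lam**3 * k**4
        + params.phase_shift
    )
    a = params.amplitude_contrast
    return -(math.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


def ctf_2d(
    params: CtfParams,
    shape: tuple[int, int],
    pixel_size: float,
    rfft: bool = True,
) -> np.ndarray:
    """Evaluate the CTF on the Fourier grid of an image.

    Parameters
    ----------
    shape : (ny, nx)
        Real-space image dimensions.
    pixel_size : float
        Å per pixel.
    rfft : bool
        If True (default) the grid matches ``numpy.fft.rfft2`` output
        (ny, nx//2 + 1); otherwise the full ``fft2`` layout.

    Returns
    -------
    ndarray
        Real CTF values in [−1, 1]; the DC element equals −amplitude_contrast
        when phase_shift is 0.
    """
    ny, nx = shape
    if not pixel_size > 0:
        raise ValueError("pixel_size must be positive")
    fy = np.fft.fftfreq(ny, d=pixel_size)[:, None]
    fx = (np.fft.rfftfreq(nx, d=pixel_size) if rfft else np.fft.fftfreq(nx, d=pixel_size))[None, :]
    k2 = fx * fx + fy * fy
    k = np.sqrt(k2)
    lam = electron_wavelength(params.voltage)
    cs_a = params.cs * _MM_TO_A
    dfu, dfv = params.defocus_u, params.defocus_v
    theta = np.arctan2(fy, fx)
    df = 0.5 * (dfu + dfv + (dfu - dfv) * np.cos(2.0 * (theta - params.astig_angle)))
    chi = math.pi * lam * df * k2 - 0.5 * math.pi * cs_a * lam**3 * k2 * k2 + params.phase_shift
    a = params.amplitude_contrast
    return -(math.sqrt(1.0 - a * a) * np.sin(chi) + a * np.cos(chi))


def ctf_zeros(params: CtfParams, azimuth: float = 0.0, max_freq: float = 0.5, n: int = 8) -> np.ndarray:
    """First ``n`` positive zeros of the CTF along one azimuth, by bracketed
    root finding on a dense grid up to ``max_freq`` (1/Å)."""
    from scipy.optimize import brentq

    ks = np.linspace(1e-6, max_freq, 20000)
    vals = ctf_1d(params, ks, azimuth)
    zeros = []
    for i in range(len(ks) - 1):
        if vals[i] == 0.0:
            zeros.append(ks[i])
        elif vals[i] * vals[i + 1] < 0:
            zeros.append(brentq(lambda k: float(ctf_1d(params, np.array([k]), azimuth)[0]), ks[i], ks[i + 1]))
        if len(zeros) >= n:
            break
    return np.array(zeros)


def phase_flip(m: "Micrograph", params: CtfParams) -> "Micrograph":
    """Multiply the micrograph's Fourier transform by the sign of its CTF.

    The amplitude spectrum is untouched (|F'| = |F|) and the operation is an
    involution. sign(0) is taken as +1 so the map is well defined at CTF
    zeros.
    """
    ny, nx = m.shape
    c = ctf_2d(params, m.shape, m.pixel_size, rfft=True)
    s = np.where(c >= 0.0, 1.0, -1.0)
    # The kx=0 (and, for even nx, kx=Nyquist) columns store conjugate pairs
    # (ky, -ky); the CTF is mathematically equal at antipodal frequencies but
    # rounding near its zeros can flip one sign of a pair, which irfft2 would
    # average to zero. Enforce exact symmetry on those columns.
    idx = np.arange(1, (ny + 1) // 2)
    s[ny - idx, 0] = s[idx, 0]
    if nx % 2 == 0:
        s[ny - idx, -1] = s[idx, -1]
    f = np.fft.rfft2(m.pixels)
    flipped = np.fft.irfft2(f * s, s=m.shape)
    return m.with_pixels(flipped.astype(m.pixels.dtype, copy=False))
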