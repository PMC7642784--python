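"""Fourier-domain utilities: binning, unbinning, rings, patches, merging.

All spectral bookkeeping uses the ``numpy.fft.rfft2`` half-plane layout for
real images. Concentric frequency rings are one Fourier pixel wide (ring k
covers radii [k, k+1) in Fourier-pixel units of the smaller image dimension),
the standard FRC binning. Conjugate-redundant coefficients — the mirrored
halves of the kx = 0 and kx = Nyquist columns — are masked out so each
independent coefficient is counted exactly once; coefficients in the grid
corners beyond the Nyquist radius are excluded from ring statistics.

Intensity scaling convention: Fourier crop/pad preserve MEAN intensity (the
DC coefficient is rescaled by the pixel-count ratio), so per-pixel mean-square
power on the shared band is preserved. Parseval checks elsewhere use this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Micrograph

__all__ = [
    "RingGrid",
    "SpectralCurve",
    "fourier_crop",
    "fourier_pad_unbin",
    "extract_patches",
    "sample_patch_positions",
    "normalize",
    "ring_average",
    "merge_frequencies",
    "radial_mask",
]


@dataclass
class SpectralCurve:
    """Per-frequency-ring values (FRC, SSNR, power, ...).

    freq are ring-centre spatial frequencies in 1/Å, ascending from 0 to
    Nyquist; n is the number of independent Fourier coefficients per ring.
    """

    freq: np.ndarray
    value: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (len(self.freq) == len(self.value) == len(self.n)):
            raise ValueError("freq, value and n must have equal length")

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"freq_invA": self.freq, "value": self.value, "n_coeffs": self.n}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpectralCurve":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        return cls(df["freq_invA"].to_numpy(), df["value"].to_numpy(), df["n_coeffs"].to_numpy())


class RingGrid:
    """Ring assignment for the rfft2 grid of a (ny, nx) real image.

    Rings are one Fourier pixel wide in units of the smaller dimension; ring
    indices run 0..min(ny, nx)//2 (the Nyquist ring). Coefficients beyond the
    Nyquist radius (grid corners) and conjugate-redundant coefficients are
    excluded via ``unique_mask``.
    """

    def __init__(self, shape: tuple[int, int], pixel_size: float):
        ny, nx = shape
        if not pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        self.shape = (ny, nx)
        self.pixel_size = float(pixel_size)
        n = min(ny, nx)
        self.n_rings = n // 2 + 1
        fy = np.fft.fftfreq(ny)[:, None]  # cycles / pixel
        fx = np.fft.rfftfreq(nx)[None, :]
        r = np.sqrt(fy * fy + fx * fx) * n  # radius in Fourier pixels
        ring = np.floor(r).astype(int)
        ring[ring > n // 2] = -1  # beyond Nyquist: excluded
        # Nyquist-radius coefficients land exactly on ring n//2; keep them.
        exact_nyq = np.isclose(r, n // 2)
        ring[exact_nyq] = n // 2
        self.ring_index_map = ring
        self.unique_mask = self._unique_mask(ny, nx)
        ok = (ring >= 0) & self.unique_mask
        self.counts = np.bincount(ring[ok], minlength=self.n_rings)
        # ring centres: midpoint of [k, k+1) in 1/Å; DC ring centred at 0
        edges = np.arange(self.n_rings + 1) / (n * self.pixel_size)
        self.ring_edges = edges
        centre = 0.5 * (edges[:-1] + edges[1:])
        centre[0] = 0.0
        self.freq = centre
        self.nyquist = 1.0 / (2.0 * self.pixel_size)

    @staticmethod
    def _unique_mask(ny: int, nx: int) -> np.ndarray:
        mask = np.ones((ny, nx // 2 + 1), dtype=bool)
        half = ny // 2
        # kx = 0 column: rows ny-1 .. half+1 are conjugates of rows 1 .. half-1
        mask[half + 1 :, 0] = False
        if nx % 2 == 0:
            mask[half + 1 :, -1] = False
        return mask

    def ring_sum(self, values: np.ndarray) -> np.ndarray:
        """Sum ``values`` (rfft2 layout, real) over unique coefficients per ring."""
        if values.shape != self.ring_index_map.shape:
            raise ValueError(
                f"values shape {values.shape} does not match grid {self.ring_index_map.shape}"
            )
        ok = (self.ring_index_map >= 0) & self.unique_mask
        return np.bincount(
            self.ring_index_map[ok], weights=np.real(values[ok]), minlength=self.n_rings
        )

    def ring_mean(self, values: np.ndarray) -> np.ndarray:
        s = self.ring_sum(values)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.counts > 0, s / self.counts, np.nan)


def ring_average(values: np.ndarray, grid: RingGrid) -> SpectralCurve:
    """Rotationally average per-coefficient values into a spectral curve."""
    return SpectralCurve(grid.freq, grid.ring_mean(values), grid.counts)


# ---------------------------------------------------------------------------
# Fourier crop / pad
# ---------------------------------------------------------------------------


def _even_floor(x: float) -> int:
    m = int(np.floor(x))
    return m if m % 2 == 0 else m - 1


def fourier_crop(m: Micrograph, target_pixel_size: float) -> Micrograph:
    """Bin a micrograph by discarding Fourier coefficients beyond a new Nyquist.

    The output dimensions are the largest even integers giving a pixel size
    >= the requested one; the achieved pixel size is recomputed and stored.
    Mean intensity is preserved.
    """
    ny, nx = m.shape
    if target_pixel_size < m.pixel_size * (1 - 1e-9):
        raise ValueError(
            f"target pixel size {target_pixel_size} is finer than current {m.pixel_size}"
        )
    my = _even_floor(ny * m.pixel_size / target_pixel_size + 1e-9)
    mx = _even_floor(nx * m.pixel_size / target_pixel_size + 1e-9)
    my, mx = min(my, ny), min(mx, nx)
    if (my, mx) == (ny, nx):
        return m.with_pixels(m.pixels.copy())
    f = np.fft.fftshift(np.fft.fft2(m.pixels))
    cy, cx = ny // 2, nx // 2
    sub = f[cy - my // 2 : cy + my // 2, cx - mx // 2 : cx + mx // 2].copy()
    # the new Nyquist shell (shifted row/col 0) loses its conjugate partners
    # in the crop; zero it so the spectrum stays exactly Hermitian and the
    # output exactly real (content strictly below the new Nyquist is intact)
    if my < ny:
        sub[0, :] = 0.0
    if mx < nx:
        sub[:, 0] = 0.0
    out = np.fft.ifft2(np.fft.ifftshift(sub)).real * (my * mx) / (ny * nx)
    new_ps = m.pixel_size * ny / my
    return m.with_pixels(out, pixel_size=new_ps)


def radial_mask(
    shape: tuple[int, int],
    pixel_size: float,
    cutoff: float,
    rolloff_width: float,
    rfft: bool = False,
) -> np.ndarray:
    """Soft radial Fourier mask: 1 below cutoff − w/2, 0 above cutoff + w/2,
    raised-cosine in between (frequencies in 1/Å)."""
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pixel_size)[:, None]
    fx = (np.fft.rfftfreq(nx, d=pixel_size) if rfft else np.fft.fftfreq(nx, d=pixel_size))[None, :]
    f = np.sqrt(fy * fy + fx * fx)
    lo = cutoff - rolloff_width / 2.0
    hi = cutoff + rolloff_width / 2.0
    if rolloff_width <= 0:
        return (f <= cutoff).astype(float)
    w = np.clip((f - lo) / (hi - lo), 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * w))


def fourier_pad_unbin(
    m: Micrograph,
    target_shape: tuple[int, int],
    cutoff: float,
    rolloff_width: float,
) -> Micrograph:
    """Upsample by zero-padding the Fourier transform and applying a soft
    radial low-pass mask.

    The output has ``target_shape`` and pixel size scaled by the dimension
    ratio; all power above cutoff + rolloff_width/2 is exactly zero.
    """
    ny, nx = m.shape
    ty, tx = target_shape
    if ty < ny or tx < nx:
        raise ValueError(f"target shape {target_shape} smaller than source {m.shape}")
    src_nyquist = 1.0 / (2.0 * m.pixel_size)
    if cutoff > src_nyquist * (1 + 1e-9):
        raise ValueError(f"cutoff {cutoff} exceeds source Nyquist {src_nyquist}")
    f = np.fft.fftshift(np.fft.fft2(m.pixels)).copy()
    # a source Nyquist shell would sit unpaired inside the padded grid and
    # break Hermitian symmetry; drop it (only when actually padding that axis)
    if ty > ny and ny % 2 == 0:
        f[0, :] = 0.0
    if tx > nx and nx % 2 == 0:
        f[:, 0] = 0.0
    big = np.zeros((ty, tx), dtype=complex)
    cy, cx = ty // 2, tx // 2
    big[cy - ny // 2 : cy + (ny + 1) // 2, cx - nx // 2 : cx + (nx + 1) // 2] = f
    new_ps = m.pixel_size * ny / ty
    mask = np.fft.fftshift(radial_mask((ty, tx), new_ps, cutoff, rolloff_width))
    big *= mask
    out = np.fft.ifft2(np.fft.ifftshift(big)).real * (ty * tx) / (ny * nx)
    return m.with_pixels(out, pixel_size=new_ps)


# ---------------------------------------------------------------------------
# Patches and normalization
# ---------------------------------------------------------------------------


def sample_patch_positions(
    shape: tuple[int, int], patch: int, n: int, seed: int
) -> np.ndarray:
    """Uniform random top-left corners of ``n`` patches fully inside ``shape``.

    Deterministic for a given seed; use the same positions for the even and
    odd members of a half-pair.
    """
    ny, nx = shape
    if patch > ny or patch > nx:
        raise ValueError(f"patch size {patch} exceeds image shape {shape}")
    rng = np.random.default_rng(seed)
    ys = rng.integers(0, ny - patch + 1, size=n)
    xs = rng.integers(0, nx - patch + 1, size=n)
    return np.stack([ys, xs], axis=1)


def extract_patches(m: Micrograph, patch: int, n: int, seed: int) -> list[np.ndarray]:
    """Extract ``n`` random square patches (see :func:`sample_patch_positions`)."""
    pos = sample_patch_positions(m.shape, patch, n, seed)
    return [m.pixels[y : y + patch, x : x + patch].copy() for y, x in pos]


def normalize(patch: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Zero-mean, unit-std normalization; returns (normalized, mean, std).

    The removed statistics are returned so denoised output can be restored to
    the original intensity scale. Constant patches are rejected.
    """
    mean = float(np.mean(patch))
    std = float(np.std(patch))
    if std <= 0 or not np.isfinite(std):
        raise ValueError("cannot normalize a constant (zero-variance) patch")
    return (patch - mean) / std, mean, std


# ---------------------------------------------------------------------------
# Frequency-domain merging
# ---------------------------------------------------------------------------


def merge_frequencies(
    denoised: Micrograph,
    original: Micrograph,
    crossover: float,
    width: float,
) -> Micrograph:
    """Combine low-frequency content of ``denoised`` with high-frequency
    content of ``original``.

    Fourier output = W(k)·F_denoised + (1 − W(k))·F_original with W a
    raised-cosine step from 1 (below crossover − width/2) to 0 (above
    crossover + width/2). With crossover = width = 0 only the DC term is
    taken from the denoised image.
    """
    if denoised.shape != original.shape:
        raise ValueError(f"shape mismatch: {denoised.shape} vs {original.shape}")
    if abs(denoised.pixel_size - original.pixel_size) > 1e-9 * denoised.pixel_size:
        raise ValueError("pixel size mismatch")
    if crossover < 0:
        raise ValueError(f"crossover must be non-negative, got {crossover}")
    w = radial_mask(denoised.shape, denoised.pixel_size, crossover, width, rfft=True)
    fd = np.fft.rfft2(denoised.pixels)
    fo = np.fft.rfft2(original.pixels)
    out = np.fft.irfft2(w * fd + (1.0 - w) * fo, s=denoised.shape)
    return denoised.with_pixels(out)
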