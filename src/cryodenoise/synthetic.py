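"""Synthetic phantom micrographs with fully known signal and noise.

Phantoms are sums of soft-edged discs — a stand-in for particle projections
with a broadband spectrum — on a constant background. Half-pairs add two
independent white Gaussian noise fields to one (optionally CTF-modulated)
signal, which is exactly the statistical situation the noise2noise objective
and the cross-correlation estimators assume. Because the generating signal
and noise powers are recorded analytically, every estimator in the package
can be validated against ground truth without external data.

A Poisson option (scaled counts) is available for realism; the estimators
only require the noise to be zero-mean and uncorrelated between halves given
the signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ctf import CtfParams, ctf_2d
from .io import HalfPair, Micrograph, write_ctf_table, write_micrograph, CtfRecord
from .spectral import RingGrid, SpectralCurve

__all__ = [
    "PhantomSpec",
    "SimulatedPair",
    "generate_phantom",
    "simulate_half_pair",
    "generate_eval_suite",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the disc-phantom generator.

    Sizes in pixels, lengths in Å. Discs have a logistic (soft) edge of
    ``edge_width`` Å; centres are drawn uniformly with a margin so no disc
    clips the image border.
    """

    size: int = 256
    pixel_size: float = 1.0
    n_blobs: int = 40
    blob_radius_range: tuple[float, float] = (6.0, 16.0)
    blob_amplitude_range: tuple[float, float] = (0.5, 1.5)
    background: float = 0.0
    edge_width: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError("size must be >= 64")
        if self.n_blobs < 0:
            raise ValueError("n_blobs must be >= 0")
        lo, hi = self.blob_radius_range
        if not 0 < lo <= hi:
            raise ValueError("blob radii must be positive and ordered")
        if hi > self.size * self.pixel_size / 4:
            raise ValueError("blob radius too large for the field of view")


@dataclass
class SimulatedPair:
    """A half-pair with known clean signal and generating spectra."""

    clean: Micrograph
    pair: HalfPair
    ctf: CtfParams | None
    noise_sigma: float
    true_signal_power: SpectralCurve
    true_noise_power: SpectralCurve


def disc_profile(dist: np.ndarray, radius: float, edge_width: float) -> np.ndarray:
    """Unit-amplitude soft disc: 1 inside, 0 outside, logistic edge."""
    return 1.0 / (1.0 + np.exp((dist - radius) / edge_width))


def generate_phantom(spec: PhantomSpec) -> Micrograph:
    """Render a phantom micrograph; deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    ps = spec.pixel_size
    img = np.full((n, n), spec.background, dtype=np.float64)
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    lo_r, hi_r = spec.blob_radius_range
    lo_a, hi_a = spec.blob_amplitude_range
    margin_px = (hi_r + 4 * spec.edge_width) / ps
    for _ in range(spec.n_blobs):
        r = rng.uniform(lo_r, hi_r)
        a = rng.uniform(lo_a, hi_a)
        cy = rng.uniform(margin_px, n - margin_px)
        cx = rng.uniform(margin_px, n - margin_px)
        d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) * ps
        img += a * disc_profile(d, r, spec.edge_width)
    return Micrograph(img, ps, name=f"phantom_{spec.seed}")


def simulate_half_pair(
    clean: Micrograph,
    ctf: CtfParams | None,
    noise_sigma: float,
    seed: int,
    noise: str = "gaussian",
) -> SimulatedPair:
    """Make an even/odd pair: signal (optionally CTF-modulated) plus two
    independent noise realizations.

    For white Gaussian noise of per-pixel standard deviation σ, the expected
    Fourier power per coefficient is σ²·Npix (unnormalized FFT convention);
    the recorded true noise curve is that constant. The true signal curve is
    the ring-averaged power of the (modulated) signal.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    signal = clean.pixels.astype(np.float64)
    if ctf is not None:
        c = ctf_2d(ctf, clean.shape, clean.pixel_size, rfft=True)
        signal = np.fft.irfft2(np.fft.rfft2(signal) * c, s=clean.shape)
    grid = RingGrid(clean.shape, clean.pixel_size)
    sig_power = grid.ring_mean(np.abs(np.fft.rfft2(signal)) ** 2)
    npix = signal.size
    noise_power = np.full(grid.n_rings, noise_sigma**2 * npix)
    if noise == "gaussian":
        n_e = rng.normal(0.0, noise_sigma, signal.shape) if noise_sigma else 0.0
        n_o = rng.normal(0.0, noise_sigma, signal.shape) if noise_sigma else 0.0
    elif noise == "poisson":
        # counts model: shift signal positive, draw Poisson with variance
        # matched to sigma² at the mean, recentre
        offset = float(signal.min())
        lam = (signal - offset) + noise_sigma**2
        n_e = rng.poisson(lam) - lam if noise_sigma else 0.0
        n_o = rng.poisson(lam) - lam if noise_sigma else 0.0
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    even = Micrograph(signal + n_e, clean.pixel_size, name=clean.name)
    odd = Micrograph(signal + n_o, clean.pixel_size, name=clean.name)
    return SimulatedPair(
        clean=Micrograph(signal, clean.pixel_size, name=clean.name),
        pair=HalfPair(even, odd),
        ctf=ctf,
        noise_sigma=noise_sigma,
        true_signal_power=SpectralCurve(grid.freq, sig_power, grid.counts),
        true_noise_power=SpectralCurve(grid.freq, noise_power, grid.counts),
    )


def sigma_for_scalar_snr(
    true_signal_power: SpectralCurve, target_snr: float, npix: int
) -> float:
    """Noise σ giving an exact ring-weighted scalar SNR (DC excluded).

    Scalar SNR = Σ n_k S_k / Σ n_k N with N = σ²·Npix constant, so
    σ² = Σ n_k S_k / (SNR · Npix · Σ n_k).
    """
    if not target_snr > 0:
        raise ValueError("target SNR must be positive")
    w = true_signal_power.n.astype(float).copy()
    w[0] = 0.0
    s_sum = float(np.nansum(w * true_signal_power.value))
    sigma2 = s_sum / (target_snr * npix * w.sum())
    return math.sqrt(sigma2)


def generate_eval_suite(
    n: int,
    spec: PhantomSpec,
    snr_targets: list[float],
    out_dir: str | Path,
    with_ctf: bool = False,
) -> dict:
    """Write a fixture directory of half-pairs with known scalar SNR.

    For each target SNR a subdirectory ``snr_<target>`` is created with
    ``pairs/even_###.mrc``, ``pairs/odd_###.mrc``, ``clean/###.mrc``,
    ``ctf.tsv`` and per-micrograph ground-truth curves ``truth/###.tsv``
    (columns freq_invA, signal_power, noise_power, n_coeffs). σ is solved in
    closed form per micrograph so the recorded Σ S / Σ N equals the target
    exactly. Returns a manifest of created paths and σ values.
    """
    import pandas as pd

    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    manifest: dict = {"targets": {}}
    rng = np.random.default_rng(spec.seed)
    for target in snr_targets:
        sub = out_dir / f"snr_{target:g}"
        for d in ("pairs", "clean", "truth"):
            (sub / d).mkdir(parents=True, exist_ok=True)
        records = []
        sigmas = []
        for i in range(n):
            pspec = PhantomSpec(
                size=spec.size,
                pixel_size=spec.pixel_size,
                n_blobs=spec.n_blobs,
                blob_radius_range=spec.blob_radius_range,
                blob_amplitude_range=spec.blob_amplitude_range,
                background=spec.background,
                edge_width=spec.edge_width,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            clean = generate_phantom(pspec)
            ctf = (
                CtfParams(
                    defocus_u=float(rng.uniform(8000, 25000)),
                    defocus_v=float(rng.uniform(8000, 25000)),
                    astig_angle=float(rng.uniform(0, math.pi)),
                )
                if with_ctf
                else None
            )
            # solve sigma on the (possibly modulated) signal spectrum
            probe = simulate_half_pair(clean, ctf, 0.0, seed=0)
            sigma = sigma_for_scalar_snr(probe.true_signal_power, target, clean.pixels.size)
            sim = simulate_half_pair(clean, ctf, sigma, seed=int(rng.integers(0, 2**31 - 1)))
            stem = f"{i:03d}"
            write_micrograph(sim.pair.even, sub / "pairs" / f"even_{stem}.mrc")
            write_micrograph(sim.pair.odd, sub / "pairs" / f"odd_{stem}.mrc")
            write_micrograph(sim.clean, sub / "clean" / f"{stem}.mrc")
            pd.DataFrame(
                {
                    "freq_invA": sim.true_signal_power.freq,
                    "signal_power": sim.true_signal_power.value,
                    "noise_power": sim.true_noise_power.value,
                    "n_coeffs": sim.true_signal_power.n,
                }
            ).to_csv(sub / "truth" / f"{stem}.tsv", sep="\t", index=False)
            records.append(
                CtfRecord(
                    micrograph_name=stem,
                    params=ctf if ctf is not None else CtfParams(15000.0, 15000.0),
                )
            )
            sigmas.append(sigma)
        write_ctf_table(records, sub / "ctf.tsv")
        manifest["targets"][target] = {"dir": str(sub), "sigmas": sigmas, "n": n}
    return manifest
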