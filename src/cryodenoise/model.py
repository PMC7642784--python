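"""noise2noise denoising model: training on half-pairs, full-image inference.

The training scheme needs no clean targets: the network maps one noisy
realization of a micrograph to the other, and because the two halves share
their signal but have noise that is uncorrelated given that signal, the
minimizer of the expected L2 loss is the same as for noisy→clean training.

`DenoisingModel` holds the half-pairs plus the preprocessing choices (CTF
phase flipping, Fourier-crop binning) and `fit()` runs patch-based training,
returning a `DenoisingResults` with the trained operator, the loss history
and full-micrograph inference.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ctf import CtfParams
from .ctf import phase_flip as ctf_phase_flip
from .io import HalfPair, Micrograph, logger
from .spectral import fourier_crop, fourier_pad_unbin, normalize, sample_patch_positions
from .unet import UNet, UNetConfig, IdentityOperator

__all__ = [
    "TrainConfig",
    "DenoisingModel",
    "DenoisingResults",
    "TrainingDivergedError",
    "denoise_micrograph",
]


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"training loss became non-finite at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    patch must be divisible by 2**depth of the network. The defaults mirror
    common practice for micrograph denoising: 192-pixel patches, 100 epochs,
    Adam at 1e-3 with L2 loss.
    """

    patch: int = 192
    batch: int = 16
    epochs: int = 100
    lr: float = 1e-3
    seed: int = 0
    loss: str = "mse"
    patches_per_pair: int = 16
    val_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not self.lr > 0:
            raise ValueError("lr must be positive")
        if self.loss not in ("mse", "mae"):
            raise ValueError(f"loss must be 'mse' or 'mae', got {self.loss!r}")


class DenoisingModel:
    """noise2noise denoiser specification bound to a set of half-pairs.

    Parameters
    ----------
    pairs : sequence of HalfPair
        Even/odd micrograph sums; all preprocessing happens here.
    ctf : mapping name -> CtfParams, optional
        Required when ``phase_flip=True``; looked up by micrograph name.
    phase_flip : bool
        Multiply each half's Fourier transform by the sign of its CTF before
        training (so the network need not learn CTF-dependent contrast
        inversions).
    bin_to : float or None
        Target pixel size (Å) for Fourier-crop binning of the training data;
        None disables binning.
    unet : UNetConfig
        Architecture of the denoising network.
    """

    def __init__(
        self,
        pairs: Sequence[HalfPair],
        ctf: Mapping[str, CtfParams] | None = None,
        *,
        phase_flip: bool = False,
        bin_to: float | None = None,
        unet: UNetConfig = UNetConfig(),
    ):
        if len(pairs) < 1:
            raise ValueError("at least one half-pair is required")
        if phase_flip and ctf is None:
            raise ValueError("phase_flip=True requires CTF parameters")
        self.unet_config = unet
        self.do_phase_flip = phase_flip
        self.bin_to = bin_to
        self._pairs = list(pairs)
        self._processed: list[tuple[np.ndarray, np.ndarray]] = []
        pixel_size = None
        for pair in pairs:
            even, odd = pair.even, pair.odd
            if phase_flip:
                params = ctf.get(pair.name) if ctf else None
                if params is None:
                    raise KeyError(f"no CTF record for micrograph {pair.name!r}")
                even = ctf_phase_flip(even, params)
                odd = ctf_phase_flip(odd, params)
            if bin_to is not None and bin_to > even.pixel_size * (1 + 1e-9):
                even = fourier_crop(even, bin_to)
                odd = fourier_crop(odd, bin_to)
            if pixel_size is None:
                pixel_size = even.pixel_size
            self._processed.append(
                (even.pixels.astype(np.float32), odd.pixels.astype(np.float32))
            )
        self.pixel_size = float(pixel_size)

    def fit(self, config: TrainConfig = TrainConfig()) -> "DenoisingResults":
        """Train the U-net with the noise2noise objective.

        Each epoch samples ``patches_per_pair`` co-located patch pairs per
        training micrograph; both directions (even→odd and odd→even) enter as
        examples, each patch normalized with its own mean/std. Optimization
        is Adam on weight-normalized convolutions. Returns a
        :class:`DenoisingResults`.
        """
        from .nn import Adam

        d = self.unet_config.depth
        if config.patch % (1 << d):
            raise ValueError(
                f"patch size {config.patch} not divisible by 2**depth = {1 << d}"
            )
        min_dim = min(min(e.shape) for e, _ in self._processed)
        if config.patch > min_dim:
            raise ValueError(
                f"patch size {config.patch} exceeds smallest processed micrograph ({min_dim})"
            )
        rng = np.random.default_rng(config.seed)
        net = UNet(self.unet_config, seed=int(rng.integers(0, 2**31 - 1)))
        opt = Adam(lr=config.lr)

        n = len(self._processed)
        n_val = int(round(config.val_fraction * n)) if n >= 2 else 0
        order = rng.permutation(n)
        val_idx = set(order[:n_val].tolist())
        train_idx = [i for i in range(n) if i not in val_idx]
        # fixed validation patches, drawn once
        val_examples = []
        for i in sorted(val_idx):
            even, odd = self._processed[i]
            pos = sample_patch_positions(
                even.shape, config.patch, config.patches_per_pair,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for y, x in pos:
                pe = normalize(even[y : y + config.patch, x : x + config.patch])[0]
                po = normalize(odd[y : y + config.patch, x : x + config.patch])[0]
                val_examples.append((pe, po))

        history = {"epoch": [], "train_loss": [], "val_loss": []}
        t0 = time.time()
        for epoch in range(1, config.epochs + 1):
            inputs, targets = [], []
            for i in train_idx:
                even, odd = self._processed[i]
                pos = sample_patch_positions(
                    even.shape, config.patch, config.patches_per_pair,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                for y, x in pos:
                    pe = normalize(even[y : y + config.patch, x : x + config.patch])[0]
                    po = normalize(odd[y : y + config.patch, x : x + config.patch])[0]
                    inputs += [pe, po]
                    targets += [po, pe]
            perm = rng.permutation(len(inputs))
            losses = []
            for start in range(0, len(perm), config.batch):
                idx = perm[start : start + config.batch]
                x = np.stack([inputs[j] for j in idx])[:, None].astype(np.float32)
                t = np.stack([targets[j] for j in idx])[:, None].astype(np.float32)
                pred = net.forward(x)
                diff = pred - t
                if config.loss == "mse":
                    loss = float(np.mean(diff.astype(np.float64) ** 2))
                    dout = (2.0 / diff.size) * diff
                else:
                    loss = float(np.mean(np.abs(diff.astype(np.float64))))
                    dout = np.sign(diff) / diff.size
                net.backward(dout.astype(np.float32))
                opt.step(net.params(), net.grads())
                losses.append(loss)
            train_loss = float(np.mean(losses))
            if not np.isfinite(train_loss):
                raise TrainingDivergedError(epoch)
            if val_examples:
                vl = []
                for pe, po in val_examples:
                    pred = net.forward(pe[None, None].astype(np.float32))[0, 0]
                    vl.append(float(np.mean((pred.astype(np.float64) - po) ** 2)))
                val_loss = float(np.mean(vl))
            else:
                val_loss = float("nan")
            history["epoch"].append(epoch)
            history["train_loss"].append(train_loss)
            history["val_loss"].append(val_loss)
            logger.info(
                "epoch %d/%d  train %.5f  val %s  (%.1fs)",
                epoch, config.epochs, train_loss,
                f"{val_loss:.5f}" if np.isfinite(val_loss) else "-",
                time.time() - t0,
            )
        metadata = {
            "pixel_size": self.pixel_size,
            "phase_flip": self.do_phase_flip,
            "bin_to": self.bin_to,
            "n_pairs": n,
            "n_train": len(train_idx),
            "n_val": n_val,
        }
        return DenoisingResults(net, config, pd.DataFrame(history), metadata)


class DenoisingResults:
    """Trained denoiser with loss history, inference and persistence."""

    def __init__(
        self,
        net: UNet,
        train_config: TrainConfig,
        loss_history: pd.DataFrame,
        training_metadata: dict,
    ):
        self.net = net
        self.train_config = train_config
        self.loss_history = loss_history
        self.training_metadata = training_metadata

    @property
    def unet_config(self) -> UNetConfig:
        return self.net.config

    def denoise(
        self,
        m: Micrograph,
        ctf: CtfParams | None = None,
        *,
        unbin: bool = True,
        cutoff: float | None = None,
        rolloff: float | None = None,
    ) -> Micrograph:
        """Denoise a full micrograph with the same preprocessing as training."""
        return denoise_micrograph(
            self.net,
            m,
            ctf=ctf,
            phase_flip=self.training_metadata["phase_flip"],
            bin_to=self.training_metadata["bin_to"],
            unbin=unbin,
            cutoff=cutoff,
            rolloff=rolloff,
        )

    def summary(self) -> str:
        cfg = self.net.config
        md = self.training_metadata
        hist = self.loss_history
        lines = [
            "noise2noise denoising results",
            "=============================",
            f"architecture      U-net depth {cfg.depth}, base {cfg.base_channels}, "
            f"expansion {cfg.expansion}, kernel {cfg.kernel}",
            f"parameters        {self.net.n_params()}",
            f"trained at        {md['pixel_size']:.4g} A/px"
            + (f" (binned to {md['bin_to']:.4g} A)" if md.get("bin_to") else ""),
            f"phase flipped     {md['phase_flip']}",
            f"pairs             {md['n_pairs']} ({md['n_train']} train / {md['n_val']} val)",
            f"epochs            {len(hist)}",
            f"final train loss  {hist['train_loss'].iloc[-1]:.6f}",
        ]
        if np.isfinite(hist["val_loss"].iloc[-1]):
            lines.append(f"final val loss    {hist['val_loss'].iloc[-1]:.6f}")
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.loss_history["epoch"], self.loss_history["train_loss"], label="train")
        if self.loss_history["val_loss"].notna().any():
            ax.plot(self.loss_history["epoch"], self.loss_history["val_loss"], label="val")
        ax.set_xlabel("epoch")
        ax.set_ylabel(f"{self.train_config.loss} loss")
        ax.legend()
        return ax

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        meta = {
            "unet_config": asdict(self.net.config),
            "seed": self.net.seed,
            "train_config": asdict(self.train_config),
            "training_metadata": self.training_metadata,
            "loss_history": self.loss_history.to_dict(orient="list"),
        }
        arrays = {f"param/{k}": v for k, v in self.net.params().items()}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DenoisingResults":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = {
                k[len("param/"):]: data[k] for k in data.files if k.startswith("param/")
            }
        net = UNet(UNetConfig(**meta["unet_config"]), seed=meta["seed"])
        net.set_params(params)
        return cls(
            net,
            TrainConfig(**meta["train_config"]),
            pd.DataFrame(meta["loss_history"]),
            meta["training_metadata"],
        )


def denoise_micrograph(
    operator,
    m: Micrograph,
    ctf: CtfParams | None = None,
    *,
    phase_flip: bool = False,
    bin_to: float | None = None,
    unbin: bool = True,
    cutoff: float | None = None,
    rolloff: float | None = None,
) -> Micrograph:
    """Full-micrograph inference pipeline.

    optional CTF phase flip → Fourier-crop to ``bin_to`` → whole-image
    normalization → reflective padding to dims divisible by 2**depth →
    operator forward → crop → de-normalization → optional zero-pad unbinning
    back to the original shape through a soft radial Fourier mask, leaving
    the output band-limited at the binned Nyquist.

    ``operator`` is any object with ``apply(2-D array) -> 2-D array`` and a
    ``config.depth`` attribute (a trained :class:`~.unet.UNet`, or
    :class:`~.unet.IdentityOperator` for pipeline diagnostics).
    """
    orig_shape, orig_ps = m.shape, m.pixel_size
    work = m
    if phase_flip:
        if ctf is None:
            raise ValueError("phase flipping requested but no CTF parameters given")
        work = ctf_phase_flip(work, ctf)
    if bin_to is not None and bin_to > work.pixel_size * (1 + 1e-9):
        work = fourier_crop(work, bin_to)
    arr, mean, std = normalize(work.pixels)
    d = operator.config.depth
    block = 1 << d
    ny, nx = arr.shape
    py = (-ny) % block
    px = (-nx) % block
    if py or px:
        arr = np.pad(arr, ((0, py), (0, px)), mode="reflect")
    out = operator.apply(arr.astype(np.float32))
    out = np.asarray(out, dtype=np.float64)[:ny, :nx]
    out = out * std + mean
    denoised = work.with_pixels(out)
    if unbin and denoised.shape != orig_shape:
        src_n = min(denoised.shape)
        src_nyq = 1.0 / (2.0 * denoised.pixel_size)
        if rolloff is None:
            rolloff = 10.0 / (src_n * denoised.pixel_size)
        if cutoff is None:
            cutoff = src_nyq - rolloff / 2.0
        denoised = fourier_pad_unbin(denoised, orig_shape, cutoff, rolloff)
    return denoised
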