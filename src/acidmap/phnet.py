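"""Multimodal pH-regression network.

Two branches read the same spectrum: a fully connected branch over the 1-D
intensity sequence, and a residual convolutional branch over the 3-channel
2-D encoding (RP/GASF/GADF). A co-attention layer uses the 1-D features as
queries over the convolutional token grid; the attended context is
concatenated with the query features and a small fully connected head
regresses pH. Training minimises mean squared error with Adam, splits data
by specimen (never by point) into train / internal-validation / external
splits, and early-stops on the internal-validation loss.

The default backbone is a deliberately small 4-block residual network on
64 x 64 encodings, sized so a few-thousand-spectrum experiment trains in
minutes on one CPU core; widths and image side are configuration, not
architecture.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .encode import encode
from .nn import Adam, Conv2d, Linear, Module, ResidualBlock, Tensor
from .preprocess import PreprocessOptions, preprocess
from .spectrum import RamanSpectrum, resample

__all__ = [
    "PHNetConfig",
    "SpectrumDataset",
    "MultimodalPHRegressor",
    "PHNet",
    "PHNetResults",
    "load_results",
]


@dataclass(frozen=True)
class PHNetConfig:
    """Architecture and training protocol.

    ``split`` is by specimen: fractions of specimens assigned to train,
    internal validation and external validation (must sum to 1).
    """

    image_side: int = 64
    seq_len: int = 256
    d_1d: int = 64
    d_attn: int = 64
    n_heads: int = 1
    conv_widths: tuple[int, int, int, int] = (8, 16, 32, 32)
    head_hidden: int = 64
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    input_noise: float = 0.3  # train-time noise SD on standardised sequences
    epochs: int = 100
    batch_size: int = 32
    patience: int = 10
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions {self.split} must sum to 1")
        if min(self.split) < 0:
            raise ValueError("split fractions must be nonnegative")
        for name in ("image_side", "seq_len", "d_1d", "d_attn", "n_heads",
                     "head_hidden", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.d_attn % self.n_heads != 0:
            raise ValueError("d_attn must be divisible by n_heads")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")


class SpectrumDataset:
    """Preprocessed, encoded spectra ready for training.

    Holds the fixed-length 1-D sequences, the (3, L, L) image encodings,
    ground-truth pH and a specimen id per point.
    """

    def __init__(
        self,
        sequences: np.ndarray,
        images: np.ndarray,
        ph: np.ndarray,
        specimen_ids: Sequence[str],
    ):
        self.sequences = np.asarray(sequences, dtype=np.float32)
        self.images = np.asarray(images, dtype=np.float32)
        self.ph = np.asarray(ph, dtype=np.float32)
        self.specimen_ids = np.asarray(specimen_ids)
        n = self.ph.size
        if not (
            self.sequences.shape[0] == self.images.shape[0]
            == self.specimen_ids.size == n
        ):
            raise ValueError("dataset component lengths disagree")

    def __len__(self) -> int:
        return int(self.ph.size)

    @classmethod
    def from_spectra(
        cls,
        spectra: Sequence[RamanSpectrum],
        specimen_ids: Sequence[str] | None = None,
        config: PHNetConfig | None = None,
        options: PreprocessOptions | None = None,
        already_preprocessed: bool = False,
    ) -> "SpectrumDataset":
        """Preprocess, resample and encode a list of labelled spectra.

        ``specimen_ids`` groups points for leakage-free splitting; when
        omitted every spectrum is its own specimen.
        """
        config = config or PHNetConfig()
        seqs, imgs, phs = [], [], []
        for spec in spectra:
            if spec.true_ph is None:
                raise ValueError("training spectra need a ground-truth pH")
            clean = spec if already_preprocessed else preprocess(spec, options)
            seqs.append(resample(clean.intensities, config.seq_len))
            imgs.append(encode(clean, side=config.image_side).channels)
            phs.append(spec.true_ph)
        if specimen_ids is None:
            specimen_ids = [f"s{i}" for i in range(len(spectra))]
        return cls(np.array(seqs), np.array(imgs), np.array(phs), specimen_ids)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.sequences).tobytes())
        h.update(np.ascontiguousarray(self.ph).tobytes())
        h.update("|".join(map(str, self.specimen_ids)).encode())
        return h.hexdigest()


class MultimodalPHRegressor(Module):
    """The network itself: 1-D branch, 2-D branch, co-attention, head."""

    def __init__(self, config: PHNetConfig, rng: np.random.Generator):
        self.config = config
        w0, w1, w2, w3 = config.conv_widths
        # 2-D branch: stem + alternating residual blocks and downsamplers.
        self.stem = Conv2d(3, w0, 3, rng, stride=2)
        self.block1 = ResidualBlock(w0, rng)
        self.down1 = Conv2d(w0, w1, 3, rng, stride=2)
        self.block2 = ResidualBlock(w1, rng)
        self.down2 = Conv2d(w1, w2, 3, rng, stride=2)
        self.block3 = ResidualBlock(w2, rng)
        self.down3 = Conv2d(w2, w3, 3, rng, stride=2)
        self.block4 = ResidualBlock(w3, rng)
        # 1-D branch.
        self.fc1 = Linear(config.seq_len, 2 * config.d_1d, rng)
        self.fc2 = Linear(2 * config.d_1d, config.d_1d, rng)
        # Co-attention projections (1-D features are the queries).
        self.w_query = Linear(config.d_1d, config.d_attn, rng)
        self.w_key = Linear(w3, config.d_attn, rng)
        self.w_value = Linear(w3, config.d_attn, rng)
        # Regression head over [attended context, query features].
        self.head1 = Linear(config.d_attn + config.d_1d, config.head_hidden, rng)
        self.head2 = Linear(config.head_hidden, 1, rng)

    # -- branches --------------------------------------------------------
    def features_1d(self, seq: Tensor) -> Tensor:
        if seq.data.shape[-1] != self.config.seq_len:
            raise ValueError(
                f"1-D input length {seq.data.shape[-1]} != configured "
                f"{self.config.seq_len}"
            )
        return self.fc2(self.fc1(seq).relu()).relu()

    def features_2d(self, img: Tensor) -> Tensor:
        """Token grid (N, T, C) from the convolutional backbone."""
        if img.data.ndim != 4 or img.data.shape[1] != 3:
            raise ValueError("expected images of shape (N, 3, L, L)")
        if img.data.shape[2] != self.config.image_side:
            raise ValueError(
                f"image side {img.data.shape[2]} != configured "
                f"{self.config.image_side}"
            )
        h = self.stem(img).relu()
        h = self.block1(h)
        h = self.down1(h).relu()
        h = self.block2(h)
        h = self.down2(h).relu()
        h = self.block3(h)
        h = self.down3(h).relu()
        h = self.block4(h)
        n, c, hh, ww = h.data.shape
        return h.reshape(n, c, hh * ww).transpose(0, 2, 1)

    def co_attention(
        self, query_1d: Tensor, tokens: Tensor
    ) -> tuple[Tensor, np.ndarray]:
        """Fuse modalities: softmax attention of 1-D queries over 2-D tokens.

        Returns the fused feature vector (attended context concatenated
        with the query features) and the attention weights
        (N, heads, tokens), which are nonnegative and sum to 1 per head.
        """
        cfg = self.config
        n, t, _ = tokens.data.shape
        heads, dh = cfg.n_heads, cfg.d_attn // cfg.n_heads
        q = self.w_query(query_1d).reshape(n, heads, dh)
        k = self.w_key(tokens).reshape(n, t, heads, dh).transpose(0, 2, 1, 3)
        v = self.w_value(tokens).reshape(n, t, heads, dh).transpose(0, 2, 1, 3)
        scores = (k @ q.reshape(n, heads, dh, 1)).reshape(n, heads, t)
        scores = scores * float(1.0 / np.sqrt(dh))
        weights = scores.softmax(-1)
        context = (weights.reshape(n, heads, 1, t) @ v).reshape(n, cfg.d_attn)
        fused = Tensor.concat([context, query_1d], axis=-1)
        return fused, weights.data

    def forward(self, seq: Tensor, img: Tensor) -> Tensor:
        f1 = self.features_1d(seq)
        tokens = self.features_2d(img)
        fused, _ = self.co_attention(f1, tokens)
        return self.head2(self.head1(fused).relu())

    def weights_digest(self) -> str:
        h = hashlib.sha256()
        for arr in self.state_arrays():
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()


def _split_by_specimen(
    specimen_ids: np.ndarray,
    fractions: tuple[float, float, float],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Assign whole specimens to train/val/external partitions."""
    unique = np.unique(specimen_ids)
    if unique.size < 2:
        raise ValueError("need >= 2 specimens for group-wise splitting")
    order = rng.permutation(unique)
    n = unique.size
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = max(1, int(round(fractions[1] * n))) if fractions[1] > 0 else 0
    n_train = min(n_train, n - max(1, n_val) - (1 if fractions[2] > 0 else 0))
    groups = {
        "train": order[:n_train],
        "val": order[n_train : n_train + n_val],
        "external": order[n_train + n_val :],
    }
    out: dict[str, np.ndarray] = {}
    for name, ids in groups.items():
        mask = np.isin(specimen_ids, ids)
        if (name == "train" or (name == "val" and fractions[1] > 0)
                or (name == "external" and fractions[2] > 0)) and not mask.any():
            raise ValueError(f"empty {name} partition under split {fractions}")
        out[name] = np.flatnonzero(mask)
    return out


class PHNet:
    """Model object: dataset + config in, fitted results out."""

    def __init__(self, dataset: SpectrumDataset, config: PHNetConfig | None = None):
        self.dataset = dataset
        self.config = config or PHNetConfig()
        self._results: PHNetResults | None = None

    def fit(self, verbose: bool = False) -> "PHNetResults":
        cfg = self.config
        ds = self.dataset
        rng = np.random.default_rng(cfg.seed)
        split = _split_by_specimen(ds.specimen_ids, cfg.split, rng)
        tr, va = split["train"], split["val"]
        # Standardisation statistics from the training partition only.
        seq_mean = ds.sequences[tr].mean(axis=0)
        seq_sd = ds.sequences[tr].std(axis=0) + 1e-6
        ph_mean = float(ds.ph[tr].mean())
        ph_sd = float(ds.ph[tr].std() + 1e-6)
        seqs = (ds.sequences - seq_mean) / seq_sd
        targets = (ds.ph - ph_mean) / ph_sd

        net = MultimodalPHRegressor(cfg, rng)
        opt = Adam(
            net.parameters(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay
        )
        history: list[dict[str, float]] = []
        best_val = np.inf
        best_weights = [a.copy() for a in net.state_arrays()]
        best_epoch = 0
        stale = 0
        for epoch in range(cfg.epochs):
            order = rng.permutation(tr)
            train_losses = []
            for start in range(0, order.size, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                net.zero_grad()
                batch_seqs = seqs[idx]
                if cfg.input_noise > 0:
                    # fresh noise per visit: the network cannot memorise a
                    # specific noise realisation of a training spectrum
                    batch_seqs = batch_seqs + rng.normal(
                        0.0, cfg.input_noise, batch_seqs.shape
                    ).astype(np.float32)
                pred = net.forward(
                    Tensor(batch_seqs), Tensor(ds.images[idx])
                ).reshape(idx.size)
                diff = pred - Tensor(targets[idx])
                loss = (diff * diff).mean()
                loss.backward()
                opt.step()
                train_losses.append(float(loss.data))
            val_loss = self._eval_loss(net, seqs, targets, va, cfg.batch_size)
            history.append(
                {
                    "epoch": epoch,
                    "train_loss": float(np.mean(train_losses)),
                    "val_loss": val_loss,
                }
            )
            if verbose:
                print(f"epoch {epoch:3d}  train {history[-1]['train_loss']:.5f}"
                      f"  val {val_loss:.5f}")
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_weights = [a.copy() for a in net.state_arrays()]
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    break
        net.load_state_arrays(best_weights)
        self._results = PHNetResults(
            network=net,
            config=cfg,
            history=pd.DataFrame(history),
            split_indices=split,
            seq_mean=seq_mean,
            seq_sd=seq_sd,
            ph_mean=ph_mean,
            ph_sd=ph_sd,
            data_fingerprint=ds.fingerprint(),
            best_epoch=best_epoch,
            dataset=ds,
        )
        return self._results

    def _eval_loss(self, net, seqs, targets, idx, batch) -> float:
        if idx.size == 0:
            return np.nan
        losses, weights = [], []
        for start in range(0, idx.size, batch):
            sl = idx[start : start + batch]
            pred = net.forward(Tensor(seqs[sl]), Tensor(self.dataset.images[sl]))
            losses.append(float(np.mean((pred.data.ravel() - targets[sl]) ** 2)))
            weights.append(sl.size)
        return float(np.average(losses, weights=weights))

    @property
    def results(self) -> "PHNetResults":
        if self._results is None:
            raise RuntimeError("model is not trained; call fit() first")
        return self._results

    def predict_ph(self, spectrum: RamanSpectrum, **kwargs) -> float:
        return self.results.predict_ph(spectrum, **kwargs)


@dataclass
class PHNetResults:
    """Fitted network with its training history and split bookkeeping."""

    network: MultimodalPHRegressor
    config: PHNetConfig
    history: pd.DataFrame
    split_indices: dict[str, np.ndarray]
    seq_mean: np.ndarray
    seq_sd: np.ndarray
    ph_mean: float
    ph_sd: float
    data_fingerprint: str
    best_epoch: int
    dataset: SpectrumDataset | None = None

    # -- prediction ------------------------------------------------------
    def predict_arrays(self, sequences: np.ndarray, images: np.ndarray) -> np.ndarray:
        seqs = (np.asarray(sequences, dtype=np.float32) - self.seq_mean) / self.seq_sd
        images = np.asarray(images, dtype=np.float32)
        out = []
        for start in range(0, seqs.shape[0], 256):
            pred = self.network.forward(
                Tensor(seqs[start : start + 256]),
                Tensor(images[start : start + 256]),
            )
            out.append(pred.data.ravel())
        return np.concatenate(out) * self.ph_sd + self.ph_mean

    def predict_ph(
        self,
        spectrum: RamanSpectrum,
        options: PreprocessOptions | None = None,
        already_preprocessed: bool = False,
    ) -> float:
        """Full pipeline for one spectrum: preprocess, resample, encode,
        both branches, co-attention, regression head."""
        clean = spectrum if already_preprocessed else preprocess(spectrum, options)
        seq = resample(clean.intensities, self.config.seq_len)[None, :]
        img = encode(clean, side=self.config.image_side).channels[None, :]
        return float(self.predict_arrays(seq, img)[0])

    def predict_dataset(self, dataset: SpectrumDataset | None = None) -> np.ndarray:
        ds = dataset or self.dataset
        if ds is None:
            raise ValueError("no dataset attached; pass one explicitly")
        return self.predict_arrays(ds.sequences, ds.images)

    # -- evaluation ------------------------------------------------------
    def split_r_squared(self) -> dict[str, float]:
        """R-squared of predicted vs true pH per split partition."""
        if self.dataset is None:
            raise ValueError("results were loaded without their dataset")
        preds = self.predict_dataset()
        out = {}
        for name, idx in self.split_indices.items():
            if idx.size == 0:
                out[name] = np.nan
                continue
            ref = self.dataset.ph[idx]
            sse = float(np.sum((preds[idx] - ref) ** 2))
            sst = float(np.sum((ref - ref.mean()) ** 2))
            out[name] = 1.0 - sse / sst if sst > 0 else np.nan
        return out

    def weights_digest(self) -> str:
        return self.network.weights_digest()

    def summary(self) -> str:
        cfg = self.config
        r2 = self.split_r_squared() if self.dataset is not None else {}
        lines = [
            "Multimodal pH regression network",
            "=" * 44,
            f"backbone widths     {cfg.conv_widths}",
            f"image side          {cfg.image_side}px   seq len {cfg.seq_len}",
            f"attention           {cfg.n_heads} head(s), d_attn {cfg.d_attn}",
            f"epochs run          {len(self.history)} (best {self.best_epoch})",
            f"final train loss    {self.history['train_loss'].iloc[-1]:.5f}",
            f"best val loss       {self.history['val_loss'].min():.5f}",
        ]
        for name, val in r2.items():
            lines.append(f"R2 ({name:<9})     {val:.4f}")
        lines.append(f"weights digest      {self.weights_digest()[:16]}")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        weights_dir = directory / "weights"
        weights_dir.mkdir(parents=True, exist_ok=True)
        # Individual .npy files: the format carries no timestamps, so a
        # rerun with the same seed reproduces every byte.
        for i, arr in enumerate(self.network.state_arrays()):
            np.save(weights_dir / f"arr_{i:03d}.npy", arr)
        np.save(weights_dir / "seq_mean.npy", self.seq_mean)
        np.save(weights_dir / "seq_sd.npy", self.seq_sd)
        meta = asdict(self.config) | {
            "ph_mean": self.ph_mean,
            "ph_sd": self.ph_sd,
            "best_epoch": self.best_epoch,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        self.history.to_csv(directory / "history.csv", index=False)
        (directory / "data_fingerprint.txt").write_text(self.data_fingerprint)


def load_results(directory: str | Path) -> PHNetResults:
    """Load a saved model artifact (without its training dataset)."""
    directory = Path(directory)
    meta = json.loads((directory / "config.json").read_text())
    ph_mean = meta.pop("ph_mean")
    ph_sd = meta.pop("ph_sd")
    best_epoch = meta.pop("best_epoch")
    meta["conv_widths"] = tuple(meta["conv_widths"])
    meta["split"] = tuple(meta["split"])
    config = PHNetConfig(**meta)
    weights_dir = directory / "weights"
    seq_mean = np.load(weights_dir / "seq_mean.npy")
    seq_sd = np.load(weights_dir / "seq_sd.npy")
    weight_files = sorted(weights_dir.glob("arr_*.npy"))
    net = MultimodalPHRegressor(config, np.random.default_rng(config.seed))
    net.load_state_arrays([np.load(f) for f in weight_files])
    return PHNetResults(
        network=net,
        config=config,
        history=pd.read_csv(directory / "history.csv"),
        split_indices={},
        seq_mean=seq_mean,
        seq_sd=seq_sd,
        ph_mean=ph_mean,
        ph_sd=ph_sd,
        data_fingerprint=(directory / "data_fingerprint.txt").read_text(),
        best_epoch=best_epoch,
    )
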