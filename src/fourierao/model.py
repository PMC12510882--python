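"""Multistage vision transformer for wavefront inference.

The model maps the 6-plane Fourier embedding to Zernike coefficients.
Each stage tiles the planes into non-overlapping square patches (32 then
16 pixels by default), attaches a radial positional encoding suited to
the circular symmetry of the pupil, and runs standard pre-projection /
post-norm transformer layers at an embedding width fixed to the patch
pixel count. Stages exchange information by merging patches back into
plane space and re-tiling at the next patch size, so no spatial
downsampling ever occurs. A global average over the feature axis and a
dense head emit the coefficient vector in lambda RMS units.

The estimator follows the scikit-learn protocol (``fit`` / ``predict``
/ ``get_params``), trained with mean-squared error on the coefficients
of the first 15 modes, the four unsensed modes supervised to zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from .embedding import (EmbeddingConfig, FourierEmbedding, IdealReference,
                        build_embedding)
from .optics import OpticalConfig
from .simulator import SimulationConfig, simulate_sample
from .zernike import Wavefront, all_modes, eligible_modes

__all__ = [
    "StageConfig",
    "ModelConfig",
    "WavefrontTransformer",
    "PredictionResult",
    "patchify",
    "merge_patches",
    "radial_positional_encoding",
    "simulate_training_set",
    "iterative_correct",
    "predict_wavefront",
]


@dataclass(frozen=True)
class StageConfig:
    """One transformer stage: patch size, depth and heads."""

    patch_size: int
    n_layers: int = 2
    n_heads: int = 2

    @property
    def embed_dim(self) -> int:
        # embedding width is tied to the patch pixel count
        return self.patch_size ** 2


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the multistage transformer."""

    stages: tuple = (StageConfig(32), StageConfig(16))
    d: int = 64
    n_planes: int = 6
    n_outputs: int = 15
    mlp_ratio: int = 4
    dropout: float = 0.1
    drop_path: float = 0.1
    rpe_harmonics: int = 16

    def __post_init__(self):
        if len(self.stages) < 1:
            raise ValueError("need at least one stage")
        for s in self.stages:
            if self.d % s.patch_size != 0:
                raise ValueError(f"d={self.d} not divisible by patch size "
                                 f"{s.patch_size}")
            if s.embed_dim % s.n_heads != 0:
                raise ValueError("head count must divide the embedding width")

    def to_json(self) -> str:
        return json.dumps({
            "stages": [[s.patch_size, s.n_layers, s.n_heads]
                       for s in self.stages],
            "d": self.d, "n_planes": self.n_planes,
            "n_outputs": self.n_outputs, "mlp_ratio": self.mlp_ratio,
            "dropout": self.dropout, "drop_path": self.drop_path,
            "rpe_harmonics": self.rpe_harmonics,
        })

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        o = json.loads(text)
        return cls(stages=tuple(StageConfig(*s) for s in o["stages"]),
                   d=o["d"], n_planes=o["n_planes"],
                   n_outputs=o["n_outputs"], mlp_ratio=o["mlp_ratio"],
                   dropout=o["dropout"], drop_path=o["drop_path"],
                   rpe_harmonics=o["rpe_harmonics"])


# -- patch bookkeeping -------------------------------------------------

def patchify(x: np.ndarray, p: int) -> np.ndarray:
    """Tile ``(..., l, d, d)`` into ``(..., l * k, p^2)`` patches."""
    *lead, l, d, d2 = x.shape
    if d != d2 or d % p != 0:
        raise ValueError("planes must be square with d divisible by p")
    g = d // p
    x = x.reshape(*lead, l, g, p, g, p)
    x = np.moveaxis(x, -2, -3)            # (..., l, g, g, p, p)
    return x.reshape(*lead, l * g * g, p * p)


def merge_patches(xp: np.ndarray, p: int, l: int, d: int) -> np.ndarray:
    """Exact inverse of :func:`patchify`."""
    *lead, lk, pp = xp.shape
    g = d // p
    if lk != l * g * g or pp != p * p:
        raise ValueError("patch sequence does not match (l, d, p)")
    x = xp.reshape(*lead, l, g, g, p, p)
    x = np.moveaxis(x, -2, -3)
    return x.reshape(*lead, l, d, d)


def _patchify_t(x: nn.Tensor, p: int, l: int, d: int) -> nn.Tensor:
    b = x.shape[0]
    g = d // p
    x = x.reshape(b, l, g, p, g, p)
    x = x.transpose(0, 1, 2, 4, 3, 5)
    return x.reshape(b, l * g * g, p * p)


def _merge_t(xp: nn.Tensor, p: int, l: int, d: int) -> nn.Tensor:
    b = xp.shape[0]
    g = d // p
    x = xp.reshape(b, l, g, g, p, p)
    x = x.transpose(0, 1, 2, 4, 3, 5)
    return x.reshape(b, l, d, d)


def radial_positional_encoding(d: int, p: int, m: int = 16) -> np.ndarray:
    """RPE of each patch center: ``[r, sin t, cos t, ..., sin mt, cos mt]``.

    Polar coordinates are measured about the plane center; the radius is
    normalized to [0, 1] by the outermost patch center. One row per
    patch of one plane, shape ``(k, 1 + 2 m)``.
    """
    g = d // p
    centers = (np.arange(g) + 0.5) * p - d / 2
    yy, xx = np.meshgrid(centers, centers, indexing="ij")
    r = np.hypot(yy, xx).ravel()
    theta = np.arctan2(yy, xx).ravel()
    rmax = r.max()
    if rmax > 0:
        r = r / rmax
    feats = [r]
    for h in range(1, m + 1):
        feats.append(np.sin(h * theta))
        feats.append(np.cos(h * theta))
    return np.stack(feats, axis=1).astype(np.float32)


# -- the network -------------------------------------------------------

class _Layer:
    """One transformer layer: post-norm MHA and MLP, both residual."""

    def __init__(self, dim: int, heads: int, mlp_ratio: int,
                 rng: np.random.Generator):
        self.dim, self.heads = dim, heads
        self.q = nn.Linear(dim, dim, rng)
        self.k = nn.Linear(dim, dim, rng)
        self.v = nn.Linear(dim, dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.ln1 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, mlp_ratio * dim, rng)
        self.fc2 = nn.Linear(mlp_ratio * dim, dim, rng)
        self.ln2 = nn.LayerNorm(dim)

    def parameters(self):
        out = []
        for m in (self.q, self.k, self.v, self.proj, self.ln1,
                  self.fc1, self.fc2, self.ln2):
            out += m.parameters()
        return out

    def _attention(self, x: nn.Tensor, train, dropout, rng) -> nn.Tensor:
        b, L, dim = x.shape
        h = self.heads
        dh = dim // h

        def split(t):
            return t.reshape(b, L, h, dh).transpose(0, 2, 1, 3)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = q.matmul(k.transpose(0, 1, 3, 2)).scale(1.0 / math.sqrt(dh))
        attn = nn.softmax(scores)
        ctx = attn.matmul(v).transpose(0, 2, 1, 3).reshape(b, L, dim)
        out = self.proj(ctx)
        if train and dropout > 0:
            out = out.mul_mask(nn.dropout_mask(out.shape, dropout, rng))
        return out

    def _mlp(self, x: nn.Tensor, train, dropout, rng) -> nn.Tensor:
        h = nn.gelu(self.fc1(x))
        if train and dropout > 0:
            h = h.mul_mask(nn.dropout_mask(h.shape, dropout, rng))
        out = self.fc2(h)
        if train and dropout > 0:
            out = out.mul_mask(nn.dropout_mask(out.shape, dropout, rng))
        return out

    def __call__(self, x: nn.Tensor, train: bool, dropout: float,
                 drop_path: float, rng: np.random.Generator) -> nn.Tensor:
        def maybe_drop_path(branch):
            if train and drop_path > 0:
                keep = 1.0 - drop_path
                mask = (rng.random((branch.shape[0], 1, 1)) < keep)
                return branch.mul_mask(mask.astype(np.float32) / keep)
            return branch

        z1 = maybe_drop_path(self.ln1(self._attention(x, train, dropout,
                                                      rng))) + x
        z2 = maybe_drop_path(self.ln2(self._mlp(z1, train, dropout,
                                                rng))) + z1
        return z2


class _Stage:
    def __init__(self, scfg: StageConfig, mcfg: ModelConfig,
                 rng: np.random.Generator):
        dim = scfg.embed_dim
        self.scfg = scfg
        # concatenation of patch pixels and RPE before one learnable
        # projection, realized as a sum of two linear maps
        self.proj_patch = nn.Linear(dim, dim, rng)
        self.proj_rpe = nn.Linear(1 + 2 * mcfg.rpe_harmonics, dim, rng)
        self.layers = [_Layer(dim, scfg.n_heads, mcfg.mlp_ratio, rng)
                       for _ in range(scfg.n_layers)]
        rpe1 = radial_positional_encoding(mcfg.d, scfg.patch_size,
                                          mcfg.rpe_harmonics)
        self.rpe = nn.Tensor(np.tile(rpe1, (mcfg.n_planes, 1)))

    def parameters(self):
        out = self.proj_patch.parameters() + self.proj_rpe.parameters()
        for layer in self.layers:
            out += layer.parameters()
        return out

    def __call__(self, planes: nn.Tensor, mcfg: ModelConfig, train: bool,
                 rng: np.random.Generator) -> nn.Tensor:
        xp = _patchify_t(planes, self.scfg.patch_size, mcfg.n_planes, mcfg.d)
        z = self.proj_patch(xp) + self.proj_rpe(self.rpe)
        z_in = z
        for layer in self.layers:
            z = layer(z, train, mcfg.dropout, mcfg.drop_path, rng)
        z = z + z_in  # stage-level skip
        return z


class _TransformerNet:
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.stages = [_Stage(s, cfg, rng) for s in cfg.stages]
        g_last = cfg.d // cfg.stages[-1].patch_size
        n_tokens = cfg.n_planes * g_last * g_last
        self.head = nn.Linear(n_tokens, cfg.n_outputs, rng)

    def parameters(self):
        out = []
        for s in self.stages:
            out += s.parameters()
        return out + self.head.parameters()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def forward(self, x: np.ndarray, train: bool = False,
                rng: Optional[np.random.Generator] = None) -> nn.Tensor:
        cfg = self.cfg
        if x.ndim != 4 or x.shape[1:] != (cfg.n_planes, cfg.d, cfg.d):
            raise ValueError(f"expected input of shape "
                             f"(batch, {cfg.n_planes}, {cfg.d}, {cfg.d})")
        rng = rng or np.random.default_rng()
        planes = nn.Tensor(x)
        for i, stage in enumerate(self.stages):
            z = stage(planes, cfg, train, rng)
            planes = _merge_t(z, stage.scfg.patch_size, cfg.n_planes, cfg.d)
        pooled = z.mean(axis=2)           # global average over features
        return self.head(pooled)

    # -- persistence ---------------------------------------------------
    def state_arrays(self):
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_arrays(self, arrays):
        for i, p in enumerate(self.parameters()):
            a = arrays[f"p{i}"]
            if a.shape != p.data.shape:
                raise ValueError("checkpoint does not match architecture")
            p.data = a.astype(np.float32)


# -- scikit-learn estimator -------------------------------------------

class WavefrontTransformer(BaseEstimator, RegressorMixin):
    """Multistage transformer regressor from embeddings to coefficients.

    Parameters mirror the architecture defaults: two stages with 32- and
    16-pixel patches, MLP four times the embedding width, dropout and
    stochastic depth 0.1, 16 angular harmonics in the positional
    encoding. Training is Adam with linear warmup and cosine decay on a
    mean-squared-error loss over the 15 output coefficients.
    """

    def __init__(self, patch_sizes=(32, 16), n_layers=2, n_heads=2,
                 mlp_ratio=4, dropout=0.1, drop_path=0.1, rpe_harmonics=16,
                 d=64, n_planes=6, n_outputs=15, epochs=2, batch_size=32,
                 learning_rate=1e-3, warmup_frac=0.05, standardize=True,
                 random_state=0):
        self.patch_sizes = patch_sizes
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.mlp_ratio = mlp_ratio
        self.dropout = dropout
        self.drop_path = drop_path
        self.rpe_harmonics = rpe_harmonics
        self.d = d
        self.n_planes = n_planes
        self.n_outputs = n_outputs
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.warmup_frac = warmup_frac
        self.standardize = standardize
        self.random_state = random_state

    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            stages=tuple(StageConfig(p, self.n_layers, self.n_heads)
                         for p in self.patch_sizes),
            d=self.d, n_planes=self.n_planes, n_outputs=self.n_outputs,
            mlp_ratio=self.mlp_ratio, dropout=self.dropout,
            drop_path=self.drop_path, rpe_harmonics=self.rpe_harmonics)

    @staticmethod
    def _as_array(X) -> np.ndarray:
        if isinstance(X, FourierEmbedding):
            X = X.planes[None]
        elif (isinstance(X, (list, tuple)) and X
              and isinstance(X[0], FourierEmbedding)):
            X = np.stack([e.planes for e in X])
        return np.asarray(X, dtype=np.float32)

    def fit(self, X, y):
        X = self._as_array(X)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError("X must be (n_samples, planes, d, d)")
        if len(X) == 0:
            raise ValueError("empty training set")
        if y.shape != (len(X), self.n_outputs):
            raise ValueError(f"y must be (n_samples, {self.n_outputs})")

        if self.standardize:
            # per-plane z-scoring: the amplitude planes sit at an offset
            # of ~1 with small aberration signal on top
            self.plane_mean_ = X.mean(axis=(0, 2, 3))
            self.plane_std_ = X.std(axis=(0, 2, 3)) + 1e-6
        else:
            self.plane_mean_ = np.zeros(X.shape[1], dtype=np.float32)
            self.plane_std_ = np.ones(X.shape[1], dtype=np.float32)
        X = ((X - self.plane_mean_[None, :, None, None])
             / self.plane_std_[None, :, None, None]).astype(np.float32)

        cfg = self._model_config()
        rng = np.random.default_rng(self.random_state)
        net = _TransformerNet(cfg, seed=self.random_state)
        n = len(X)
        bs = min(self.batch_size, n)
        steps_per_epoch = (n + bs - 1) // bs
        opt = nn.Adam(net.parameters(), lr=self.learning_rate,
                      total_steps=self.epochs * steps_per_epoch,
                      warmup_frac=self.warmup_frac)

        history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s in range(steps_per_epoch):
                idx = order[s * bs:(s + 1) * bs]
                pred = net.forward(X[idx], train=True, rng=rng)
                target = nn.Tensor(y[idx])
                loss = (pred - target).square().mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            history.append(epoch_loss / n)

        self.net_ = net
        self.config_ = cfg
        self.loss_history_ = history
        self.n_features_in_ = X[0].size
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        X = self._as_array(X)
        X = ((X - self.plane_mean_[None, :, None, None])
             / self.plane_std_[None, :, None, None]).astype(np.float32)
        out = np.empty((len(X), self.n_outputs), dtype=np.float32)
        bs = max(self.batch_size, 1)
        for s in range(0, len(X), bs):
            out[s:s + bs] = self.net_.forward(X[s:s + bs], train=False).data
        return out

    def predict_wavefront(self, emb: FourierEmbedding,
                          wavelength: float = 510.0) -> Wavefront:
        vec = self.predict(emb)[0]
        return Wavefront.from_vector(vec, all_modes(4), wavelength)

    # -- persistence ---------------------------------------------------
    def save(self, path):
        check_is_fitted(self, "net_")
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path / "weights.npz",
                            plane_mean=self.plane_mean_,
                            plane_std=self.plane_std_,
                            **self.net_.state_arrays())
        (path / "config.json").write_text(json.dumps({
            "model": json.loads(self.config_.to_json()),
            "estimator": self.get_params(),
        }, indent=2))

    @classmethod
    def load(cls, path) -> "WavefrontTransformer":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        est = cls(**meta["estimator"])
        cfg = ModelConfig.from_json(json.dumps(meta["model"]))
        net = _TransformerNet(cfg, seed=est.random_state)
        with np.load(path / "weights.npz") as z:
            arrays = dict(z)
        est.plane_mean_ = arrays.pop("plane_mean")
        est.plane_std_ = arrays.pop("plane_std")
        net.load_state_arrays(arrays)
        est.net_ = net
        est.config_ = cfg
        est.loss_history_ = []
        est.n_features_in_ = cfg.n_planes * cfg.d * cfg.d
        return est


# -- data generation and the correction loop ---------------------------

def simulate_training_set(n_samples: int,
                          config: Optional[SimulationConfig] = None,
                          seed: int = 0,
                          reference: Optional[IdealReference] = None,
                          ecfg: Optional[EmbeddingConfig] = None):
    """Simulate volumes and embed them: returns ``(X, y, rms)``.

    ``X`` is ``(n, 6, d, d)``, ``y`` the 15-mode coefficient vectors and
    ``rms`` the ground-truth wavefront RMS per sample.
    """
    config = config or SimulationConfig()
    reference = reference or IdealReference.build(config.optics, ecfg=ecfg)
    modes15 = all_modes(config.max_n)
    seeds = np.random.SeedSequence(seed).generate_state(n_samples)
    X, y, rms = [], [], []
    for s in seeds:
        sample = simulate_sample(config, int(s % (2 ** 31)))
        emb = build_embedding(sample.camera_counts, cfg=config.optics,
                              ecfg=ecfg, reference=reference)
        X.append(emb.planes)
        y.append(sample.ground_truth.to_vector(modes15))
        rms.append(sample.ground_truth.rms())
    return (np.stack(X).astype(np.float32),
            np.stack(y).astype(np.float32), np.asarray(rms))


@dataclass
class PredictionResult:
    """History of an iterative correction run."""

    initial: Wavefront
    predictions: list              # per-iteration predicted Wavefronts
    residuals: list                # per-iteration residual Wavefronts
    residual_rms: list             # lambda RMS after each iteration

    @property
    def final_residual(self) -> Wavefront:
        return self.residuals[-1] if self.residuals else self.initial


def iterative_correct(initial: Wavefront,
                      predictor: Callable[[FourierEmbedding], Wavefront],
                      config: Optional[SimulationConfig] = None,
                      iterations: int = 3,
                      seed: int = 0,
                      gain: float = 0.5,
                      modes: Optional[Sequence] = None,
                      reference: Optional[IdealReference] = None,
                      ecfg: Optional[EmbeddingConfig] = None) -> PredictionResult:
    """Closed-loop correction: image, infer, subtract, repeat.

    Each iteration simulates a fresh acquisition under the current
    residual wavefront, embeds it, asks the predictor for the wavefront
    and subtracts ``gain`` times the prediction — the in-silico
    analogue of an integrator-controlled deformable mirror, whose loop
    gain is conventionally kept below unity so that estimator bias and
    sign errors near zero residual cannot feed back into divergence.
    Only the ``modes`` of the prediction are applied (default: the
    sensed modes; piston, tip, tilt and defocus encode offsets and
    translations, and injecting them into the residual would shift the
    focal plane of every later acquisition).
    """
    config = config or SimulationConfig()
    reference = reference or IdealReference.build(config.optics, ecfg=ecfg)
    if modes is None:
        modes = (list(config.modes) if config.modes is not None
                 else eligible_modes(config.max_n))
    seeds = np.random.SeedSequence(seed).generate_state(max(iterations, 1))
    residual = initial
    predictions, residuals, rms_hist = [], [], []
    for it in range(iterations):
        sample = simulate_sample(config, int(seeds[it] % (2 ** 31)),
                                 wavefront=residual)
        emb = build_embedding(sample.camera_counts, cfg=config.optics,
                              ecfg=ecfg, reference=reference)
        pred = predictor(emb)
        pred = Wavefront({tuple(m): gain * pred.amplitude(m)
                          for m in modes}, pred.wavelength)
        residual = residual - pred
        predictions.append(pred)
        residuals.append(residual)
        rms_hist.append(residual.rms())
    return PredictionResult(initial, predictions, residuals, rms_hist)


def predict_wavefront(model: WavefrontTransformer, volume: np.ndarray,
                      cfg: Optional[OpticalConfig] = None,
                      reference: Optional[IdealReference] = None) -> Wavefront:
    """Embed a raw volume and return the model's wavefront estimate."""
    cfg = cfg or OpticalConfig()
    emb = build_embedding(volume, cfg=cfg, reference=reference)
    return model.predict_wavefront(emb, cfg.wavelength)
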