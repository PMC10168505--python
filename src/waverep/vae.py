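"""Convolutional VAE encodings of physiological waveforms.

Three modality presets share one architecture family:

* ``spinc``  — 2-channel (volume-time + flow-time) spirogram, 5 latents;
* ``rspinc`` — 1-channel flow-volume curve with the 5 spirogram EDFs
  injected at the decoder input (latent 2, decoder input width 7), so the
  learned coordinates carry only residual signal;
* ``plenc``  — 1-channel 100-sample PPG pulse, 5 latents.

Encoder: three stride-1 conv layers each followed by max pooling, then
three dense layers ending in separate mean/log-variance heads. Decoder
mirrors it: three dense layers, then three (upsample -> stride-1
convolution) stages back to the input shape. Loss = mean squared
reconstruction error + beta * KL(posterior || N(0, I)) over the *learned*
coordinates only. Inputs are z-scored per channel with training-set
statistics (inverted at reconstruction); injected EDFs are z-scored the
same way.

Training is deterministic given the config seed (single-threaded numpy).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from ._autodiff import Adam, Tensor, no_grad

MODALITIES = ("spinc", "rspinc", "plenc")


@dataclass
class ModelConfig:
    modality: str = "spinc"
    input_length: int = 1000
    input_channels: int = 2
    latent_dim: int = 5
    n_injected_features: int = 0
    conv_channels: tuple[int, int, int] = (16, 32, 64)
    kernel_size: int = 5
    pool_factor: int = 2
    fc_widths: tuple[int, int] = (256, 128)
    kl_weight: float = 1e-3
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 30
    patience: int = 5
    lr_decay: float = 0.5      # multiplier applied when validation plateaus
    lr_patience: int = 2
    val_fraction: float = 0.2
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be >= 0")

    @property
    def decoder_input_dim(self) -> int:
        return self.latent_dim + self.n_injected_features

    def encoder_lengths(self) -> tuple[int, int, int, int]:
        L = self.input_length
        p = self.pool_factor
        L1 = L // p
        L2 = L1 // p
        L3 = L2 // p
        return L, L1, L2, L3


def default_config(modality: str, **overrides) -> ModelConfig:
    """Modality presets; keyword overrides win."""
    presets = {
        "spinc": dict(input_length=1000, input_channels=2, latent_dim=5,
                      n_injected_features=0),
        "rspinc": dict(input_length=1000, input_channels=1, latent_dim=2,
                       n_injected_features=5),
        "plenc": dict(input_length=100, input_channels=1, latent_dim=5,
                      n_injected_features=0),
    }
    if modality not in presets:
        raise ValueError(f"modality must be one of {MODALITIES}")
    kwargs = {**presets[modality], **overrides}
    return ModelConfig(modality=modality, **kwargs)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def gaussian_kl(mu: np.ndarray, log_var: np.ndarray,
                injected_mask: np.ndarray | None = None) -> float:
    """KL(N(mu, sigma^2) || N(0, 1)) summed over learned coordinates,
    averaged over the batch. ``injected_mask`` marks learned positions
    (True = learned); injected positions are excluded."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    lv = np.atleast_2d(np.asarray(log_var, dtype=float))
    if injected_mask is not None:
        mask = np.asarray(injected_mask, dtype=bool)
        mu, lv = mu[:, mask], lv[:, mask]
    per_sample = -0.5 * np.sum(1 + lv - mu ** 2 - np.exp(lv), axis=1)
    return float(per_sample.mean())


def vae_loss(x: np.ndarray, x_hat: np.ndarray, mu: np.ndarray,
             log_var: np.ndarray, beta: float,
             injected_mask: np.ndarray | None = None) -> dict[str, float]:
    """Total loss and its components: MSE averaged over all elements plus
    beta times the KL over learned coordinates."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat shapes differ")
    recon = float(((x - x_hat) ** 2).mean())
    kl = gaussian_kl(mu, log_var, injected_mask)
    return {"loss": recon + beta * kl, "reconstruction": recon, "kl": kl}


# ---------------------------------------------------------------------------
# parameters and forward passes
# ---------------------------------------------------------------------------

def _init_params(cfg: ModelConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    c1, c2, c3 = cfg.conv_channels
    K = cfg.kernel_size
    f1, f2 = cfg.fc_widths
    _, _, _, L3 = cfg.encoder_lengths()
    flat = c3 * L3

    def conv(cout, cin):
        scale = np.sqrt(2.0 / (cin * K))
        return rng.standard_normal((cout, cin, K)) * scale

    def dense(din, dout, scale=None):
        s = scale if scale is not None else np.sqrt(2.0 / din)
        return rng.standard_normal((din, dout)) * s

    arrays = {
        "enc_conv1_w": conv(c1, cfg.input_channels),
        "enc_conv1_b": np.zeros(c1),
        "enc_conv2_w": conv(c2, c1), "enc_conv2_b": np.zeros(c2),
        "enc_conv3_w": conv(c3, c2), "enc_conv3_b": np.zeros(c3),
        "enc_fc1_w": dense(flat, f1), "enc_fc1_b": np.zeros(f1),
        "enc_fc2_w": dense(f1, f2), "enc_fc2_b": np.zeros(f2),
        "enc_mu_w": dense(f2, cfg.latent_dim, scale=0.01),
        "enc_mu_b": np.zeros(cfg.latent_dim),
        "enc_lv_w": dense(f2, cfg.latent_dim, scale=0.01),
        "enc_lv_b": np.full(cfg.latent_dim, -2.0),
        "dec_fc1_w": dense(cfg.decoder_input_dim, f2),
        "dec_fc1_b": np.zeros(f2),
        "dec_fc2_w": dense(f2, f1), "dec_fc2_b": np.zeros(f1),
        "dec_fc3_w": dense(f1, flat), "dec_fc3_b": np.zeros(flat),
        "dec_conv3_w": conv(c2, c3), "dec_conv3_b": np.zeros(c2),
        "dec_conv2_w": conv(c1, c2), "dec_conv2_b": np.zeros(c1),
        "dec_conv1_w": conv(cfg.input_channels, c1),
        "dec_conv1_b": np.zeros(cfg.input_channels),
    }
    dt = np.dtype(cfg.dtype)
    return {k: Tensor(v.astype(dt), requires_grad=True)
            for k, v in arrays.items()}


def _encode_fwd(P: dict[str, Tensor], cfg: ModelConfig,
                x: Tensor) -> tuple[Tensor, Tensor]:
    p = cfg.pool_factor
    h = x.conv1d(P["enc_conv1_w"], P["enc_conv1_b"]).relu().maxpool1d(p)
    h = h.conv1d(P["enc_conv2_w"], P["enc_conv2_b"]).relu().maxpool1d(p)
    h = h.conv1d(P["enc_conv3_w"], P["enc_conv3_b"]).relu().maxpool1d(p)
    B = h.shape[0]
    h = h.reshape(B, -1)
    h = (h @ P["enc_fc1_w"] + P["enc_fc1_b"]).relu()
    h = (h @ P["enc_fc2_w"] + P["enc_fc2_b"]).relu()
    mu = h @ P["enc_mu_w"] + P["enc_mu_b"]
    log_var = h @ P["enc_lv_w"] + P["enc_lv_b"]
    return mu, log_var


def _decode_fwd(P: dict[str, Tensor], cfg: ModelConfig, d: Tensor) -> Tensor:
    c1, c2, c3 = cfg.conv_channels
    L, L1, L2, L3 = cfg.encoder_lengths()
    h = (d @ P["dec_fc1_w"] + P["dec_fc1_b"]).relu()
    h = (h @ P["dec_fc2_w"] + P["dec_fc2_b"]).relu()
    h = (h @ P["dec_fc3_w"] + P["dec_fc3_b"]).relu()
    B = h.shape[0]
    h = h.reshape(B, c3, L3)
    h = h.upsample_to(L2).conv1d(P["dec_conv3_w"], P["dec_conv3_b"]).relu()
    h = h.upsample_to(L1).conv1d(P["dec_conv2_w"], P["dec_conv2_b"]).relu()
    return h.upsample_to(L).conv1d(P["dec_conv1_w"], P["dec_conv1_b"])


# ---------------------------------------------------------------------------
# trained model container
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    config: ModelConfig
    params: dict[str, np.ndarray]
    x_mean: np.ndarray  # per-channel standardization stats
    x_std: np.ndarray
    edf_mean: np.ndarray | None
    edf_std: np.ndarray | None
    training_curve: list[dict] = field(default_factory=list)
    seed: int = 0

    def _tensors(self) -> dict[str, Tensor]:
        return {k: Tensor(v) for k, v in self.params.items()}


def _as_batched(curves: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    x = np.asarray(curves, dtype=float)
    if x.ndim == 2:
        if cfg.input_channels != 1:
            raise ValueError(
                f"expected (n, {cfg.input_channels}, {cfg.input_length})")
        x = x[:, None, :]
    if x.ndim != 3 or x.shape[1:] != (cfg.input_channels, cfg.input_length):
        raise ValueError(
            f"curves must have shape (n, {cfg.input_channels}, "
            f"{cfg.input_length}), got {x.shape}")
    return x


def train(dataset: np.ndarray, config: ModelConfig,
          edfs: np.ndarray | None = None) -> TrainedModel:
    """Train a VAE with Adam, an internal 80/20 train/validation split,
    and early stopping on validation loss (best-parameters restore).

    ``edfs``: (n, n_injected_features) expert features, required iff the
    modality injects features (rspinc).
    """
    cfg = config
    x = _as_batched(dataset, cfg)
    n = x.shape[0]
    if cfg.n_injected_features:
        if edfs is None:
            raise ValueError(f"{cfg.modality} requires injected EDFs")
        edfs = np.asarray(edfs, dtype=float)
        if edfs.shape != (n, cfg.n_injected_features):
            raise ValueError(
                f"edfs must have shape ({n}, {cfg.n_injected_features})")
        if not np.all(np.isfinite(edfs)):
            raise ValueError("edfs must be finite")
    elif edfs is not None:
        raise ValueError(f"{cfg.modality} does not take injected EDFs")

    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    x_mean = x[tr_idx].mean(axis=(0, 2), keepdims=True)
    x_std = x[tr_idx].std(axis=(0, 2), keepdims=True)
    x_std[x_std == 0] = 1.0
    dt = np.dtype(cfg.dtype)
    xs = ((x - x_mean) / x_std).astype(dt)

    edf_mean = edf_std = None
    es = None
    if cfg.n_injected_features:
        edf_mean = edfs[tr_idx].mean(axis=0)
        edf_std = edfs[tr_idx].std(axis=0)
        edf_std[edf_std == 0] = 1.0
        es = ((edfs - edf_mean) / edf_std).astype(dt)

    P = _init_params(cfg, rng)
    opt = Adam(list(P.values()), lr=cfg.learning_rate)

    def run_batch(idx: np.ndarray, sample: bool) -> dict[str, float] | Tensor:
        xb = Tensor(xs[idx])
        mu, log_var = _encode_fwd(P, cfg, xb)
        if sample:
            eps = Tensor(rng.standard_normal(mu.shape).astype(dt))
            z = mu + (log_var * 0.5).exp() * eps
        else:
            z = mu
        d = z
        if es is not None:
            d = Tensor.concat([Tensor(es[idx]), z], axis=1)
        x_hat = _decode_fwd(P, cfg, d)
        diff = x_hat - xb
        recon = (diff * diff).mean()
        kl = ((1.0 + log_var - mu * mu - log_var.exp()).sum(axis=1)
              * (-0.5)).mean()
        return recon + kl * cfg.kl_weight

    def eval_loss(idx: np.ndarray) -> float:
        total = 0.0
        with no_grad():
            for lo in range(0, len(idx), 256):
                sub = idx[lo:lo + 256]
                loss = run_batch(sub, sample=False)
                total += float(loss.data) * len(sub)
        return total / len(idx)

    curve: list[dict] = []
    best_val = np.inf
    best_params = {k: v.data.copy() for k, v in P.items()}
    stale = 0
    lr_stale = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        tr_loss = 0.0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            loss = run_batch(idx, sample=True)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}; lower the learning "
                    "rate or kl_weight")
            opt.zero_grad()
            loss.backward()
            opt.step()
            tr_loss += float(loss.data) * len(idx)
        val = eval_loss(val_idx)
        curve.append({"epoch": epoch, "train": tr_loss / len(tr_idx),
                      "val": val})
        if val < best_val - 1e-9:
            best_val = val
            best_params = {k: v.data.copy() for k, v in P.items()}
            stale = 0
            lr_stale = 0
        else:
            stale += 1
            lr_stale += 1
            if stale >= cfg.patience:
                break
            if lr_stale >= cfg.lr_patience:
                opt.lr *= cfg.lr_decay
                lr_stale = 0

    return TrainedModel(config=cfg, params=best_params,
                        x_mean=x_mean[0], x_std=x_std[0],
                        edf_mean=edf_mean, edf_std=edf_std,
                        training_curve=curve, seed=cfg.seed)


def select_hyperparameters(dataset: np.ndarray, configs: list[ModelConfig],
                           edfs: np.ndarray | None = None) -> TrainedModel:
    """Train every config and return the model with the lowest final
    validation loss."""
    if not configs:
        raise ValueError("empty config grid")
    models = [train(dataset, c, edfs) for c in configs]
    return min(models, key=lambda m: m.training_curve[-1]["val"])


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

@dataclass
class Encoding:
    """Posterior means, one row per encoded individual."""

    values: np.ndarray
    model_id: str = ""


def encode(model: TrainedModel, curves: np.ndarray,
           batch_size: int = 512) -> Encoding:
    """Posterior mean coordinates (no sampling)."""
    cfg = model.config
    x = _as_batched(curves, cfg)
    xs = ((x - model.x_mean[None]) / model.x_std[None]).astype(
        np.dtype(cfg.dtype))
    P = model._tensors()
    out = []
    with no_grad():
        for lo in range(0, len(xs), batch_size):
            mu, _ = _encode_fwd(P, cfg, Tensor(xs[lo:lo + batch_size]))
            out.append(mu.data)
    return Encoding(values=np.vstack(out), model_id=cfg.modality)


def decode(model: TrainedModel, z: np.ndarray,
           edfs: np.ndarray | None = None) -> np.ndarray:
    """Decode latent vectors (plus injected EDFs for rspinc) to curves in
    the original units."""
    cfg = model.config
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != cfg.latent_dim:
        raise ValueError(f"z must have width {cfg.latent_dim}")
    if cfg.n_injected_features:
        if edfs is None:
            raise ValueError(f"{cfg.modality} decode requires EDFs")
        edfs = np.atleast_2d(np.asarray(edfs, dtype=float))
        if edfs.shape != (z.shape[0], cfg.n_injected_features):
            raise ValueError(
                f"edfs must have shape ({z.shape[0]}, "
                f"{cfg.n_injected_features})")
        es = (edfs - model.edf_mean) / model.edf_std
        d = np.column_stack([es, z])
    else:
        if edfs is not None:
            raise ValueError(f"{cfg.modality} decode takes no EDFs")
        d = z
    P = model._tensors()
    with no_grad():
        x_hat = _decode_fwd(P, cfg, Tensor(d)).data
    return x_hat * model.x_std[None] + model.x_mean[None]


def reconstruct(model: TrainedModel, curves: np.ndarray,
                edfs: np.ndarray | None = None) -> np.ndarray:
    enc = encode(model, curves)
    return decode(model, enc.values, edfs)


def reconstruction_mse(model: TrainedModel, curves: np.ndarray,
                       edfs: np.ndarray | None = None,
                       standardized: bool = True) -> float:
    """Validation-style MSE averaged across time points then samples;
    computed on standardized curves by default (comparable across models
    and to a PCA baseline fit on the same standardization)."""
    x = _as_batched(curves, model.config)
    recon = _as_batched(reconstruct(model, curves, edfs), model.config)
    if standardized:
        x = (x - model.x_mean[None]) / model.x_std[None]
        recon = (recon - model.x_mean[None]) / model.x_std[None]
    return float(((x - recon) ** 2).mean(axis=(1, 2)).mean())


def latent_traversal(model: TrainedModel, edfs: np.ndarray,
                     coordinate: int, grid: np.ndarray) -> np.ndarray:
    """Decode one curve per grid value, varying one latent coordinate with
    all others fixed at zero and the injected EDFs held constant."""
    cfg = model.config
    if cfg.modality != "rspinc":
        raise ValueError("latent traversal is defined for rspinc models")
    if not (0 <= coordinate < cfg.latent_dim):
        raise ValueError(f"coordinate must be in [0, {cfg.latent_dim})")
    grid = np.asarray(grid, dtype=float).ravel()
    z = np.zeros((grid.size, cfg.latent_dim))
    z[:, coordinate] = grid
    e = np.tile(np.asarray(edfs, dtype=float).ravel(), (grid.size, 1))
    return decode(model, z, e)


# ---------------------------------------------------------------------------
# cross-seed alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    permutation: np.ndarray  # enc_b column matched to each enc_a column
    signs: np.ndarray
    mean_abs_corr: float
    excluded: list[int] = field(default_factory=list)


def align_runs(enc_a: Encoding | np.ndarray,
               enc_b: Encoding | np.ndarray) -> Alignment:
    """Match coordinates of two runs by Hungarian assignment on the
    absolute correlation matrix; returns the permutation, sign flips, and
    the achieved mean |correlation|. Constant coordinates are excluded."""
    A = enc_a.values if isinstance(enc_a, Encoding) else np.asarray(enc_a)
    B = enc_b.values if isinstance(enc_b, Encoding) else np.asarray(enc_b)
    if A.shape != B.shape:
        raise ValueError("encodings must share individuals and latent_dim")
    k = A.shape[1]
    const_a = [j for j in range(k) if A[:, j].std() == 0]
    const_b = [j for j in range(k) if B[:, j].std() == 0]
    excluded = sorted(set(const_a) | set(const_b))
    corr = np.zeros((k, k))
    for i in range(k):
        if i in const_a:
            continue
        for j in range(k):
            if j in const_b:
                continue
            corr[i, j] = np.corrcoef(A[:, i], B[:, j])[0, 1]
    rows, cols = linear_sum_assignment(-np.abs(corr))
    perm = np.empty(k, dtype=int)
    perm[rows] = cols
    signs = np.sign(corr[rows, perm[rows]])
    signs[signs == 0] = 1
    used = [i for i in range(k) if i not in excluded]
    mean_abs = float(np.abs(corr[used, perm[used]]).mean()) if used else 0.0
    return Alignment(permutation=perm, signs=signs.astype(int),
                     mean_abs_corr=mean_abs, excluded=excluded)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str) -> None:
    """Self-describing .npz archive: config JSON + weights + stats."""
    cfg = asdict(model.config)
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    np.savez(path, __config__=json.dumps(cfg),
             __curve__=json.dumps(model.training_curve),
             x_mean=model.x_mean, x_std=model.x_std,
             edf_mean=(model.edf_mean if model.edf_mean is not None
                       else np.array([])),
             edf_std=(model.edf_std if model.edf_std is not None
                      else np.array([])),
             **arrays)


def load_model(path: str) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        cfg_dict = json.loads(str(z["__config__"]))
        for key in ("conv_channels", "fc_widths"):
            cfg_dict[key] = tuple(cfg_dict[key])
        cfg = ModelConfig(**cfg_dict)
        params = {k[len("param_"):]: z[k] for k in z.files
                  if k.startswith("param_")}
        edf_mean = z["edf_mean"] if z["edf_mean"].size else None
        edf_std = z["edf_std"] if z["edf_std"].size else None
        return TrainedModel(config=cfg, params=params,
                            x_mean=z["x_mean"], x_std=z["x_std"],
                            edf_mean=edf_mean, edf_std=edf_std,
                            training_curve=json.loads(str(z["__curve__"])),
                            seed=cfg.seed)
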