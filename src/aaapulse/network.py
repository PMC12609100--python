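"""Severity-estimation CNN with continuous property-adversarial regularization (CPAR).

A one-dimensional AlexNet-style feature extractor reads the brachial and
tibial waveforms stacked as a (1, 2, 256) tensor. Five dilated convolutions
(kernel 5 then 3,3,3,3, stride 1, dilation 3, length-preserving padding) act
along the time axis only, so the two rows are processed independently. A skip
connection links layer 2 to layer 4 (1x1 projection when widths differ), a
convolutional block attention module (CBAM, per-row channel + temporal
attention, spatial kernel 7, channel reduction 16) follows layers 3 and 5,
and a compression stage (1x1 convolution to 32 channels, 4x average pooling)
yields a latent tensor of shape (32, 2, 64). Three parallel regressor heads
(fully connected 64, 64, 1) read the flattened latent: one estimates the
aneurysm volumetric severity index (VSI, %), the other two are adversaries
predicting subject height and age.

Training is a three-player optimisation: the VSI head minimises its MSE on
labeled data; each adversarial head minimises a bounded disturbance loss
``mean(log(1/(1 - tanh|e|)))`` on labeled + unlabeled data; and the feature
extractor minimises ``L_label - lambda (L_height + L_age)``, i.e. it is
rewarded for making the adversaries fail, which drives the latent features
to be uninformative about the confounders. All three parameter sets have
their own Adam optimizer. At inference only the extractor and the VSI head
run.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, concat

__all__ = [
    "NetworkConfig",
    "TrainingConfig",
    "ModelState",
    "build_network",
    "input_preprocess",
    "label_loss",
    "disturbance_loss",
    "training_step",
    "train",
    "predict_vsi",
    "TrainingHistory",
]


@dataclass
class NetworkConfig:
    """Architecture hyperparameters; the defaults match the reference design
    (feature extractor ~810k parameters, each head 266,433)."""

    input_width: int = 256
    input_height: int = 2
    channels: tuple[int, ...] = (96, 192, 288, 288, 288)
    kernels: tuple[int, ...] = (5, 3, 3, 3, 3)
    dilation: int = 3
    cbam_after: tuple[int, ...] = (3, 5)  # 1-based conv layer indices
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    skip_from: int = 2
    skip_to: int = 4
    latent_channels: int = 32
    pool_factor: int = 4
    head_widths: tuple[int, ...] = (64, 64)

    @property
    def latent_width(self) -> int:
        return self.input_width // self.pool_factor

    @property
    def latent_shape(self) -> tuple[int, int, int]:
        return (self.latent_channels, self.input_height, self.latent_width)

    def validate(self) -> None:
        if len(self.channels) != len(self.kernels):
            raise ValueError("channels and kernels must have equal length")
        if self.input_width % self.pool_factor:
            raise ValueError("input width must be divisible by the pooling factor")
        if not (1 <= self.skip_from < self.skip_to <= len(self.channels)):
            raise ValueError("invalid skip connection layer indices")


@dataclass
class TrainingConfig:
    """Optimisation hyperparameters. ``for_modality`` loads the selected
    per-modality values (batch size 16; Adam betas, CPAR weight lambda and
    the three learning rates differ between the pressure and PVR variants)."""

    batch_size: int = 16
    beta1: float = 0.950
    beta2: float = 0.950
    lam: float = 6.5e-4
    lr_f: float = 1.2e-3
    lr_l: float = 1.1e-3
    lr_eta: float = 7.0e-4
    patience: int = 25
    max_epochs: int = 100
    seed: int = 0
    modality: str = "pvr"
    adversarial_sign: str = "reversal"  # "reversal" (make adversaries fail) or "printed"

    @classmethod
    def for_modality(cls, modality: str, **overrides) -> "TrainingConfig":
        if modality == "pvr":
            base = dict(beta1=0.950, beta2=0.950, lam=6.5e-4,
                        lr_f=1.2e-3, lr_l=1.1e-3, lr_eta=7.0e-4)
        elif modality == "abp":
            base = dict(beta1=0.989, beta2=0.970, lam=7.3e-4,
                        lr_f=2.2e-4, lr_l=3.6e-5, lr_eta=5.5e-6)
        else:
            raise ValueError("modality must be 'pvr' or 'abp'")
        base.update(overrides)
        return cls(modality=modality, **base)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class _Conv:
    def __init__(self, cin, cout, k, dilation, rng):
        scale = np.sqrt(2.0 / (cin * k))
        self.w = Tensor(rng.standard_normal((cout, cin, k)) * scale, requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d_row(self.w, self.b, self.dilation)

    def params(self):
        return [self.w, self.b]


class _BatchNorm:
    """Batch normalisation with statistics and affine parameters per
    (channel, row), so the two waveform rows never mix."""

    def __init__(self, c, h, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones((1, c, h, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, h, 1)), requires_grad=True)
        self.rm = np.zeros((1, c, h, 1))
        self.rv = np.ones((1, c, h, 1))
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 3), keepdims=True)
            self.rm = (1 - self.momentum) * self.rm + self.momentum * mu.data
            self.rv = (1 - self.momentum) * self.rv + self.momentum * var.data
            xhat = (x - mu) / ((var + self.eps) ** 0.5)
        else:
            xhat = (x - Tensor(self.rm)) / Tensor(np.sqrt(self.rv + self.eps))
        return xhat * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class _CBAM:
    """Convolutional block attention, applied independently per row.

    Channel attention pools along time only (per row) through a shared
    two-layer MLP; temporal attention convolves the channel-wise mean and max
    maps with a kernel-7 convolution. Keeping the pooling per-row preserves
    the extractor's row independence.
    """

    def __init__(self, c, reduction, spatial_kernel, rng):
        hidden = max(1, c // reduction)
        s1 = np.sqrt(2.0 / c)
        s2 = np.sqrt(2.0 / hidden)
        self.w1 = Tensor(rng.standard_normal((c, hidden)) * s1, requires_grad=True)
        self.w2 = Tensor(rng.standard_normal((hidden, c)) * s2, requires_grad=True)
        self.spatial = _Conv(2, 1, spatial_kernel, 1, rng)

    def _mlp(self, s: Tensor) -> Tensor:
        # s: (N, C, H) -> treat as (N*H, C)
        n, c, h = s.shape
        flat = s.transpose(0, 2, 1).reshape(n * h, c)
        out = (flat @ self.w1).relu() @ self.w2
        return out.reshape(n, h, c).transpose(0, 2, 1)

    def __call__(self, x: Tensor) -> Tensor:
        att_c = (self._mlp(x.mean(axis=3)) + self._mlp(x.max(axis=3))).sigmoid()
        n, c, h = att_c.shape
        x = x * att_c.reshape(n, c, h, 1)
        t_avg = x.mean(axis=1, keepdims=True)
        t_max = x.max(axis=1, keepdims=True)
        att_s = self.spatial(concat([t_avg, t_max], axis=1)).sigmoid()
        return x * att_s

    def params(self):
        return [self.w1, self.w2] + self.spatial.params()


class _Head:
    """Fully connected regressor head (widths e.g. 4096 -> 64 -> 64 -> 1)."""

    def __init__(self, n_in, widths, rng):
        self.layers = []
        prev = n_in
        for wdt in list(widths) + [1]:
            scale = np.sqrt(2.0 / prev)
            w = Tensor(rng.standard_normal((prev, wdt)) * scale, requires_grad=True)
            b = Tensor(np.zeros(wdt), requires_grad=True)
            self.layers.append((w, b))
            prev = wdt

    def __call__(self, z: Tensor) -> Tensor:
        for i, (w, b) in enumerate(self.layers):
            z = z @ w + b
            if i < len(self.layers) - 1:
                z = z.relu()
        return z.reshape(-1)

    def params(self):
        return [p for wb in self.layers for p in wb]


class FeatureExtractor:
    def __init__(self, config: NetworkConfig, rng):
        cfg = config
        self.cfg = cfg
        chans = [1] + list(cfg.channels)
        self.convs = [
            _Conv(chans[i], chans[i + 1], cfg.kernels[i], cfg.dilation, rng)
            for i in range(len(cfg.channels))
        ]
        self.bns = [_BatchNorm(c, cfg.input_height) for c in cfg.channels]
        self.cbams = {
            i: _CBAM(cfg.channels[i - 1], cfg.cbam_reduction, cfg.cbam_spatial_kernel, rng)
            for i in cfg.cbam_after
        }
        c_from, c_to = cfg.channels[cfg.skip_from - 1], cfg.channels[cfg.skip_to - 1]
        self.skip_proj = None if c_from == c_to else _Conv(c_from, c_to, 1, 1, rng)
        self.compress = _Conv(cfg.channels[-1], cfg.latent_channels, 1, 1, rng)

    def set_training(self, flag: bool) -> None:
        for bn in self.bns:
            bn.training = flag

    def __call__(self, x: Tensor) -> Tensor:
        cfg = self.cfg
        skip_out = None
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns), start=1):
            h = bn(conv(x))
            if i == cfg.skip_to and skip_out is not None:
                proj = skip_out if self.skip_proj is None else self.skip_proj(skip_out)
                h = h + proj
            x = h.relu()
            if i == cfg.skip_from:
                skip_out = x
            if i in self.cbams:
                x = self.cbams[i](x)
        z = self.compress(x).avgpool_w(cfg.pool_factor)
        return z

    def params(self):
        out = []
        for conv in self.convs:
            out += conv.params()
        for bn in self.bns:
            out += bn.params()
        for cbam in self.cbams.values():
            out += cbam.params()
        if self.skip_proj is not None:
            out += self.skip_proj.params()
        out += self.compress.params()
        return out


@dataclass
class TrainingHistory:
    epoch: list[int] = field(default_factory=list)
    label_loss: list[float] = field(default_factory=list)
    disturbance_height: list[float] = field(default_factory=list)
    disturbance_age: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)

    def as_dict(self):
        return {
            "epoch": self.epoch,
            "label_loss": self.label_loss,
            "disturbance_height": self.disturbance_height,
            "disturbance_age": self.disturbance_age,
            "val_loss": self.val_loss,
        }


class ModelState:
    """Feature extractor plus the three regressor heads and training metadata.

    The four parameter sets are disjoint; inference touches only the
    extractor and the VSI head.
    """

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        config = config or NetworkConfig()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        self.extractor = FeatureExtractor(config, rng)
        n_latent = int(np.prod(config.latent_shape))
        self.head_label = _Head(n_latent, config.head_widths, rng)
        self.head_height = _Head(n_latent, config.head_widths, rng)
        self.head_age = _Head(n_latent, config.head_widths, rng)
        self.target_stats = {"height": (0.0, 1.0), "age": (0.0, 1.0)}
        self.history: TrainingHistory | None = None
        self.trained = False

    # -- parameter bookkeeping ----------------------------------------------
    def params_f(self):
        return self.extractor.params()

    def params_l(self):
        return self.head_label.params()

    def params_eta_h(self):
        return self.head_height.params()

    def params_eta_a(self):
        return self.head_age.params()

    def n_params_extractor(self) -> int:
        return sum(p.data.size for p in self.params_f())

    def n_params_head(self) -> int:
        return sum(p.data.size for p in self.params_l())

    def set_training(self, flag: bool) -> None:
        self.extractor.set_training(flag)

    def latent(self, x: Tensor) -> Tensor:
        z = self.extractor(x)
        return z.reshape(x.shape[0], -1)

    def forward_label(self, x: Tensor) -> Tensor:
        return self.head_label(self.latent(x))

    # -- persistence ---------------------------------------------------------
    def state_arrays(self):
        return [p.data for p in (self.params_f() + self.params_l()
                                 + self.params_eta_h() + self.params_eta_a())] + [
            bn.rm for bn in self.extractor.bns
        ] + [bn.rv for bn in self.extractor.bns]

    def copy_weights(self) -> list[np.ndarray]:
        return [a.copy() for a in self.state_arrays()]

    def load_weights(self, arrays: list[np.ndarray]) -> None:
        for tgt, src in zip(self.state_arrays(), arrays):
            tgt[...] = src

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(
                {
                    "config": self.config,
                    "weights": self.copy_weights(),
                    "target_stats": self.target_stats,
                    "trained": self.trained,
                    "history": self.history.as_dict() if self.history else None,
                },
                fh,
            )

    @classmethod
    def load(cls, path) -> "ModelState":
        with open(path, "rb") as fh:
            blob = pickle.load(fh)
        state = cls(blob["config"])
        state.load_weights(blob["weights"])
        state.target_stats = blob["target_stats"]
        state.trained = blob["trained"]
        return state


def build_network(config: NetworkConfig | None = None, seed: int = 0) -> ModelState:
    """Construct an initialised model (latent shape enforced by the config)."""
    return ModelState(config, seed)


# ---------------------------------------------------------------------------
# inputs and losses
# ---------------------------------------------------------------------------


def input_preprocess(brachial: np.ndarray, tibial: np.ndarray,
                     width: int = 256, eps: float = 1e-12) -> np.ndarray:
    """Stack the two waveforms into (1, 2, W), each row z-scored independently.

    Per-row standardisation makes the network input invariant to the
    arbitrary amplitude scale of cuff recordings; a constant row maps to
    zeros.
    """
    rows = []
    for w in (brachial, tibial):
        w = np.asarray(w, dtype=float).ravel()
        if len(w) != width:
            raise ValueError(f"waveform length {len(w)} != {width}")
        sd = w.std()
        rows.append((w - w.mean()) / (sd + eps) if sd > eps else np.zeros(width))
    return np.stack(rows)[None, :, :]


def preprocess_batch(brachial: np.ndarray, tibial: np.ndarray) -> np.ndarray:
    """Vectorised preprocessing of (n, W) arrays into (n, 1, 2, W)."""
    out = np.empty((len(brachial), 1, 2, brachial.shape[1]))
    for j, w in enumerate((brachial, tibial)):
        mu = w.mean(axis=1, keepdims=True)
        sd = w.std(axis=1, keepdims=True)
        out[:, 0, j, :] = np.where(sd > 1e-12, (w - mu) / (sd + 1e-12), 0.0)
    return out


def label_loss(predictions: Tensor, labels: np.ndarray) -> Tensor:
    """Mean squared error on the severity index (% units)."""
    if predictions.data.size == 0:
        raise ValueError("empty batch")
    return ((predictions - Tensor(labels)) ** 2).mean()


def disturbance_loss(predictions: Tensor, targets: np.ndarray) -> Tensor:
    """Bounded adversarial regression loss ``mean(log(1/(1 - tanh|e|)))``.

    Computed via the exact identity ``log(1/(1-tanh x)) = softplus(2x) - ln 2``
    (numerically stable for large errors, asymptotically ``2|e| - ln 2``).
    Targets are expected on a standardised scale.
    """
    e = (predictions - Tensor(targets)).abs()
    return ((2.0 * e).softplus() - np.log(2.0)).mean()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _grads(loss: Tensor, params: list[Tensor]) -> list[np.ndarray]:
    loss.zero_grad_tree()
    loss.backward()
    return [np.zeros_like(p.data) if p.grad is None else p.grad.copy() for p in params]


@dataclass
class _Optimizers:
    opt_f: Adam
    opt_l: Adam
    opt_h: Adam
    opt_a: Adam


def _make_optimizers(state: ModelState, config: TrainingConfig) -> _Optimizers:
    return _Optimizers(
        opt_f=Adam(state.params_f(), config.lr_f, config.beta1, config.beta2),
        opt_l=Adam(state.params_l(), config.lr_l, config.beta1, config.beta2),
        opt_h=Adam(state.params_eta_h(), config.lr_eta, config.beta1, config.beta2),
        opt_a=Adam(state.params_eta_a(), config.lr_eta, config.beta1, config.beta2),
    )


def training_step(
    labeled: tuple[np.ndarray, np.ndarray],
    unlabeled: tuple[np.ndarray, np.ndarray, np.ndarray] | None,
    state: ModelState,
    config: TrainingConfig,
    opts: _Optimizers,
    labeled_demo: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[float, float, float]:
    """One joint update of the four parameter sets.

    ``labeled`` is ``(x, vsi)``; ``unlabeled`` is ``(x, height_z, age_z)``
    with standardised demographics; ``labeled_demo`` carries the labeled
    batch's standardised (height, age) so the adversaries see both pools.
    Update laws: the VSI head descends its MSE (labeled only); each adversary
    descends its disturbance loss (labeled + unlabeled); the extractor
    descends ``L_label - lambda (L_height + L_age)`` ("reversal" mode; the
    alternative "printed" mode uses ``+ lambda``). A NaN loss aborts.
    """
    x_lab, y_lab = labeled
    xs = []
    demos = []
    if labeled_demo is not None:
        xs.append(x_lab)
        demos.append(labeled_demo)
    if unlabeled is not None:
        x_unl, h_unl, a_unl = unlabeled
        xs.append(x_unl)
        demos.append((h_unl, a_unl))
    if not demos:
        raise ValueError("no demographic targets available for the adversaries")

    # the label objective is computed on a labeled-only forward pass, so that
    # its value and gradients are independent of the adversarial pool (and the
    # lam = 0 trajectory coincides exactly with plain supervised training)
    loss_l = label_loss(state.forward_label(Tensor(x_lab)), y_lab)

    z_adv = state.latent(Tensor(np.concatenate(xs, axis=0)))
    h_t = np.concatenate([d[0] for d in demos])
    a_t = np.concatenate([d[1] for d in demos])
    loss_h = disturbance_loss(state.head_height(z_adv), h_t)
    loss_a = disturbance_loss(state.head_age(z_adv), a_t)

    vals = (float(loss_l.data), float(loss_h.data), float(loss_a.data))
    if not all(np.isfinite(vals)):
        raise FloatingPointError(f"non-finite training loss {vals}")

    pf, pl = state.params_f(), state.params_l()
    ph, pa = state.params_eta_h(), state.params_eta_a()
    g_l = _grads(loss_l, pl + pf)
    # the two adversarial heads are parameter-disjoint, so one backward pass
    # of the summed disturbance losses yields each head's own gradient and
    # the extractor's combined disturbance gradient
    g_d = _grads(loss_h + loss_a, ph + pa + pf)

    nl, nh, na = len(pl), len(ph), len(pa)
    sign = -1.0 if config.adversarial_sign == "reversal" else 1.0
    gf = [gl + sign * config.lam * gd for gl, gd in zip(g_l[nl:], g_d[nh + na:])]
    opts.opt_l.step(g_l[:nl])
    opts.opt_h.step(g_d[:nh])
    opts.opt_a.step(g_d[nh : nh + na])
    opts.opt_f.step(gf)
    return vals


@dataclass
class _Split:
    """Preprocessed arrays for one dataset split."""

    x: np.ndarray  # (n, 1, 2, W)
    vsi: np.ndarray | None
    height_z: np.ndarray
    age_z: np.ndarray


def _prepare(dataset, modality: str, stats: dict) -> _Split:
    pair = (("pvr_brachial", "pvr_tibial") if modality == "pvr"
            else ("bp_brachial", "bp_tibial"))
    x = preprocess_batch(dataset.waveforms[pair[0]], dataset.waveforms[pair[1]])
    hm, hs = stats["height"]
    am, as_ = stats["age"]
    return _Split(
        x=x,
        vsi=dataset.vsi if dataset.labeled else None,
        height_z=(dataset.height - hm) / hs,
        age_z=(dataset.age - am) / as_,
    )


def train(
    labeled,
    unlabeled,
    validation,
    config: TrainingConfig,
    network_config: NetworkConfig | None = None,
    freeze_adversaries: bool = False,
    verbose: bool = False,
) -> ModelState:
    """Train on `WaveDataset` splits with early stopping on validation MSE.

    Returns the model restored to the best-validation checkpoint, with the
    per-epoch loss history attached. ``freeze_adversaries`` skips the
    adversarial updates entirely (used to realise the plain supervised
    baseline; with ``lam=0`` the (extractor, VSI-head) trajectory is
    identical either way).
    """
    rng = np.random.default_rng(config.seed)
    state = ModelState(network_config, seed=int(rng.integers(2**31)))

    pool_h = np.concatenate([labeled.height] + ([unlabeled.height] if unlabeled is not None else []))
    pool_a = np.concatenate([labeled.age] + ([unlabeled.age] if unlabeled is not None else []))
    state.target_stats = {
        "height": (float(pool_h.mean()), float(pool_h.std() + 1e-12)),
        "age": (float(pool_a.mean()), float(pool_a.std() + 1e-12)),
    }

    lab = _prepare(labeled, config.modality, state.target_stats)
    unl = _prepare(unlabeled, config.modality, state.target_stats) if unlabeled is not None else None
    val = _prepare(validation, config.modality, state.target_stats)
    val_y = validation.vsi

    opts = _make_optimizers(state, config)
    history = TrainingHistory()
    best = (np.inf, state.copy_weights(), -1)
    n = len(lab.x)
    bs = config.batch_size

    for epoch in range(config.max_epochs):
        state.set_training(True)
        order = rng.permutation(n)
        unl_order = rng.permutation(len(unl.x)) if unl is not None else None
        ep_losses = []
        for bi, start in enumerate(range(0, n, bs)):
            idx = order[start : start + bs]
            batch_lab = (lab.x[idx], lab.vsi[idx])
            demo_lab = (lab.height_z[idx], lab.age_z[idx])
            batch_unl = None
            if unl is not None:
                # unlabeled batches interleaved 1:1 with the labeled ones
                uidx = unl_order[(bi * bs) % len(unl.x) : (bi * bs) % len(unl.x) + bs]
                if len(uidx):
                    batch_unl = (unl.x[uidx], unl.height_z[uidx], unl.age_z[uidx])
            if freeze_adversaries:
                vals = _supervised_step(batch_lab, state, config, opts)
            else:
                vals = training_step(batch_lab, batch_unl, state, config, opts,
                                     labeled_demo=demo_lab)
            ep_losses.append(vals)
        state.set_training(False)
        vpred = _predict_array(state, val.x)
        vloss = float(np.mean((vpred - val_y) ** 2))
        mean_losses = np.mean(ep_losses, axis=0)
        history.epoch.append(epoch)
        history.label_loss.append(float(mean_losses[0]))
        history.disturbance_height.append(float(mean_losses[1]))
        history.disturbance_age.append(float(mean_losses[2]))
        history.val_loss.append(vloss)
        if verbose:
            print(f"epoch {epoch}: L_L {mean_losses[0]:.2f} val {vloss:.2f}")
        if vloss < best[0]:
            best = (vloss, state.copy_weights(), epoch)
        elif epoch - best[2] >= config.patience:
            break

    state.load_weights(best[1])
    state.history = history
    state.trained = True
    if best[2] < 0:
        import warnings

        warnings.warn("validation loss never improved; returning initial weights")
    return state


def _supervised_step(labeled, state, config, opts):
    x_lab, y_lab = labeled
    pred = state.forward_label(Tensor(x_lab))
    loss_l = label_loss(pred, y_lab)
    if not np.isfinite(loss_l.data):
        raise FloatingPointError("non-finite training loss")
    pf, pl = state.params_f(), state.params_l()
    g = _grads(loss_l, pl + pf)
    opts.opt_l.step(g[: len(pl)])
    opts.opt_f.step(g[len(pl):])
    return (float(loss_l.data), np.nan, np.nan)


def _predict_array(state: ModelState, x: np.ndarray, batch: int = 256) -> np.ndarray:
    out = []
    for start in range(0, len(x), batch):
        out.append(state.forward_label(Tensor(x[start : start + batch])).data)
    return np.concatenate(out)


def predict_vsi(state: ModelState, brachial: np.ndarray, tibial: np.ndarray) -> float:
    """Severity estimate (%) for one recording; adversarial heads never run."""
    if not state.trained:
        raise RuntimeError("model has not been trained")
    state.set_training(False)
    x = input_preprocess(np.asarray(brachial), np.asarray(tibial),
                         width=state.config.input_width)
    return float(state.forward_label(Tensor(x[None])).data[0])


def predict_dataset(state: ModelState, dataset, modality: str | None = None) -> np.ndarray:
    """Severity estimates for every record of a dataset split."""
    if not state.trained:
        raise RuntimeError("model has not been trained")
    state.set_training(False)
    modality = modality or "pvr"
    split = _prepare(dataset, modality, state.target_stats)
    return _predict_array(state, split.x)
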