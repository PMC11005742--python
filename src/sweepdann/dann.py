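"""Domain-adversarial sweep classifier.

The model has three parts: a convolutional feature extractor G_f, a 5-class
predictor G_y (four fully connected layers, batch-norm after the first
two, softmax output) and a domain discriminator G_d (three fully connected
layers) fed through a gradient-reversal layer R(.). Training minimises

    E = (1/n) sum_source L_y(G_y(G_f(x)), y)
        - (lambda/N) sum_all L_d(G_d(R(G_f(x))), d)

where n counts source cases, N source plus target cases, L_y is 5-class
cross-entropy and L_d binary cross-entropy on the domain label (source=0,
target=1). The reversal layer makes one gradient-descent pass implement the
adversarial saddle point: theta_d descends L_d while theta_f ascends it.

The feature extractor scans each statistic's positional series with (1,5)
kernels and (1,4) pooling, then mixes statistics at fixed position with
(3,1) kernels and (2,1) pooling, followed by two residual bottleneck
modules. Comparator extractors (generic 2-D CNN, 1-D CNN, simple RNN) are
built in the same engine for architecture comparisons.

Deep ensembling averages the predictive distributions of M independently
initialised and trained models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .featengine import StandardizedDataset
from .nn import (
    Adam,
    BatchNorm,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    GradReverse,
    MaxPool2D,
    ReLU,
    Residual,
    Sequential,
    SimpleRNN,
    bce_with_logits,
    sigmoid,
    softmax_cross_entropy,
    softmax_probs,
)

N_CLASSES = 5
CLASS_ORDER = ("hard", "linked_hard", "soft", "linked_soft", "neutral")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one adversarial model."""

    lam: float = 1.0  # adversarial weight lambda
    lam_warmup: bool = False  # ramp lambda 0 -> lam over training (optional)
    M: int = 5  # deep-ensemble size
    extractor: str = "ours"  # ours | cnn2d | cnn1d | rnn
    conv_channels: tuple[int, int] = (8, 16)
    bottleneck_reduce: int = 4
    dropout: float = 0.5
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    patience: int = 10
    rnn_hidden: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.M < 1:
            raise ValueError("ensemble size M must be >= 1")


@dataclass
class EnsemblePrediction:
    probs: np.ndarray  # (B, 5) arithmetic mean of member distributions
    member_probs: np.ndarray  # (M, B, 5)
    domain_score: np.ndarray  # (B,) mean discriminator output


def _bottleneck(channels: int, reduce: int, rng) -> Residual:
    mid = max(channels // reduce, 1)
    return Residual(
        Sequential(
            [
                Conv2D(channels, mid, (1, 1), rng),
                ReLU(),
                Conv2D(mid, mid, (3, 1), rng),
                ReLU(),
                Conv2D(mid, channels, (1, 1), rng),
            ]
        )
    )


def build_feature_extractor(
    config: ModelConfig, m: int, n_stats: int, rng: np.random.Generator
) -> tuple[Sequential, int]:
    """Build the extractor for grids of shape (n_stats, m); returns (net, dim)."""
    c1, c2 = config.conv_channels
    kind = config.extractor
    if kind == "ours":
        if m % 4:
            raise ValueError(f"stage-1 pooling (1,4) needs m divisible by 4, got m={m}")
        if n_stats % 2:
            raise ValueError(f"stage-2 pooling (2,1) needs an even statistic count, got {n_stats}")
        layers = [
            Conv2D(1, c1, (1, 5), rng),
            ReLU(),
            MaxPool2D((1, 4), name="stage-1 pool (1,4)"),
            Conv2D(c1, c2, (3, 1), rng),
            ReLU(),
            MaxPool2D((2, 1), name="stage-2 pool (2,1)"),
        ]
        layers += [
            _bottleneck(c2, config.bottleneck_reduce, rng),
            _bottleneck(c2, config.bottleneck_reduce, rng),
            Flatten(),
        ]
        dim = c2 * (n_stats // 2) * (m // 4)
    elif kind == "cnn2d":
        if m % 4 or n_stats % 4:
            raise ValueError("generic 2D CNN needs n_stats and m divisible by 4")
        layers = [
            Conv2D(1, c1, (3, 3), rng),
            ReLU(),
            MaxPool2D((2, 2), name="cnn2d pool 1"),
            Conv2D(c1, c2, (3, 3), rng),
            ReLU(),
            MaxPool2D((2, 2), name="cnn2d pool 2"),
            Flatten(),
        ]
        dim = c2 * (n_stats // 4) * (m // 4)
    elif kind == "cnn1d":
        # sequence-series comparator: every statistic row is an independent
        # 1-channel series processed with shared conv weights; statistics are
        # only combined downstream by the fully connected head
        if m % 4:
            raise ValueError("1D CNN needs m divisible by 4")
        layers = [
            Conv2D(1, c1, (1, 5), rng),
            ReLU(),
            MaxPool2D((1, 4), name="cnn1d pool 1"),
            Conv2D(c1, c1, (1, 3), rng),
            ReLU(),
            MaxPool2D((1, 4), name="cnn1d pool 2"),
            Flatten(),
        ]
        dim = c1 * n_stats * (m // 16)
    elif kind == "rnn":
        layers = [SimpleRNN(n_stats, config.rnn_hidden, rng)]
        dim = config.rnn_hidden
    else:
        raise ValueError(f"unknown extractor {kind!r}")
    return Sequential(layers), dim


def _build_classifier(dim: int, config: ModelConfig, rng, drop_rng) -> Sequential:
    return Sequential(
        [
            Dense(dim, 128, rng),
            BatchNorm(128),
            ReLU(),
            Dropout(config.dropout, drop_rng),
            Dense(128, 64, rng),
            BatchNorm(64),
            ReLU(),
            Dropout(config.dropout, drop_rng),
            Dense(64, 32, rng),
            ReLU(),
            Dense(32, N_CLASSES, rng),
        ]
    )


def _build_discriminator(dim: int, config: ModelConfig, rng, drop_rng) -> Sequential:
    return Sequential(
        [
            GradReverse(config.lam),
            Dense(dim, 128, rng),
            ReLU(),
            Dropout(config.dropout, drop_rng),
            Dense(128, 32, rng),
            ReLU(),
            Dense(32, 1, rng),
        ]
    )


class DannModel:
    """One adversarial model (theta_f, theta_y, theta_d) for (n_stats, m) grids."""

    def __init__(self, config: ModelConfig, m: int, n_stats: int = 40):
        self.config = config
        self.m = m
        self.n_stats = n_stats
        ss = np.random.SeedSequence(config.seed)
        init_f, init_y, init_d, drop_y, drop_d, self._shuffle_ss = ss.spawn(6)
        self.extractor, self.embed_dim = build_feature_extractor(
            config, m, n_stats, np.random.default_rng(init_f)
        )
        self.classifier = _build_classifier(
            self.embed_dim, config, np.random.default_rng(init_y), np.random.default_rng(drop_y)
        )
        self.discriminator = _build_discriminator(
            self.embed_dim, config, np.random.default_rng(init_d), np.random.default_rng(drop_d)
        )
        self._lam_eff = config.lam  # effective lambda (differs under warm-up)
        self.history: list[dict] = []

    # -- plumbing -----------------------------------------------------------

    def _adapt(self, X: np.ndarray) -> np.ndarray:
        """Reshape (B, n_stats, m) grids for the configured extractor."""
        if X.ndim != 3 or X.shape[1] != self.n_stats or X.shape[2] != self.m:
            raise ValueError(f"expected (B, {self.n_stats}, {self.m}) input, got {X.shape}")
        kind = self.config.extractor
        if kind in ("ours", "cnn2d", "cnn1d"):
            return X[:, None, :, :]
        return X.transpose(0, 2, 1)  # rnn: (B, T=m, D=n_stats)

    def _nets(self):
        return (self.extractor, self.classifier, self.discriminator)

    def train_mode(self, mode: bool):
        for net in self._nets():
            net.train(mode)

    # -- inference ----------------------------------------------------------

    def embed(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        self.train_mode(False)
        out = [self.extractor.forward(self._adapt(X[i : i + batch])) for i in range(0, len(X), batch)]
        return np.concatenate(out) if out else np.empty((0, self.embed_dim))

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        self.train_mode(False)
        out = []
        for i in range(0, len(X), batch):
            z = self.extractor.forward(self._adapt(X[i : i + batch]))
            out.append(softmax_probs(self.classifier.forward(z)))
        return np.concatenate(out) if out else np.empty((0, N_CLASSES))

    def domain_scores(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        self.train_mode(False)
        out = []
        for i in range(0, len(X), batch):
            z = self.extractor.forward(self._adapt(X[i : i + batch]))
            out.append(sigmoid(self.discriminator.forward(z)).reshape(-1))
        return np.concatenate(out) if out else np.empty(0)

    # -- training -----------------------------------------------------------

    def loss_on_batch(
        self,
        xs: np.ndarray,
        ys: np.ndarray,
        xt: np.ndarray | None,
        compute_grads: bool = True,
        adversarial: bool = True,
    ) -> dict:
        """Forward (and optionally backward) pass of the objective on one batch.

        Returns the Eq.-style decomposition {"total": L_y - lambda*L_d,
        "ly": L_y, "ld": L_d}. Gradients accumulate in each layer's ``grads``:
        descending them implements the adversarial update (theta_y, theta_f
        descend the total objective; theta_d descends L_d, i.e. ascends it).
        """
        if xs.shape[0] == 0:
            raise ValueError("batch must contain source cases")
        n_src = xs.shape[0]
        use_disc = adversarial and xt is not None
        x_all = np.concatenate([xs, xt]) if use_disc else xs
        z = self.extractor.forward(self._adapt(x_all))
        logits_y = self.classifier.forward(z[:n_src])
        ly, g_logits_y = softmax_cross_entropy(logits_y, ys)
        ld = 0.0
        if use_disc:
            dom = np.concatenate([np.zeros(n_src), np.ones(len(xt))])
            logits_d = self.discriminator.forward(z)
            ld, g_logits_d = bce_with_logits(logits_d, dom)
        if compute_grads:
            gz = np.zeros_like(z)
            gz[:n_src] += self.classifier.backward(g_logits_y)
            if use_disc:
                gz += self.discriminator.backward(g_logits_d)
            self.extractor.backward(gz)
        return {"total": ly - self._lam_eff * ld, "ly": ly, "ld": ld}

    def evaluate(self, X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        """(mean cross-entropy, accuracy) in eval mode."""
        p = self.predict_proba(X)
        loss = float(-np.mean(np.log(p[np.arange(len(y)), y] + 1e-300)))
        acc = float(np.mean(p.argmax(axis=1) == y))
        return loss, acc

    def fit(
        self,
        Xs: np.ndarray,
        ys: np.ndarray,
        Xval: np.ndarray,
        yval: np.ndarray,
        Xt: np.ndarray | None = None,
        adversarial: bool = True,
    ) -> "DannModel":
        """Transductive adversarial training with validation-selected checkpoint.

        Stops early after ``patience`` epochs without validation-loss
        improvement and restores the best parameters; aborts on non-finite
        loss, keeping the last finite checkpoint.
        """
        cfg = self.config
        opt_nets = list(self._nets()) if (adversarial and Xt is not None) else [
            self.extractor,
            self.classifier,
        ]
        opt = Adam(opt_nets, lr=cfg.lr)
        rng = np.random.default_rng(self._shuffle_ss)
        best = {"loss": np.inf, "state": None, "epoch": -1}
        bs = cfg.batch_size
        nt = 0 if Xt is None else len(Xt)
        t_order = np.empty(0, dtype=int)
        t_ptr = 0
        for epoch in range(cfg.epochs):
            if cfg.lam_warmup:
                # sigmoid ramp 0 -> lam, the standard adversarial schedule
                p = epoch / max(cfg.epochs - 1, 1)
                self._lam_eff = cfg.lam * (2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0)
                self.discriminator.layers[0].lam = self._lam_eff
            self.train_mode(True)
            order = rng.permutation(len(Xs))
            ep_ly = ep_ld = 0.0
            n_batches = 0
            for i in range(0, len(Xs), bs):
                sel = order[i : i + bs]
                if nt:
                    take = min(len(sel), nt)
                    if t_ptr + take > nt:
                        t_order = rng.permutation(nt)
                        t_ptr = 0
                    if t_order.size == 0:
                        t_order = rng.permutation(nt)
                    xt = Xt[t_order[t_ptr : t_ptr + take]]
                    t_ptr += take
                else:
                    xt = None
                losses = self.loss_on_batch(Xs[sel], ys[sel], xt, adversarial=adversarial)
                if not np.isfinite(losses["total"]):
                    if best["state"] is not None:
                        self._load_states(best["state"])
                    return self
                opt.step()
                ep_ly += losses["ly"]
                ep_ld += losses["ld"]
                n_batches += 1
            val_loss, val_acc = self.evaluate(Xval, yval)
            self.history.append(
                {
                    "epoch": epoch,
                    "ly": ep_ly / n_batches,
                    "ld": ep_ld / n_batches,
                    "val_loss": val_loss,
                    "val_acc": val_acc,
                }
            )
            if val_loss < best["loss"] - 1e-6:
                best = {"loss": val_loss, "state": self._dump_states(), "epoch": epoch}
            elif epoch - best["epoch"] >= cfg.patience:
                break
        if best["state"] is not None:
            self._load_states(best["state"])
        return self

    def _dump_states(self):
        return [net.state_dict() for net in self._nets()]

    def _load_states(self, states):
        for net, st in zip(self._nets(), states):
            net.load_state_dict(st)


# ---------------------------------------------------------------------------
# ensemble, saliency, confidence


def train_transductive(
    source: StandardizedDataset,
    val: StandardizedDataset,
    target: StandardizedDataset | None,
    config: ModelConfig,
) -> DannModel:
    """Train one model from standardized datasets (labels on source side only)."""
    if source.labels is None or val.labels is None:
        raise ValueError("source and validation datasets need labels")
    model = DannModel(config, m=source.X.shape[2], n_stats=source.X.shape[1])
    model.fit(
        source.X,
        np.asarray(source.labels),
        val.X,
        np.asarray(val.labels),
        None if target is None else target.X,
        adversarial=config.lam > 0 and target is not None,
    )
    return model


def train_ensemble(
    source: StandardizedDataset,
    val: StandardizedDataset,
    target: StandardizedDataset | None,
    config: ModelConfig,
) -> list[DannModel]:
    """M independently initialised and trained models (deep ensemble)."""
    seeds = np.random.SeedSequence(config.seed).generate_state(config.M) % (2**31 - 1)
    return [
        train_transductive(source, val, target, replace(config, seed=int(s))) for s in seeds
    ]


def ensemble_predict(models: list[DannModel], X: np.ndarray) -> EnsemblePrediction:
    """Mean of member predictive distributions (and mean domain score)."""
    if not models:
        raise ValueError("need at least one model")
    shapes = {(m.n_stats, m.m) for m in models}
    if len(shapes) != 1:
        raise ValueError("ensemble members disagree on input shape")
    member = np.stack([m.predict_proba(X) for m in models])
    dom = np.stack([m.domain_scores(X) for m in models]).mean(axis=0)
    return EnsemblePrediction(member.mean(axis=0), member, dom)


def predict_dataset(models: list[DannModel], dataset: StandardizedDataset) -> EnsemblePrediction:
    if dataset.scale is None:
        raise ValueError("dataset is not standardized: fit/apply min-max scaling first")
    return ensemble_predict(models, dataset.X)


def smoothgrad_saliency(
    model: DannModel,
    x: np.ndarray,
    noise_sd: float = 0.1,
    n_samples: int = 25,
    seed: int = 0,
) -> np.ndarray:
    """Mean absolute input-gradient of the predicted-class probability.

    Gaussian noise of scale ``noise_sd`` is added to ``x`` (a single
    (n_stats, m) grid) ``n_samples`` times; with noise_sd=0 and n_samples=1
    this reduces to the plain gradient magnitude.
    """
    rng = np.random.default_rng(seed)
    model.train_mode(False)
    p0 = model.predict_proba(x[None])[0]
    cls = int(p0.argmax())
    acc = np.zeros_like(x, dtype=float)
    for _ in range(n_samples):
        noisy = x + (rng.normal(0, noise_sd, size=x.shape) if noise_sd > 0 else 0.0)
        z = model.extractor.forward(model._adapt(noisy[None]))
        logits = model.classifier.forward(z)
        p = softmax_probs(logits)[0]
        # d p_cls / d logits_j = p_cls (delta_{cls j} - p_j)
        g_logits = (p[cls] * (np.eye(N_CLASSES)[cls] - p))[None]
        gz = model.classifier.backward(g_logits)
        gx = model.extractor.backward(gz)
        if model.config.extractor == "rnn":
            gx = gx.transpose(0, 2, 1)
        acc += np.abs(gx.reshape(x.shape))
    return acc / n_samples


def prediction_confidence(probs: np.ndarray) -> float:
    """Mean over cases of the maximum class probability."""
    probs = np.atleast_2d(probs)
    if probs.shape[0] == 0:
        raise ValueError("need at least one prediction")
    return float(probs.max(axis=1).mean())
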