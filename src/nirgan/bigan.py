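"""Template-conditioned bidirectional GAN for class-aware spectrum generation.

A bidirectional GAN learns three networks jointly: an encoder E mapping a
spectrum x to a latent code E(x), a generator G mapping latent codes z back
to spectra, and a discriminator D that scores (spectrum, latent) couples —
real couples (x, E(x)) against generated couples (G(z), z).  At the saddle
point of

    min_{G,E} max_D  E[log D(x, E(x))] + E[log(1 − D(G(z), z))]

the generator produces spectra indistinguishable from real ones.  A plain
bidirectional GAN, however, samples z from a fixed N(0, I) prior, so the
class of G(z) is uncontrolled.  Two modifications make generation
class-conditional and classification-aware:

1. **Template-conditioned latent prior.**  To generate a spectrum "like"
   a template x_i, z is drawn from N(mu, diag(sigma^2)) with mu = E(x_i) and
   sigma adapted from the five most recent encodings of the template's
   class seen during training (sigma defaults to 1 until five history
   records exist):

       sigma_d = sqrt( sum_{j=1..5} (h_jd − mu_d)^2 / 4 )

2. **Classification-augmented losses.**  A softmax classifier C is
   pre-trained on real spectra with cross-entropy, then during adversarial
   training C's loss on *generated* spectra (against the template's label)
   is added to both the discriminator and the generator objectives, and C
   itself keeps training on generated spectra.  The generator is thereby
   pushed to produce spectra that carry their template's class identity.

Training batches are drawn by balanced per-class resampling with
replacement, so minority manufacturers get equal representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import ClassCatalog, SpectralDataset
from .dataops import SplitPlan, balanced_resample
from .nn import MLP, BatchNorm, Dense, Dropout, ReLU, RMSprop, Sigmoid, sigmoid, softmax

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "LatentPrior",
    "BiGANModel",
    "LossTrace",
    "TrainingDiverged",
    "build_model",
    "encode",
    "update_prior",
    "sample_latent",
    "generate",
    "discriminate",
    "classify",
    "loss_classification",
    "loss_discriminator",
    "loss_generator",
    "pretrain_classifier",
    "warmstart_generator",
    "refresh_batchnorm",
    "train",
]

LOG_EPS = 1e-7     # probability clipping inside every cross-entropy term
HISTORY_LEN = 5    # encodings kept for the adaptive prior sigma


class TrainingDiverged(RuntimeError):
    """Raised when a training loss becomes non-finite."""


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of one MLP: widths include input and output."""

    layer_widths: tuple[int, ...]
    hidden_activation: str = "relu"          # 'relu' | 'sigmoid'
    output_activation: str = "linear"        # applied outside the MLP
    dropout_rate: float = 0.0                # before each dense layer
    batch_norm: bool = False                 # after each dense layer

    def __post_init__(self) -> None:
        if len(self.layer_widths) < 2 or any(w < 1 for w in self.layer_widths):
            raise ValueError(f"invalid layer widths {self.layer_widths}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass
class TrainConfig:
    """Hyperparameters of the adversarial training scheme.

    Defaults follow the published recipe where one exists: 2074-channel
    input, latent dimension 30, encoder 2074-120-30 with batch norm,
    generator 30-360-2074, classifier 2074-150-k with sigmoid hidden units,
    RMSprop at library defaults, batch size 60, 150 adversarial epochs.
    """

    n_channels: int = 2074
    latent_dim: int = 30
    e_hidden: int = 120
    g_hidden: int = 360
    c_hidden: int = 150
    d_hidden: int = 120
    # Dropout in the encoder is configurable but off by default: multiplying
    # out 20% of the channels swamps the percent-level manufacturer signal,
    # and with it active the warm-start cannot learn past drug identity.
    dropout_rate: float = 0.0
    batch_size: int = 60
    epochs: int = 150
    pretrain_epochs: int = 300
    warmup_epochs: int = 600
    n_per_class: int = 60
    learning_rate: float = 1e-3
    rms_rho: float = 0.9
    rms_eps: float = 1e-7
    rng_seed: int = 0
    sigma_floor: float = 1e-6
    # scope of the 5-deep encoding history behind the adaptive prior sigma:
    # per template class (the "local" variance of the class being generated)
    # or one global stream.  A global stream mixes classes, so its sigma is
    # the between-class latent spread and conditioning washes out; per-class
    # history keeps sigma at the within-class spread.
    per_class_history: bool = True

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.n_per_class < 1:
            raise ValueError("batch_size and n_per_class must be >= 1")
        if self.epochs < 0 or self.pretrain_epochs < 0:
            raise ValueError("epoch counts must be >= 0")


@dataclass
class LatentPrior:
    """Template-conditioned normal prior N(mu, diag(sigma^2)) with history."""

    mu: np.ndarray
    sigma: np.ndarray
    history: list[np.ndarray] = field(default_factory=list)
    sigma_floor: float = 1e-6

    def __post_init__(self) -> None:
        if len(self.history) > HISTORY_LEN:
            raise ValueError(f"history holds at most {HISTORY_LEN} records")


def update_prior(prior: LatentPrior, new_encoding: np.ndarray) -> LatentPrior:
    """Recenter the prior on a new encoding and adapt sigma from history.

    With a full history of five records the per-dimension scale is the
    root mean square deviation of those records about the new mean (divisor
    4), floored at ``sigma_floor``; with fewer records sigma stays at its
    default of 1.  The new encoding is then appended, evicting the oldest
    record beyond five.
    """
    mu = np.asarray(new_encoding, dtype=float)
    if mu.shape != prior.mu.shape:
        raise ValueError(f"encoding shape {mu.shape} != prior shape {prior.mu.shape}")
    if len(prior.history) >= HISTORY_LEN:
        h = np.stack(prior.history[-HISTORY_LEN:])
        sigma = np.sqrt(np.sum((h - mu) ** 2, axis=0) / (HISTORY_LEN - 1))
        sigma = np.maximum(sigma, prior.sigma_floor)
    else:
        sigma = np.ones_like(mu)
    history = (prior.history + [mu])[-HISTORY_LEN:]
    return LatentPrior(mu=mu, sigma=sigma, history=history, sigma_floor=prior.sigma_floor)


def sample_latent(prior: LatentPrior, rng: np.random.Generator) -> np.ndarray:
    """Draw z ~ N(mu, diag(sigma^2))."""
    return prior.mu + prior.sigma * rng.standard_normal(prior.mu.shape)


# ---------------------------------------------------------------------------
# losses (sum form; probabilities clipped before every log)


def loss_classification(c: np.ndarray, c_hat: np.ndarray) -> float:
    """Cross-entropy −Σ c_i log ĉ_i of predicted class probabilities.

    `c` is a one-hot label (or a batch of them), `c_hat` the matching
    probability vector(s).
    """
    c = np.asarray(c, dtype=float)
    c_hat = np.asarray(c_hat, dtype=float)
    if c.shape != c_hat.shape:
        raise ValueError(f"label shape {c.shape} != prediction shape {c_hat.shape}")
    return float(-np.sum(c * np.log(np.clip(c_hat, LOG_EPS, 1.0))))


def loss_discriminator(y: np.ndarray, y_hat: np.ndarray, cls_loss: float = 0.0) -> float:
    """Binary cross-entropy over (real=1, generated=0) couples plus the
    classification loss on generated samples."""
    y = np.asarray(y, dtype=float)
    y_hat = np.clip(np.asarray(y_hat, dtype=float), LOG_EPS, 1.0 - LOG_EPS)
    if y.size == 0:
        raise ValueError("empty batch")
    bce = -np.sum(y * np.log(y_hat) + (1.0 - y) * np.log(1.0 - y_hat))
    return float(bce + cls_loss)


def loss_generator(y_hat: np.ndarray, cls_loss: float = 0.0) -> float:
    """Non-saturating generator loss −Σ log ŷ on generated couples plus the
    classification loss on generated samples."""
    y_hat = np.clip(np.asarray(y_hat, dtype=float), LOG_EPS, 1.0)
    if y_hat.size == 0:
        raise ValueError("empty batch")
    return float(-np.sum(np.log(y_hat)) + cls_loss)


# ---------------------------------------------------------------------------
# model


@dataclass
class BiGANModel:
    """Parameter sets for E, G, D, C plus optimizer and prior state."""

    E: MLP
    G: MLP
    D: MLP
    C: MLP
    opt_E: RMSprop
    opt_G: RMSprop
    opt_D: RMSprop
    opt_C: RMSprop
    catalog: ClassCatalog
    config: TrainConfig
    prior: LatentPrior
    class_priors: dict[int, LatentPrior] = field(default_factory=dict)
    offset_mean: float = 0.0   # mean per-spectrum offset of the training set
    scale_mean: float = 1.0    # mean per-spectrum scale of the training set
    pretrained: bool = False
    trained: bool = False

    @property
    def k(self) -> int:
        return self.catalog.k

    def scale(self, x: np.ndarray) -> np.ndarray:
        """Standard normal variate (SNV) transform: each spectrum is centred
        and scaled by its own mean and standard deviation.

        SNV removes per-spectrum multiplicative scatter and baseline offset,
        the dominant nuisance variation of diffuse-reflectance NIR; it has
        no fitted parameters, so train/test leakage is impossible.
        """
        x = np.asarray(x, dtype=float)
        mu = x.mean(axis=-1, keepdims=True)
        sd = x.std(axis=-1, keepdims=True)
        return (x - mu) / (sd + 1e-12)

    def unscale(self, x: np.ndarray) -> np.ndarray:
        """Map SNV-space spectra back to absorbance-like units using the
        training set's mean offset and scale (per-spectrum gain is not
        recoverable; generated spectra are returned at the average gain)."""
        return np.asarray(x, dtype=float) * self.scale_mean + self.offset_mean

    def set_preprocessing(self, X_train: np.ndarray) -> None:
        self.offset_mean = float(X_train.mean(axis=1).mean())
        self.scale_mean = float(X_train.std(axis=1).mean())


@dataclass
class LossTrace:
    """Per-epoch mean losses of the alternating optimisation."""

    d_loss: list[float] = field(default_factory=list)
    g_loss: list[float] = field(default_factory=list)
    c_loss: list[float] = field(default_factory=list)


def _build_mlp(spec: NetworkSpec, rng_init: np.random.Generator,
               rng_drop: np.random.Generator) -> MLP:
    layers: list = []
    widths = spec.layer_widths
    act = {"relu": ReLU, "sigmoid": Sigmoid}[spec.hidden_activation]
    for i in range(len(widths) - 1):
        last = i == len(widths) - 2
        if spec.dropout_rate > 0:
            layers.append(Dropout(spec.dropout_rate, rng_drop))
        layers.append(Dense(widths[i], widths[i + 1], rng_init))
        if spec.batch_norm:
            layers.append(BatchNorm(widths[i + 1]))
        if not last:
            layers.append(act())
    return MLP(layers)


def default_specs(catalog: ClassCatalog, config: TrainConfig) -> dict[str, NetworkSpec]:
    """The four network architectures implied by the configuration."""
    L, m = config.n_channels, config.latent_dim
    return {
        "E": NetworkSpec((L, config.e_hidden, m), "relu", "linear",
                         dropout_rate=config.dropout_rate, batch_norm=True),
        "G": NetworkSpec((m, config.g_hidden, L), "relu", "linear"),
        "D": NetworkSpec((L + m, config.d_hidden, 1), "relu", "sigmoid"),
        "C": NetworkSpec((L, config.c_hidden, catalog.k), "sigmoid", "softmax"),
    }


def build_model(catalog: ClassCatalog, config: TrainConfig | None = None,
                specs: dict[str, NetworkSpec] | None = None) -> BiGANModel:
    """Construct an untrained model with seeded, reproducible initialisation."""
    config = config or TrainConfig()
    if catalog.k < 2:
        raise ValueError("need at least 2 classes")
    specs = specs or default_specs(catalog, config)
    m = config.latent_dim
    if specs["E"].layer_widths[-1] != m or specs["G"].layer_widths[0] != m:
        raise ValueError("encoder output, generator input and prior dimension must agree")
    if specs["D"].layer_widths[0] != config.n_channels + m:
        raise ValueError("discriminator input must be the (spectrum, latent) couple width")
    if specs["C"].layer_widths[-1] != catalog.k:
        raise ValueError("classifier output width must equal the class count")
    ss = np.random.SeedSequence(config.rng_seed)
    init_seeds = ss.spawn(4)
    drop_seeds = ss.spawn(4)
    nets = {}
    for name, iseed, dseed in zip("EGDC", init_seeds, drop_seeds):
        nets[name] = _build_mlp(specs[name], np.random.default_rng(iseed),
                                np.random.default_rng(dseed))
    prior = LatentPrior(mu=np.zeros(m), sigma=np.ones(m), sigma_floor=config.sigma_floor)
    return BiGANModel(
        E=nets["E"], G=nets["G"], D=nets["D"], C=nets["C"],
        opt_E=RMSprop(nets["E"], config.learning_rate, config.rms_rho, config.rms_eps),
        opt_G=RMSprop(nets["G"], config.learning_rate, config.rms_rho, config.rms_eps),
        opt_D=RMSprop(nets["D"], config.learning_rate, config.rms_rho, config.rms_eps),
        opt_C=RMSprop(nets["C"], config.learning_rate, config.rms_rho, config.rms_eps),
        catalog=catalog, config=config, prior=prior,
    )


def _as_batch(x: np.ndarray, width: int, what: str) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != width:
        raise ValueError(f"{what} must have width {width}, got {x.shape[1]}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{what} contains non-finite values")
    return x, single


def encode(model: BiGANModel, x: np.ndarray) -> np.ndarray:
    """Latent representation E(x) in evaluation mode (dropout off)."""
    xb, single = _as_batch(x, model.config.n_channels, "spectrum")
    z = model.E.forward(model.scale(xb), train=False)
    return z[0] if single else z


def generate(model: BiGANModel, z: np.ndarray) -> np.ndarray:
    """Spectrum G(z) in absorbance units (inverse of the recorded scaling)."""
    zb, single = _as_batch(z, model.config.latent_dim, "latent vector")
    x = model.unscale(model.G.forward(zb, train=False))
    return x[0] if single else x


def discriminate(model: BiGANModel, x: np.ndarray, z: np.ndarray) -> float | np.ndarray:
    """Probability that (x, z) is a real couple (x, E(x))."""
    xb, single_x = _as_batch(x, model.config.n_channels, "spectrum")
    zb, single_z = _as_batch(z, model.config.latent_dim, "latent vector")
    if xb.shape[0] != zb.shape[0]:
        raise ValueError("x and z batch sizes differ")
    logit = model.D.forward(np.hstack([model.scale(xb), zb]), train=False)
    p = sigmoid(logit)[:, 0]
    return float(p[0]) if (single_x and single_z) else p


def classify(model: BiGANModel, x: np.ndarray) -> np.ndarray:
    """Class probability vector C(x) (softmax over the k classes)."""
    xb, single = _as_batch(x, model.config.n_channels, "spectrum")
    p = softmax(model.C.forward(model.scale(xb), train=False))
    return p[0] if single else p


# ---------------------------------------------------------------------------
# training


def _one_hot(class_ids: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros((len(class_ids), k))
    out[np.arange(len(class_ids)), np.asarray(class_ids) - 1] = 1.0
    return out


def _batches(indices: np.ndarray, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(len(indices))
    for start in range(0, len(indices), batch_size):
        yield indices[order[start:start + batch_size]]


def _check_finite(value: float, what: str, epoch: int) -> None:
    if not np.isfinite(value):
        raise TrainingDiverged(f"{what} became non-finite at epoch {epoch}")


def pretrain_classifier(model: BiGANModel, dataset: SpectralDataset, split: SplitPlan,
                        epochs: int | None = None) -> list[float]:
    """Train C on real training spectra with balanced resampled batches.

    Returns the per-epoch mean cross-entropy.  With ``epochs=0`` the
    parameters are left untouched.
    """
    cfg = model.config
    epochs = cfg.pretrain_epochs if epochs is None else epochs
    model.set_preprocessing(dataset.X[split.all_train()])
    trace: list[float] = []
    for epoch in range(epochs):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 1, epoch]))
        idx = balanced_resample(split, dataset, cfg.n_per_class,
                                rng_seed=int(rng.integers(2**31)))
        losses = []
        for rows in _batches(idx, cfg.batch_size, rng):
            xs = model.scale(dataset.X[rows])
            y = _one_hot(dataset.class_ids[rows], model.k)
            logits = model.C.forward(xs, train=True)
            p = softmax(logits)
            loss = loss_classification(y, p) / len(rows)
            _check_finite(loss, "classifier pre-training loss", epoch)
            model.C.backward((p - y) / len(rows))
            model.opt_C.step()
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    if epochs > 0:
        model.pretrained = True
    return trace


def refresh_batchnorm(model: BiGANModel, X: np.ndarray) -> None:
    """Recompute the encoder's batch-norm running statistics on `X`.

    Training-mode forward passes (no parameter updates) settle the running
    mean/variance to the current weights, so evaluation-mode encodings match
    the statistics the training batches saw.  Deterministic given `X`.
    """
    bs = model.config.batch_size
    for s in range(0, len(X), bs):
        model.E.forward(model.scale(X[s:s + bs]), train=True)


def _update_prior_for_batch(model: BiGANModel, enc: np.ndarray,
                            class_ids: np.ndarray) -> np.ndarray:
    """Stream batch encodings through the prior history; return per-row sigma."""
    sigmas = np.empty_like(enc)
    for i in range(enc.shape[0]):
        if model.config.per_class_history:
            cid = int(class_ids[i])
            p = model.class_priors.get(cid)
            if p is None:
                p = LatentPrior(mu=np.zeros(enc.shape[1]), sigma=np.ones(enc.shape[1]),
                                sigma_floor=model.config.sigma_floor)
            p = update_prior(p, enc[i])
            model.class_priors[cid] = p
            sigmas[i] = p.sigma
        # the global history is always maintained (it also serves inference)
        model.prior = update_prior(model.prior, enc[i])
        if not model.config.per_class_history:
            sigmas[i] = model.prior.sigma
    return sigmas


def warmstart_generator(model: BiGANModel, dataset: SpectralDataset, split: SplitPlan,
                        epochs: int | None = None) -> list[float]:
    """Warm-start E and G toward the bidirectional fixed point G = E^-1.

    At the adversarial optimum of a bidirectional GAN the generator inverts
    the encoder; reaching that saddle point by adversarial updates alone is
    slow, so E and G are first trained directly on its two symptoms: the
    reconstruction error ||G(z) - x||^2 and the classification loss of the
    *frozen* pre-trained classifier on G(z) (the generator term of the
    classification-augmented objective, with C as the anchor).  z is drawn
    from the conditioned prior around E(x), exactly as in formal training,
    so the generator learns to keep its outputs class-consistent under
    prior sampling.  Returns the per-epoch mean classification loss.
    """
    if not model.pretrained:
        raise RuntimeError("classifier must be pre-trained before the warm-start")
    cfg = model.config
    epochs = cfg.warmup_epochs if epochs is None else epochs
    k = model.k
    trace: list[float] = []
    for epoch in range(epochs):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 3, epoch]))
        idx = balanced_resample(split, dataset, cfg.n_per_class,
                                rng_seed=int(rng.integers(2**31)))
        cls_losses = []
        for rows in _batches(idx, cfg.batch_size, rng):
            m = len(rows)
            xs = model.scale(dataset.X[rows])
            labels = dataset.class_ids[rows]
            y_onehot = _one_hot(labels, k)
            enc = model.E.forward(xs, train=True)
            sigmas = _update_prior_for_batch(model, enc, labels)
            z = enc + sigmas * rng.standard_normal(enc.shape)
            x_rec = model.G.forward(z, train=True)
            c_p = softmax(model.C.forward(x_rec, train=False))
            cls_loss = loss_classification(y_onehot, c_p) / m
            _check_finite(cls_loss, "warm-start classification loss", epoch)
            g_cls = model.C.backward((c_p - y_onehot) / m)   # C is not stepped
            g_rec = 2.0 * (x_rec - xs) / m
            gz = model.G.backward(g_rec + g_cls)
            model.E.backward(gz)
            model.opt_G.step()
            model.opt_E.step()
            cls_losses.append(cls_loss)
        trace.append(float(np.mean(cls_losses)))
    return trace


def train(model: BiGANModel, dataset: SpectralDataset, split: SplitPlan,
          epochs: int | None = None, warmup_epochs: int | None = None) -> LossTrace:
    """Full training: generator warm-start, then alternating adversarial
    optimisation of D, G and C over the frozen encoder's latent space.

    Per formal batch: balanced template spectra are encoded (evaluation
    mode, so the conditioning is deterministic), the per-class conditioned
    prior is updated and sampled, spectra are generated, then

    * D minimises binary cross-entropy on real couples (x, E(x)) vs
      generated couples (G(z), z);
    * G minimises the non-saturating adversarial loss plus the
      classification loss of C on G(z) against the template labels;
    * C minimises cross-entropy on the generated samples.

    E's representation is learned during the warm-start and held fixed
    here: continuing to move the encoder underneath the prior histories
    erodes the latent class structure the conditioning depends on.

    Raises :class:`TrainingDiverged` if any loss becomes non-finite.
    """
    if not model.pretrained:
        raise RuntimeError("classifier must be pre-trained before adversarial training")
    cfg = model.config
    epochs = cfg.epochs if epochs is None else epochs
    warmstart_generator(model, dataset, split, epochs=warmup_epochs)
    refresh_batchnorm(model, dataset.X[split.all_train()])
    L, k = cfg.n_channels, model.k
    trace = LossTrace()
    for epoch in range(epochs):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 2, epoch]))
        idx = balanced_resample(split, dataset, cfg.n_per_class,
                                rng_seed=int(rng.integers(2**31)))
        d_losses, g_losses, c_losses = [], [], []
        for rows in _batches(idx, cfg.batch_size, rng):
            m = len(rows)
            xs = model.scale(dataset.X[rows])
            labels = dataset.class_ids[rows]
            y_onehot = _one_hot(labels, k)

            # deterministic conditioning on the frozen encoder
            enc = model.E.forward(xs, train=False)
            sigmas = _update_prior_for_batch(model, enc, labels)
            z = enc + sigmas * rng.standard_normal(enc.shape)
            x_fake = model.G.forward(z, train=True)

            # --- discriminator step: real couples 1, generated couples 0
            couples = np.vstack([np.hstack([xs, enc]), np.hstack([x_fake, z])])
            y = np.concatenate([np.ones(m), np.zeros(m)])
            logits = model.D.forward(couples, train=True)[:, 0]
            p = np.clip(sigmoid(logits), LOG_EPS, 1.0 - LOG_EPS)
            model.D.backward(((p - y) / (2 * m))[:, None])
            model.opt_D.step()

            # --- generator step through the updated D and C
            d_logits = model.D.forward(np.hstack([x_fake, z]), train=True)[:, 0]
            d_p = np.clip(sigmoid(d_logits), LOG_EPS, 1.0 - LOG_EPS)
            gin = model.D.backward(((d_p - 1.0) / m)[:, None])
            gx_d = gin[:, :L]
            c_logits = model.C.forward(x_fake, train=True)
            c_p = softmax(c_logits)
            cls_loss = loss_classification(y_onehot, c_p) / m
            gx_c = model.C.backward((c_p - y_onehot) / m)
            model.G.backward(gx_d + gx_c)
            model.opt_G.step()

            # --- classifier step on the generated samples
            c_logits2 = model.C.forward(x_fake, train=True)
            c_p2 = softmax(c_logits2)
            c_loss = loss_classification(y_onehot, c_p2) / m
            model.C.backward((c_p2 - y_onehot) / m)
            model.opt_C.step()

            d_loss = loss_discriminator(y, p, cls_loss * m) / (2 * m)
            g_loss = loss_generator(d_p, cls_loss * m) / m
            for val, what in ((d_loss, "discriminator loss"),
                              (g_loss, "generator loss"),
                              (c_loss, "classifier loss")):
                _check_finite(val, what, epoch)
            d_losses.append(d_loss)
            g_losses.append(g_loss)
            c_losses.append(c_loss)
        trace.d_loss.append(float(np.mean(d_losses)))
        trace.g_loss.append(float(np.mean(g_losses)))
        trace.c_loss.append(float(np.mean(c_losses)))
    if epochs > 0 or cfg.warmup_epochs > 0:
        model.trained = True
    return trace
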