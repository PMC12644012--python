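"""CSAE pretraining, encoder transfer, and the GRU seizure classifier.

The convolutional sparse autoencoder (CSAE) maps a normalized feature
vector of length D, viewed as a 1-channel 1-D signal, through two
conv(3x1)-BN-ReLU-dropout blocks (channels 1 -> 32 -> 16) to a latent
map of shape 16 x D, and mirrors back (16 -> 16 -> 1, linear output).
Pretraining minimises the sparse reconstruction loss

    L = ||x - x_hat||_2^2 + lambda * ||h||_1

(per sample, averaged over the batch) with Adam. The pretrained encoder
is then transferred — frozen by default, including batch-norm statistics
— into the classifier: latent 16 x D treated as a D-step sequence of
16-dim inputs, a GRU with 64 hidden units, dropout 0.5 on the final
hidden state, and a dense softmax pair. Class index 1 is always ictal
(the positive class). Everything is deterministic under fixed seeds.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ._nn import (GRU, Adam, BatchNorm1d, Conv1d, Dense, Dropout, ReLU,
                  softmax, softmax_cross_entropy)
from .features import FeatureTable

__all__ = [
    "CsaeConfig", "ClassifierConfig", "CSAE", "ModelBundle",
    "sparse_loss", "pretrain_csae", "build_classifier", "train_classifier",
    "predict_proba", "predict", "save_bundle", "load_bundle",
]


@dataclass(frozen=True)
class CsaeConfig:
    enc_channels: tuple = (1, 32, 16)
    dec_channels: tuple = (16, 16, 1)
    kernel: int = 3
    dropout_ae: float = 0.2
    lambda_sparse: float = 1e-4
    lr: float = 1e-3
    batch: int = 32
    max_epochs_ae: int = 30
    recon_stop_threshold: float = 1e-3  # on mean per-feature squared error

    def __post_init__(self):
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be odd and positive")
        if self.lambda_sparse < 0:
            raise ValueError("lambda_sparse must be non-negative")
        if min(self.lr, self.batch, self.max_epochs_ae, self.recon_stop_threshold) <= 0:
            raise ValueError("lr, batch, max_epochs_ae, recon_stop_threshold must be positive")
        if self.enc_channels[-1] != self.dec_channels[0] or self.dec_channels[-1] != 1:
            raise ValueError("decoder must mirror encoder: latent channels in, 1 channel out")


@dataclass(frozen=True)
class ClassifierConfig:
    gru_hidden: int = 64
    dropout_clf: float = 0.5
    max_epochs_clf: int = 50
    frozen: bool = True
    seed: int = 0
    lr: float = 1e-3
    batch: int = 32
    scalar_sequence: bool = False  # strict flatten: length D*16 of 1-dim steps

    def __post_init__(self):
        if self.gru_hidden < 1:
            raise ValueError("gru_hidden must be >= 1")
        if not (0 <= self.dropout_clf < 1):
            raise ValueError("dropout must be in [0, 1)")


def _collect(layers, prefix: str, what: str) -> dict:
    out = {}
    for i, layer in enumerate(layers):
        for k, v in getattr(layer, what).items():
            out[f"{prefix}{i}.{k}"] = v
    return out


def _run_layers(layers, x, training: bool, rng=None):
    for layer in layers:
        if isinstance(layer, Dropout):
            x = layer.forward(x, training=training, rng=rng)
        else:
            x = layer.forward(x, training=training)
    return x


def _back_layers(layers, dy):
    for layer in reversed(layers):
        dy = layer.backward(dy)
    return dy


class CSAE:
    """Convolutional sparse autoencoder over length-D feature vectors."""

    def __init__(self, input_dim: int, cfg: CsaeConfig = CsaeConfig(), seed: int = 0):
        if input_dim < cfg.kernel:
            raise ValueError(f"input_dim must be >= kernel length {cfg.kernel}")
        self.cfg = cfg
        self.input_dim = input_dim
        rng = np.random.default_rng([int(seed), 0])
        enc = []
        for cin, cout in zip(cfg.enc_channels, cfg.enc_channels[1:]):
            enc += [Conv1d(cin, cout, cfg.kernel, rng), BatchNorm1d(cout),
                    ReLU(), Dropout(cfg.dropout_ae)]
        self.enc = enc
        dec = []
        pairs = list(zip(cfg.dec_channels, cfg.dec_channels[1:]))
        for cin, cout in pairs[:-1]:
            dec += [Conv1d(cin, cout, cfg.kernel, rng), BatchNorm1d(cout), ReLU()]
        dec.append(Conv1d(*pairs[-1], cfg.kernel, rng))  # linear regression layer
        self.dec = dec

    @property
    def latent_channels(self) -> int:
        return self.cfg.enc_channels[-1]

    def encode(self, X: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        """(N, D) feature vectors -> latent maps (N, C_latent, D)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(f"expected D={self.input_dim}, got {X.shape[1]}")
        return _run_layers(self.enc, X[:, None, :], training, rng)

    def decode(self, h: np.ndarray, training: bool = False) -> np.ndarray:
        """Latent maps (N, C_latent, D) -> reconstructions (N, D)."""
        if h.ndim != 3 or h.shape[1] != self.latent_channels or h.shape[2] != self.input_dim:
            raise ValueError(
                f"latent must be (N, {self.latent_channels}, {self.input_dim}), got {h.shape}"
            )
        return _run_layers(self.dec, h, training)[:, 0, :]

    def params(self) -> dict:
        return {**_collect(self.enc, "enc", "params"), **_collect(self.dec, "dec", "params")}

    def grads(self) -> dict:
        return {**_collect(self.enc, "enc", "grads"), **_collect(self.dec, "dec", "grads")}

    def zero_grads(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0


def sparse_loss(x: np.ndarray, x_hat: np.ndarray, h: np.ndarray,
                lambda_sparse: float) -> float:
    """L = ||x - x_hat||_2^2 + lambda ||h||_1, summed per sample, batch-averaged."""
    if lambda_sparse < 0:
        raise ValueError("lambda_sparse must be non-negative")
    x = np.atleast_2d(x)
    x_hat = np.atleast_2d(x_hat)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    n = x.shape[0]
    if np.asarray(h).shape[0] != n:
        raise ValueError("latent batch size mismatch")
    recon = ((x - x_hat) ** 2).reshape(n, -1).sum(axis=1)
    l1 = np.abs(h).reshape(n, -1).sum(axis=1)
    return float(np.mean(recon + lambda_sparse * l1))


def pretrain_csae(train_X: np.ndarray, cfg: CsaeConfig = CsaeConfig(),
                  seed: int = 0):
    """Train the CSAE with Adam; returns ``(csae, history)``.

    Stops after ``max_epochs_ae`` epochs or once the epoch-mean
    per-feature reconstruction error drops below ``recon_stop_threshold``.
    History rows carry the full sparse loss and its two terms.
    """
    X = np.atleast_2d(np.asarray(train_X, dtype=float))
    n, d = X.shape
    csae = CSAE(d, cfg, seed)
    rng = np.random.default_rng([int(seed), 1])
    opt = Adam(csae.params(), lr=cfg.lr)
    history = []
    for epoch in range(cfg.max_epochs_ae):
        order = rng.permutation(n)
        tot_loss = tot_recon = tot_l1 = 0.0
        for start in range(0, n, cfg.batch):
            idx = order[start:start + cfg.batch]
            xb = X[idx]
            b = len(idx)
            h = csae.encode(xb, training=True, rng=rng)
            xhat = csae.decode(h, training=True)
            recon = ((xb - xhat) ** 2).sum(axis=1)
            l1 = np.abs(h).reshape(b, -1).sum(axis=1)
            loss = float(np.mean(recon + cfg.lambda_sparse * l1))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite CSAE loss at epoch {epoch}: recon={recon.mean()}, "
                    f"l1={l1.mean()}"
                )
            csae.zero_grads()
            dxhat = 2.0 * (xhat - xb) / b
            dh = _back_layers(csae.dec, dxhat[:, None, :])
            dh = dh + cfg.lambda_sparse * np.sign(h) / b
            _back_layers(csae.enc, dh)
            opt.step(csae.grads())
            tot_loss += loss * b
            tot_recon += recon.sum()
            tot_l1 += l1.sum()
        recon_mse = tot_recon / (n * d)
        history.append({
            "epoch": epoch,
            "loss": tot_loss / n,
            "recon_mse_per_feature": recon_mse,
            "latent_l1": tot_l1 / n,
        })
        if recon_mse < cfg.recon_stop_threshold:
            break
    return csae, history


# ---------------------------------------------------------------------------
# classifier


@dataclass
class ModelBundle:
    """Frozen transferred encoder + GRU + dense head, with training history."""

    encoder: list
    gru: GRU
    dense: Dense
    dropout: Dropout
    csae_cfg: CsaeConfig
    clf_cfg: ClassifierConfig
    input_dim: int
    latent_channels: int
    class_labels: tuple = ("interictal", "ictal")  # (negative, positive=ictal)
    history: list = field(default_factory=list)

    def encoder_params(self) -> dict:
        return _collect(self.encoder, "enc", "params")


def _transfer_encoder(csae: CSAE) -> list:
    """Deep-copy conv/BN blocks of the encoder, dropping dropout (Frozen Conv: BN-ReLU)."""
    layers = []
    for layer in csae.enc:
        if isinstance(layer, Dropout):
            continue
        layers.append(copy.deepcopy(layer))
    return layers


def build_classifier(csae: CSAE, clf_cfg: ClassifierConfig = ClassifierConfig()) -> ModelBundle:
    """Transfer the pretrained encoder and attach GRU(hidden) + dense softmax head."""
    rng = np.random.default_rng([int(clf_cfg.seed), 2])
    in_dim = 1 if clf_cfg.scalar_sequence else csae.latent_channels
    gru = GRU(in_dim, clf_cfg.gru_hidden, rng)
    dense = Dense(clf_cfg.gru_hidden, 2, rng)
    return ModelBundle(
        encoder=_transfer_encoder(csae),
        gru=gru,
        dense=dense,
        dropout=Dropout(clf_cfg.dropout_clf),
        csae_cfg=csae.cfg,
        clf_cfg=clf_cfg,
        input_dim=csae.input_dim,
        latent_channels=csae.latent_channels,
    )


def _encode_frozen(bundle: ModelBundle, X: np.ndarray):
    """Transferred conv blocks; BN always uses the pretrained running stats."""
    x = np.atleast_2d(np.asarray(X, dtype=float))[:, None, :]
    # training=False keeps batch-norm in eval mode even when fine-tuning
    return _run_layers(bundle.encoder, x, training=False)


def _to_sequence(bundle: ModelBundle, latent: np.ndarray) -> np.ndarray:
    if bundle.clf_cfg.scalar_sequence:
        n = latent.shape[0]
        return latent.reshape(n, -1)[:, :, None]  # (N, C*D, 1)
    return np.transpose(latent, (0, 2, 1))        # (N, D, C)


def _forward_head(bundle: ModelBundle, seq: np.ndarray, training: bool, rng=None):
    h = bundle.gru.forward(seq, training=training)
    h = bundle.dropout.forward(h, training=training, rng=rng)
    return bundle.dense.forward(h, training=training)


def _labels_to_binary(labels: np.ndarray):
    classes = sorted(np.unique(labels).tolist())
    if len(classes) != 2:
        raise ValueError(f"classifier needs exactly two classes, got {classes}")
    if "ictal" in classes:
        pos = "ictal"
        neg = classes[0] if classes[1] == "ictal" else classes[1]
    else:
        neg, pos = classes
    y = (np.asarray(labels) == pos).astype(int)
    return y, (neg, pos)


def train_classifier(bundle: ModelBundle, train_table: FeatureTable,
                     clf_cfg: ClassifierConfig | None = None) -> ModelBundle:
    """Cross-entropy training of the GRU head (conv blocks frozen by default)."""
    cfg = clf_cfg if clf_cfg is not None else bundle.clf_cfg
    X = train_table.values
    y, class_labels = _labels_to_binary(train_table.labels)
    bundle.class_labels = class_labels
    n = len(y)
    rng = np.random.default_rng([int(cfg.seed), 3])

    trainable = {**_collect([bundle.gru], "gru", "params"),
                 **_collect([bundle.dense], "dense", "params")}
    grad_src = {**_collect([bundle.gru], "gru", "grads"),
                **_collect([bundle.dense], "dense", "grads")}
    if not cfg.frozen:
        trainable.update(_collect(bundle.encoder, "enc", "params"))
        grad_src.update(_collect(bundle.encoder, "enc", "grads"))
    opt = Adam(trainable, lr=cfg.lr)

    latent_all = _encode_frozen(bundle, X) if cfg.frozen else None
    history = []
    for epoch in range(cfg.max_epochs_clf):
        order = rng.permutation(n)
        tot_loss = 0.0
        correct = 0
        for start in range(0, n, cfg.batch):
            idx = order[start:start + cfg.batch]
            if cfg.frozen:
                latent = latent_all[idx]
            else:
                latent = _encode_frozen(bundle, X[idx])
            seq = _to_sequence(bundle, latent)
            logits = _forward_head(bundle, seq, training=True, rng=rng)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite classifier loss at epoch {epoch}")
            for g in grad_src.values():
                g[...] = 0.0
            dh = bundle.dense.backward(dlogits)
            dh = bundle.dropout.backward(dh)
            dseq = bundle.gru.backward(dh)
            if not cfg.frozen:
                if bundle.clf_cfg.scalar_sequence:
                    dlat = dseq[:, :, 0].reshape(latent.shape)
                else:
                    dlat = np.transpose(dseq, (0, 2, 1))
                _back_layers(bundle.encoder, dlat)
            opt.step(grad_src)
            tot_loss += loss * len(idx)
            correct += int((np.argmax(logits, axis=1) == y[idx]).sum())
        history.append({"epoch": epoch, "loss": tot_loss / n, "acc": correct / n})
    bundle.history = history
    return bundle


def predict_proba(bundle: ModelBundle, table: FeatureTable) -> np.ndarray:
    """Class probabilities, column 1 = ictal. Requires a normalized table."""
    if table.norm_state == "raw":
        raise ValueError("table must be normalized with the training normalizer first")
    latent = _encode_frozen(bundle, table.values)
    seq = _to_sequence(bundle, latent)
    logits = _forward_head(bundle, seq, training=False)
    return softmax(logits)


def predict(bundle: ModelBundle, table: FeatureTable) -> np.ndarray:
    """Hard labels in {0, 1}; argmax with ties resolved to class 0."""
    return np.argmax(predict_proba(bundle, table), axis=1)


# ---------------------------------------------------------------------------
# checkpointing


def _layer_state(layer) -> dict:
    state = {k: v for k, v in layer.params.items()}
    if isinstance(layer, BatchNorm1d):
        state["running_mean"] = layer.running_mean
        state["running_var"] = layer.running_var
    return state


def save_bundle(path, bundle: ModelBundle) -> None:
    """Single-file checkpoint: parameter arrays + JSON config; round-trip is bit-exact."""
    arrays = {}
    for i, layer in enumerate(bundle.encoder):
        for k, v in _layer_state(layer).items():
            arrays[f"enc{i}.{k}"] = v
    for k, v in bundle.gru.params.items():
        arrays[f"gru.{k}"] = v
    for k, v in bundle.dense.params.items():
        arrays[f"dense.{k}"] = v
    meta = {
        "csae_cfg": asdict(bundle.csae_cfg),
        "clf_cfg": asdict(bundle.clf_cfg),
        "input_dim": bundle.input_dim,
        "latent_channels": bundle.latent_channels,
        "class_labels": list(bundle.class_labels),
        "history": bundle.history,
    }
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_bundle(path) -> ModelBundle:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"].tobytes()).decode())
        arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
    csae_cfg = CsaeConfig(**{**meta["csae_cfg"],
                             "enc_channels": tuple(meta["csae_cfg"]["enc_channels"]),
                             "dec_channels": tuple(meta["csae_cfg"]["dec_channels"])})
    clf_cfg = ClassifierConfig(**meta["clf_cfg"])
    # rebuild skeleton then overwrite every parameter array
    skeleton = CSAE(meta["input_dim"], csae_cfg, seed=0)
    bundle = build_classifier(skeleton, clf_cfg)
    for i, layer in enumerate(bundle.encoder):
        for k in layer.params:
            layer.params[k][...] = arrays[f"enc{i}.{k}"]
        if isinstance(layer, BatchNorm1d):
            layer.running_mean[...] = arrays[f"enc{i}.running_mean"]
            layer.running_var[...] = arrays[f"enc{i}.running_var"]
    for k in bundle.gru.params:
        bundle.gru.params[k][...] = arrays[f"gru.{k}"]
    for k in bundle.dense.params:
        bundle.dense.params[k][...] = arrays[f"dense.{k}"]
    bundle.class_labels = tuple(meta["class_labels"])
    bundle.history = meta["history"]
    return bundle
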