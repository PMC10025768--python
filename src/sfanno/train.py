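"""Supervised source-model training and the portable model artifact.

The source objective is the sum of the ZINB reconstruction loss, the
classifier cross-entropy, and the co-training cross-entropy of two frozen
auxiliary classifier heads (their gradients reach the encoder only; the head
weights are never stepped).  One-hot labels are replaced by smoothed labels
``q' = (1 - eps) * onehot + eps / K`` with ``eps = 0.1`` by default.

The serialized artifact carries weights, architecture, class names, gene
list, and the preprocessing scaling statistics - nothing per-cell - so it can
cross the privacy boundary and is the only object the adaptation stage ever
sees from the source side.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .autodiff import Adam, Tensor
from .io import PreprocessedData, ScalingStats
from .likelihoods import bernoulli_nll, zinb_nll
from .network import Autoencoder, NetworkSpec

_FORMAT_VERSION = 1


@dataclass
class TrainConfig:
    warmup_epochs: int = 20
    joint_epochs: int = 80
    batch_size: int = 256
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    label_smoothing: float = 0.1
    corruption_sigma: float = 0.0
    latent_dim: int = 32
    encoder_hidden: Sequence[int] = (256, 64)
    decoder_hidden: Sequence[int] = (64, 256)
    likelihood: str = "zinb"

    def __post_init__(self):
        if not (0.0 <= self.label_smoothing < 0.5):
            raise ValueError("label smoothing must lie in [0, 0.5)")
        if self.batch_size <= 0 or self.joint_epochs < 0 or self.warmup_epochs < 0:
            raise ValueError("epochs must be non-negative and batch size positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


def _smooth_targets(y: np.ndarray, K: int, eps: float) -> np.ndarray:
    q = np.full((len(y), K), eps / K)
    q[np.arange(len(y)), y] += 1.0 - eps
    return q


def _validate_labels(y, K) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("labels must be a 1-D index array")
    if ((y < 0) | (y >= K)).any():
        raise ValueError(f"class index outside 0..{K - 1}")
    return y.astype(int)


def smoothed_cross_entropy(p, y, K: int, eps: float = 0.0) -> Tensor:
    """Label-smoothed cross-entropy on probability vectors.

    With ``eps = 0`` this is the plain cross-entropy against one-hot labels.
    ``y`` holds 0-based class indices.
    """
    y = _validate_labels(y, K)
    pt = p if isinstance(p, Tensor) else Tensor(np.asarray(p, dtype=np.float64))
    sums = pt.data.sum(axis=1)
    if np.abs(sums - 1.0).max() > 1e-4:
        raise ValueError("probability rows must sum to 1")
    q = _smooth_targets(y, K, eps)
    logp = pt.clip(1e-12, 1.0).log()
    return -(Tensor(q) * logp).sum(axis=1).mean()


def _smoothed_ce_from_logp(logp: Tensor, y: np.ndarray, K: int, eps: float) -> Tensor:
    q = _smooth_targets(_validate_labels(y, K), K, eps)
    return -(Tensor(q) * logp).sum(axis=1).mean()


def aux_co_training_loss(p1, p2, y, K: int, eps: float = 0.0) -> Tensor:
    """Sum of the two auxiliary heads' smoothed cross-entropies."""
    return smoothed_cross_entropy(p1, y, K, eps) + smoothed_cross_entropy(p2, y, K, eps)


@dataclass
class SourceModel:
    """The pre-trained artifact shared across the privacy boundary."""

    net: Autoencoder
    class_names: List[str]
    gene_names: List[str]
    scaling_stats: Optional[ScalingStats]
    label_smoothing: float
    train_log: List[dict] = field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def likelihood(self) -> str:
        return self.net.spec.likelihood

    def embed(self, x_input: np.ndarray) -> np.ndarray:
        return self.net.encode(Tensor(np.asarray(x_input, dtype=np.float64))).data

    def predict(self, x_input: np.ndarray):
        """Latent embedding plus softmax probabilities from c, c1, c2."""
        z = self.embed(x_input)
        p, p1, p2 = self.net.predict_probs(z)
        return z, p, p1, p2

    # -- persistence -------------------------------------------------------
    def save(self, path):
        meta = {
            "format_version": _FORMAT_VERSION,
            "spec": self.net.spec_dict(),
            "class_names": self.class_names,
            "gene_names": self.gene_names,
            "scaling_stats": self.scaling_stats.to_dict() if self.scaling_stats else None,
            "label_smoothing": self.label_smoothing,
        }
        buf = _io.BytesIO()
        np.savez(buf, **self.net.state_dict())
        Path(path).write_bytes(buf.getvalue())
        Path(str(path) + ".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path) -> "SourceModel":
        meta = json.loads(Path(str(path) + ".json").read_text())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError(
                f"model sidecar format version {meta.get('format_version')!r} "
                f"is not supported (expected {_FORMAT_VERSION})"
            )
        spec_d = dict(meta["spec"])
        n_classes = spec_d.pop("n_classes")
        spec = NetworkSpec(**spec_d)
        net = Autoencoder(spec, n_classes, seed=0)
        with np.load(_io.BytesIO(Path(path).read_bytes())) as state:
            net.load_state_dict({k: state[k] for k in state.files})
        stats = meta["scaling_stats"]
        return cls(
            net=net,
            class_names=list(meta["class_names"]),
            gene_names=list(meta["gene_names"]),
            scaling_stats=ScalingStats.from_dict(stats) if stats else None,
            label_smoothing=float(meta["label_smoothing"]),
        )


def _recon_loss(net: Autoencoder, x, params_target, sf):
    if net.spec.likelihood == "zinb":
        z, params = net.forward(x, size_factors=sf)
        return z, zinb_nll(params_target, params)
    z, params = net.forward(x)
    return z, bernoulli_nll(params_target, params)


def train_source(
    source: PreprocessedData, labels: Sequence[str], config: Optional[TrainConfig] = None
) -> SourceModel:
    """Train the source model and package the data-free artifact.

    Minimizes ``L = L_recon + L_cls + L_aux`` by mini-batch Adam after an
    optional reconstruction-only warmup.  The auxiliary heads stay at their
    two distinct random initializations throughout.
    """
    config = config or TrainConfig()
    class_names = sorted(set(labels))
    K = len(class_names)
    if K < 2:
        raise ValueError("source data must contain at least two cell types")
    y = np.array([class_names.index(l) for l in labels])
    counts = np.bincount(y, minlength=K)
    if (counts < 2).any():
        small = [class_names[i] for i in np.where(counts < 2)[0]]
        raise ValueError(f"every class needs >= 2 cells; too small: {small}")

    n, p = source.x_input.shape
    spec = NetworkSpec(
        input_dim=p,
        latent_dim=config.latent_dim,
        encoder_hidden=tuple(config.encoder_hidden),
        decoder_hidden=tuple(config.decoder_hidden),
        likelihood=config.likelihood,
    )
    net = Autoencoder(spec, K, seed=config.seed)
    rng = np.random.default_rng(config.seed)
    trainable = net.encoder_params + net.decoder_params + net.classifier_params
    opt = Adam(trainable, lr=config.learning_rate)
    eps = config.label_smoothing
    log: List[dict] = []

    def run_epoch(joint: bool) -> dict:
        order = rng.permutation(n)
        tot = dict(recon=0.0, cls=0.0, aux=0.0, n=0)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = source.x_input[idx]
            if config.corruption_sigma > 0:
                xb = xb + rng.normal(0.0, config.corruption_sigma, xb.shape)
            sfb = source.size_factors[idx]
            z, recon = _recon_loss(net, xb, source.raw_counts[idx], sfb)
            loss = recon
            cls_v = aux_v = 0.0
            if joint:
                lp, lp1, lp2 = net.class_logprobs(z)
                cls = _smoothed_ce_from_logp(lp, y[idx], K, eps)
                aux = _smoothed_ce_from_logp(lp1, y[idx], K, eps) + _smoothed_ce_from_logp(
                    lp2, y[idx], K, eps
                )
                loss = recon + cls + aux
                cls_v, aux_v = float(cls.data), float(aux.data)
            opt.zero_grad()
            for prm in net.aux_params:
                prm.grad = None
            loss.backward()
            opt.step()
            w = len(idx)
            tot["recon"] += float(recon.data) * w
            tot["cls"] += cls_v * w
            tot["aux"] += aux_v * w
            tot["n"] += w
        m = tot["n"]
        return {
            "recon": tot["recon"] / m,
            "cls": tot["cls"] / m,
            "aux": tot["aux"] / m,
            "total": (tot["recon"] + tot["cls"] + tot["aux"]) / m,
        }

    for epoch in range(config.warmup_epochs):
        rec = run_epoch(joint=False)
        log.append({"phase": "warmup", "epoch": epoch, **rec})
    for epoch in range(config.joint_epochs):
        rec = run_epoch(joint=True)
        log.append({"phase": "joint", "epoch": epoch, **rec})

    return SourceModel(
        net=net,
        class_names=class_names,
        gene_names=list(source.gene_names),
        scaling_stats=source.scaling_stats,
        label_smoothing=eps,
        train_log=log,
    )
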