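"""ZINB / Bernoulli denoising autoencoder with classifier heads.

Encoder ``h`` maps the normalized expression input to a ``d``-dimensional
latent space; decoder ``g`` emits the count-likelihood parameters through
link functions (exponential link scaled by per-cell size factors for the
mean, softplus for the dispersion, logistic for the dropout / Bernoulli
mean).  A linear-softmax classifier ``c`` and two auxiliary classifiers
``c1, c2`` with independent random initializations sit on the latent space;
the auxiliaries are never updated after initialization so that their
disagreement can serve as an uncertainty signal on new data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np

from .autodiff import Parameter, Tensor, log_softmax
from .likelihoods import BernoulliParams, ZINBParams

_MEAN_CLIP = 15.0  # exp-link raw activation clamp


@dataclass
class NetworkSpec:
    """Architecture description, serialized alongside the weights."""

    input_dim: int
    latent_dim: int = 32
    encoder_hidden: Tuple[int, ...] = (256, 64)
    decoder_hidden: Tuple[int, ...] = (64, 256)
    activation: str = "elu"
    likelihood: str = "zinb"  # "zinb" | "bernoulli"

    def __post_init__(self):
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if any(w <= 0 for w in (*self.encoder_hidden, *self.decoder_hidden)):
            raise ValueError("hidden widths must be positive")
        if self.likelihood not in ("zinb", "bernoulli"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        self.encoder_hidden = tuple(self.encoder_hidden)
        self.decoder_hidden = tuple(self.decoder_hidden)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init=False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            limit = np.sqrt(6.0 / (n_in + n_out))
            w = rng.uniform(-limit, limit, size=(n_in, n_out))
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> List[Parameter]:
        return [self.W, self.b]


class Autoencoder:
    """Encoder/decoder pair plus main and frozen auxiliary classifier heads."""

    def __init__(self, spec: NetworkSpec, n_classes: int, seed: int = 0):
        self.spec = spec
        self.n_classes = int(n_classes)
        rng = np.random.default_rng(seed)
        p, d = spec.input_dim, spec.latent_dim

        self.enc: List[Linear] = []
        last = p
        for w in spec.encoder_hidden:
            self.enc.append(Linear(last, w, rng))
            last = w
        self.enc.append(Linear(last, d, rng))  # linear latent layer

        self.dec: List[Linear] = []
        last = d
        for w in spec.decoder_hidden:
            self.dec.append(Linear(last, w, rng))
            last = w
        if spec.likelihood == "zinb":
            self.head_mean = Linear(last, p, rng)
            self.head_disp = Linear(last, p, rng)
            self.head_drop = Linear(last, p, rng)
            self._out_heads = [self.head_mean, self.head_disp, self.head_drop]
        else:
            self.head_theta = Linear(last, p, rng)
            self._out_heads = [self.head_theta]

        self.classifier = Linear(d, n_classes, rng)
        # auxiliary heads: distinct random initializations, permanently frozen
        self.aux1 = Linear(d, n_classes, np.random.default_rng(seed + 101))
        self.aux2 = Linear(d, n_classes, np.random.default_rng(seed + 202))

    # -- parameter groups --------------------------------------------------
    @property
    def encoder_params(self) -> List[Parameter]:
        return [p for layer in self.enc for p in layer.params]

    @property
    def decoder_params(self) -> List[Parameter]:
        return [p for layer in (*self.dec, *self._out_heads) for p in layer.params]

    @property
    def classifier_params(self) -> List[Parameter]:
        return self.classifier.params

    @property
    def aux_params(self) -> List[Parameter]:
        return [*self.aux1.params, *self.aux2.params]

    def all_params(self) -> List[Parameter]:
        return (
            self.encoder_params
            + self.decoder_params
            + self.classifier_params
            + self.aux_params
        )

    # -- forward passes ----------------------------------------------------
    def _act(self, x: Tensor) -> Tensor:
        return x.elu()

    def encode(self, x) -> Tensor:
        h = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        for layer in self.enc[:-1]:
            h = self._act(layer(h))
        return self.enc[-1](h)

    def decode(self, z: Tensor, size_factors=None):
        h = z
        for layer in self.dec:
            h = self._act(layer(h))
        if self.spec.likelihood == "zinb":
            raw_mean = self.head_mean(h).clip(-_MEAN_CLIP, _MEAN_CLIP)
            mean = raw_mean.exp()
            if size_factors is not None:
                sf = np.asarray(size_factors, dtype=np.float64).reshape(-1, 1)
                mean = Tensor(sf) * mean
            disp = self.head_disp(h).softplus() + 1e-7
            drop = self.head_drop(h).sigmoid()
            return ZINBParams(dropout=drop, mean=mean, dispersion=disp)
        theta = self.head_theta(h).sigmoid()
        return BernoulliParams(theta=theta)

    def forward(self, x, size_factors=None):
        """Return (latent embedding, likelihood parameters)."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if x.shape[-1] != self.spec.input_dim:
            raise ValueError(
                f"input has {x.shape[-1]} features, network expects {self.spec.input_dim}"
            )
        z = self.encode(x)
        return z, self.decode(z, size_factors)

    def class_logprobs(self, z: Tensor) -> Tuple[Tensor, Tensor, Tensor]:
        """Log-probabilities from the main and the two auxiliary heads."""
        return (
            log_softmax(self.classifier(z)),
            log_softmax(self.aux1(z)),
            log_softmax(self.aux2(z)),
        )

    def predict_probs(self, z) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Numpy softmax probabilities (no gradient graph)."""
        zt = z if isinstance(z, Tensor) else Tensor(np.asarray(z, dtype=np.float64))
        lp, lp1, lp2 = self.class_logprobs(zt.detach())
        return np.exp(lp.data), np.exp(lp1.data), np.exp(lp2.data)

    # -- (de)serialization -------------------------------------------------
    def _layer_map(self) -> Dict[str, Linear]:
        m = {f"enc{i}": l for i, l in enumerate(self.enc)}
        m.update({f"dec{i}": l for i, l in enumerate(self.dec)})
        if self.spec.likelihood == "zinb":
            m.update(mean=self.head_mean, disp=self.head_disp, drop=self.head_drop)
        else:
            m.update(theta=self.head_theta)
        m.update(cls=self.classifier, aux1=self.aux1, aux2=self.aux2)
        return m

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {}
        for name, layer in self._layer_map().items():
            out[f"{name}.W"] = layer.W.data.copy()
            out[f"{name}.b"] = layer.b.data.copy()
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]):
        for name, layer in self._layer_map().items():
            layer.W.data = np.asarray(state[f"{name}.W"], dtype=np.float64).copy()
            layer.b.data = np.asarray(state[f"{name}.b"], dtype=np.float64).copy()

    def spec_dict(self) -> dict:
        d = asdict(self.spec)
        d["n_classes"] = self.n_classes
        return d
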