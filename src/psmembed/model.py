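"""The two encoders that share one embedding hypersphere.

The spectrum encoder (SSN) is a two-layer fully connected network over
the 80,000-bin vector: 80,000 -> 1024 -> 256, ReLU activations, dropout
0.3 after the first hidden layer, and an L2-normalization output. The
peptide encoder (PSN) embeds each of the 30 vocabulary symbols into a
256-vector, runs a single bidirectional LSTM with hidden size 1024 per
direction, concatenates the final forward and backward hidden states
(2048), and maps them through 2048 -> 1024 -> 256 fully connected ReLU
layers onto the same unit sphere. Pad positions are masked out of the
recurrence so embeddings do not depend on the padded length.

Everything runs on the package's own reverse-mode engine; a
``desk_scale`` configuration shrinks the hidden sizes for CPU-sized
experiments while keeping the architecture identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp

from ._autograd import Tensor, affine, concat_cols, gather_rows


@dataclass(frozen=True)
class ModelConfig:
    input_dim: int = 80_000
    ssn_hidden: int = 1024
    embed_dim: int = 256
    vocab_size: int = 30
    aa_embed_dim: int = 256
    lstm_hidden: int = 1024      # per direction; concat width = 2x
    psn_hidden: int = 1024
    dropout: float = 0.3
    pad_len: int = 64
    seed: int = 0
    dtype: str = "float32"
    # branch-specific overrides; must agree when both given
    ssn_embed_dim: Optional[int] = None
    psn_embed_dim: Optional[int] = None

    def __post_init__(self):
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        se = self.ssn_embed_dim if self.ssn_embed_dim is not None else self.embed_dim
        pe = self.psn_embed_dim if self.psn_embed_dim is not None else self.embed_dim
        if se != pe:
            raise ValueError(
                f"embedding width must match between branches ({se} vs {pe})")
        for name in ("input_dim", "ssn_hidden", "embed_dim", "vocab_size",
                     "aa_embed_dim", "lstm_hidden", "psn_hidden", "pad_len"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "ModelConfig":
        """A CPU-sized configuration with the same layer structure."""
        base = dict(ssn_hidden=128, embed_dim=64, aa_embed_dim=32,
                    lstm_hidden=64, psn_hidden=64, dropout=0.0, seed=seed)
        base.update(overrides)
        return cls(**base)


def _uniform(rng, fan_in, shape, dtype):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class SiameseEmbedder:
    """Paired spectrum/peptide encoders with shared output geometry."""

    def __init__(self, config: ModelConfig):
        self.config = config
        c = config
        dtype = np.dtype(c.dtype)
        rng = np.random.default_rng(c.seed)
        H, E = c.lstm_hidden, c.aa_embed_dim
        p: Dict[str, Tensor] = {}
        p["ssn_w1"] = Tensor(_uniform(rng, c.input_dim, (c.input_dim, c.ssn_hidden), dtype), True)
        p["ssn_b1"] = Tensor(np.zeros(c.ssn_hidden, dtype), True)
        # output layers sit under a ReLU feeding the normalization; a small
        # positive bias keeps units alive at initialization
        p["ssn_w2"] = Tensor(_uniform(rng, c.ssn_hidden, (c.ssn_hidden, c.embed_dim), dtype), True)
        p["ssn_b2"] = Tensor(np.full(c.embed_dim, 0.1, dtype), True)
        p["embed"] = Tensor(rng.normal(0, 1.0, (c.vocab_size, E)).astype(dtype), True)
        for d in ("f", "b"):
            p[f"lstm_wx_{d}"] = Tensor(_uniform(rng, E, (E, 4 * H), dtype), True)
            p[f"lstm_wh_{d}"] = Tensor(_uniform(rng, H, (H, 4 * H), dtype), True)
            bias = np.zeros(4 * H, dtype)
            bias[H:2 * H] = 1.0  # forget-gate bias, standard recurrent init
            p[f"lstm_b_{d}"] = Tensor(bias, True)
        p["psn_w1"] = Tensor(_uniform(rng, 2 * H, (2 * H, c.psn_hidden), dtype), True)
        p["psn_b1"] = Tensor(np.zeros(c.psn_hidden, dtype), True)
        p["psn_w2"] = Tensor(_uniform(rng, c.psn_hidden, (c.psn_hidden, c.embed_dim), dtype), True)
        p["psn_b2"] = Tensor(np.full(c.embed_dim, 0.1, dtype), True)
        self.params = p
        self.training_steps = 0

    # -- plumbing -------------------------------------------------------

    def parameters(self) -> Dict[str, Tensor]:
        return self.params

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()

    def _dropout(self, t: Tensor, training: bool, rng) -> Tensor:
        p = self.config.dropout
        if not training or p == 0.0:
            return t
        if rng is None:
            raise ValueError("training-mode forward pass needs an rng for dropout")
        keep = (rng.random(t.data.shape) >= p).astype(t.data.dtype) / (1.0 - p)
        return t * Tensor(keep)

    # -- spectrum branch ------------------------------------------------

    def ssn_forward(self, spectra, training: bool = False, rng=None) -> Tensor:
        """Encode binned spectra (dense or sparse rows) to unit vectors."""
        if not sp.issparse(spectra):
            spectra = np.asarray(spectra, dtype=self.params["ssn_w1"].data.dtype)
        if spectra.shape[1] != self.config.input_dim:
            raise ValueError(
                f"expected input width {self.config.input_dim}, got {spectra.shape[1]}")
        h1 = affine(spectra, self.params["ssn_w1"], self.params["ssn_b1"]).relu()
        h1 = self._dropout(h1, training, rng)
        h2 = (h1.matmul(self.params["ssn_w2"]) + self.params["ssn_b2"]).relu()
        return h2.normalize_rows()

    # -- peptide branch -------------------------------------------------

    def _lstm_pass(self, xs, mask, direction: str) -> Tensor:
        """Run one LSTM direction over masked timesteps; final hidden state.

        ``xs`` is a list of (b, E) tensors in processing order and
        ``mask`` the matching (b, T) 0/1 array; masked steps carry the
        previous state through, so trailing pads never touch the state.
        """
        H = self.config.lstm_hidden
        wx = self.params[f"lstm_wx_{direction}"]
        wh = self.params[f"lstm_wh_{direction}"]
        b = self.params[f"lstm_b_{direction}"]
        n = mask.shape[0]
        dtype = wx.data.dtype
        h = Tensor(np.zeros((n, H), dtype))
        c = Tensor(np.zeros((n, H), dtype))
        for t, x_t in enumerate(xs):
            z = x_t.matmul(wx) + h.matmul(wh) + b
            i_g = z.cols(0, H).sigmoid()
            f_g = z.cols(H, 2 * H).sigmoid()
            g_g = z.cols(2 * H, 3 * H).tanh()
            o_g = z.cols(3 * H, 4 * H).sigmoid()
            c_new = f_g * c + i_g * g_g
            h_new = o_g * c_new.tanh()
            m = mask[:, t:t + 1].astype(dtype)
            if m.all():
                h, c = h_new, c_new
            else:
                mt, inv = Tensor(m), Tensor(1.0 - m)
                h = h_new * mt + h * inv
                c = c_new * mt + c * inv
        return h

    def psn_forward(self, tokens, training: bool = False, rng=None) -> Tensor:
        """Encode 64-length token sequences to unit vectors."""
        tokens = np.asarray(tokens)
        if tokens.ndim != 2:
            raise ValueError("tokens must be a (batch, pad_len) array")
        if tokens.min() < 0 or tokens.max() >= self.config.vocab_size:
            raise ValueError("token id out of vocabulary range")
        mask = tokens != 0
        # trailing all-pad columns contribute nothing; skip them
        lengths = mask.sum(axis=1)
        t_max = int(lengths.max()) if len(lengths) else 0
        if t_max == 0:
            raise ValueError("batch contains only padding")
        xs = [gather_rows(self.params["embed"], tokens[:, t]) for t in range(t_max)]
        h_fwd = self._lstm_pass(xs, mask[:, :t_max], "f")
        h_bwd = self._lstm_pass(xs[::-1], mask[:, :t_max][:, ::-1], "b")
        feats = self._dropout(concat_cols(h_fwd, h_bwd), training, rng)
        h1 = (feats.matmul(self.params["psn_w1"]) + self.params["psn_b1"]).relu()
        h1 = self._dropout(h1, training, rng)
        h2 = (h1.matmul(self.params["psn_w2"]) + self.params["psn_b2"]).relu()
        return h2.normalize_rows()

    # -- inference conveniences -----------------------------------------

    def embed_spectra(self, spectra) -> np.ndarray:
        return self.ssn_forward(spectra, training=False).data

    def embed_peptides(self, tokens) -> np.ndarray:
        return self.psn_forward(tokens, training=False).data

    # -- persistence ----------------------------------------------------

    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["_config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        arrays["_training_steps"] = np.asarray(self.training_steps)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SiameseEmbedder":
        with np.load(path) as data:
            cfg = ModelConfig(**json.loads(bytes(data["_config_json"]).decode()))
            model = cls(cfg)
            for k in model.params:
                model.params[k] = Tensor(data[k], True)
            model.training_steps = int(data["_training_steps"])
        return model


def init_model(config: ModelConfig) -> SiameseEmbedder:
    """Deterministically initialize both encoders from ``config.seed``."""
    return SiameseEmbedder(config)
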