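"""Training loop: peptide-disjoint splitting, mini-batch sextuplet
mining, SNAP-loss descent with Adam, and in-batch accuracy evaluation.

A "pair" throughout is (peptide string, raw spectrum). Spectra are
binned once up front into sparse rows and peptides tokenized once, so
each optimization step is encode -> mine -> loss -> update.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from . import preprocess
from .model import SiameseEmbedder
from .snaploss import (EmbeddedBatch, LossConfig, batch_accuracy,
                       mine_sextuplets, snap_loss_graph)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    train_frac: float = 0.8
    batch_size: int = 1024
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 1
    margin: float = 0.2
    seed: int = 0
    label_aware_mining: bool = True

    def __post_init__(self):
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must lie strictly between 0 and 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "TrainConfig":
        """CPU-sized defaults: small batches, a larger step size."""
        base = dict(batch_size=64, learning_rate=1e-3, epochs=40, seed=seed)
        base.update(overrides)
        return cls(**base)


class Adam:
    """Adam with coupled L2 weight decay (decay added to the gradient)."""

    def __init__(self, params: Dict[str, "object"], lr: float,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1 ** self.t)
            v_hat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.data.dtype)


def split_by_peptide(pairs: Sequence[Tuple[str, object]], frac: float = 0.8,
                     seed: int = 0):
    """Partition pairs so no peptide string crosses the split.

    Unique peptides (first-appearance order) are shuffled with ``seed``
    and divided ``frac``/(1-frac); every spectrum follows its peptide.
    """
    peptides = list(dict.fromkeys(p for p, _ in pairs))
    if len(peptides) < 2:
        raise ValueError("need at least 2 unique peptides to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(peptides)))
    n_train = min(max(int(round(frac * len(peptides))), 1), len(peptides) - 1)
    train_set = {peptides[i] for i in order[:n_train]}
    train = [pr for pr in pairs if pr[0] in train_set]
    test = [pr for pr in pairs if pr[0] not in train_set]
    assert not ({p for p, _ in train} & {p for p, _ in test})
    return train, test


def encode_pairs(pairs, model_config, vocab: Optional[preprocess.Vocabulary] = None):
    """Bin and tokenize pairs once: (sparse spectra, tokens, labels)."""
    vocab = vocab or preprocess.Vocabulary.default()
    rows, tokens, labels = [], [], []
    for peptide, spectrum in pairs:
        binned = preprocess.bin_spectrum(
            spectrum, max_mass=model_config.input_dim * preprocess.DEFAULT_BIN_WIDTH)
        rows.append(sp.csr_matrix(binned.vector[None, :]))
        tokens.append(preprocess.encode_peptide(
            peptide, vocab, pad_len=model_config.pad_len).tokens)
        labels.append(peptide)
    X = sp.vstack(rows, format="csr").astype(np.float32)
    return X, np.stack(tokens), labels


@dataclass
class EpochLog:
    epoch: int
    loss: float
    accuracy: float
    batches: int


def train(model: SiameseEmbedder, pairs, cfg: TrainConfig,
          out_dir: Optional[str] = None) -> List[EpochLog]:
    """Optimize both encoders on labeled pairs; returns per-epoch logs.

    Each step: forward both branches in training mode, mine the hardest
    sextuplets from the resulting distance matrices, evaluate the
    quadruple-hinge loss, and take one Adam step. Batches with fewer
    than two distinct peptides are skipped. With the same seed the loss
    trace is bit-reproducible.
    """
    if not pairs:
        raise ValueError("empty training set")
    X, tokens, labels = encode_pairs(pairs, model.config)
    labels_arr = np.asarray(labels, dtype=object)
    opt = Adam(model.params, cfg.learning_rate, cfg.weight_decay)
    loss_cfg = LossConfig(margin=cfg.margin)
    rng = np.random.default_rng(cfg.seed)
    n = X.shape[0]
    logs: List[EpochLog] = []
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses, accs = [], []
        for start in range(0, n, cfg.batch_size):
            sel = perm[start:start + cfg.batch_size]
            if len(sel) < 2:
                continue
            batch_labels = list(labels_arr[sel])
            if len(set(batch_labels)) < 2:
                logger.warning("epoch %d: batch with < 2 distinct peptides skipped",
                               epoch)
                continue
            Qt = model.ssn_forward(X[sel], training=True, rng=rng)
            Pt = model.psn_forward(tokens[sel], training=True, rng=rng)
            ebatch = EmbeddedBatch(Qt.data, Pt.data, batch_labels)
            idx = mine_sextuplets(ebatch, label_aware=cfg.label_aware_mining)
            loss = snap_loss_graph(Qt, Pt, idx, loss_cfg)
            model.zero_grad()
            loss.backward()
            opt.step()
            model.training_steps += 1
            losses.append(float(loss.data))
            accs.append(batch_accuracy(ebatch))
        logs.append(EpochLog(epoch, float(np.mean(losses)) if losses else math.nan,
                             float(np.mean(accs)) if accs else math.nan,
                             len(losses)))
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)
            model.save(os.path.join(out_dir, "checkpoint.npz"))
    return logs


def _round_robin_batches(labels: Sequence[str], batch_size: int):
    """Index batches with at most one spectrum per peptide where possible."""
    groups: Dict[str, list] = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, []).append(i)
    depth = max(len(g) for g in groups.values())
    for rep in range(depth):
        layer = [g[rep] for g in groups.values() if rep < len(g)]
        for start in range(0, len(layer), batch_size):
            yield layer[start:start + batch_size]


def evaluate(model: SiameseEmbedder, pairs, batch_size: int = 64) -> float:
    """Mean in-batch nearest-peptide accuracy, dropout disabled.

    Batches are assembled round-robin over peptides so each holds one
    spectrum per peptide where replicate counts allow; the return value
    is the spectrum-weighted accuracy across batches.
    """
    if not pairs:
        raise ValueError("empty evaluation set")
    X, tokens, labels = encode_pairs(pairs, model.config)
    labels_arr = np.asarray(labels, dtype=object)
    correct = 0
    total = 0
    for batch in _round_robin_batches(labels, batch_size):
        sel = np.asarray(batch)
        Q = model.embed_spectra(X[sel])
        P = model.embed_peptides(tokens[sel])
        acc = batch_accuracy(EmbeddedBatch(Q, P, list(labels_arr[sel])))
        correct += acc * len(sel)
        total += len(sel)
    return correct / total
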