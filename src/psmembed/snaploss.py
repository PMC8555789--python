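"""Squared-distance matrices, hardest-sextuplet mining, and the
quadruple-hinge SNAP loss.

For a batch of b spectrum embeddings Q and peptide embeddings P (row i
of P is the true peptide of spectrum i), three pairwise squared
Euclidean distance (SED) matrices are formed with the Gramian identity
D = g 1^T - 2 A B^T + 1 g^T. Per anchor pair (q_i, p_i) four hardest
negatives are mined: the closest other spectrum and peptide to q_i, and
the closest other spectrum and peptide to p_i. The loss averages the
four hinge terms max(d_i - d_n + margin, 0) over contributing anchors:

    L = 1/(4 b) * sum_i sum_{r=1..4} max(d_i - d_nr + margin, 0)

Rows sharing the anchor's peptide string are ineligible as negatives by
default (a strict index-only mode reproduces mining that excludes only
the anchor itself). Batch accuracy is the fraction of spectra whose
nearest in-batch peptide carries their own label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from ._autograd import Tensor, gather_rows

__all__ = [
    "EmbeddedBatch", "DistanceTriple", "SextupletIndices", "LossConfig",
    "pairwise_sed", "distance_triple", "mine_sextuplets", "snap_loss",
    "snap_loss_graph", "batch_accuracy",
]


@dataclass(frozen=True)
class LossConfig:
    margin: float = 0.2

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


@dataclass
class EmbeddedBatch:
    """Paired spectrum/peptide embeddings with peptide-string labels."""

    Q: np.ndarray
    P: np.ndarray
    labels: Sequence[str]

    def __post_init__(self):
        self.Q = np.asarray(self.Q)
        self.P = np.asarray(self.P)
        if self.Q.shape != self.P.shape:
            raise ValueError("Q and P must have identical shapes")
        if len(self.labels) != self.Q.shape[0]:
            raise ValueError("one label per row required")

    def __len__(self) -> int:
        return self.Q.shape[0]


@dataclass
class DistanceTriple:
    d_qq: np.ndarray
    d_qp: np.ndarray
    d_pp: np.ndarray


@dataclass
class SextupletIndices:
    """Per-anchor hardest-negative indices (j, k, l, m); ``valid`` is
    False for anchors with no eligible negative, which drop out of the
    loss."""

    j: np.ndarray  # negative spectrum for q_i  (row scan of D_QQ)
    k: np.ndarray  # negative peptide for q_i   (row scan of D_QP)
    l: np.ndarray  # negative spectrum for p_i  (column scan of D_QP)
    m: np.ndarray  # negative peptide for p_i   (row scan of D_PP)
    valid: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones(len(self.j), dtype=bool)


def pairwise_sed(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs squared Euclidean distances via the Gramian identity.

    Entry (i, j) is ||a_i - b_j||^2; tiny negatives from floating-point
    cancellation are clamped to 0.
    """
    A = np.asarray(A, dtype=np.float64)
    B = np.asarray(B, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError(
            f"embedding widths differ: {A.shape} vs {B.shape}")
    g_a = np.einsum("ij,ij->i", A, A)
    g_b = np.einsum("ij,ij->i", B, B)
    D = g_a[:, None] - 2.0 * (A @ B.T) + g_b[None, :]
    np.maximum(D, 0.0, out=D)
    return D


def distance_triple(batch: EmbeddedBatch) -> DistanceTriple:
    """The three SED matrices D_QxQ, D_QxP, D_PxP of a batch."""
    return DistanceTriple(
        d_qq=pairwise_sed(batch.Q, batch.Q),
        d_qp=pairwise_sed(batch.Q, batch.P),
        d_pp=pairwise_sed(batch.P, batch.P),
    )


def _eligibility(labels: Sequence[str], label_aware: bool) -> np.ndarray:
    """(b, b) boolean matrix: may column r serve as negative for row i?"""
    b = len(labels)
    elig = ~np.eye(b, dtype=bool)
    if label_aware:
        lab = np.asarray(labels, dtype=object)
        elig &= lab[:, None] != lab[None, :]
    return elig


def _masked_argmin(D: np.ndarray, elig: np.ndarray) -> np.ndarray:
    masked = np.where(elig, D, np.inf)
    return np.argmin(masked, axis=1)  # ties -> lowest index


def mine_sextuplets(batch: EmbeddedBatch, label_aware: bool = True,
                    triple: DistanceTriple | None = None) -> SextupletIndices:
    """Hardest negatives per anchor from the batch distance matrices.

    ``label_aware=False`` excludes only the anchor's own row, mining
    literal nearest neighbours even when a peptide occurs twice in the
    batch.
    """
    if len(batch) < 2:
        raise ValueError("mining needs a batch of at least 2")
    if triple is None:
        triple = distance_triple(batch)
    elig = _eligibility(batch.labels, label_aware)
    valid = elig.any(axis=1)
    j = _masked_argmin(triple.d_qq, elig)
    k = _masked_argmin(triple.d_qp, elig)
    l = _masked_argmin(triple.d_qp.T, elig)
    m = _masked_argmin(triple.d_pp, elig)
    idx = np.arange(len(batch))
    for arr in (j, k, l, m):
        arr[~valid] = idx[~valid]  # placeholder; excluded from the loss
    return SextupletIndices(j, k, l, m, valid)


def snap_loss_graph(Qt: Tensor, Pt: Tensor, idx: SextupletIndices,
                    cfg: LossConfig = LossConfig()) -> Tensor:
    """Differentiable quadruple-hinge loss over the mined sextuplets."""
    n_valid = int(idx.valid.sum())
    if n_valid == 0:
        return Tensor(np.zeros(()))
    diff = Qt - Pt
    d_pos = (diff * diff).sum_rows()
    total = None
    for anchor, other, indices in (
        (Qt, Qt, idx.j),   # negative spectrum for q_i
        (Qt, Pt, idx.k),   # negative peptide for q_i
        (Pt, Qt, idx.l),   # negative spectrum for p_i
        (Pt, Pt, idx.m),   # negative peptide for p_i
    ):
        neg = anchor - gather_rows(other, indices)
        d_neg = (neg * neg).sum_rows()
        hinge = (d_pos - d_neg + cfg.margin).relu()
        total = hinge if total is None else total + hinge
    w = idx.valid.astype(Qt.data.dtype)
    return total.dot(w) * (1.0 / (4.0 * n_valid))


def snap_loss(batch: EmbeddedBatch, idx: SextupletIndices,
              cfg: LossConfig = LossConfig()) -> float:
    """Scalar SNAP loss of a batch under mined sextuplet indices."""
    Qt, Pt = Tensor(np.asarray(batch.Q, dtype=np.float64)), \
        Tensor(np.asarray(batch.P, dtype=np.float64))
    return float(snap_loss_graph(Qt, Pt, idx, cfg).data)


def batch_accuracy(batch: EmbeddedBatch) -> float:
    """Fraction of spectra whose nearest in-batch peptide is correct.

    The scan runs over all peptide rows; a duplicate peptide counts as
    correct if it carries the same string label.
    """
    if len(batch) < 1:
        raise ValueError("empty batch")
    D = pairwise_sed(batch.Q, batch.P)
    nearest = np.argmin(D, axis=1)
    lab = np.asarray(batch.labels, dtype=object)
    return float(np.mean(lab[nearest] == lab))
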