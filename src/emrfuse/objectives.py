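"""Training objectives: shared projection space, symmetric InfoNCE, joint loss.

The contrastive term treats the i-th structured/text pair in a batch as the
positive and every other in-batch pairing as a negative, averaging the
struct->text and text->struct directions with a -1/(2N) normalization:

    L_cont = -(1/2N) * sum_i [ log softmax_j s(z_s_i, z_t_j)/tau |_{j=i}
                             + log softmax_j s(z_t_i, z_s_j)/tau |_{j=i} ]

with s(.,.) cosine similarity and a learnable temperature tau kept positive by
log-space parameterization (clamped to [1e-3, 10] after each step).
"""

from __future__ import annotations

import numpy as np

from .nn import Linear, Module, Parameter, Tensor

__all__ = [
    "ProjectionHead",
    "Temperature",
    "cosine_similarity_matrix",
    "contrastive_loss",
    "cross_entropy",
    "l2_regularization",
    "total_loss",
    "DivergenceError",
]

TAU_MIN, TAU_MAX = 1e-3, 10.0


class DivergenceError(RuntimeError):
    """A loss component became non-finite during training."""


class ProjectionHead(Module):
    """Two-layer map (affine -> GELU -> affine) into the shared space Z.

    One head is shared by both modalities, so their pooled vectors must have
    the same width.
    """

    def __init__(self, d_in: int, d_z: int, rng: np.random.Generator):
        self.fc1 = Linear(d_in, d_in, rng)
        self.fc2 = Linear(d_in, d_z, rng)

    def __call__(self, pooled: Tensor) -> Tensor:
        return self.fc2(self.fc1(pooled).gelu())


class Temperature(Module):
    """Learnable tau > 0, optimized in log-space."""

    def __init__(self, init: float = 0.07):
        if not TAU_MIN <= init <= TAU_MAX:
            raise ValueError(f"tau init must lie in [{TAU_MIN}, {TAU_MAX}]")
        self.log_tau = Parameter(np.array(np.log(init)))

    @property
    def value(self) -> float:
        return float(np.exp(self.log_tau.data))

    def tensor(self) -> Tensor:
        return self.log_tau.exp()

    def clamp_(self) -> None:
        self.log_tau.data = np.clip(
            self.log_tau.data, np.log(TAU_MIN), np.log(TAU_MAX)
        )


def _l2_normalize(z: Tensor, eps: float = 1e-12) -> Tensor:
    norm = ((z * z).sum(axis=-1, keepdims=True) + eps) ** 0.5
    return z / norm


def cosine_similarity_matrix(z_a: Tensor, z_b: Tensor) -> Tensor:
    """(N, d) x (N, d) -> (N, N) of pairwise cosine similarities."""
    return _l2_normalize(z_a) @ _l2_normalize(z_b).swapaxes(-1, -2)


def contrastive_loss(z_struct: Tensor, z_text: Tensor, tau) -> Tensor:
    """Symmetric InfoNCE over a batch of matched cross-modal pairs."""
    n = z_struct.shape[0]
    if n == 0:
        raise ValueError("empty batch")
    if z_text.shape[0] != n:
        raise ValueError("mismatched batch sizes")
    tau_t = tau.tensor() if isinstance(tau, Temperature) else Tensor._coerce(tau)
    sim = cosine_similarity_matrix(z_struct, z_text) / tau_t  # (N, N)
    diag = np.arange(n)
    # struct -> text: softmax over rows; text -> struct: softmax over columns
    # (column softmax of sim equals row softmax of sim^T, and s is symmetric in its args)
    row_lse = sim.logsumexp(axis=1)
    col_lse = sim.logsumexp(axis=0)
    positives = sim[diag, diag]
    loss = -(1.0 / (2 * n)) * ((positives - row_lse) + (positives - col_lse)).sum()
    return loss


def cross_entropy(logits: Tensor, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> Tensor:
    """Mean (optionally class-weighted) cross-entropy on integer labels."""
    labels = np.asarray(labels, dtype=int)
    n = logits.shape[0]
    lse = logits.logsumexp(axis=-1)
    picked = logits[np.arange(n), labels]
    nll = lse - picked
    if class_weights is not None:
        w = np.asarray(class_weights, dtype=float)[labels]
        return (nll * Tensor(w)).sum() / float(w.sum())
    return nll.mean()


def l2_regularization(named_params: list[tuple[str, Parameter]]) -> Tensor:
    """Squared norm of trainable weights, excluding biases and norm parameters."""
    total = Tensor(0.0)
    for name, p in named_params:
        if not p.requires_grad:
            continue
        leaf = name.rsplit(".", 1)[-1]
        if leaf in ("bias", "beta", "gamma", "log_tau"):
            continue
        total = total + (p * p).sum()
    return total


def total_loss(task: Tensor, contrastive: Tensor, reg: Tensor,
               alpha: float, beta: float, gamma: float) -> Tensor:
    """Weighted joint objective alpha*L_task + beta*L_cont + gamma*L_reg."""
    if alpha < 0 or beta < 0 or gamma < 0:
        raise ValueError("loss weights must be non-negative")
    if alpha == 0 and beta == 0:
        raise ValueError("at least one of alpha, beta must be positive")
    for part, label in ((task, "task"), (contrastive, "contrastive"), (reg, "reg")):
        if not np.all(np.isfinite(part.data)):
            raise DivergenceError(f"non-finite {label} loss component")
    return alpha * task + beta * contrastive + gamma * reg
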