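"""Slice attention module (SAM).

Given the per-view embedding matrix I (M_k x C), the pairwise affinity

    a_ij = exp(I_i . I_j) / sum_i' exp(I_i' . I_j)

is a column-stochastic softmax over the *contributing* slice index i: each
column j distributes one unit of influence over the slices feeding slice j.
The attended features carry a learnable residual gate beta, initialised 0:

    I~_j = beta * sum_i a_ij I_i + I_j

so at initialisation the module is an exact identity — the model starts as
its attention-free ablation and the gate opens only if attention helps.

Functions here operate on plain arrays for analysis, and on autograd
tensors inside the model (see :class:`SliceAttention`).
"""

from __future__ import annotations

import numpy as np

from .nn import Module, Parameter, Tensor, concat, softmax

__all__ = ["attention_scores", "apply_attention", "fuse_views", "attention_mass",
           "SliceAttention", "export_attention_csv"]


# ---------------------------------------------------------------------------
# array-level reference operations
# ---------------------------------------------------------------------------

def attention_scores(embeddings: np.ndarray) -> np.ndarray:
    """Column-stochastic slice-affinity matrix from (M, C) embeddings.

    Computed with per-column max subtraction; every column sums to 1.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    if emb.ndim != 2:
        raise ValueError(f"embeddings must be (M, C), got {emb.shape}")
    if not np.isfinite(emb).all():
        raise FloatingPointError("non-finite embeddings")
    # explicit multiply-reduce rather than BLAS matmul: identical rows then
    # yield bitwise-identical scores, so equal embeddings give exactly 1/M
    scores = (emb[:, None, :] * emb[None, :, :]).sum(axis=-1)
    scores -= scores.max(axis=0, keepdims=True)
    np.exp(scores, out=scores)
    scores /= scores.sum(axis=0, keepdims=True)
    return scores


def apply_attention(embeddings: np.ndarray, attn: np.ndarray,
                    beta: float) -> np.ndarray:
    """Residual-gated attention: I~_j = beta * sum_i a_ij I_i + I_j."""
    emb = np.asarray(embeddings, dtype=np.float64)
    attn = np.asarray(attn, dtype=np.float64)
    m = emb.shape[0]
    if attn.shape != (m, m):
        raise ValueError(f"attention matrix {attn.shape} does not match "
                         f"{m} embeddings")
    return beta * (attn.T @ emb) + emb


def fuse_views(ix: np.ndarray, iy: np.ndarray, iz: np.ndarray) -> np.ndarray:
    """Concatenate the three views' embeddings into the slice feature vector.

    Order is (x, y, z), row-major within each view:
    length (M_x + M_y + M_z) * C.
    """
    parts = [np.asarray(a, dtype=np.float64).ravel() for a in (ix, iy, iz)]
    if not all(np.isfinite(p).all() for p in parts):
        raise FloatingPointError("non-finite embeddings")
    return np.concatenate(parts)


def attention_mass(attn: np.ndarray, informative: set[int] | list[int]) -> float:
    """Average column mass assigned to an informative slice set.

    For a column-stochastic A this is mean_j sum_{i in informative} a_ij,
    in [0, 1]; a uniform matrix gives |informative| / M.  Used to quantify
    whether attention concentrates on slices known to carry signal.
    """
    informative = sorted(set(int(i) for i in informative))
    if not informative:
        raise ValueError("informative slice set must be non-empty")
    attn = np.asarray(attn, dtype=np.float64)
    m = attn.shape[0]
    if any(i < 0 or i >= m for i in informative):
        raise ValueError(f"informative indices out of range 0..{m - 1}")
    return float(attn[informative, :].sum(axis=0).mean())


def export_attention_csv(matrices: dict[str, np.ndarray], directory) -> list:
    """Write one CSV per view for inspection (filenames attention_<view>.csv)."""
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for view, attn in matrices.items():
        p = directory / f"attention_{view}.csv"
        np.savetxt(p, np.asarray(attn), delimiter=",")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# differentiable module
# ---------------------------------------------------------------------------

class SliceAttention(Module):
    """Per-view attention with its own scalar gate beta (initialised 0)."""

    def __init__(self):
        super().__init__()
        self.beta = Parameter(np.zeros(1, dtype=np.float32), decay=False)

    def scores(self, emb: Tensor) -> Tensor:
        """(N, M, C) -> (N, M, M) column-stochastic attention, batched."""
        s = emb @ emb.swapaxes(-1, -2)       # s[n, i, j] = I_i . I_j
        return softmax(s, axis=-2)           # normalise over contributing i

    def forward(self, emb: Tensor) -> tuple[Tensor, Tensor]:
        attn = self.scores(emb)
        attended = self.beta * (attn.swapaxes(-1, -2) @ emb) + emb
        return attended, attn
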