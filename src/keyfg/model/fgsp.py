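"""Fine-Grained Score Predictor (FGSP): foreground token scoring.

Each encoder token j gets a class probability C_j (max over classes of
the sigmoid class logits) and a foreground probability S_j (sigmoid of a
scalar logit); the product P_j = C_j * S_j ranks tokens, and the top
fraction is kept, steering object queries toward probable foreground
regions — the decisive cue when foreground and background look alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..nn import Linear, Module, Tensor

__all__ = ["TokenScore", "fgsp_scores", "select_foreground_tokens", "FGSPHead"]


@dataclass(frozen=True)
class TokenScore:
    class_prob: float      # C_j
    foreground_prob: float  # S_j

    @property
    def product(self) -> float:  # P_j
        return self.class_prob * self.foreground_prob


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def fgsp_scores(class_logits: np.ndarray, foreground_logits: np.ndarray) -> list[TokenScore]:
    """Score tokens from (N, n_classes) class logits and (N,) foreground
    logits: C_j = max_c sigmoid(logit), S_j = sigmoid(fg logit)."""
    cl = np.atleast_2d(np.asarray(class_logits, dtype=float))
    fg = np.atleast_1d(np.asarray(foreground_logits, dtype=float))
    if cl.shape[0] != fg.shape[0]:
        raise ValueError("one class-logit row and one foreground logit per token")
    C = _sigmoid(cl).max(axis=1)
    S = _sigmoid(fg)
    return [TokenScore(float(c), float(s)) for c, s in zip(C, S)]


def select_foreground_tokens(scores: list[TokenScore], keep_ratio: float) -> np.ndarray:
    """Indices of the top ceil(keep_ratio * N) tokens by P_j.

    Ties are broken toward the lower index (stable sort), so an all-equal
    score list keeps the leading tokens.  Returned indices are sorted.
    """
    if not scores:
        raise ValueError("empty token list")
    if not 0.0 < keep_ratio <= 1.0:
        raise ValueError("keep_ratio must lie in (0, 1]")
    p = np.array([s.product for s in scores])
    n_keep = int(np.ceil(keep_ratio * len(scores)))
    order = np.argsort(-p, kind="stable")
    return np.sort(order[:n_keep])


class FGSPHead(Module):
    """Linear class and foreground heads over encoder tokens."""

    def __init__(self, d_model: int, n_classes: int, rng: np.random.Generator):
        self.class_head = Linear(d_model, n_classes, rng)
        self.fg_head = Linear(d_model, 1, rng)
        # bias class logits low so that initial foreground probabilities
        # are small (focal-loss-friendly prior)
        self.class_head.bias.data[:] = -2.0

    def __call__(self, tokens: Tensor) -> tuple[Tensor, Tensor]:
        return self.class_head(tokens), self.fg_head(tokens).reshape(tokens.shape[0])
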