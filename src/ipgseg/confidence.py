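"""Similarity-based confidence, uncertainty, gating, and the
spatial-information-consistency loss.

A candidate pixel's confidence for category i is the mean cosine similarity
between its (projected) feature vector and the features of category i's
current prompt points; its uncertainty is the population variance of those
similarities.  A pixel is admitted as a pseudo label only when confidence
clears the high threshold tau_h AND uncertainty stays below kappa_h — the
two-indicator gate that keeps unreliable labels out of training.  Confidence
against the low threshold tau_l additionally classifies pixels into
foreground (+1), background (-1) or abstain (0).

The consistency loss pulls gated pixels' confidences toward 1 for their own
category and toward 0 for every other category; it is the (negated)
one-vs-rest log-likelihood of the gated pixels and is the training signal
for the prompt projection.  Cosine means can be negative while the loss
takes logarithms, so confidences are clipped to [eps, 1-eps] before logs;
the clip saturates the gradient rather than producing infinities.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

CLIP_EPS = 1e-7


@dataclass(frozen=True)
class Thresholds:
    """Gate thresholds: tau_high/tau_low on confidence, kappa_high on
    uncertainty.  Defaults are the framework's standard settings."""

    tau_high: float = 0.8
    tau_low: float = 0.5
    kappa_high: float = 0.2

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau_low < self.tau_high <= 1.0):
            raise ValueError("need 0 <= tau_low < tau_high <= 1")
        if self.kappa_high <= 0:
            raise ValueError("kappa_high must be positive")


@dataclass(frozen=True)
class PromptFeatureSet:
    """Projected feature vectors of one category's prompt points, (n, D)."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if v.shape[0] < 1:
            raise ValueError("prompt feature set must be nonempty")
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms == 0):
            raise ValueError("prompt feature set contains a zero-norm vector")
        object.__setattr__(self, "vectors", v)

    @property
    def n(self) -> int:
        return self.vectors.shape[0]


@dataclass(frozen=True)
class ConfidenceRecord:
    """Audit record for one (pixel, category) decision."""

    row: int
    col: int
    category: int
    p: float
    u: float
    y: int
    g: int
    iteration: int = 0


def records_to_csv(records: list[ConfidenceRecord], path: str | Path) -> None:
    """Write audit records as (row, col, category, p, u, y, g, iteration)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "category", "p", "u", "y", "g",
                         "iteration"])
        for rec in records:
            writer.writerow([rec.row, rec.col, rec.category,
                             f"{rec.p:.10f}", f"{rec.u:.10f}",
                             rec.y, rec.g, rec.iteration])


def cosine_similarity(f_a: np.ndarray, f_ij: np.ndarray) -> float:
    """Cosine of the angle between two nonzero feature vectors, in [-1, 1]."""
    a = np.asarray(f_a, dtype=np.float64)
    b = np.asarray(f_ij, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def similarities(f_a: np.ndarray, prompt_set: PromptFeatureSet) -> np.ndarray:
    """Cosine similarities of one pixel feature against all prompt features."""
    a = np.asarray(f_a, dtype=np.float64)
    na = np.linalg.norm(a)
    if na == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vectors")
    v = prompt_set.vectors
    return np.clip(v @ a / (np.linalg.norm(v, axis=1) * na), -1.0, 1.0)


def confidence(f_a: np.ndarray, prompt_set: PromptFeatureSet) -> float:
    """Mean similarity of a pixel to a category's prompt features."""
    return float(similarities(f_a, prompt_set).mean())


def uncertainty(f_a: np.ndarray, prompt_set: PromptFeatureSet) -> float:
    """Population variance of the similarities (0 for a single prompt)."""
    s = similarities(f_a, prompt_set)
    return float(((s - s.mean()) ** 2).mean())


def batch_confidence(feats: np.ndarray, prompt_set: PromptFeatureSet
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized confidence and uncertainty for an (m, D) feature block."""
    f = np.atleast_2d(np.asarray(feats, dtype=np.float64))
    fn = np.linalg.norm(f, axis=1, keepdims=True)
    if np.any(fn == 0):
        raise ValueError("zero-norm feature vector")
    v = prompt_set.vectors
    vn = np.linalg.norm(v, axis=1, keepdims=True)
    s = np.clip((f / fn) @ (v / vn).T, -1.0, 1.0)  # (m, n)
    p = s.mean(axis=1)
    u = ((s - p[:, None]) ** 2).mean(axis=1)
    return p, u


def threshold_label(p: float, thresholds: Thresholds) -> int:
    """Foreground/background/abstain decision: +1 if p >= tau_high, -1 if
    p <= tau_low, else 0."""
    if p >= thresholds.tau_high:
        return 1
    if p <= thresholds.tau_low:
        return -1
    return 0


def selection_gate(p: float, u: float, thresholds: Thresholds) -> int:
    """1 iff confidence clears tau_high and uncertainty stays within
    kappa_high; only gated pixels enter training."""
    return int(p >= thresholds.tau_high and u <= thresholds.kappa_high)


def consistency_loss(gates: np.ndarray, p_all: np.ndarray, category: int,
                     eps: float = CLIP_EPS) -> float:
    """Spatial-information-consistency loss for one category's gated pixels.

    Parameters
    ----------
    gates:
        (m,) gate indicators for the pixels.
    p_all:
        (m, K) confidences of each pixel against every category's prompts.
    category:
        1-based index i of the category owning these pixels.

    Returns the negated one-vs-rest log-likelihood
    ``-sum_a g_a [log p_a^(i) + sum_{j != i} log(1 - p_a^(j))]``; pixels
    with g=0 contribute nothing, confidences are clipped to [eps, 1-eps].
    """
    p_all = np.atleast_2d(np.asarray(p_all, dtype=np.float64))
    gates = np.asarray(gates, dtype=np.float64)
    k = p_all.shape[1]
    if k < 2:
        raise ValueError("consistency loss needs K >= 2 categories")
    if not 1 <= category <= k:
        raise ValueError(f"category {category} outside 1..{k}")
    p = np.clip(p_all, eps, 1.0 - eps)
    i = category - 1
    own = np.log(p[:, i])
    others = np.log(1.0 - p).sum(axis=1) - np.log(1.0 - p[:, i])
    return float(-(gates * (own + others)).sum())


# ---------------------------------------------------------------------------
# analytic gradient through the projection
# ---------------------------------------------------------------------------


def total_consistency_loss_and_grad(
    weight: np.ndarray,
    gated_feats: list[np.ndarray],
    prompt_feats: list[np.ndarray],
    eps: float = CLIP_EPS,
) -> tuple[float, np.ndarray]:
    """Total consistency loss over all categories and its gradient with
    respect to the D x D projection applied to every feature vector.

    Parameters
    ----------
    weight:
        Current projection matrix W; pixel/prompt vectors are scored as
        ``cos(W f_a, W f_p)``.
    gated_feats:
        One (m_i, D) block of RAW (unprojected) features per category i,
        holding that category's gated pixels (all gates are 1 here by
        construction; an empty block contributes nothing).
    prompt_feats:
        One (n_j, D) block of RAW features per category j's prompt points.

    The gradient is the exact chain rule through the cosine similarities and
    the clipping (confidences outside [eps, 1-eps] saturate to zero
    gradient); finite differences verify it in the test suite.
    """
    w = np.asarray(weight, dtype=np.float64)
    k = len(prompt_feats)
    if k < 2:
        raise ValueError("consistency loss needs K >= 2 categories")
    if len(gated_feats) != k:
        raise ValueError("gated_feats and prompt_feats must align per category")

    proj_prompts = []
    for pf in prompt_feats:
        pf = np.atleast_2d(np.asarray(pf, dtype=np.float64))
        proj_prompts.append(pf @ w.T)

    loss = 0.0
    grad = np.zeros_like(w)
    for i, raw_a in enumerate(gated_feats):
        raw_a = np.atleast_2d(np.asarray(raw_a, dtype=np.float64))
        if raw_a.size == 0:
            continue
        u = raw_a @ w.T                      # (m, D) projected pixels
        un = np.linalg.norm(u, axis=1, keepdims=True)
        uh = u / un
        for j in range(k):
            raw_p = np.atleast_2d(np.asarray(prompt_feats[j], dtype=np.float64))
            v = proj_prompts[j]              # (n, D)
            vn = np.linalg.norm(v, axis=1, keepdims=True)
            vh = v / vn
            s = uh @ vh.T                    # (m, n)
            n = s.shape[1]
            p = s.mean(axis=1)               # (m,)
            inside = (p > eps) & (p < 1.0 - eps)
            pc = np.clip(p, eps, 1.0 - eps)
            if j == i:
                loss -= np.log(pc).sum()
                dl_dp = np.where(inside, -1.0 / pc, 0.0)
            else:
                loss -= np.log(1.0 - pc).sum()
                dl_dp = np.where(inside, 1.0 / (1.0 - pc), 0.0)
            ws = dl_dp[:, None] / n          # (m, 1) weight per similarity
            wmat = np.broadcast_to(ws, s.shape)
            # d s / d u and d s / d v through the normalized dot product
            row = (wmat * s).sum(axis=1, keepdims=True)
            gu = (wmat @ vh - row * uh) / un
            col = (wmat * s).sum(axis=0)[:, None]
            gv = (wmat.T @ uh - col * vh) / vn
            grad += gu.T @ raw_a + gv.T @ raw_p
    return float(loss), grad
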