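"""Objective components for unsupervised cross-subject adaptation.

Four families of losses are implemented, all operating on feature batches
taken at the network's first fully connected layer:

* **Softmax cross-entropy** (``Ls``) — the supervised classification loss on
  labeled source windows.
* **Multiple-kernel maximum mean discrepancy** (``Lm``) — a kernel two-sample
  distance between source and target feature distributions.  For a Gaussian
  kernel ``k(x, y) = exp(-||x - y||^2 / (2 sigma^2))`` the squared MMD has the
  plug-in (V-statistic) form

  ``MMD^2 = 1/m^2 sum k(x_i, x_j) + 1/n^2 sum k(y_i, y_j) - 2/(mn) sum k(x_i, y_j)``

  and ``Lm`` averages it over a bank of bandwidths.
* **Center loss** (``Lc``) — half the summed squared distance of each source
  feature to its class center, ``Lc = 1/2 sum_i ||x_i - C_{y_i}||^2``, with the
  analytic feature gradient ``x_i - C_{y_i}`` and the running center update
  ``C_j <- C_j - alpha * dC_j`` where
  ``dC_j = sum_{i: y_i=j} (C_j - x_i) / (1 + #{i: y_i=j})``.
* **Adversarial pieces** — binary domain-confusion cross-entropy with a
  gradient-reversal contract (DANN), and the Wasserstein critic objective
  ``mean(f(x_s)) - mean(f(x_t))`` (Kantorovich-Rubinstein dual; the Lipschitz
  constraint is enforced by the training loop's gradient penalty).

Everything here is pure NumPy; the functions used inside the training loop
also expose analytic gradients with respect to the features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FeatureBatch",
    "LabeledFeatureBatch",
    "KernelBank",
    "ClassCenters",
    "LossWeights",
    "LossBreakdown",
    "gaussian_kernel",
    "mk_mmd2",
    "mk_mmd2_grad",
    "center_loss",
    "center_loss_grad",
    "update_centers",
    "softmax_xent",
    "softmax_xent_grad",
    "total_loss",
    "domain_confusion_loss",
    "GradientReversal",
    "wasserstein_critic_loss",
]


@dataclass
class FeatureBatch:
    """A stack of feature vectors, shape [m, d]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature batch contains NaN or Inf")


@dataclass
class LabeledFeatureBatch(FeatureBatch):
    """Feature vectors with integer class labels in [0, A)."""

    labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.values.shape[0],):
            raise ValueError("labels length must match the number of feature rows")


@dataclass
class KernelBank:
    """Gaussian bandwidths defining the multiple-kernel MMD estimator."""

    sigmas: Sequence[float]

    def __post_init__(self) -> None:
        self.sigmas = [float(s) for s in self.sigmas]
        if not self.sigmas:
            raise ValueError("kernel bank must contain at least one bandwidth")
        if any(s <= 0 for s in self.sigmas):
            raise ValueError("all bandwidths must be positive")

    @classmethod
    def median_heuristic(
        cls,
        X: np.ndarray,
        Y: np.ndarray,
        factors: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
    ) -> "KernelBank":
        """Bandwidths at multiples of the median pairwise distance of the
        joint batch (the standard median heuristic)."""
        Z = np.vstack([np.atleast_2d(X), np.atleast_2d(Y)])
        d2 = _sqdist(Z, Z)
        med = float(np.sqrt(np.median(d2[np.triu_indices(len(Z), k=1)])))
        if med <= 0:
            med = 1.0  # all points coincide; any bandwidth gives MMD^2 = 0
        return cls([f * med for f in factors])


@dataclass
class ClassCenters:
    """Per-class feature centroids with their running-update rate alpha."""

    C: np.ndarray
    alpha: float = 0.5

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=np.float64)
        if self.C.ndim != 2 or self.C.shape[0] < 2:
            raise ValueError("centers must be [A, d] with A >= 2")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("centers contain NaN or Inf")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")

    @classmethod
    def zeros(cls, n_classes: int, dim: int, alpha: float = 0.5) -> "ClassCenters":
        return cls(np.zeros((n_classes, dim)), alpha=alpha)


@dataclass
class LossWeights:
    """Weights of the combined objective L = Ls + lambda * Lc + beta * Lm."""

    lambda_center: float = 0.0
    beta_mmd: float = 0.0

    def __post_init__(self) -> None:
        if self.lambda_center < 0 or self.beta_mmd < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class LossBreakdown:
    """One iteration's objective components and their weighted total."""

    Ls: float
    Lc: float
    Lm: float
    total: float
    aux: float = 0.0  # domain-confusion / critic loss for DANN / WD


def _sqdist(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise squared Euclidean distances, clipped at 0 for roundoff."""
    d2 = (
        np.sum(X * X, axis=1)[:, None]
        + np.sum(Y * Y, axis=1)[None, :]
        - 2.0 * X @ Y.T
    )
    return np.maximum(d2, 0.0)


def gaussian_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """Gaussian kernel ``exp(-||x - y||^2 / (2 sigma^2))``; value in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal dimension")
    d2 = float(np.sum((x - y) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureBatch) else np.atleast_2d(np.asarray(X, dtype=np.float64))


def mk_mmd2(X, Y, bank: KernelBank, unbiased: bool = False) -> float:
    """Multiple-kernel squared MMD between feature batches X [m,d] and Y [n,d].

    The default is the biased plug-in (V-statistic) estimator, which is
    always >= 0 and exactly 0 when X and Y are identical multisets; the
    U-statistic variant (``unbiased=True``, requires m, n >= 2) removes the
    diagonal terms.  Returns the mean over the bank's bandwidths.
    """
    Xv, Yv = _as_values(X), _as_values(Y)
    m, n = Xv.shape[0], Yv.shape[0]
    if m < 1 or n < 1:
        raise ValueError("mk_mmd2 requires at least one sample per batch")
    if Xv.shape[1] != Yv.shape[1]:
        raise ValueError(f"feature dimension mismatch: {Xv.shape[1]} vs {Yv.shape[1]}")
    if unbiased and (m < 2 or n < 2):
        raise ValueError("unbiased estimator requires m, n >= 2")
    dxx, dyy, dxy = _sqdist(Xv, Xv), _sqdist(Yv, Yv), _sqdist(Xv, Yv)
    total = 0.0
    for sigma in bank.sigmas:
        g = 1.0 / (2.0 * sigma**2)
        kxx, kyy, kxy = np.exp(-g * dxx), np.exp(-g * dyy), np.exp(-g * dxy)
        if unbiased:
            np.fill_diagonal(kxx, 0.0)
            np.fill_diagonal(kyy, 0.0)
            total += (
                kxx.sum() / (m * (m - 1))
                + kyy.sum() / (n * (n - 1))
                - 2.0 * kxy.mean()
            )
        else:
            total += kxx.mean() + kyy.mean() - 2.0 * kxy.mean()
    return float(total / len(bank.sigmas))


def mk_mmd2_grad(X, Y, bank: KernelBank) -> tuple[np.ndarray, np.ndarray]:
    """Analytic gradient of the biased :func:`mk_mmd2` w.r.t. X and Y rows.

    For one bandwidth, d MMD^2 / d x_i =
    ``-(2/(m^2 sigma^2)) sum_j kxx[i,j](x_i - x_j) + (2/(mn sigma^2)) sum_j kxy[i,j](x_i - y_j)``.
    """
    Xv, Yv = _as_values(X), _as_values(Y)
    m, n = Xv.shape[0], Yv.shape[0]
    gX = np.zeros_like(Xv)
    gY = np.zeros_like(Yv)
    dxx, dyy, dxy = _sqdist(Xv, Xv), _sqdist(Yv, Yv), _sqdist(Xv, Yv)
    for sigma in bank.sigmas:
        g = 1.0 / (2.0 * sigma**2)
        kxx, kyy, kxy = np.exp(-g * dxx), np.exp(-g * dyy), np.exp(-g * dxy)
        inv = 1.0 / sigma**2
        # d/dx_i of kxx terms (both (i,j) and (j,i) contribute):
        gX += (-2.0 * inv / m**2) * (kxx.sum(1)[:, None] * Xv - kxx @ Xv)
        gX += (2.0 * inv / (m * n)) * (kxy.sum(1)[:, None] * Xv - kxy @ Yv)
        gY += (-2.0 * inv / n**2) * (kyy.sum(1)[:, None] * Yv - kyy @ Yv)
        gY += (2.0 * inv / (m * n)) * (kxy.sum(0)[:, None] * Yv - kxy.T @ Xv)
    k = len(bank.sigmas)
    return gX / k, gY / k


def _check_labels(labels: np.ndarray, n_classes: int) -> None:
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")


def center_loss(batch: LabeledFeatureBatch, centers: ClassCenters) -> float:
    """Center loss ``1/2 sum_i ||x_i - C_{y_i}||^2``; 0 iff every feature sits
    on its class center."""
    _check_labels(batch.labels, centers.C.shape[0])
    diff = batch.values - centers.C[batch.labels]
    return float(0.5 * np.sum(diff * diff))


def center_loss_grad(batch: LabeledFeatureBatch, centers: ClassCenters) -> np.ndarray:
    """Gradient of the center loss w.r.t. the features: row i is x_i - C_{y_i}."""
    _check_labels(batch.labels, centers.C.shape[0])
    return batch.values - centers.C[batch.labels]


def update_centers(batch: LabeledFeatureBatch, centers: ClassCenters) -> ClassCenters:
    """One running update of the class centers from a feature batch.

    For each class j: ``dC_j = sum_{i: y_i = j} (C_j - x_i) / (1 + n_j)`` and
    ``C_j <- C_j - alpha * dC_j``.  Classes absent from the batch are unchanged
    (their indicator sum is empty, so dC_j = 0).
    """
    A, d = centers.C.shape
    _check_labels(batch.labels, A)
    counts = np.bincount(batch.labels, minlength=A).astype(np.float64)
    sums = np.zeros((A, d))
    np.add.at(sums, batch.labels, batch.values)
    delta = (counts[:, None] * centers.C - sums) / (1.0 + counts[:, None])
    return ClassCenters(centers.C - centers.alpha * delta, alpha=centers.alpha)


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    return z - np.log(np.sum(np.exp(z), axis=1, keepdims=True))


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class under the softmax."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    labels = np.asarray(labels, dtype=np.int64)
    _check_labels(labels, logits.shape[1])
    lp = _log_softmax(logits)
    return float(-lp[np.arange(len(labels)), labels].mean())


def softmax_xent_grad(logits: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Gradient of :func:`softmax_xent` w.r.t. the logits: (p - onehot) / m."""
    logits = np.atleast_2d(np.asarray(logits, dtype=np.float64))
    labels = np.asarray(labels, dtype=np.int64)
    _check_labels(labels, logits.shape[1])
    p = np.exp(_log_softmax(logits))
    p[np.arange(len(labels)), labels] -= 1.0
    return p / len(labels)


def total_loss(Ls: float, Lc: float, Lm: float, weights: LossWeights) -> LossBreakdown:
    """Combine the components into L = Ls + lambda * Lc + beta * Lm."""
    total = Ls + weights.lambda_center * Lc + weights.beta_mmd * Lm
    return LossBreakdown(Ls=float(Ls), Lc=float(Lc), Lm=float(Lm), total=float(total))


def domain_confusion_loss(domain_logits: np.ndarray, domain_labels: np.ndarray) -> float:
    """Binary cross-entropy of the domain classifier over a mixed batch.

    Source windows carry domain label 0, target windows label 1.  A classifier
    emitting probability 1/2 everywhere scores ln 2 (maximal confusion).
    """
    domain_labels = np.asarray(domain_labels, dtype=np.int64)
    if domain_labels.size and not np.isin(domain_labels, [0, 1]).all():
        raise ValueError("domain labels must be 0 (source) or 1 (target)")
    logits = np.atleast_2d(np.asarray(domain_logits, dtype=np.float64))
    if logits.shape[1] != 2:
        raise ValueError("domain logits must have exactly 2 columns")
    return softmax_xent(logits, domain_labels)


class GradientReversal:
    """Gradient-reversal contract used between the feature extractor and the
    domain classifier (the DANN trick).

    The forward pass is the identity; the backward pass multiplies the
    upstream sensitivity by ``-lambda_d``, so the extractor ascends the
    domain-confusion loss that the domain classifier descends.
    """

    def __init__(self, lambda_d: float = 1.0) -> None:
        if lambda_d < 0:
            raise ValueError("lambda_d must be >= 0")
        self.lambda_d = float(lambda_d)

    def forward(self, features: np.ndarray) -> np.ndarray:
        return features

    def backward(self, upstream: np.ndarray) -> np.ndarray:
        return -self.lambda_d * np.asarray(upstream)


def wasserstein_critic_loss(
    critic_scores_source: np.ndarray, critic_scores_target: np.ndarray
) -> float:
    """Empirical Kantorovich-Rubinstein objective
    ``mean(f(x_s)) - mean(f(x_t))`` of a critic f.

    The critic maximizes this under a 1-Lipschitz constraint (gradient penalty
    added by the training loop); the feature extractor minimizes it.
    """
    s = np.asarray(critic_scores_source, dtype=np.float64).ravel()
    t = np.asarray(critic_scores_target, dtype=np.float64).ravel()
    if s.size == 0 or t.size == 0:
        raise ValueError("critic score batches must be non-empty")
    return float(s.mean() - t.mean())
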