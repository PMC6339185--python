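"""Feature-distribution diagnostics: class centers, inter-class distances,
maximum inner-class distances, and the 2-D projection protocol.

The quantities here describe how a trained extractor lays classes out in
feature space.  For class *a* with empirical center ``c_a`` (the mean of its
features):

* ``inter_class[a, b] = ||c_a - c_b||`` — inter-class distance;
* ``max_inner[a] = max_i ||x_i - c_a||`` over class-a features — the maximum
  inner-class distance;
* a class is *overlap-flagged* when its maximum inner-class distance exceeds
  its smallest inter-class distance: edge points then reach past a
  neighbouring center and risk confusion.

Centers here are empirical per-class means of the supplied features; they are
deliberately distinct from the running :class:`~haradapt.losses.ClassCenters`
maintained by the CMMD optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .adapt import TrainConfig, TrainResult, train
from .losses import ClassCenters, LabeledFeatureBatch, center_loss
from .model import NetConfig, extract_features
from .sensordata import DomainSplit

__all__ = [
    "DistributionReport",
    "distribution_report",
    "overlap_flags",
    "Projection2D",
    "project_2d",
    "report_to_frame",
    "projection_to_frame",
]


@dataclass
class DistributionReport:
    """Per-class geometry of a labeled feature batch."""

    centers: np.ndarray      # [A, d] empirical class means
    inter_class: np.ndarray  # [A, A] symmetric center-to-center distances
    max_inner: np.ndarray    # [A] max feature-to-own-center distance
    center_loss_value: float
    n_per_class: np.ndarray  # [A]


def distribution_report(batch: LabeledFeatureBatch, n_classes: int | None = None) -> DistributionReport:
    """Compute the distribution report; every class must be present."""
    labels = batch.labels
    if n_classes is None:
        n_classes = int(labels.max()) + 1 if labels.size else 0
    counts = np.bincount(labels, minlength=n_classes)
    absent = np.flatnonzero(counts == 0)
    if n_classes < 1 or absent.size:
        raise ValueError(f"classes absent from the batch: {absent.tolist()}")
    centers = np.stack([batch.values[labels == a].mean(axis=0) for a in range(n_classes)])
    diff = centers[:, None, :] - centers[None, :, :]
    inter = np.sqrt(np.sum(diff * diff, axis=-1))
    max_inner = np.array([
        np.max(np.linalg.norm(batch.values[labels == a] - centers[a], axis=1))
        for a in range(n_classes)
    ])
    lc = center_loss(batch, ClassCenters(centers, alpha=1.0)) if n_classes >= 2 else 0.0
    return DistributionReport(
        centers=centers,
        inter_class=inter,
        max_inner=max_inner,
        center_loss_value=float(lc),
        n_per_class=counts,
    )


def overlap_flags(report: DistributionReport) -> np.ndarray:
    """Flag class a when ``max_inner[a]`` exceeds ``min_{b != a} inter_class[a, b]``."""
    A = len(report.max_inner)
    masked = report.inter_class + np.diag(np.full(A, np.inf))
    return report.max_inner > masked.min(axis=1)


@dataclass
class Projection2D:
    """Labeled 2-D feature clouds for source and target after training with a
    2-unit first FC layer (scatter-export format)."""

    source_points: np.ndarray
    source_labels: np.ndarray
    target_points: np.ndarray
    target_labels: np.ndarray
    result: TrainResult


def project_2d(split: DomainSplit, net: NetConfig, cfg: TrainConfig) -> Projection2D:
    """Train with the first FC layer forced to two units and return the 2-D
    source/target feature clouds (the feature-visualization protocol).

    Target points cover both the adaptation and the evaluation portions;
    their labels are attached after training, for coloring only.
    """
    net2 = dc_replace(net, fc_units=2)
    result = train(split, net2, cfg)
    src = split.source_train
    tgt_data = np.concatenate([split.target_train.data, split.target_test.data])
    tgt_labels = np.concatenate([split.target_train.labels, split.target_test.labels])
    return Projection2D(
        source_points=extract_features(result.state, src),
        source_labels=src.labels.copy(),
        target_points=extract_features(result.state, tgt_data),
        target_labels=tgt_labels,
        result=result,
    )


def report_to_frame(reports: dict[str, DistributionReport]) -> pd.DataFrame:
    """Arrange reports as a delimited table: Distance_a_b / Max_a rows, one
    column per subject or run (1-based class numbering)."""
    if not reports:
        raise ValueError("no reports given")
    A = len(next(iter(reports.values())).max_inner)
    index = [f"Distance_{a + 1}_{b + 1}" for a in range(A) for b in range(a + 1, A)]
    index += [f"Max_{a + 1}" for a in range(A)]
    data = {}
    for name, rep in reports.items():
        col = [rep.inter_class[a, b] for a in range(A) for b in range(a + 1, A)]
        col += list(rep.max_inner)
        data[name] = col
    return pd.DataFrame(data, index=index)


def projection_to_frame(proj: Projection2D) -> pd.DataFrame:
    """Flatten a 2-D projection into (x, y, label, domain) rows."""
    frames = []
    for pts, labels, domain in (
        (proj.source_points, proj.source_labels, "source"),
        (proj.target_points, proj.target_labels, "target"),
    ):
        frames.append(pd.DataFrame({
            "x": pts[:, 0], "y": pts[:, 1], "label": labels, "domain": domain,
        }))
    return pd.concat(frames, ignore_index=True)
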