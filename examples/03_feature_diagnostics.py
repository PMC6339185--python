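"""Feature-space geometry: distances, overlap flags and the 2-D projection.

Trains a network whose first fully connected layer has just two units, so
the tapped features are directly plottable, then reports per-class
inter-class distances, maximum inner-class distances and which classes risk
confusion (max inner-class distance exceeding the nearest center distance).
"""

from haradapt import TrainConfig
from haradapt.diagnostics import (
    distribution_report, overlap_flags, project_2d, report_to_frame,
)
from haradapt.losses import LabeledFeatureBatch
from haradapt.experiments import synthetic_shift_task

split, net = synthetic_shift_task(seed=2)
proj = project_2d(split, net, TrainConfig(method="only_source",
                                          iterations=300, batch_size=64, seed=2))
print(f"2-D source cloud: {proj.source_points.shape}, "
      f"target cloud: {proj.target_points.shape}")

report = distribution_report(
    LabeledFeatureBatch(proj.source_points, labels=proj.source_labels),
    n_classes=split.source_train.n_classes)
print(report_to_frame({"source": report}).round(3))
flags = overlap_flags(report)
print("overlap-flagged classes:", [i for i, f in enumerate(flags) if f])

# A flagged class has points farther from its own center than the nearest
# other center — exactly the geometry that produces confusions at the
# decision boundary and limits how well the classifier transfers.
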