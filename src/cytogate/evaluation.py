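"""Comparing two gatings of the same events.

Two comparison styles, both agnostic to cluster numbering: congruent-
cluster matching pairs foreground components of two fitted models whose
means agree on both channels within a tolerance, and event-level F1 scores
a predicted per-event assignment against a reference assignment after an
optimal one-to-one cluster matching on the confusion table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .classify import FOREGROUND_ROLE, classify_components
from .core import MixtureModel

__all__ = ["GatingComparison", "congruent_clusters", "event_f1"]


@dataclass
class GatingComparison:
    n_congruent: int = 0
    mapping: list[tuple[int, int]] = field(default_factory=list)
    f1: float = 0.0
    per_cluster_f1: dict[int, float] = field(default_factory=dict)


def congruent_clusters(
    model_a: MixtureModel,
    model_b: MixtureModel,
    tol: float = 2500.0,
    sd_threshold: float = 2500.0,
) -> GatingComparison:
    """Greedy one-to-one matching of foreground components by mean position.

    A pair is eligible when the two means differ by at most ``tol`` channel
    units on BOTH axes; eligible pairs are consumed closest first by
    Euclidean distance between means. Returns the matched (a, b) index
    pairs and their count.
    """
    fg_a = [j for j, r in enumerate(classify_components(model_a, sd_threshold)) if r == FOREGROUND_ROLE]
    fg_b = [j for j, r in enumerate(classify_components(model_b, sd_threshold)) if r == FOREGROUND_ROLE]
    candidates = []
    for ja in fg_a:
        for jb in fg_b:
            diff = np.abs(model_a.means[ja] - model_b.means[jb])
            if np.all(diff <= tol):
                candidates.append(
                    (float(np.hypot(diff[0], diff[1])), ja, jb)
                )
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    mapping = []
    for _, ja, jb in candidates:
        if ja in used_a or jb in used_b:
            continue
        used_a.add(ja)
        used_b.add(jb)
        mapping.append((ja, jb))
    return GatingComparison(n_congruent=len(mapping), mapping=sorted(mapping))


def event_f1(pred: np.ndarray, ref: np.ndarray) -> GatingComparison:
    """Event-level F1 after optimal one-to-one cluster matching.

    Labels are cluster indices (>= 0) or negatives for background/outlier,
    which count as non-cluster events on either side. The confusion table
    between predicted and reference clusters is matched by maximizing total
    overlap (assignment problem); each matched pair scores
    F1 = 2TP / (2TP + FP + FN) over events, and the overall F1 is the
    event-weighted mean over matched reference clusters (reference cluster
    sizes as weights; unmatched reference clusters contribute zero).
    """
    pred = np.asarray(pred, dtype=int)
    ref = np.asarray(ref, dtype=int)
    if pred.shape != ref.shape:
        raise ValueError(
            f"label vectors differ in length: {pred.shape} vs {ref.shape}"
        )
    pred_ids = np.unique(pred[pred >= 0])
    ref_ids = np.unique(ref[ref >= 0])
    if len(ref_ids) == 0:
        return GatingComparison(f1=1.0 if len(pred_ids) == 0 else 0.0)
    if len(pred_ids) == 0:
        return GatingComparison(f1=0.0)

    confusion = np.zeros((len(pred_ids), len(ref_ids)), dtype=int)
    for i, p in enumerate(pred_ids):
        sel = pred == p
        for j, r in enumerate(ref_ids):
            confusion[i, j] = int(np.sum(sel & (ref == r)))
    rows, cols = linear_sum_assignment(confusion, maximize=True)

    per_cluster: dict[int, float] = {}
    mapping = []
    ref_sizes = {int(r): int(np.sum(ref == r)) for r in ref_ids}
    weighted = 0.0
    weight_total = sum(ref_sizes.values())
    for i, j in zip(rows, cols):
        p, r = int(pred_ids[i]), int(ref_ids[j])
        tp = confusion[i, j]
        fp = int(np.sum(pred == p)) - tp
        fn = ref_sizes[r] - tp
        f1 = 2 * tp / (2 * tp + fp + fn) if tp else 0.0
        per_cluster[r] = f1
        mapping.append((p, r))
        weighted += f1 * ref_sizes[r]
    overall = weighted / weight_total if weight_total else 0.0
    return GatingComparison(
        n_congruent=len(mapping),
        mapping=sorted(mapping),
        f1=float(overall),
        per_cluster_f1=per_cluster,
    )
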