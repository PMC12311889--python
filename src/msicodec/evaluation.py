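"""Matching predicted clusters to a baseline segmentation and scoring them.

Segmentation produces arbitrary cluster ids, so before accuracy can be
computed each predicted cluster is *matched* to the baseline class that
appears most frequently among its pixels (majority vote).  Matching is
per-cluster independent: two clusters may map to the same class, which is how
an over-segmented prediction (k chosen with a margin) merges back down to the
anatomical classes.  Accuracy is the percentage of baseline-labeled pixels
whose matched class equals the baseline class; unlabeled baseline pixels are
excluded from both the vote and the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import UNLABELED, LabelMap

__all__ = ["MatchingTable", "match_clusters", "apply_matching", "accuracy",
           "evaluation_report"]

#: Mapping value for predicted clusters with no baseline-labeled pixels.
UNASSIGNED = "unassigned"


@dataclass
class MatchingTable:
    """Majority-vote mapping from predicted cluster id to baseline class id.

    ``mapping[c]`` is the baseline class for cluster ``c`` or the string
    ``"unassigned"`` when the cluster has no pixels on labeled baseline.
    ``tallies[c]`` holds the per-class vote counts behind the decision.
    """

    mapping: dict[int, int | str] = field(default_factory=dict)
    tallies: dict[int, dict[int, int]] = field(default_factory=dict)


def _check_same_grid(a: LabelMap, b: LabelMap) -> None:
    if a.labels.shape != b.labels.shape:
        raise ValueError(
            f"label maps have different grids: {a.labels.shape} vs {b.labels.shape}"
        )


def match_clusters(pred: LabelMap, baseline: LabelMap) -> MatchingTable:
    """Assign every predicted cluster to its majority baseline class.

    Ties break toward the smallest baseline class id; clusters lying entirely
    on unlabeled baseline pixels are marked ``"unassigned"``.
    """
    _check_same_grid(pred, baseline)
    table = MatchingTable()
    pred_flat = pred.labels.ravel()
    base_flat = baseline.labels.ravel()
    for cluster in np.unique(pred_flat[pred_flat != UNLABELED]):
        on_cluster = base_flat[pred_flat == cluster]
        on_cluster = on_cluster[on_cluster != UNLABELED]
        if on_cluster.size == 0:
            table.mapping[int(cluster)] = UNASSIGNED
            table.tallies[int(cluster)] = {}
            continue
        classes, counts = np.unique(on_cluster, return_counts=True)
        # np.unique returns ascending classes; argmax takes the first maximum,
        # which is the tie-to-smallest-id rule
        table.mapping[int(cluster)] = int(classes[np.argmax(counts)])
        table.tallies[int(cluster)] = {int(c): int(n) for c, n in zip(classes, counts)}
    return table


def apply_matching(pred: LabelMap, table: MatchingTable) -> LabelMap:
    """Replace predicted cluster ids by their matched baseline class ids."""
    out = np.full_like(pred.labels, UNLABELED)
    clusters = np.unique(pred.labels[pred.labels != UNLABELED])
    missing = [int(c) for c in clusters if int(c) not in table.mapping]
    if missing:
        raise ValueError(f"matching table lacks predicted clusters {missing}")
    for cluster in clusters:
        target = table.mapping[int(cluster)]
        out[pred.labels == cluster] = UNLABELED if target == UNASSIGNED else target
    return LabelMap(labels=out, provenance="prediction")


def accuracy(matched: LabelMap, baseline: LabelMap) -> float:
    """Percentage of baseline-labeled pixels carrying the correct class.

    Matched pixels left unlabeled (-1) on labeled baseline count as wrong.
    """
    _check_same_grid(matched, baseline)
    labeled = baseline.labels != UNLABELED
    total = int(labeled.sum())
    if total == 0:
        raise ValueError("baseline contains no labeled pixels")
    correct = int((matched.labels[labeled] == baseline.labels[labeled]).sum())
    return 100.0 * correct / total


def evaluation_report(
    pred: LabelMap, baseline: LabelMap
) -> tuple[float, MatchingTable, pd.DataFrame]:
    """Full evaluation: matching, overall accuracy and a per-cluster table."""
    table = match_clusters(pred, baseline)
    matched = apply_matching(pred, table)
    overall = accuracy(matched, baseline)
    rows = []
    for cluster in sorted(table.mapping):
        tally = table.tallies[cluster]
        mapped = table.mapping[cluster]
        votes = sum(tally.values())
        rows.append(
            {
                "cluster": cluster,
                "mapped_class": mapped,
                "labeled_pixels": votes,
                "majority_votes": tally.get(mapped, 0) if votes else 0,
                "cluster_purity": (tally.get(mapped, 0) / votes) if votes else np.nan,
            }
        )
    frame = pd.DataFrame(rows)
    return overall, table, frame
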