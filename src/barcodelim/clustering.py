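"""Objective clustering at preset p-distance thresholds.

Clusters are the connected components of the graph that links two sequences
whenever their p-distance is <= the threshold (single linkage by transitive
closure), which places any sequence within the threshold of any cluster
member into that cluster.  Thresholds are fractions; the comparison is
closed (``<=``).  Identical haplotypes can be collapsed beforehand, which
the GMYC stage requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .model import Alignment, HaplotypeCollapse, Partition
from .distances import DistanceMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdClustering:
    """Result of clustering a distance matrix at one threshold."""

    threshold: float
    partition: Partition
    n_clusters: int
    n_singletons: int


def cluster_at_threshold(
    dm: DistanceMatrix, threshold: float
) -> ThresholdClustering:
    """Single-linkage components of the graph with edges where d <= threshold.

    Cluster labels are deterministic: each cluster is named after its
    lexicographically smallest specimen id.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if dm.n_undefined_pairs:
        raise ValueError(
            "distance matrix has undefined pairs; clustering requires all "
            "pairs to be defined"
        )
    adj = dm.d <= threshold
    np.fill_diagonal(adj, True)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    ids = np.array(dm.ids)
    assignment: dict[str, str] = {}
    sizes = np.bincount(comp, minlength=n_comp)
    for c in range(n_comp):
        members = ids[comp == c]
        label = min(members)
        for sid in members:
            assignment[sid] = label
    partition = Partition(assignment, source=f"clustering({threshold:g})")
    return ThresholdClustering(
        threshold=threshold,
        partition=partition,
        n_clusters=int(n_comp),
        n_singletons=int((sizes == 1).sum()),
    )


def threshold_sweep(
    dm: DistanceMatrix, thresholds: list[float]
) -> list[ThresholdClustering]:
    """Cluster at each threshold (ascending); counts are non-increasing."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return [cluster_at_threshold(dm, t) for t in thresholds]


def collapse_haplotypes(
    alignment: Alignment,
) -> tuple[Alignment, HaplotypeCollapse]:
    """Remove exact full-string duplicate sequences, keeping first occurrence.

    Equality includes missing characters; near-duplicates are not collapsed.
    The returned mapping allows entity membership to be re-expanded after
    delimitation.
    """
    seen: dict[str, str] = {}
    kept: list[tuple[str, str]] = []
    removed: dict[str, list[str]] = {}
    for sid, seq in zip(alignment.ids, alignment.seqs):
        if seq in seen:
            removed.setdefault(seen[seq], []).append(sid)
        else:
            seen[seq] = sid
            kept.append((sid, seq))
    collapse = HaplotypeCollapse(
        kept_ids=tuple(s for s, _ in kept),
        removed={k: tuple(v) for k, v in removed.items()},
    )
    if collapse.n_removed:
        logger.info(
            "collapsed %d identical haplotypes (%d kept)",
            collapse.n_removed,
            len(collapse.kept_ids),
        )
    return Alignment.from_pairs(kept), collapse
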