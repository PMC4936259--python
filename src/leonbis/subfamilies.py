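"""Subfamily clustering and orphan detection.

Sequences are clustered on fractional-identity distance with average-linkage
hierarchical clustering; the tree is cut automatically at the largest gap in
the sorted merge heights, so the number of subfamilies is data-driven rather
than user-set. Sequences too far from everything (min distance >= the orphan
threshold) are set aside as orphans before clustering and handled separately
downstream by direct comparison with the query subfamily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .msa_io import GAP, Alignment

logger = logging.getLogger(__name__)

# pairs sharing fewer mutually ungapped columns than this are treated as
# maximally distant: identity over a handful of columns is noise
MIN_OVERLAP_COLUMNS = 10

DEFAULT_ORPHAN_THRESHOLD = 0.85

# smallest jump in sorted merge heights that justifies cutting the tree:
# below this, height variation is identity noise within one family
DEFAULT_MIN_SPLIT_GAP = 0.1


def pairwise_distances(aln: Alignment) -> np.ndarray:
    """Pairwise identity distances d = 1 - (identical / mutually ungapped).

    Pairs with fewer than 10 mutually ungapped columns get d = 1.
    """
    seqs = np.array([list(seq) for _, seq in aln.records])
    ungapped = seqs != GAP
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            n_both = int(both.sum())
            if n_both < MIN_OVERLAP_COLUMNS:
                d = 1.0
            else:
                ident = int((seqs[i][both] == seqs[j][both]).sum())
                d = 1.0 - ident / n_both
            dm[i, j] = dm[j, i] = d
    return dm


@dataclass
class SubfamilyPartition:
    """Disjoint subfamilies plus orphans covering all sequence indices."""

    subfamilies: list[list[int]]
    orphans: list[int]
    query_subfamily: int

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for sub in self.subfamilies:
            if not sub:
                raise ValueError("empty subfamily")
            if seen & set(sub):
                raise ValueError("overlapping subfamilies")
            seen |= set(sub)
        if seen & set(self.orphans):
            raise ValueError("orphans overlap subfamilies")

    def subfamily_of(self, seq_index: int) -> int | None:
        for k, sub in enumerate(self.subfamilies):
            if seq_index in sub:
                return k
        return None

    @property
    def n_subfamilies(self) -> int:
        return len(self.subfamilies)


def _auto_cut(Z: np.ndarray, min_split_gap: float = DEFAULT_MIN_SPLIT_GAP) -> np.ndarray:
    """Cut an average-linkage tree at the largest gap in sorted merge heights.

    Returns 1-based flat cluster labels. The cut is only made when the
    largest gap exceeds ``min_split_gap``; smaller height variation is
    treated as identity noise within a single family and the tree is left
    uncut (one cluster).
    """
    heights = np.sort(Z[:, 2])
    gaps = np.diff(heights)
    if len(gaps) == 0 or gaps.max() <= min_split_gap:
        return np.ones(Z.shape[0] + 1, dtype=int)
    i = int(np.argmax(gaps))  # ties -> lowest height, for determinism
    threshold = (heights[i] + heights[i + 1]) / 2.0
    return fcluster(Z, threshold, criterion="distance")


def cluster_subfamilies(
    dm: np.ndarray,
    query_index: int,
    orphan_threshold: float = DEFAULT_ORPHAN_THRESHOLD,
    min_split_gap: float = DEFAULT_MIN_SPLIT_GAP,
) -> SubfamilyPartition:
    """Partition sequences into subfamilies and orphans.

    Orphans are pulled out first (min distance to every other sequence >=
    ``orphan_threshold``); the remainder is clustered by average linkage with
    the automatic largest-gap cut. Singleton clusters produced by the cut are
    absorbed into their average-linkage-nearest cluster so that subfamily
    statistics always rest on >= 2 sequences where possible. A query that
    qualifies as an orphan instead becomes a singleton query subfamily.
    """
    n = dm.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences to cluster")

    off_diag = dm + np.diag(np.full(n, np.inf))
    is_orphan = off_diag.min(axis=1) >= orphan_threshold
    orphans = [i for i in range(n) if is_orphan[i] and i != query_index]
    members = [i for i in range(n) if i not in set(orphans)]

    if len(members) == 1:
        subfamilies = [[members[0]]]
    else:
        sub_dm = dm[np.ix_(members, members)]
        Z = linkage(squareform(sub_dm, checks=False), method="average")
        labels = _auto_cut(Z, min_split_gap)
        clusters: dict[int, list[int]] = {}
        for local, lab in enumerate(labels):
            clusters.setdefault(int(lab), []).append(members[local])
        subfamilies = sorted(clusters.values(), key=lambda s: min(s))
        subfamilies = _absorb_singletons(subfamilies, dm, query_index)

    query_subfamily = next(
        k for k, sub in enumerate(subfamilies) if query_index in sub
    )
    part = SubfamilyPartition(subfamilies, orphans, query_subfamily)
    logger.info(
        "clustered %d sequences into %d subfamilies (%d orphans)",
        n, part.n_subfamilies, len(orphans),
    )
    return part


def _absorb_singletons(
    subfamilies: list[list[int]], dm: np.ndarray, query_index: int
) -> list[list[int]]:
    """Merge singleton clusters into their nearest cluster by mean distance.

    The query is exempt: a lone query stays a singleton query subfamily.
    """
    while True:
        singleton = next(
            (k for k, s in enumerate(subfamilies)
             if len(s) == 1 and s[0] != query_index),
            None,
        )
        if singleton is None or len(subfamilies) == 1:
            return subfamilies
        i = subfamilies[singleton][0]
        best, best_d = None, np.inf
        for k, sub in enumerate(subfamilies):
            if k == singleton:
                continue
            d = dm[i, sub].mean()
            if d < best_d - 1e-12:  # ties keep the lowest-index cluster
                best, best_d = k, d
        subfamilies[best] = sorted(subfamilies[best] + [i])
        del subfamilies[singleton]
        subfamilies = sorted(subfamilies, key=lambda s: min(s))
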