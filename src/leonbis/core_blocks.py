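"""Per-subfamily score tracks, core-block detection and block relatedness.

A *core block* is a maximal run of alignment columns each of which lies in at
least one sliding window whose mean normalized column score exceeds the
threshold (default 0.05). Blocks from different subfamilies are compared
column-by-column as they sit in the master alignment: two overlapping blocks
are related when the summed column-pair relatedness score over the overlap is
strictly positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .msa_io import Alignment
from .priors import DirichletMixture
from .scoring import ColumnObservation, bild_score, column_pair_score
from .subfamilies import SubfamilyPartition

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 7
DEFAULT_BLOCK_THRESHOLD = 0.05

# a single observation is dominated by the prior; columns with fewer residues
# than this are forced to prob 0 so singleton subfamilies cannot self-certify
MIN_COLUMN_OBSERVATIONS = 2


def subfamily_columns(aln: Alignment, members: list[int]) -> list[ColumnObservation]:
    """Per-column residue counts over the given member sequences."""
    seqs = [aln.records[i][1] for i in members]
    return [
        ColumnObservation.from_residues("".join(s[c] for s in seqs))
        for c in range(aln.n_cols)
    ]


@dataclass
class ScoreTrack:
    """Per-column BILD scores for one subfamily."""

    subfamily_index: int
    probs: np.ndarray   # normalized scores in [0, 1]
    raw_S: np.ndarray   # log-odds in nats


def score_track(
    aln: Alignment,
    members: list[int],
    prior: DirichletMixture,
    subfamily_index: int = 0,
    columns: list[ColumnObservation] | None = None,
) -> ScoreTrack:
    """Score every alignment column over the member sequences.

    Columns with fewer than two residue observations in the subfamily get
    ``prob = 0`` (and raw score 0): they carry no evidence of conservation.
    """
    if not members:
        raise ValueError("members must be non-empty")
    if columns is None:
        columns = subfamily_columns(aln, members)
    probs = np.zeros(aln.n_cols)
    raw = np.zeros(aln.n_cols)
    for c, col in enumerate(columns):
        if col.n_obs < MIN_COLUMN_OBSERVATIONS:
            continue
        sc = bild_score(col, prior)
        probs[c] = sc.prob
        raw[c] = sc.S
    return ScoreTrack(subfamily_index, probs, raw)


@dataclass
class CoreBlock:
    """Contiguous column interval [start, end) of one subfamily's track."""

    subfamily_index: int
    start: int
    end: int
    mean_prob: float
    block_score: float
    related_to_query: bool | str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlap(self, other: "CoreBlock") -> tuple[int, int] | None:
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return (lo, hi) if lo < hi else None


def detect_core_blocks(
    track: ScoreTrack,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_BLOCK_THRESHOLD,
) -> list[CoreBlock]:
    """Sliding-window detection of core blocks on a score track.

    A column is covered iff it lies in at least one length-``window`` window
    whose mean prob is strictly above ``threshold``; maximal covered runs
    become blocks, so every block spans at least ``window`` columns.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    n = len(track.probs)
    if window > n:
        logger.warning("window %d exceeds alignment width %d: no blocks", window, n)
        return []

    means = np.lib.stride_tricks.sliding_window_view(track.probs, window).mean(axis=1)
    covered = np.zeros(n, dtype=bool)
    for w in np.nonzero(means > threshold)[0]:
        covered[w : w + window] = True

    blocks: list[CoreBlock] = []
    c = 0
    while c < n:
        if covered[c]:
            start = c
            while c < n and covered[c]:
                c += 1
            blocks.append(
                CoreBlock(
                    subfamily_index=track.subfamily_index,
                    start=start,
                    end=c,
                    mean_prob=float(track.probs[start:c].mean()),
                    block_score=float(track.raw_S[start:c].sum()),
                )
            )
        else:
            c += 1
    return blocks


def block_relatedness(
    block_a: CoreBlock,
    block_b: CoreBlock,
    columns_a: list[ColumnObservation],
    columns_b: list[ColumnObservation],
    prior: DirichletMixture,
) -> tuple[bool, float]:
    """Sum of column-pair relatedness scores over the blocks' overlap.

    Related iff the sum is strictly positive. Columns where one subfamily is
    fully gapped contribute 0 (empty column => R = 0). Raises if the blocks
    do not overlap in the alignment.
    """
    ov = block_a.overlap(block_b)
    if ov is None:
        raise ValueError("blocks do not overlap")
    score = sum(
        column_pair_score(columns_a[c], columns_b[c], prior)
        for c in range(ov[0], ov[1])
    )
    return score > 0.0, float(score)


def mark_query_related_blocks(
    blocks_by_subfamily: dict[int, list[CoreBlock]],
    partition: SubfamilyPartition,
    columns_by_subfamily: dict[int, list[ColumnObservation]],
    prior: DirichletMixture,
) -> None:
    """Annotate every block with its relatedness to the query subfamily.

    Query-subfamily blocks are related by definition. Any other block is
    related iff it overlaps, and scores strictly positive against, at least
    one query-subfamily block. Mutates ``related_to_query`` in place.
    """
    q = partition.query_subfamily
    query_blocks = blocks_by_subfamily.get(q, [])
    if not query_blocks:
        logger.warning("query subfamily has no core blocks; all other blocks unrelated")
    for k, blocks in blocks_by_subfamily.items():
        for block in blocks:
            if k == q:
                block.related_to_query = "is_query_subfamily"
                continue
            block.related_to_query = False
            for qb in query_blocks:
                if block.overlap(qb) is None:
                    continue
                related, _ = block_relatedness(
                    block, qb, columns_by_subfamily[k], columns_by_subfamily[q], prior
                )
                if related:
                    block.related_to_query = True
                    break
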