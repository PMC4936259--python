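"""End-to-end pipeline: cluster, score, link, flag, chain, filter.

The five stages mirror the method's design: (1) subfamily clustering with
orphan set-aside; (2) per-subfamily BILD score tracks and core-block
detection, with inconsistent-segment flagging; (3) relatedness of every
subfamily block to the query subfamily's blocks; (4) orphan comparison
against the query blocks; (5) chaining of query-related blocks into regions,
sequence filtering and ranking. Fully deterministic: identical inputs give
identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from . import core_blocks as cb
from . import regions as rg
from .consistency import (
    SegmentVerdict,
    compare_orphans_to_query,
    flag_inconsistent_segments,
)
from .msa_io import Alignment
from .priors import DirichletMixture
from .regions import HomologyReport
from .subfamilies import (
    DEFAULT_ORPHAN_THRESHOLD,
    SubfamilyPartition,
    cluster_subfamilies,
    pairwise_distances,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunable pipeline parameters with their published/package defaults."""

    window: int = cb.DEFAULT_WINDOW
    block_threshold: float = cb.DEFAULT_BLOCK_THRESHOLD
    max_gap: int = rg.DEFAULT_MAX_GAP
    min_region_length: int = rg.DEFAULT_MIN_REGION_LENGTH
    score_cutoff: float = rg.DEFAULT_SCORE_CUTOFF
    orphan_threshold: float = DEFAULT_ORPHAN_THRESHOLD

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 < self.block_threshold < 1:
            raise ValueError("block_threshold must be in (0, 1)")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_region_length < 1:
            raise ValueError("min_region_length must be >= 1")
        if not 0 < self.orphan_threshold <= 1:
            raise ValueError("orphan_threshold must be in (0, 1]")


@dataclass
class PipelineResult:
    """Everything the pipeline computed, for reporting and inspection."""

    alignment: Alignment
    partition: SubfamilyPartition
    tracks: dict[int, "cb.ScoreTrack"]
    blocks_by_subfamily: dict[int, list["cb.CoreBlock"]]
    segment_verdicts: list[SegmentVerdict]
    orphan_blocks: dict[int, list]
    report: HomologyReport
    config: RunConfig


def run_pipeline(
    aln: Alignment, prior: DirichletMixture, config: RunConfig | None = None
) -> PipelineResult:
    config = config or RunConfig()
    dm = pairwise_distances(aln)
    partition = cluster_subfamilies(dm, aln.query_index, config.orphan_threshold)

    members_by_sub = {k: sub for k, sub in enumerate(partition.subfamilies)}
    columns_by_sub = {
        k: cb.subfamily_columns(aln, sub) for k, sub in members_by_sub.items()
    }
    tracks = {
        k: cb.score_track(aln, sub, prior, subfamily_index=k,
                          columns=columns_by_sub[k])
        for k, sub in members_by_sub.items()
    }
    blocks_by_sub = {
        k: cb.detect_core_blocks(t, config.window, config.block_threshold)
        for k, t in tracks.items()
    }

    verdicts = flag_inconsistent_segments(
        aln, members_by_sub, blocks_by_sub, columns_by_sub, prior
    )
    flagged_by_seq: dict[str, set[tuple[int, int]]] = {}
    inconsistent_by_seq: dict[str, list[SegmentVerdict]] = {}
    for v in verdicts:
        if v.inconsistent:
            flagged_by_seq.setdefault(v.seq_id, set()).add((v.start, v.end))
            inconsistent_by_seq.setdefault(v.seq_id, []).append(v)

    cb.mark_query_related_blocks(blocks_by_sub, partition, columns_by_sub, prior)

    q = partition.query_subfamily
    orphan_blocks = compare_orphans_to_query(
        aln,
        partition.orphans,
        blocks_by_sub.get(q, []),
        columns_by_sub[q],
        prior,
    )

    regions_by_seq: dict[str, list[rg.Region]] = {}
    for k, members in members_by_sub.items():
        related = [
            b for b in blocks_by_sub.get(k, [])
            if b.related_to_query in (True, "is_query_subfamily")
        ]
        for i in members:
            sid, seq = aln.records[i]
            eligible = [
                b for b in related
                if rg.sequence_claims_block(seq, b, flagged_by_seq.get(sid, set()))
            ]
            regions_by_seq[sid] = rg.chain_blocks(
                sid, eligible, config.max_gap, config.min_region_length
            )
    for i, passed in orphan_blocks.items():
        sid = aln.records[i][0]
        regions_by_seq[sid] = rg.chain_blocks(
            sid, [b for b, _ in passed], config.max_gap, config.min_region_length
        )

    report = rg.filter_and_rank(
        aln.ids,
        aln.query_id,
        regions_by_seq,
        inconsistent_by_seq,
        {aln.records[i][0] for i in partition.orphans},
        config.score_cutoff,
    )
    logger.info(
        "retained %d/%d sequences", len(report.retained_ids), aln.n_seqs
    )
    return PipelineResult(
        alignment=aln,
        partition=partition,
        tracks=tracks,
        blocks_by_subfamily=blocks_by_sub,
        segment_verdicts=verdicts,
        orphan_blocks=orphan_blocks,
        report=report,
        config=config,
    )
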