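"""Chaining of core blocks into regions; sequence filtering and ranking.

Blocks that match the query are chained greedily left to right: consecutive
blocks joined while the inter-block gap (next.start - prev.end, in alignment
columns) is at most ``max_gap`` (default 40). Chains spanning fewer than
``min_region_length`` columns (default 21, inclusive) are discarded. A
region's score is the sum of its member block scores; a sequence survives
iff at least one of its regions scores above the cutoff (default 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .consistency import SegmentVerdict
from .core_blocks import CoreBlock
from .msa_io import GAP, UNKNOWN, CoordinateMap

DEFAULT_MAX_GAP = 40
DEFAULT_MIN_REGION_LENGTH = 21
DEFAULT_SCORE_CUTOFF = 0.0


@dataclass
class Region:
    """A chain of core blocks claimed by one sequence."""

    seq_id: str
    blocks: list[CoreBlock]
    start: int
    end: int
    region_score: float


@dataclass
class SequenceVerdict:
    """Final per-sequence outcome of the pipeline."""

    seq_id: str
    status: str                    # query | related | removed | orphan-removed
    rank: int | None
    total_score: float
    regions: list[Region]
    inconsistent_segments: list[SegmentVerdict] = field(default_factory=list)


@dataclass
class HomologyReport:
    """Per-sequence verdicts, in input order."""

    verdicts: list[SequenceVerdict]

    def by_id(self, seq_id: str) -> SequenceVerdict:
        for v in self.verdicts:
            if v.seq_id == seq_id:
                return v
        raise KeyError(seq_id)

    @property
    def retained_ids(self) -> list[str]:
        return [v.seq_id for v in self.verdicts if v.status in ("query", "related")]


def chain_blocks(
    seq_id: str,
    seq_blocks: list[CoreBlock],
    max_gap: int = DEFAULT_MAX_GAP,
    min_region_length: int = DEFAULT_MIN_REGION_LENGTH,
) -> list[Region]:
    """Greedy left-to-right chaining of sorted, disjoint blocks."""
    if max_gap < 0 or min_region_length < 1:
        raise ValueError("max_gap must be >= 0 and min_region_length >= 1")
    blocks = sorted(seq_blocks, key=lambda b: (b.start, b.end))
    regions: list[Region] = []
    chain: list[CoreBlock] = []
    for block in blocks:
        if chain and block.start - chain[-1].end <= max_gap:
            chain.append(block)
        else:
            if chain:
                regions.append(_finish_chain(seq_id, chain))
            chain = [block]
    if chain:
        regions.append(_finish_chain(seq_id, chain))
    return [r for r in regions if r.end - r.start >= min_region_length]


def _finish_chain(seq_id: str, chain: list[CoreBlock]) -> Region:
    return Region(
        seq_id=seq_id,
        blocks=list(chain),
        start=chain[0].start,
        end=chain[-1].end,
        region_score=sum(b.block_score for b in chain),
    )


def sequence_claims_block(seq: str, block: CoreBlock, flagged: set[tuple[int, int]]) -> bool:
    """A block counts for a sequence iff the sequence has at least one
    non-gap, non-unknown residue inside it and was not flagged inconsistent
    across it."""
    if (block.start, block.end) in flagged:
        return False
    return any(seq[c] not in (GAP, UNKNOWN) for c in range(block.start, block.end))


def filter_and_rank(
    seq_ids: list[str],
    query_id: str,
    regions_by_seq: dict[str, list[Region]],
    inconsistent_by_seq: dict[str, list[SegmentVerdict]],
    orphan_ids: set[str],
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> HomologyReport:
    """Retain sequences with a region scoring above the cutoff; rank the rest.

    Retained non-query sequences are ranked 1..k by descending total score
    (ties broken by input order); the query is always retained, unranked.
    """
    keep: dict[str, float] = {}
    for sid in seq_ids:
        regs = regions_by_seq.get(sid, [])
        if any(r.region_score > score_cutoff for r in regs):
            keep[sid] = sum(r.region_score for r in regs)

    order = {sid: i for i, sid in enumerate(seq_ids)}
    ranked = sorted(
        (sid for sid in keep if sid != query_id),
        key=lambda s: (-keep[s], order[s]),
    )
    ranks = {sid: i + 1 for i, sid in enumerate(ranked)}

    verdicts = []
    for sid in seq_ids:
        if sid == query_id:
            status, rank = "query", None
        elif sid in keep:
            status, rank = "related", ranks[sid]
        elif sid in orphan_ids:
            status, rank = "orphan-removed", None
        else:
            status, rank = "removed", None
        verdicts.append(
            SequenceVerdict(
                seq_id=sid,
                status=status,
                rank=rank,
                total_score=keep.get(sid, 0.0),
                regions=regions_by_seq.get(sid, []) if sid in keep or sid == query_id else [],
                inconsistent_segments=inconsistent_by_seq.get(sid, []),
            )
        )
    return HomologyReport(verdicts)


def regions_to_sequence_coords(
    region: Region, cmap: CoordinateMap
) -> list[tuple[int, int]]:
    """Translate a region's column interval into a residue interval.

    Residue indices over the sequence's non-gap columns are consecutive, so a
    region maps to at most one 0-based half-open residue interval — shorter
    than the column span when the region crosses gap runs, empty when the
    sequence is entirely gapped across it.
    """
    residues = [int(cmap.col_to_res[c]) for c in range(region.start, region.end)
                if cmap.col_to_res[c] >= 0]
    if not residues:
        return []
    return [(residues[0], residues[-1] + 1)]
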