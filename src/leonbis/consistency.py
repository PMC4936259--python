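"""Detection of inconsistent sequence segments and orphan comparison.

A sequence segment aligned to a core block is scored as the product over
paired positions of the posterior-predictive probability of its residue given
the block column (leave-one-out: the sequence's own residues are removed from
the column counts first). The unrelatedness baseline is the score of a
uniformly random residue per column, i.e. sum over columns of
log[ sum_a (1/20) * p_post(a) ] = N * log(1/20). Segments scoring below the
baseline are flagged inconsistent and excluded from region chaining.

The same machinery compares orphan sequences against the query subfamily's
core blocks; blocks an orphan passes become that orphan's blocks for
downstream chaining, scored by the segment's log-odds over the baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .core_blocks import CoreBlock
from .msa_io import GAP, UNKNOWN, Alignment
from .priors import N_AA, DirichletMixture
from .scoring import ColumnObservation, posterior_predictive, posterior_predictive_all

logger = logging.getLogger(__name__)

LOG_UNIFORM = math.log(1.0 / N_AA)


@dataclass
class SegmentVerdict:
    """Outcome of scoring one sequence's segment across one core block."""

    seq_id: str
    start: int          # alignment columns, half-open
    end: int
    log_score: float
    log_baseline: float

    @property
    def inconsistent(self) -> bool:
        return self.log_score < self.log_baseline


def _paired_positions(
    seq: str, block: CoreBlock
) -> list[tuple[int, str]]:
    """(column, residue) pairs where the sequence has a scorable residue."""
    return [
        (c, seq[c])
        for c in range(block.start, block.end)
        if seq[c] not in (GAP, UNKNOWN)
    ]


def segment_log_score(
    residues: list[str],
    block_columns: list[ColumnObservation],
    prior: DirichletMixture,
) -> float:
    """Log probability of the segment under relatedness to the block.

    ``residues[i]`` is scored against ``block_columns[i]``; the caller is
    responsible for leave-one-out (columns must not contain the scored
    sequence's own residues). Positions are independent, so the result is a
    plain sum of log posterior predictives.
    """
    if not residues:
        raise ValueError("empty pairing: no residues aligned to the block")
    if len(residues) != len(block_columns):
        raise ValueError("residues and block columns must pair one-to-one")
    total = 0.0
    for res, col in zip(residues, block_columns):
        total += math.log(max(posterior_predictive(col, prior, res), 1e-300))
    return total


def random_baseline(
    block_columns: list[ColumnObservation], prior: DirichletMixture
) -> float:
    """Log score of a uniformly random segment of the same length.

    Per column the expected probability is sum_a (1/L) * p_post(a) with
    L = 20; the posterior predictive sums to one, so each column contributes
    log(1/20). The sum is computed explicitly as a self-check of that
    normalization.
    """
    if not block_columns:
        raise ValueError("block has no columns")
    total = 0.0
    for col in block_columns:
        total += math.log((posterior_predictive_all(col, prior) / N_AA).sum())
    return total


def _leave_one_out(
    columns: list[ColumnObservation], pairs: list[tuple[int, str]], offset: int
) -> list[ColumnObservation]:
    return [columns[c - offset].remove(res) for c, res in pairs]


def flag_inconsistent_segments(
    aln: Alignment,
    members_by_subfamily: dict[int, list[int]],
    blocks_by_subfamily: dict[int, list[CoreBlock]],
    columns_by_subfamily: dict[int, list[ColumnObservation]],
    prior: DirichletMixture,
) -> list[SegmentVerdict]:
    """Score every member sequence against every block of its own subfamily.

    A sequence entirely gapped across a block yields no verdict for that
    block. Verdicts are ordered by (subfamily, block, member) for
    reproducibility.
    """
    verdicts: list[SegmentVerdict] = []
    for k, members in members_by_subfamily.items():
        columns = columns_by_subfamily[k]
        for block in blocks_by_subfamily.get(k, []):
            for i in members:
                seq_id, seq = aln.records[i]
                pairs = _paired_positions(seq, block)
                if not pairs:
                    continue
                loo = _leave_one_out(columns, pairs, offset=0)
                score = segment_log_score([r for _, r in pairs], loo, prior)
                baseline = random_baseline(loo, prior)
                verdicts.append(
                    SegmentVerdict(seq_id, block.start, block.end, score, baseline)
                )
    return verdicts


def compare_orphans_to_query(
    aln: Alignment,
    orphans: list[int],
    query_blocks: list[CoreBlock],
    query_columns: list[ColumnObservation],
    prior: DirichletMixture,
) -> dict[int, list[tuple[CoreBlock, SegmentVerdict]]]:
    """Score each orphan against the query subfamily's core blocks.

    Returns, per orphan index, the query blocks the orphan *passes*
    (log_score >= log_baseline) re-scored as that orphan's own blocks: the
    block score is the segment's log-odds over the baseline, which is >= 0
    for a passing block so the downstream "> 0" region cutoff applies
    uniformly. Orphans gapped across all query blocks get an empty list.
    """
    if not query_blocks:
        logger.warning("no query-subfamily blocks: orphans cannot be validated")
        return {i: [] for i in orphans}
    out: dict[int, list[tuple[CoreBlock, SegmentVerdict]]] = {}
    for i in orphans:
        seq_id, seq = aln.records[i]
        passed: list[tuple[CoreBlock, SegmentVerdict]] = []
        for qb in query_blocks:
            pairs = _paired_positions(seq, qb)
            if not pairs:
                continue
            cols = [query_columns[c] for c, _ in pairs]
            score = segment_log_score([r for _, r in pairs], cols, prior)
            baseline = random_baseline(cols, prior)
            verdict = SegmentVerdict(seq_id, qb.start, qb.end, score, baseline)
            if score >= baseline:
                block = CoreBlock(
                    subfamily_index=-1,  # orphan-owned
                    start=qb.start,
                    end=qb.end,
                    mean_prob=qb.mean_prob,
                    block_score=score - baseline,
                    related_to_query=True,
                )
                passed.append((block, verdict))
        out[i] = passed
    return out
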