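"""Serialization of pipeline results: JSON report, GFF3, BED6, filtered FASTA.

Internal coordinates are 0-based half-open throughout; GFF3 output converts
to 1-based inclusive, BED6 stays 0-based half-open, per each format's
convention. Alignment-space features use the reserved seqid ``MSA``.
"""

from __future__ import annotations

import json
from pathlib import Path

from .msa_io import build_coordinate_map, write_alignment
from .pipeline import PipelineResult
from .regions import regions_to_sequence_coords

SCHEMA_VERSION = 1


def report_to_dict(result: PipelineResult) -> dict:
    aln = result.alignment
    part = result.partition
    blocks = [
        {
            "subfamily": k,
            "start": b.start,
            "end": b.end,
            "mean_prob": round(b.mean_prob, 9),
            "block_score": round(b.block_score, 9),
            "related_to_query": b.related_to_query,
        }
        for k in sorted(result.blocks_by_subfamily)
        for b in result.blocks_by_subfamily[k]
    ]
    sequences = []
    for v in result.report.verdicts:
        cmap = build_coordinate_map(aln, v.seq_id)
        sequences.append(
            {
                "id": v.seq_id,
                "status": v.status,
                "rank": v.rank,
                "total_score": round(v.total_score, 9),
                "regions": [
                    {
                        "start": r.start,
                        "end": r.end,
                        "region_score": round(r.region_score, 9),
                        "n_blocks": len(r.blocks),
                        "residue_intervals": regions_to_sequence_coords(r, cmap),
                    }
                    for r in v.regions
                ],
                "inconsistent_segments": [
                    {
                        "start": s.start,
                        "end": s.end,
                        "log_score": round(s.log_score, 9),
                        "log_baseline": round(s.log_baseline, 9),
                    }
                    for s in v.inconsistent_segments
                ],
            }
        )
    return {
        "schema_version": SCHEMA_VERSION,
        "query_id": aln.query_id,
        "n_sequences": aln.n_seqs,
        "n_columns": aln.n_cols,
        "parameters": {
            "window": result.config.window,
            "block_threshold": result.config.block_threshold,
            "max_gap": result.config.max_gap,
            "min_region_length": result.config.min_region_length,
            "score_cutoff": result.config.score_cutoff,
            "orphan_threshold": result.config.orphan_threshold,
        },
        "subfamilies": [
            {"index": k, "members": [aln.records[i][0] for i in sub]}
            for k, sub in enumerate(part.subfamilies)
        ],
        "query_subfamily": part.query_subfamily,
        "orphans": [aln.records[i][0] for i in part.orphans],
        "core_blocks": blocks,
        "sequences": sequences,
    }


def write_json_report(result: PipelineResult, path) -> None:
    Path(path).write_text(
        json.dumps(report_to_dict(result), indent=1, sort_keys=True) + "\n"
    )


def write_filtered_fasta(result: PipelineResult, path) -> None:
    """Alignment restricted to the query and retained sequences."""
    write_alignment(result.alignment.subset(result.report.retained_ids), path)


def write_blocks_bed(result: PipelineResult, path) -> None:
    """Core blocks as BED6 in alignment space (0-based half-open)."""
    lines = []
    for k in sorted(result.blocks_by_subfamily):
        for b in result.blocks_by_subfamily[k]:
            related = b.related_to_query in (True, "is_query_subfamily")
            lines.append(
                f"MSA\t{b.start}\t{b.end}\tsubfamily{k}"
                f"\t{b.block_score:.3f}\t{'+' if related else '.'}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _gff3_line(seqid, source, ftype, start, end, score, attrs) -> str:
    # convert 0-based half-open -> GFF3 1-based inclusive
    score_s = f"{score:.3f}" if score is not None else "."
    attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
    return f"{seqid}\t{source}\t{ftype}\t{start + 1}\t{end}\t{score_s}\t.\t.\t{attr_s}"


def write_gff3(result: PipelineResult, path) -> None:
    """Blocks, regions and inconsistent segments as GFF3.

    Alignment-space features carry seqid ``MSA``; each retained sequence's
    regions are additionally emitted in its own residue coordinates.
    """
    aln = result.alignment
    lines = ["##gff-version 3"]
    for k in sorted(result.blocks_by_subfamily):
        for i, b in enumerate(result.blocks_by_subfamily[k]):
            lines.append(_gff3_line(
                "MSA", "leonbis", "core_block", b.start, b.end, b.block_score,
                {"ID": f"block_s{k}_{i}", "subfamily": k,
                 "related_to_query": b.related_to_query},
            ))
    for v in result.report.verdicts:
        for j, r in enumerate(v.regions):
            lines.append(_gff3_line(
                "MSA", "leonbis", "conserved_region", r.start, r.end,
                r.region_score, {"ID": f"region_{v.seq_id}_{j}", "sequence": v.seq_id},
            ))
        for j, s in enumerate(v.inconsistent_segments):
            lines.append(_gff3_line(
                "MSA", "leonbis", "inconsistent_segment", s.start, s.end, None,
                {"ID": f"inconsistent_{v.seq_id}_{j}", "sequence": v.seq_id},
            ))
    for v in result.report.verdicts:
        if v.status not in ("query", "related"):
            continue
        cmap = build_coordinate_map(aln, v.seq_id)
        for j, r in enumerate(v.regions):
            for rs, re_ in regions_to_sequence_coords(r, cmap):
                lines.append(_gff3_line(
                    v.seq_id, "leonbis", "conserved_region", rs, re_,
                    r.region_score, {"ID": f"region_{v.seq_id}_{j}_seqspace"},
                ))
    Path(path).write_text("\n".join(lines) + "\n")


def write_all(result: PipelineResult, prefix) -> dict[str, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "json": prefix.with_suffix(".report.json"),
        "fasta": prefix.with_suffix(".filtered.fasta"),
        "bed": prefix.with_suffix(".blocks.bed"),
        "gff3": prefix.with_suffix(".gff3"),
    }
    write_json_report(result, paths["json"])
    write_filtered_fasta(result, paths["fasta"])
    write_blocks_bed(result, paths["bed"])
    write_gff3(result, paths["gff3"])
    return paths
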