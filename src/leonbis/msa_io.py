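"""Alignment input/output and coordinate bookkeeping.

The whole pipeline operates in *alignment column space*: 0-based, half-open
intervals. Conversion to per-sequence residue coordinates happens only at
reporting time, through :class:`CoordinateMap`.

Accepted residue alphabet: the 20 canonical amino acids, plus ``X`` (unknown,
treated as missing data by the scoring modules) and ``-`` (gap). Lowercase is
uppercased on input; anything else (``*``, ``.``, ambiguity codes B/Z/J,
selenocysteine U) is rejected with an error naming the record and column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
_ALLOWED = frozenset(AMINO_ACIDS + UNKNOWN + GAP)


class AlignmentError(ValueError):
    """Raised for malformed alignment input (ragged rows, bad characters...)."""


@dataclass
class Alignment:
    """A protein multiple sequence alignment with a designated query.

    Parameters
    ----------
    records:
        Ordered ``(id, aligned_seq)`` pairs. All sequences must have equal
        length and use only the accepted alphabet.
    query_id:
        Identifier of the query sequence; must be one of the record ids.
    """

    records: list[tuple[str, str]]
    query_id: str
    n_cols: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sequence ids: {dup}")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"not an alignment: records have differing lengths {sorted(lengths)}"
            )
        self.n_cols = lengths.pop()
        if self.n_cols < 1:
            raise AlignmentError("alignment has zero columns")
        for rid, seq in self.records:
            for col, ch in enumerate(seq):
                if ch not in _ALLOWED:
                    raise AlignmentError(
                        f"illegal character {ch!r} in record {rid!r} at column {col}"
                    )
        if self.query_id not in ids:
            raise AlignmentError(f"query not found: {self.query_id!r}")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def n_seqs(self) -> int:
        return len(self.records)

    @property
    def query_index(self) -> int:
        return self.ids.index(self.query_id)

    def sequence(self, seq_id: str) -> str:
        for rid, seq in self.records:
            if rid == seq_id:
                return seq
        raise KeyError(seq_id)

    def column(self, col: int) -> str:
        return "".join(seq[col] for _, seq in self.records)

    def subset(self, keep_ids: list[str]) -> "Alignment":
        """Row-subset preserving input order; columns are kept verbatim."""
        keep = set(keep_ids)
        recs = [(rid, seq) for rid, seq in self.records if rid in keep]
        return Alignment(recs, self.query_id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.records == other.records and self.query_id == other.query_id


def read_alignment(path, query_id: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Raises :class:`AlignmentError` on ragged records, illegal characters or a
    missing query id, and when fewer than two records are present.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if len(records) < 2:
        raise AlignmentError(f"{path}: need at least 2 aligned sequences, got {len(records)}")
    return Alignment(records, query_id)


def write_alignment(aln: Alignment, path) -> None:
    """Write an alignment as aligned FASTA (60-column wrapping)."""
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records]
    SeqIO.write(recs, str(path), "fasta")


@dataclass
class CoordinateMap:
    """Bijection between non-gap alignment columns and residue indices.

    ``col_to_res[c]`` is the 0-based residue index at column ``c`` or -1 for a
    gap column; ``res_to_col[r]`` is the column holding residue ``r``.
    """

    seq_id: str
    col_to_res: np.ndarray
    res_to_col: np.ndarray

    @property
    def n_residues(self) -> int:
        return len(self.res_to_col)


def build_coordinate_map(aln: Alignment, seq_id: str) -> CoordinateMap:
    seq = aln.sequence(seq_id)  # KeyError if unknown
    col_to_res = np.full(len(seq), -1, dtype=np.int64)
    res_to_col = []
    r = 0
    for c, ch in enumerate(seq):
        if ch != GAP:
            col_to_res[c] = r
            res_to_col.append(c)
            r += 1
    return CoordinateMap(seq_id, col_to_res, np.asarray(res_to_col, dtype=np.int64))
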