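"""Deterministic synthetic alignments with known ground truth.

The generator emulates the structure of a curated homology benchmark at desk
scale: a handful of subfamilies sharing one or more planted conserved blocks
with the query's subfamily (plus optional subfamily-private blocks), embedded
in background-composition columns; a few entirely unrelated sequences drawn
from background and verified to share < 50 % identity with the query; and
optional corrupted segments, where a related sequence's residues across a
planted block are overwritten with uniform draws (mimicking badly predicted
sequence stretches).

No indel evolution is modelled: alignments are ungapped by construction,
keeping the ground-truth block coordinates exact. One explicit RNG stream per
fixture; the same seed yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .msa_io import AMINO_ACIDS, Alignment
from .priors import N_AA

# mildly non-uniform background, loosely shaped like natural residue usage:
# common residues (A, G, L, S, E, K...) elevated, W and C rare
_BACKGROUND = np.array([
    0.083, 0.014, 0.054, 0.067, 0.039, 0.071, 0.022, 0.058, 0.058, 0.097,
    0.024, 0.041, 0.047, 0.039, 0.055, 0.066, 0.053, 0.069, 0.011, 0.032,
])
_BACKGROUND = _BACKGROUND / _BACKGROUND.sum()


@dataclass(frozen=True)
class PlantedBlock:
    """One conserved column interval to plant.

    ``shared``: drawn from the same per-column consensus in every subfamily
    (creates query-related blocks); otherwise each subfamily gets its own
    consensus. ``conservation``: probability that a member carries the
    consensus residue at a block column (the rest is background noise).
    """

    start: int
    end: int
    shared: bool = True
    conservation: float = 0.9


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic alignment."""

    seed: int
    n_subfamilies: int = 3
    members_per_subfamily: int = 6
    n_cols: int = 160
    planted_blocks: tuple[PlantedBlock, ...] = (
        PlantedBlock(20, 55, shared=True),
        PlantedBlock(75, 100, shared=False),
        PlantedBlock(115, 145, shared=True),
    )
    n_unrelated: int = 4
    n_corrupted_segments: int = 0
    # probability that a member carries its subfamily's consensus residue at
    # NON-block columns: 0 keeps them iid background (sharp planted-block
    # ground truth); raising it makes subfamilies separable by identity
    # clustering, emulating families homologous along their whole length
    subfamily_similarity: float = 0.0
    max_unrelated_identity: float = 0.5
    max_resample_attempts: int = 100

    def __post_init__(self) -> None:
        ivals = sorted((b.start, b.end) for b in self.planted_blocks)
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1:
                raise ValueError("planted blocks must be disjoint")
        if ivals and (ivals[0][0] < 0 or ivals[-1][1] > self.n_cols):
            raise ValueError("planted blocks must fit within n_cols")
        if min(self.n_subfamilies, self.members_per_subfamily) < 1:
            raise ValueError("need at least one subfamily with one member")


@dataclass
class FixtureTruth:
    """Ground-truth labels accompanying a generated alignment."""

    related_ids: list[str]
    unrelated_ids: list[str]
    subfamily_of: dict[str, int]
    block_columns: list[tuple[int, int]]
    shared_block_columns: list[tuple[int, int]]
    corrupted: list[tuple[str, int, int]]  # (seq_id, start, end) in columns

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _draw(rng: np.random.Generator, probs: np.ndarray, size: int) -> list[str]:
    idx = rng.choice(N_AA, size=size, p=probs)
    return [AMINO_ACIDS[i] for i in idx]


def generate_fixture(spec: FixtureSpec) -> tuple[Alignment, FixtureTruth]:
    """Build the alignment and its truth labels from a :class:`FixtureSpec`.

    The query is the first member of subfamily 0. Unrelated sequences are
    resampled (up to ``max_resample_attempts``) until they share less than
    ``max_unrelated_identity`` with the query; corrupted segments are applied
    to non-query related sequences, cycling over shared planted blocks.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = sorted(spec.planted_blocks, key=lambda b: b.start)

    # per-block consensus residues: one per column, either global or per-subfamily
    consensus: dict[tuple[int, int | None], list[str]] = {}
    for bi, b in enumerate(blocks):
        if b.shared:
            consensus[(bi, None)] = _draw(rng, _BACKGROUND, b.end - b.start)
        else:
            for k in range(spec.n_subfamilies):
                consensus[(bi, k)] = _draw(rng, _BACKGROUND, b.end - b.start)

    in_block = np.zeros(spec.n_cols, dtype=bool)
    for b in blocks:
        in_block[b.start : b.end] = True

    records: list[tuple[str, str]] = []
    subfamily_of: dict[str, int] = {}
    for k in range(spec.n_subfamilies):
        sub_consensus = _draw(rng, _BACKGROUND, spec.n_cols)
        for m in range(spec.members_per_subfamily):
            sid = "query" if (k == 0 and m == 0) else f"sub{k}_seq{m}"
            row = _draw(rng, _BACKGROUND, spec.n_cols)
            if spec.subfamily_similarity > 0:
                for c in range(spec.n_cols):
                    if not in_block[c] and rng.random() < spec.subfamily_similarity:
                        row[c] = sub_consensus[c]
            for bi, b in enumerate(blocks):
                cons = consensus[(bi, None if b.shared else k)]
                for j, c in enumerate(range(b.start, b.end)):
                    if rng.random() < b.conservation:
                        row[c] = cons[j]
            records.append((sid, "".join(row)))
            subfamily_of[sid] = k

    query_seq = records[0][1]
    unrelated_ids = []
    for u in range(spec.n_unrelated):
        sid = f"unrelated{u}"
        for attempt in range(spec.max_resample_attempts):
            row = "".join(_draw(rng, _BACKGROUND, spec.n_cols))
            ident = sum(a == b for a, b in zip(row, query_seq)) / spec.n_cols
            if ident < spec.max_unrelated_identity:
                break
        else:
            raise RuntimeError(
                f"could not sample an unrelated sequence below "
                f"{spec.max_unrelated_identity:.0%} identity in "
                f"{spec.max_resample_attempts} attempts"
            )
        records.append((sid, row))
        unrelated_ids.append(sid)

    # corrupt segments of non-query related sequences across shared blocks
    corrupted: list[tuple[str, int, int]] = []
    shared = [b for b in blocks if b.shared]
    victims = [sid for sid, _ in records[1:] if sid not in unrelated_ids]
    uniform = np.full(N_AA, 1.0 / N_AA)
    by_id = dict(records)
    for t in range(spec.n_corrupted_segments):
        if not shared or not victims:
            break
        sid = victims[t % len(victims)]
        b = shared[t % len(shared)]
        row = list(by_id[sid])
        row[b.start : b.end] = _draw(rng, uniform, b.end - b.start)
        by_id[sid] = "".join(row)
        corrupted.append((sid, b.start, b.end))
    records = [(sid, by_id[sid]) for sid, _ in records]

    aln = Alignment(records, query_id="query")
    truth = FixtureTruth(
        related_ids=[sid for sid, _ in records if sid not in unrelated_ids],
        unrelated_ids=unrelated_ids,
        subfamily_of=subfamily_of,
        block_columns=[(b.start, b.end) for b in blocks],
        shared_block_columns=[(b.start, b.end) for b in shared],
        corrupted=corrupted,
    )
    return aln, truth
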