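"""Homolog sequence alignment and reference-numbered position mapping.

All cross-strain residue positions in this package are expressed in the
numbering of the reference (SEL) photolyase *excluding the initiator
methionine*.  A record whose FASTA sequence still carries the leading Met
declares ``numbering_offset=1``; position ``p`` then refers to sequence
index ``p - 1 + numbering_offset``.

Homologs are mapped to the reference by pairwise global alignment
(Needleman–Wunsch with BLOSUM62 and affine gaps, via Biopython); position
mapping to a single reference is the only alignment product the downstream
variant analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "GAP",
    "ProteinRecord",
    "AlignParams",
    "AlignmentPair",
    "PositionMap",
    "global_align",
    "percent_identity",
    "identity_matrix",
    "build_position_map",
    "map_position",
    "read_fasta_records",
]

GAP = "-"

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class ProteinRecord:
    """A strain's photolyase sequence with its numbering convention."""

    id: str
    sequence: str
    numbering_offset: int = 0  # 1 if an initiator Met present in sequence is excluded from numbering

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(self.sequence.upper()) - _AA
        if bad:
            raise ValueError(f"invalid residue letters in {self.id!r}: {sorted(bad)}")

    @property
    def numbered_length(self) -> int:
        return len(self.sequence) - self.numbering_offset


@dataclass(frozen=True)
class AlignParams:
    matrix: object = "BLOSUM62"  # matrix name, or a substitution_matrices.Array
    gap_open: float = 10.0
    gap_extend: float = 1.0


@dataclass
class AlignmentPair:
    ref_id: str
    query_id: str
    aligned_ref: str
    aligned_query: str
    score: float
    params: AlignParams
    percent_identity: float


@dataclass
class PositionMap:
    """Bidirectional map between reference-numbered and query-numbered positions."""

    ref_id: str
    query_id: str
    # ref numbering position -> (query position | None, query residue | GAP)
    forward: dict[int, tuple[int | None, str]] = field(default_factory=dict)
    inverse: dict[int, int] = field(default_factory=dict)  # query position -> ref position


def _aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = (
        substitution_matrices.load(params.matrix) if isinstance(params.matrix, str) else params.matrix
    )
    aligner.open_gap_score = -abs(params.gap_open)
    aligner.extend_gap_score = -abs(params.gap_extend)
    return aligner


def percent_identity(aligned_a: str, aligned_b: str) -> float:
    """Identical columns / aligned columns, excluding columns gapped in both."""
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b) if not (x == GAP and y == GAP)]
    if not pairs:
        raise ValueError("empty alignment")
    same = sum(1 for x, y in pairs if x == y and x != GAP)
    return 100.0 * same / len(pairs)


def global_align(ref: ProteinRecord, query: ProteinRecord, params: AlignParams | None = None) -> AlignmentPair:
    """Optimal global alignment of a homolog to the reference."""
    params = params or AlignParams()
    aligner = _aligner(params)
    alns = aligner.align(ref.sequence.upper(), query.sequence.upper())
    best = alns[0]  # deterministic first optimal traceback
    a, b = str(best[0]), str(best[1])
    return AlignmentPair(
        ref_id=ref.id,
        query_id=query.id,
        aligned_ref=a,
        aligned_query=b,
        score=float(best.score),
        params=params,
        percent_identity=percent_identity(a, b),
    )


def identity_matrix(records: Sequence[ProteinRecord], params: AlignParams | None = None) -> pd.DataFrame:
    """Symmetric pairwise percent-identity matrix; diagonal 100."""
    if len(records) < 2:
        raise ValueError("need at least two records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    mat = np.full((len(records), len(records)), 100.0)
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            pid = global_align(records[i], records[j], params).percent_identity
            mat[i, j] = mat[j, i] = pid
    return pd.DataFrame(mat, index=ids, columns=ids)


def build_position_map(ref: ProteinRecord, query: ProteinRecord, params: AlignParams | None = None) -> PositionMap:
    """Align and convert alignment columns to reference-numbered positions."""
    pair = global_align(ref, query, params)
    pm = PositionMap(ref_id=ref.id, query_id=query.id)
    ri = qi = 0  # 0-based indices into the raw sequences
    for ra, qa in zip(pair.aligned_ref, pair.aligned_query):
        if ra != GAP:
            ref_pos = ri + 1 - ref.numbering_offset  # numbered position; <=0 for the excluded Met
            if ref_pos >= 1:
                if qa != GAP:
                    q_pos = qi + 1 - query.numbering_offset
                    if q_pos >= 1:
                        pm.forward[ref_pos] = (q_pos, qa)
                        pm.inverse[q_pos] = ref_pos
                    else:
                        pm.forward[ref_pos] = (None, GAP)
                else:
                    pm.forward[ref_pos] = (None, GAP)
            ri += 1
        if qa != GAP:
            qi += 1
    return pm


def map_position(pm: PositionMap, ref_pos: int) -> tuple[str, int | None]:
    """Residue and query-numbered position aligned to a reference position.

    Returns ``(residue, query_position)``; ``(GAP, None)`` when the reference
    position is deleted in the query.
    """
    if ref_pos not in pm.forward:
        valid = sorted(pm.forward)
        lo, hi = (valid[0], valid[-1]) if valid else (None, None)
        raise KeyError(f"reference position {ref_pos} outside mapped range [{lo}, {hi}]")
    q_pos, aa = pm.forward[ref_pos]
    return aa, q_pos


def read_fasta_records(path, offsets: dict[str, int] | None = None) -> list[ProteinRecord]:
    """Read protein FASTA into records; ``offsets`` maps id -> numbering_offset."""
    from Bio import SeqIO

    offsets = offsets or {}
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), offsets.get(rec.id, 0)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
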