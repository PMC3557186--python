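"""Ortholog-group conservation statistics.

Identity matrices under an explicit gap policy (pairwise deletion by
default), rounded group means for comparison with percent-identity figures,
clade-diagnostic residues (uniform within a clade, absent outside it) and
per-taxon unique positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aligner import GAP, MSA, pairwise_identity


@dataclass(frozen=True)
class IdentityMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray  # square, NaN for undefined pairs
    gap_policy: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass(frozen=True)
class DiagnosticResidue:
    column: int  # 1-based alignment column
    clade: tuple[str, ...]
    clade_residue: str
    complement_residues: tuple[str, ...]


def identity_matrix(msa: MSA, gap_policy: str = "exclude-gap-columns") -> IdentityMatrix:
    if len(msa.ids) < 2:
        raise ValueError("identity_matrix: need at least 2 rows")
    n = len(msa.ids)
    mat = np.ones((n, n))
    for i in range(n):
        mat[i, i] = pairwise_identity(msa.rows[i], msa.rows[i], gap_policy)
        for j in range(i + 1, n):
            v = pairwise_identity(msa.rows[i], msa.rows[j], gap_policy)
            mat[i, j] = mat[j, i] = v
    return IdentityMatrix(ids=msa.ids, matrix=mat, gap_policy=gap_policy)


def group_mean_identity(matrix: IdentityMatrix) -> int:
    """Mean pairwise identity over distinct pairs, as integer percent.

    Undefined (NaN) pairs are excluded; rounding is half-up to match the
    conventional "on average N% identical" phrasing.
    """
    n = len(matrix.ids)
    vals = [
        matrix.matrix[i, j]
        for i in range(n)
        for j in range(i + 1, n)
        if not math.isnan(matrix.matrix[i, j])
    ]
    if not vals:
        raise ValueError("group_mean_identity: no defined pairs")
    pct = 100.0 * sum(vals) / len(vals)
    return int(math.floor(pct + 0.5))


def diagnostic_residues(
    msa: MSA, partition: dict[str, str], skip_gap_columns: bool = True
) -> list[DiagnosticResidue]:
    """Columns where one clade is uniform for a residue never seen outside it.

    ``partition`` maps every MSA id to a clade label; a missing id is an
    error. Columns containing a gap are skipped under the default policy.
    """
    missing = set(msa.ids) - set(partition)
    if missing:
        raise KeyError(f"ids missing from partition: {sorted(missing)}")
    clades: dict[str, list[int]] = {}
    for i, sid in enumerate(msa.ids):
        clades.setdefault(partition[sid], []).append(i)

    out: list[DiagnosticResidue] = []
    for col in range(msa.n_cols):
        column = [row[col] for row in msa.rows]
        if skip_gap_columns and GAP in column:
            continue
        for clade_label, members in clades.items():
            inside = {column[i] for i in members}
            if len(inside) != 1:
                continue
            residue = inside.pop()
            outside = [column[i] for i in range(len(column)) if i not in members]
            if not outside or residue in outside:
                continue
            out.append(
                DiagnosticResidue(
                    column=col + 1,
                    clade=tuple(msa.ids[i] for i in members),
                    clade_residue=residue,
                    complement_residues=tuple(sorted(set(outside))),
                )
            )
    return out


def taxon_unique_positions(msa: MSA) -> tuple[dict[str, int], int]:
    """Per-taxon counts of columns where exactly one row differs.

    A column counts for taxon t when every other row carries one identical
    residue and t carries a different one (strict one-row-differs rule).
    Returns (per-taxon counts, total).
    """
    if len(msa.ids) < 3:
        raise ValueError("taxon_unique_positions: need at least 3 rows")
    counts = {sid: 0 for sid in msa.ids}
    total = 0
    for col in range(msa.n_cols):
        column = [row[col] for row in msa.rows]
        tally: dict[str, list[int]] = {}
        for i, ch in enumerate(column):
            tally.setdefault(ch, []).append(i)
        if len(tally) != 2:
            continue
        (r1, idx1), (r2, idx2) = tally.items()
        if len(idx1) == 1 and len(idx2) > 1:
            counts[msa.ids[idx1[0]]] += 1
            total += 1
        elif len(idx2) == 1 and len(idx1) > 1:
            counts[msa.ids[idx2[0]]] += 1
            total += 1
    return counts, total
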