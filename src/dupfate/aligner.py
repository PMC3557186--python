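"""Deterministic pairwise global alignment and multiple-alignment I/O.

The aligner is an affine-gap (Gotoh) global aligner: a gap of length L costs
``gap_open + gap_extend * L``. Traceback is deterministic with the tie-break
order substitution > gap-in-b > gap-in-a, so identical inputs always give
identical alignments. Multiple alignments are normally *consumed* (aligned
FASTA); :func:`star_msa` is a convenience that merges pairwise alignments
around a center sequence for callers that have none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import IUPAC_DNA

GAP = "-"

_PROTEIN_ONLY = set("EFILPQZ*")  # symbols that cannot be IUPAC DNA


@dataclass(frozen=True)
class ScoringParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0   # positive penalty, charged once per gap
    gap_extend: float = 0.5  # positive penalty per gap column

    def as_dict(self) -> dict:
        return {
            "match": self.match,
            "mismatch": self.mismatch,
            "gap_open": self.gap_open,
            "gap_extend": self.gap_extend,
        }


#: BLOSUM62-style defaults for protein input.
PROTEIN_PARAMS = ScoringParams(match=4.0, mismatch=-2.0, gap_open=11.0, gap_extend=1.0)


@dataclass(frozen=True)
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    parameters: ScoringParams


def _alphabet_of(seq: str) -> str:
    up = set(seq.upper())
    if up & _PROTEIN_ONLY:
        return "protein"
    if up <= set(IUPAC_DNA) | {"U"}:
        return "dna"
    return "protein"


def global_align(
    a: str, b: str, params: ScoringParams | None = None
) -> AlignmentResult:
    """Optimal global alignment of two sequences under affine-gap scoring.

    IUPAC ambiguity symbols score as mismatches unless literally identical.
    Tie-break order in the traceback: substitution, then gap in ``b``
    (a-residue over '-'), then gap in ``a``.
    """
    if not a or not b:
        raise ValueError("global_align: empty sequence")
    if _alphabet_of(a) != _alphabet_of(b):
        raise ValueError("global_align: mixed alphabets")
    if params is None:
        params = ScoringParams() if _alphabet_of(a) == "dna" else PROTEIN_PARAMS

    a, b = a.upper(), b.upper()
    n, m = len(a), len(b)
    match, mism = params.match, params.mismatch
    go, ge = params.gap_open, params.gap_extend
    NEG = -np.inf

    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)

    # State matrices: M substitution, X gap-in-b (consumes a), Y gap-in-a.
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    X[1:, 0] = -(go + ge * np.arange(1, n + 1))
    Y[0, 1:] = -(go + ge * np.arange(1, m + 1))

    jj = np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], match, mism)
        Hprev = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = Hprev[:-1] + sub
        X[i] = np.maximum(
            np.maximum(M[i - 1], Y[i - 1]) - (go + ge), X[i - 1] - ge
        )
        X[i, 0] = -(go + ge * i)
        # Horizontal (gap-in-a) via prefix max: Y[i,j] = max_{k<j} G[k]-go-ge*(j-k)
        G = np.maximum(M[i], X[i])
        P = np.maximum.accumulate(G + ge * jj)
        Y[i, 1:] = P[:-1] - go - ge * jj[1:]
        Y[i, 0] = NEG

    score = max(M[n, m], X[n, m], Y[n, m])

    # Deterministic traceback; values are exact sums of 0.5 multiples.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    if M[n, m] == score:
        state = "M"
    elif X[n, m] == score:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mism
            prev = M[i, j] - s
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i, j = i - 1, j - 1
            state = _pick(M[i, j], X[i, j], Y[i, j], prev)
        elif state == "X":
            prev = X[i, j]
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
            if M[i, j] - (go + ge) == prev:
                state = "M"
            elif X[i, j] - ge == prev:
                state = "X"
            else:
                state = "Y"
        else:  # Y
            prev = Y[i, j]
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
            if M[i, j] - (go + ge) == prev:
                state = "M"
            elif X[i, j] - (go + ge) == prev:
                state = "X"
            else:
                state = "Y"
        if i == 0 and j == 0:
            break
    return AlignmentResult(
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(score),
        parameters=params,
    )


def _pick(m: float, x: float, y: float, target: float) -> str:
    if m == target:
        return "M"
    if x == target:
        return "X"
    return "Y"


# ---------------------------------------------------------------------------
# Identity
# ---------------------------------------------------------------------------


def pairwise_identity(
    row_a: str, row_b: str, gap_policy: str = "exclude-gap-columns"
) -> float:
    """Fraction of identical counted columns between two aligned rows.

    Under ``exclude-gap-columns`` any column with a gap in either row is not
    counted; under ``gaps-mismatch`` single-gap columns count as mismatches
    (double-gap columns are never counted). Returns NaN when no column is
    counted (undefined identity).
    """
    if len(row_a) != len(row_b):
        raise ValueError("pairwise_identity: length mismatch")
    if gap_policy not in {"exclude-gap-columns", "gaps-mismatch"}:
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    matches = counted = 0
    for x, y in zip(row_a.upper(), row_b.upper()):
        if x == GAP and y == GAP:
            continue
        if x == GAP or y == GAP:
            if gap_policy == "gaps-mismatch":
                counted += 1
            continue
        counted += 1
        if x == y:
            matches += 1
    if counted == 0:
        return float("nan")
    return matches / counted


# ---------------------------------------------------------------------------
# MSA container and aligned-FASTA I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MSA:
    ids: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("MSA: ids and rows differ in number")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("MSA: duplicate ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("MSA: ragged rows")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise KeyError(f"id {seq_id!r} not in MSA") from None


def read_msa(path: str | Path, alphabet: str = "dna") -> MSA:
    """Read an aligned FASTA; ragged or empty input is rejected."""
    try:
        aln = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise ValueError(f"cannot read MSA from {path}: {exc}") from exc
    return MSA(
        ids=tuple(rec.id for rec in aln),
        rows=tuple(str(rec.seq).upper() for rec in aln),
        alphabet=alphabet,
    )


def write_msa(msa: MSA, path: str | Path) -> None:
    aln = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=i, description="") for i, row in zip(msa.ids, msa.rows)]
    )
    with open(path, "w") as fh:
        AlignIO.write(aln, fh, "fasta")


# ---------------------------------------------------------------------------
# Center-star multiple alignment (convenience built on global_align)
# ---------------------------------------------------------------------------


def star_msa(
    seqs: dict[str, str],
    center_id: str,
    params: ScoringParams | None = None,
    alphabet: str = "dna",
) -> MSA:
    """Merge pairwise global alignments against a center sequence into an MSA.

    Standard center-star merge: insertions relative to the center are padded
    to the maximum insertion length seen at each center position. This is a
    convenience for callers without a precomputed alignment; for distant
    sequences a dedicated MSA tool will do better.
    """
    if center_id not in seqs:
        raise KeyError(f"center id {center_id!r} not among sequences")
    center = seqs[center_id]
    others = [i for i in seqs if i != center_id]
    pair: dict[str, AlignmentResult] = {
        i: global_align(center, seqs[i], params) for i in others
    }

    # ins[k] = max inserted columns after k center residues (k = 0..len).
    ins: dict[int, int] = {}
    for res in pair.values():
        k = run = 0
        for ca in res.aligned_a:
            if ca == GAP:
                run += 1
            else:
                if run:
                    ins[k] = max(ins.get(k, 0), run)
                    run = 0
                k += 1
        if run:
            ins[k] = max(ins.get(k, 0), run)

    def build_center() -> str:
        out = [GAP * ins.get(0, 0)]
        for k, ch in enumerate(center, start=1):
            out.append(ch)
            out.append(GAP * ins.get(k, 0))
        return "".join(out)

    def rebuild(res: AlignmentResult) -> str:
        out = []
        k = 0
        buf: list[str] = []
        for ca, cb in zip(res.aligned_a, res.aligned_b):
            if ca == GAP:
                buf.append(cb)
            else:
                out.append("".join(buf) + GAP * (ins.get(k, 0) - len(buf)))
                buf = []
                out.append(cb)
                k += 1
        out.append("".join(buf) + GAP * (ins.get(k, 0) - len(buf)))
        return "".join(out)

    ids = [center_id] + others
    rows = [build_center()] + [rebuild(pair[i]) for i in others]
    return MSA(ids=tuple(ids), rows=tuple(rows), alphabet=alphabet)
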