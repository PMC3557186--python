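"""Counting-based dN/dS (Nei–Gojobori 1986) screen for coding pairs.

For each codon, the number of synonymous sites is the fraction of one-step
mutations that preserve the amino acid (summed over the three positions,
each contributing syn/3). Differences between two codons are resolved by
averaging over all orderings of single-step changes, excluding pathways that
pass through a stop codon. Proportions are Jukes–Cantor corrected,
``d = -(3/4) ln(1 - (4/3) p)``, and omega = dN/dS. This is a screen-level
statistic — no branch models, no likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import pandas as pd

from ._seq import GENETIC_CODE, STOP_CODONS
from .aligner import GAP, MSA

_BASES = "ACGT"


def synonymous_sites(codon: str) -> float:
    """Fractional synonymous site count in [0, 3] for one sense codon."""
    codon = codon.upper()
    aa = GENETIC_CODE.get(codon)
    if aa is None:
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    if aa == "*":
        raise ValueError(f"stop codon {codon!r} has no site count")
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if GENETIC_CODE[mutant] == aa:
                syn += 1
    return syn / 3.0


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons.

    Multi-substitution codons are averaged over all orderings of single
    steps; orderings passing through a stop codon are excluded (when every
    ordering is blocked, all are used with stop treated as its own state).
    """
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for frm, to in steps:
            if GENETIC_CODE[frm] == GENETIC_CODE[to]:
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


@dataclass(frozen=True)
class CodonPair:
    """Two codon-aligned sequences with gap-containing codon columns removed."""

    seq_a: str
    seq_b: str
    removed_codons: int

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("CodonPair: unequal lengths")
        if len(self.seq_a) % 3:
            raise ValueError("CodonPair: length not a multiple of 3")
        for seq, label in ((self.seq_a, "a"), (self.seq_b, "b")):
            for i in range(0, len(seq) - 3, 3):  # terminal stop permitted
                if seq[i : i + 3] in STOP_CODONS:
                    raise ValueError(
                        f"CodonPair: internal stop codon in sequence {label} "
                        f"at codon {i // 3 + 1}"
                    )


def make_codon_pair(a: str, b: str) -> CodonPair:
    """Strip gap-containing codon columns from two aligned coding sequences."""
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in length")
    if len(a) % 3:
        raise ValueError("aligned length not a multiple of 3")
    keep_a, keep_b = [], []
    removed = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3].upper(), b[i : i + 3].upper()
        if GAP in ca or GAP in cb:
            removed += 1
            continue
        keep_a.append(ca)
        keep_b.append(cb)
    return CodonPair(seq_a="".join(keep_a), seq_b="".join(keep_b), removed_codons=removed)


@dataclass(frozen=True)
class DnDsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # NaN when undefined (saturation)
    dN: float
    omega: float  # NaN when undefined (dS == 0 or saturated)
    removed_codons: int
    flags: tuple[str, ...]


def _jc(p: float) -> tuple[float, bool]:
    if p == 0.0:
        return 0.0, False
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        return float("nan"), True
    import math

    return -0.75 * math.log(arg), False


def ng86(a: str, b: str) -> DnDsResult:
    """NG86 dN/dS for one aligned coding pair (gap codons removed first)."""
    pair = make_codon_pair(a, b)
    ncod = len(pair.seq_a) // 3
    if ncod == 0:
        raise ValueError("ng86: no ungapped codon columns")
    # Trim a shared terminal stop: it is not part of the coding comparison.
    if (
        pair.seq_a[-3:] in STOP_CODONS or pair.seq_b[-3:] in STOP_CODONS
    ):
        pair = CodonPair(pair.seq_a[:-3], pair.seq_b[:-3], pair.removed_codons)
        ncod -= 1
        if ncod == 0:
            raise ValueError("ng86: nothing left after trimming terminal stop")

    s_a = s_b = sd = nd = 0.0
    for i in range(0, ncod * 3, 3):
        ca, cb = pair.seq_a[i : i + 3], pair.seq_b[i : i + 3]
        s_a += synonymous_sites(ca)
        s_b += synonymous_sites(cb)
        dsd, dnd = _codon_differences(ca, cb)
        sd += dsd
        nd += dnd
    S = (s_a + s_b) / 2.0
    N = 3.0 * ncod - S
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    dS, satS = _jc(pS)
    dN, satN = _jc(pN)

    flags = []
    if satS or satN:
        flags.append("saturation")
        omega = float("nan")
    elif dS == 0.0:
        flags.append("omega-undefined")
        omega = float("nan")
    else:
        omega = dN / dS
    return DnDsResult(
        S=S, N=N, Sd=sd, Nd=nd, pS=pS, pN=pN, dS=dS, dN=dN,
        omega=omega, removed_codons=pair.removed_codons, flags=tuple(flags),
    )


def pairwise_screen(msa: MSA) -> pd.DataFrame:
    """NG86 for all unordered pairs of a codon MSA; failures flagged, not dropped."""
    rows = []
    n = len(msa.ids)
    for i in range(n):
        for j in range(i + 1, n):
            ida, idb = msa.ids[i], msa.ids[j]
            base = {"id_a": ida, "id_b": idb}
            try:
                r = ng86(msa.rows[i], msa.rows[j])
            except ValueError as exc:
                rows.append({**base, "flags": f"error:{exc}"})
                continue
            rows.append(
                {
                    **base,
                    "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
                    "pS": r.pS, "pN": r.pN, "dS": r.dS, "dN": r.dN,
                    "omega": r.omega, "removed_codons": r.removed_codons,
                    "flags": ";".join(r.flags),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "id_a", "id_b", "S", "N", "Sd", "Nd", "pS", "pN",
            "dS", "dN", "omega", "removed_codons", "flags",
        ],
    )
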