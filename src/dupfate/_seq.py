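"""Shared nucleotide/protein alphabet tables and the standard genetic code.

IUPAC degenerate matching is central to the motif machinery: a subject symbol
matches a pattern symbol iff the subject's possible bases are a subset of the
pattern's (conservative matching — an ``N`` in the subject never matches ``Y``).
"""

from __future__ import annotations

from Bio.Data import CodonTable

# IUPAC nucleotide code -> set of concrete bases.
IUPAC_DNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_standard = CodonTable.unambiguous_dna_by_id[1]
#: codon -> one-letter amino acid, with '*' for the three terminators.
GENETIC_CODE: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    GENETIC_CODE[_stop] = "*"

STOP_CODONS = frozenset(_standard.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if GENETIC_CODE[c] != "*"))

# Transition partners under the purine/pyrimidine classes (K80).
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def normalize_dna(seq: str) -> str:
    """Uppercase, convert RNA U to T, and validate against the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(IUPAC_DNA) - {"-"}
    if bad:
        raise ValueError(f"non-IUPAC nucleotide symbol(s): {sorted(bad)!r}")
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def symbol_matches(subject: str, pattern: str) -> bool:
    """True iff the subject symbol's base set is a subset of the pattern's."""
    try:
        return IUPAC_DNA[subject] <= IUPAC_DNA[pattern]
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC symbol: {exc.args[0]!r}") from None


def translate_codon(codon: str) -> str:
    """Translate one codon; degenerate codons give 'X' unless every resolution
    yields the same amino acid (e.g. GGN -> G, TAR -> *)."""
    if codon in GENETIC_CODE:
        return GENETIC_CODE[codon]
    options = set()
    for b1 in IUPAC_DNA[codon[0]]:
        for b2 in IUPAC_DNA[codon[1]]:
            for b3 in IUPAC_DNA[codon[2]]:
                options.add(GENETIC_CODE[b1 + b2 + b3])
                if len(options) > 1:
                    return "X"
    return options.pop()
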