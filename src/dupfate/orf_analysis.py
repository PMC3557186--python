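"""Gene-fate calling: translation, premature-stop detection, alternative-start
rescue and proteolytic cleavage-motif location.

A duplicate gene is called a pseudogene when its reading frame terminates well
before the span expected from an intact ortholog (a premature termination
codon, PTC). Before making that call, a nearby upstream in-frame ATG is tried:
a frameshifted annotated start can be rescued by an alternative initiator that
restores a complete open reading frame — a documented fate in real gene
families, distinct from both "intact" and "pseudogene".
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

from ._seq import GENETIC_CODE, normalize_dna, translate_codon
from .gene_models import GeneModel, SplicedGene, splice

# Furin / prohormone-convertase consensus R-X-[KR]-R, the motif whose intact
# coding distinguishes a cleavable precursor from a dead one.
DEFAULT_CLEAVAGE_MOTIF = "RX[KR]R"

INTACT = "INTACT"
PSEUDOGENE = "PSEUDOGENE"
RESCUED_ALT_START = "RESCUED_ALT_START"
NO_TERMINATOR = "NO_TERMINATOR"


@dataclass(frozen=True)
class TranslationResult:
    protein: str
    partial_codon: bool  # trailing incomplete codon was dropped


@dataclass(frozen=True)
class OrfReport:
    gene_id: str
    status: str
    start_used: int  # 1-based mRNA position of the start actually used
    protein: str
    stop_positions: tuple[tuple[int, int], ...]  # (codon index, mRNA pos), 1-based
    premature_stops: tuple[tuple[int, int], ...]
    rescue_start: int | None = None
    cleavage_site: tuple[int, str] | None = None  # (1-based protein pos, text)

    def __post_init__(self) -> None:
        if self.status in {INTACT, RESCUED_ALT_START} and self.premature_stops:
            raise ValueError(f"{self.status} report carries premature stops")


def translate(cds: str) -> TranslationResult:
    """Standard-code translation; stops are '*', degenerate codons 'X' unless
    all resolutions agree; a trailing partial codon is dropped and flagged."""
    s = normalize_dna(cds)
    if len(s) < 3:
        raise ValueError("translate: sequence shorter than one codon")
    aas = [translate_codon(s[i : i + 3]) for i in range(0, len(s) - 2, 3)]
    return TranslationResult(protein="".join(aas), partial_codon=len(s) % 3 != 0)


def scan_stops(mrna: str, start: int) -> list[tuple[int, int]]:
    """All in-frame stop codons downstream of a 1-based start position.

    Returns (codon index, mRNA position) pairs, both 1-based; the position is
    the first nucleotide of the stop codon.
    """
    s = normalize_dna(mrna)
    if not 1 <= start <= len(s):
        raise ValueError(f"start {start} outside mRNA of length {len(s)}")
    stops = []
    idx = 0
    for i in range(start - 1, len(s) - 2, 3):
        idx += 1
        if GENETIC_CODE.get(s[i : i + 3]) == "*":
            stops.append((idx, i + 1))
    return stops


def _orf_span(mrna: str, start0: int) -> tuple[int | None, list[tuple[int, int]]]:
    """First in-frame stop (codon index) from 0-based start, plus all stops."""
    stops = scan_stops(mrna, start0 + 1)
    return (stops[0][0] if stops else None), stops


def attempt_alt_start(
    mrna: str,
    annotated_start: int,
    window: int = 90,
    min_codons: int = 1,
    exon_bounds: tuple[int, int] | None = None,
) -> int | None:
    """Nearest upstream ATG whose frame yields a complete ORF.

    ``annotated_start`` is 1-based. A candidate rescues when its frame reaches
    a terminal stop with at least ``min_codons`` codons before it. When
    ``exon_bounds`` (1-based inclusive mRNA interval) is given, candidates
    outside it are ignored (same-exon constraint). Returns the 1-based rescue
    position or None.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    s = normalize_dna(mrna)
    lo = max(0, annotated_start - 1 - window)
    candidates = [
        p for p in range(annotated_start - 2, lo - 1, -1) if s[p : p + 3] == "ATG"
    ]
    for p in candidates:  # nearest first
        if exon_bounds is not None and not (
            exon_bounds[0] <= p + 1 <= exon_bounds[1]
        ):
            continue
        first_stop, _ = _orf_span(s, p)
        if first_stop is not None and first_stop - 1 >= min_codons:
            return p + 1
    return None


def locate_cleavage_site(
    protein: str, motif: str = DEFAULT_CLEAVAGE_MOTIF, all_matches: bool = False
):
    """First (or all) occurrence(s) of a degenerate protein motif.

    The motif grammar: one-letter amino acids, ``X`` for any residue, and
    ``[..]`` character classes — e.g. the default furin/PC site ``RX[KR]R``.
    Returns (1-based position, matched text), a list of such in detail mode,
    or None.
    """
    pattern = re.compile(motif.replace("X", "."))
    hits = [(m.start() + 1, m.group()) for m in pattern.finditer(protein)]
    if all_matches:
        return hits
    return hits[0] if hits else None


def classify_status(
    spliced: SplicedGene,
    reference: GeneModel | SplicedGene | None = None,
    min_fraction: float = 0.9,
    min_codons: int = 100,
    alt_start_window: int = 90,
    cleavage_motif: str = DEFAULT_CLEAVAGE_MOTIF,
) -> OrfReport:
    """Call the fate of one spliced gene.

    A gene is INTACT when the ORF from its annotated start (or first ATG)
    reaches a terminal stop covering the expected span: >= ``min_fraction`` of
    the reference protein length when a reference is given, else
    >= ``min_codons`` codons. Otherwise an upstream alternative initiator is
    tried (RESCUED_ALT_START); failing that the gene is a PSEUDOGENE (with
    stop-codon evidence) or NO_TERMINATOR.
    """
    mrna = spliced.mrna
    gene = spliced.gene
    if gene.annotated_cds_start is not None:
        start0 = gene.annotated_cds_start
    else:
        pos = mrna.find("ATG")
        if pos < 0:
            raise ValueError(f"gene {gene.gene_id!r}: no ATG and no annotated start")
        start0 = pos

    expected = _expected_codons(reference, min_fraction, min_codons)
    first_stop, stops = _orf_span(mrna, start0)

    def protein_from(p0: int) -> str:
        usable = len(mrna) - p0 - ((len(mrna) - p0) % 3)
        if usable < 3:
            return ""
        res = translate(mrna[p0 : p0 + usable])
        return res.protein.split("*")[0]

    if first_stop is not None and first_stop - 1 >= expected:
        prot = protein_from(start0)
        return OrfReport(
            gene_id=gene.gene_id,
            status=INTACT,
            start_used=start0 + 1,
            protein=prot,
            stop_positions=tuple(stops),
            premature_stops=(),
            cleavage_site=locate_cleavage_site(prot, cleavage_motif),
        )

    exon_idx = spliced.exon_of_mrna_pos(start0)
    bounds = _exon_mrna_bounds(spliced, exon_idx)
    rescue = attempt_alt_start(
        mrna,
        start0 + 1,
        window=alt_start_window,
        min_codons=expected,
        exon_bounds=bounds,
    )
    if rescue is not None:
        prot = protein_from(rescue - 1)
        _, rstops = _orf_span(mrna, rescue - 1)
        return OrfReport(
            gene_id=gene.gene_id,
            status=RESCUED_ALT_START,
            start_used=rescue,
            protein=prot,
            stop_positions=tuple(rstops),
            premature_stops=(),
            rescue_start=rescue,
            cleavage_site=locate_cleavage_site(prot, cleavage_motif),
        )

    prot = protein_from(start0)
    if first_stop is None:
        status = NO_TERMINATOR
        premature: tuple = ()
    else:
        status = PSEUDOGENE
        premature = tuple((c, p) for c, p in stops if c - 1 < expected)
    return OrfReport(
        gene_id=gene.gene_id,
        status=status,
        start_used=start0 + 1,
        protein=prot,
        stop_positions=tuple(stops),
        premature_stops=premature,
        cleavage_site=locate_cleavage_site(prot, cleavage_motif),
    )


def _expected_codons(
    reference, min_fraction: float, min_codons: int
) -> int:
    if reference is None:
        return min_codons
    spliced = reference if isinstance(reference, SplicedGene) else splice(reference)
    if spliced.cds:
        ref_len = len(spliced.cds) // 3 - (
            1 if GENETIC_CODE.get(spliced.cds[-3:]) == "*" else 0
        )
    else:
        start = spliced.mrna.find("ATG")
        first_stop, _ = _orf_span(spliced.mrna, max(start, 0))
        ref_len = (first_stop - 1) if first_stop else len(spliced.mrna) // 3
    return max(1, math.ceil(min_fraction * ref_len))


def _exon_mrna_bounds(spliced: SplicedGene, exon_index: int) -> tuple[int, int]:
    """1-based inclusive mRNA interval covered by the given exon (1-based)."""
    off = 0
    for i, (s, e) in enumerate(spliced.gene.exons, start=1):
        width = e - s
        if i == exon_index:
            return (off + 1, off + width)
        off += width
    raise IndexError(f"exon {exon_index} out of range")


def orf_table(reports: list[OrfReport]):
    """TSV-ready gene-fate table."""
    import pandas as pd

    rows = [
        {
            "gene_id": r.gene_id,
            "status": r.status,
            "start_used": r.start_used,
            "n_premature_stops": len(r.premature_stops),
            "first_stop_codon_index": r.stop_positions[0][0] if r.stop_positions else pd.NA,
            "rescue_start": r.rescue_start if r.rescue_start is not None else pd.NA,
            "cleavage_site_pos": r.cleavage_site[0] if r.cleavage_site else pd.NA,
        }
        for r in reports
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id", "status", "start_used", "n_premature_stops",
            "first_stop_codon_index", "rescue_start", "cleavage_site_pos",
        ],
    )
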