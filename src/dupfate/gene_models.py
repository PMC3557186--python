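"""Gene models: validated exon/intron structures and splicing.

A :class:`GeneModel` is one genomic gene — its sequence plus ordered exon
intervals. Internally all coordinates are 0-based half-open; every file format
and report uses 1-based inclusive coordinates (the convention of the genomics
literature this package serves). :func:`splice` turns a gene into its
pre-mRNA/mRNA/intron decomposition, which every downstream stage consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO

from ._seq import GENETIC_CODE, normalize_dna, reverse_complement

log = logging.getLogger(__name__)

PARALOG_LABELS = ("1a", "1b", "2a", "2b", "other")


class GeneValidationError(ValueError):
    """Raised when a gene model violates a structural invariant."""


class GeneLoadError(ValueError):
    """Raised when an input file cannot be resolved into gene models."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: sequence plus ordered exon intervals (0-based half-open)."""

    gene_id: str
    species: str
    paralog_label: str
    sequence: str
    exons: tuple[tuple[int, int], ...]
    annotated_cds_start: int | None = None  # 0-based position in spliced mRNA
    missing_features: frozenset[str] = frozenset()  # e.g. {"exon1", "intron2"}

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_dna(self.sequence))
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))
        validate_gene(self)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intervals between consecutive exons (may be empty intervals)."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)


def validate_gene(gene: GeneModel) -> None:
    exons = gene.exons
    if not exons:
        raise GeneValidationError(f"gene {gene.gene_id!r}: no exons")
    if gene.paralog_label not in PARALOG_LABELS:
        raise GeneValidationError(
            f"gene {gene.gene_id!r}: paralog_label {gene.paralog_label!r} "
            f"not in {PARALOG_LABELS}"
        )
    n = len(gene.sequence)
    prev_end = None
    for start, end in exons:
        if not (0 <= start < end <= n):
            raise GeneValidationError(
                f"gene {gene.gene_id!r}: exon ({start}, {end}) out of bounds "
                f"for sequence of length {n}"
            )
        if prev_end is not None and start < prev_end:
            raise GeneValidationError(
                f"gene {gene.gene_id!r}: exons overlap or are unsorted at "
                f"({start}, {end})"
            )
        if prev_end is not None and start == prev_end:
            log.warning(
                "gene %s: abutting exons at %d produce a zero-length intron",
                gene.gene_id, start,
            )
        prev_end = end
    if gene.annotated_cds_start is not None:
        mrna_len = sum(e - s for s, e in exons)
        if not (0 <= gene.annotated_cds_start < mrna_len):
            raise GeneValidationError(
                f"gene {gene.gene_id!r}: annotated_cds_start "
                f"{gene.annotated_cds_start} outside mRNA of length {mrna_len}"
            )


@dataclass(frozen=True)
class SplicedGene:
    """A gene together with its spliced decomposition.

    ``mrna`` is the exon concatenation 5'->3'; ``introns`` carries each intron
    sequence with its gene-level interval. ``cds`` runs from the annotated CDS
    start to the first in-frame terminator (or mRNA end).
    """

    gene: GeneModel
    premrna: str
    mrna: str
    introns: tuple[tuple[str, tuple[int, int]], ...]
    cds: str | None

    def mrna_to_gene(self, pos: int) -> int:
        """Map a 0-based mRNA position to its 0-based gene position."""
        if not 0 <= pos < len(self.mrna):
            raise IndexError(f"mRNA position {pos} out of range")
        off = 0
        for start, end in self.gene.exons:
            width = end - start
            if pos < off + width:
                return start + (pos - off)
            off += width
        raise AssertionError("unreachable")

    def gene_to_mrna(self, pos: int) -> int | None:
        """Map a 0-based gene position to mRNA; None for intronic positions."""
        off = 0
        for start, end in self.gene.exons:
            if start <= pos < end:
                return off + (pos - start)
            off += end - start
        return None

    def exon_of_mrna_pos(self, pos: int) -> int:
        """1-based index of the exon containing a 0-based mRNA position."""
        off = 0
        for i, (start, end) in enumerate(self.gene.exons, start=1):
            off += end - start
            if pos < off:
                return i
        raise IndexError(f"mRNA position {pos} out of range")


def splice(gene: GeneModel) -> SplicedGene:
    """Assemble mRNA and introns from the exon intervals."""
    seq = gene.sequence
    mrna = "".join(seq[s:e] for s, e in gene.exons)
    introns = tuple((seq[s:e], (s, e)) for s, e in gene.introns)
    cds = None
    if gene.annotated_cds_start is not None:
        cds = _cds_from(mrna, gene.annotated_cds_start)
    return SplicedGene(gene=gene, premrna=seq, mrna=mrna, introns=introns, cds=cds)


def _cds_from(mrna: str, start: int) -> str:
    out = []
    for i in range(start, len(mrna) - 2, 3):
        codon = mrna[i : i + 3]
        out.append(codon)
        if GENETIC_CODE.get(codon) == "*":
            break
    return "".join(out)


# ---------------------------------------------------------------------------
# File I/O: FASTA + (GFF3 subset | 6-column TSV) feature tables
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("gene_id", "species", "paralog", "exon_index", "start", "end")


def load_genes(sequence_file: str | Path, feature_file: str | Path) -> list[GeneModel]:
    """Load gene models from a FASTA plus a GFF3-or-TSV exon table.

    Feature coordinates are 1-based inclusive in files and converted to the
    internal 0-based half-open convention here. Reverse-strand GFF3 features
    are normalized to the coding strand (sequence reverse-complemented,
    intervals flipped) with a log note.
    """
    sequence_file, feature_file = Path(sequence_file), Path(feature_file)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(sequence_file), "fasta"):
        seqs[rec.id] = normalize_dna(str(rec.seq))
    if not seqs:
        raise GeneLoadError(f"no FASTA records in {sequence_file}")

    text = feature_file.read_text()
    if _looks_like_gff3(text, feature_file):
        records = _parse_gff3(text)
    else:
        records = _parse_tsv(text)
    if not records:
        raise GeneLoadError(f"no exon records in {feature_file}")

    by_gene: dict[str, list[dict]] = {}
    for rec in records:
        by_gene.setdefault(rec["gene_id"], []).append(rec)

    genes = []
    for gene_id, rows in by_gene.items():
        if gene_id not in seqs:
            raise GeneLoadError(
                f"feature table references sequence id {gene_id!r} absent "
                f"from {sequence_file}"
            )
        seq = seqs[gene_id]
        strands = {r.get("strand", "+") for r in rows}
        if strands == {"-"}:
            log.info("gene %s: reverse strand, normalizing to coding strand", gene_id)
            n = len(seq)
            seq = reverse_complement(seq)
            for r in rows:
                r["start"], r["end"] = n - r["end"] + 1, n - r["start"] + 1
        elif "-" in strands:
            raise GeneLoadError(f"gene {gene_id!r}: mixed strands in exon records")
        rows.sort(key=lambda r: r["start"])
        exons = tuple((r["start"] - 1, r["end"]) for r in rows)  # to 0-based half-open
        first = rows[0]
        genes.append(
            GeneModel(
                gene_id=gene_id,
                species=first.get("species", "unknown"),
                paralog_label=first.get("paralog", "other"),
                sequence=seq,
                exons=exons,
            )
        )
    return genes


def _looks_like_gff3(text: str, path: Path) -> bool:
    if path.suffix.lower() in {".gff", ".gff3"}:
        return True
    return text.lstrip().startswith("##gff-version")


def _parse_gff3(text: str) -> list[dict]:
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GeneLoadError(f"GFF3 line {lineno}: expected 9 columns")
        seqid, _source, ftype, start, end, _score, strand, _phase, attrs = fields
        if ftype != "exon":
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
        )
        records.append(
            {
                "gene_id": attr.get("gene_id", seqid),
                "species": attr.get("species", "unknown"),
                "paralog": attr.get("paralog", "other"),
                "start": int(start),
                "end": int(end),
                "strand": strand,
            }
        )
    return records


def _parse_tsv(text: str) -> list[dict]:
    records = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if fields == list(TSV_COLUMNS):  # optional header
            continue
        if len(fields) != 6:
            raise GeneLoadError(f"feature TSV line {lineno}: expected 6 columns")
        gene_id, species, paralog, exon_index, start, end = fields
        records.append(
            {
                "gene_id": gene_id,
                "species": species,
                "paralog": paralog,
                "exon_index": int(exon_index),
                "start": int(start),
                "end": int(end),
            }
        )
    records.sort(key=lambda r: (r["gene_id"], r.get("exon_index", 0)))
    return records


def write_features(genes: list[GeneModel], path: str | Path) -> None:
    """Write the 6-column TSV feature dialect (1-based inclusive coordinates).

    Round-trips bit-exactly through :func:`load_genes`.
    """
    lines = ["\t".join(TSV_COLUMNS)]
    for g in genes:
        for i, (s, e) in enumerate(g.exons, start=1):
            lines.append(
                f"{g.gene_id}\t{g.species}\t{g.paralog_label}\t{i}\t{s + 1}\t{e}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(genes: list[GeneModel], path: str | Path) -> None:
    """Plain single-line-per-sequence FASTA (deterministic bytes)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.sequence}\n")


def feature_length_table(genes: list[GeneModel]):
    """Per-gene exon/intron length table (Figure-1-style architecture summary).

    Genes with fewer exons than the widest gene are padded with NA.
    """
    import pandas as pd

    if not genes:
        raise ValueError("feature_length_table: empty gene list")
    kmax = max(g.n_exons for g in genes)
    cols = [f"exon{i}" for i in range(1, kmax + 1)] + [
        f"intron{i}" for i in range(1, kmax)
    ]
    rows = {}
    for g in genes:
        row: dict[str, object] = {c: pd.NA for c in cols}
        for i, (s, e) in enumerate(g.exons, start=1):
            row[f"exon{i}"] = e - s
        for i, (s, e) in enumerate(g.introns, start=1):
            row[f"intron{i}"] = e - s
        for feat in g.missing_features:
            if feat in row:
                row[feat] = pd.NA
        rows[g.gene_id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def with_cds_start(gene: GeneModel, start: int) -> GeneModel:
    return replace(gene, annotated_cds_start=start)
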