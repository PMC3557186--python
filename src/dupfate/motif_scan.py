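"""Degenerate-consensus scanning: splice sites, branch points, YCAY counts.

Transcript-processing capacity is audited at three levels:

* exon/intron boundaries against donor (MAG/GTRAGT or RAG/GTRAGT) and
  acceptor (CAG/G) consensus sequences, with the GT / AG dinucleotides
  immediately flanking each boundary treated as the critical positions;
* branch points, scanned as TNCTRAY within each intron (N = any base,
  R = A/G, Y = C/T), with the distance from motif end to the 3' splice site;
* YCAY tetramers — the recognition element of Nova splicing regulators —
  counted per exon and intron as a proxy for splicing-regulation potential.

Two donor dialects are audited side by side because the field's consensus is
written both as MAG/GTRAGT and RAG/GTRAGT; reports show agreement per dialect
rather than silently choosing one.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import IUPAC_DNA, normalize_dna, symbol_matches
from .gene_models import SplicedGene

#: donor consensus dialects, written exonic/intronic around the boundary "/"
DONOR_CONSENSUS = {"mag": "MAG/GTRAGT", "rag": "RAG/GTRAGT"}
ACCEPTOR_CONSENSUS = {"canonical": "CAG/G"}

BRANCH_POINT_PATTERN = "TNCTRAY"
YCAY_PATTERN = "YCAY"


@dataclass(frozen=True)
class MotifPattern:
    pattern: str
    name: str

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC_DNA)
        if bad:
            raise ValueError(
                f"pattern {self.name!r}: invalid IUPAC symbol(s) {sorted(bad)!r}"
            )
        object.__setattr__(self, "pattern", self.pattern.upper())

    def __len__(self) -> int:
        return len(self.pattern)


@dataclass(frozen=True)
class MotifHit:
    pattern_name: str
    feature_id: str  # "gene", "exon2", "intron1", ...
    start: int       # 1-based within the scanned feature
    gene_start: int  # 1-based within the gene sequence (0 if unanchored)
    matched: str


def scan_iupac(
    seq: str,
    pattern: MotifPattern | str,
    allow_overlap: bool = True,
    feature_id: str = "gene",
    gene_offset: int = 0,
) -> list[MotifHit]:
    """Every window of ``seq`` matching the degenerate pattern.

    A subject symbol matches a pattern symbol iff the subject's possible
    bases are a subset of the pattern's. Overlapping windows are reported
    when ``allow_overlap`` (the default), otherwise matching restarts after
    each hit. ``gene_offset`` anchors feature-relative starts to gene
    coordinates (0-based offset of the feature within the gene).
    """
    if isinstance(pattern, str):
        pattern = MotifPattern(pattern=pattern, name=pattern)
    s = normalize_dna(seq)
    k = len(pattern)
    hits: list[MotifHit] = []
    i = 0
    while i <= len(s) - k:
        window = s[i : i + k]
        if all(symbol_matches(w, p) for w, p in zip(window, pattern.pattern)):
            hits.append(
                MotifHit(
                    pattern_name=pattern.name,
                    feature_id=feature_id,
                    start=i + 1,
                    gene_start=gene_offset + i + 1,
                    matched=window,
                )
            )
            i += 1 if allow_overlap else k
        else:
            i += 1
    return hits


# ---------------------------------------------------------------------------
# Splice-site auditing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConsensusAgreement:
    consensus: str                 # e.g. "MAG/GTRAGT"
    agreement: tuple[bool, ...]    # per consensus position, exonic then intronic
    overall_intact: bool


@dataclass(frozen=True)
class SpliceSiteAudit:
    boundary_id: str  # "intron1_donor", "intron2_acceptor", ...
    exonic_context: str
    intronic_context: str
    per_consensus: tuple[ConsensusAgreement, ...]
    critical_intact: bool  # GT at intron +1,+2 (donor) / AG at -2,-1 (acceptor)
    evaluable: bool = True


def _evaluate(exonic: str, intronic: str, consensus: str) -> ConsensusAgreement:
    exo_pat, int_pat = consensus.split("/")
    subject = exonic[-len(exo_pat):] if exo_pat else ""
    subject += intronic[: len(int_pat)]
    pattern = exo_pat + int_pat
    agree = tuple(
        len(subject) > i and symbol_matches(subject[i], pattern[i])
        for i in range(len(pattern))
    )
    return ConsensusAgreement(
        consensus=consensus, agreement=agree, overall_intact=all(agree)
    )


def audit_splice_sites(
    spliced: SplicedGene,
    donor_consensus: dict[str, str] | None = None,
    acceptor_consensus: dict[str, str] | None = None,
) -> list[SpliceSiteAudit]:
    """One audit per donor and acceptor boundary, against every consensus.

    Donor context: last 3 exonic nt + first 6 intronic nt. Acceptor context:
    last 3 intronic nt + first 1 exonic nt. Introns shorter than the context
    windows yield unevaluable audits.
    """
    donor_consensus = donor_consensus or DONOR_CONSENSUS
    acceptor_consensus = acceptor_consensus or ACCEPTOR_CONSENSUS
    gene = spliced.gene
    audits: list[SpliceSiteAudit] = []
    for idx, (intron_seq, (istart, iend)) in enumerate(spliced.introns, start=1):
        exon_before = gene.sequence[gene.exons[idx - 1][0] : gene.exons[idx - 1][1]]
        exon_after = gene.sequence[gene.exons[idx][0] : gene.exons[idx][1]]

        donor_ok = len(intron_seq) >= 6
        exo = exon_before[-3:]
        intr = intron_seq[:6]
        if donor_ok:
            per = tuple(
                _evaluate(exo, intr, c) for _, c in sorted(donor_consensus.items())
            )
            critical = intron_seq[:2] == "GT"
        else:
            per = ()
            critical = False
        audits.append(
            SpliceSiteAudit(
                boundary_id=f"intron{idx}_donor",
                exonic_context=exo,
                intronic_context=intr,
                per_consensus=per,
                critical_intact=critical,
                evaluable=donor_ok,
            )
        )

        acc_ok = len(intron_seq) >= 3
        intr3 = intron_seq[-3:]
        exo1 = exon_after[:1]
        if acc_ok:
            per = tuple(
                _evaluate_acceptor(intr3, exo1, c)
                for _, c in sorted(acceptor_consensus.items())
            )
            critical = intron_seq[-2:] == "AG"
        else:
            per = ()
            critical = False
        audits.append(
            SpliceSiteAudit(
                boundary_id=f"intron{idx}_acceptor",
                exonic_context=exo1,
                intronic_context=intr3,
                per_consensus=per,
                critical_intact=critical,
                evaluable=acc_ok,
            )
        )
    return audits


def _evaluate_acceptor(intronic: str, exonic: str, consensus: str) -> ConsensusAgreement:
    int_pat, exo_pat = consensus.split("/")
    subject = intronic[-len(int_pat):] + (exonic[: len(exo_pat)] if exo_pat else "")
    pattern = int_pat + exo_pat
    agree = tuple(
        len(subject) > i and symbol_matches(subject[i], pattern[i])
        for i in range(len(pattern))
    )
    return ConsensusAgreement(
        consensus=consensus, agreement=agree, overall_intact=all(agree)
    )


def splice_audit_table(gene_id: str, audits: list[SpliceSiteAudit]) -> pd.DataFrame:
    rows = []
    for a in audits:
        row = {
            "gene_id": gene_id,
            "boundary": a.boundary_id,
            "exonic": a.exonic_context,
            "intronic": a.intronic_context,
            "critical_intact": a.critical_intact,
            "evaluable": a.evaluable,
        }
        for agr in a.per_consensus:
            row[f"intact[{agr.consensus}]"] = agr.overall_intact
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Branch points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BranchPointHit:
    intron_index: int
    intron_start: int   # 1-based within the intron
    gene_start: int     # 1-based within the gene
    matched: str
    distance_to_3ss: int  # bases between motif end and the intron 3' end


def find_branch_points(
    spliced: SplicedGene, pattern: str = BRANCH_POINT_PATTERN
) -> dict[int, list[BranchPointHit]]:
    """All branch-point motif hits per intron; introns with no hit map to []."""
    pat = MotifPattern(pattern=pattern, name="branch_point")
    out: dict[int, list[BranchPointHit]] = {}
    for idx, (intron_seq, (istart, _iend)) in enumerate(spliced.introns, start=1):
        hits = scan_iupac(
            intron_seq, pat, feature_id=f"intron{idx}", gene_offset=istart
        )
        out[idx] = [
            BranchPointHit(
                intron_index=idx,
                intron_start=h.start,
                gene_start=h.gene_start,
                matched=h.matched,
                distance_to_3ss=len(intron_seq) - (h.start - 1 + len(pat)),
            )
            for h in hits
        ]
    return out


def branch_point_table(gene_id: str, bp: dict[int, list[BranchPointHit]]) -> pd.DataFrame:
    rows = []
    for idx in sorted(bp):
        if not bp[idx]:
            rows.append(
                {
                    "gene_id": gene_id, "intron": idx, "motif": "NOT FOUND",
                    "gene_pos": pd.NA, "intron_pos": pd.NA, "dist_3ss": pd.NA,
                }
            )
        for h in bp[idx]:
            rows.append(
                {
                    "gene_id": gene_id, "intron": idx, "motif": h.matched,
                    "gene_pos": h.gene_start, "intron_pos": h.intron_start,
                    "dist_3ss": h.distance_to_3ss,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "intron", "motif", "gene_pos", "intron_pos", "dist_3ss"]
    )


# ---------------------------------------------------------------------------
# YCAY counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class YcayTable:
    gene_id: str
    counts: dict[str, int | None]  # feature -> count, None = NA (unsequenced)
    total: int
    partial: bool  # some feature excluded from the total

    def __post_init__(self) -> None:
        s = sum(v for v in self.counts.values() if v is not None)
        if s != self.total:
            raise ValueError("YcayTable: total != sum of counted features")


def count_ycay(spliced: SplicedGene, pattern: str = YCAY_PATTERN) -> YcayTable:
    """Overlapping YCAY counts per exon/intron; unsequenced features are NA."""
    gene = spliced.gene
    pat = MotifPattern(pattern=pattern, name="YCAY")
    counts: dict[str, int | None] = {}
    features: list[tuple[str, str]] = []
    for i, (s, e) in enumerate(gene.exons, start=1):
        features.append((f"exon{i}", gene.sequence[s:e]))
        if i <= len(gene.introns):
            s2, e2 = gene.introns[i - 1]
            features.append((f"intron{i}", gene.sequence[s2:e2]))
    partial = False
    total = 0
    for name, seq in features:
        if name in gene.missing_features:
            counts[name] = None
            partial = True
            continue
        n = len(scan_iupac(seq, pat, feature_id=name))
        counts[name] = n
        total += n
    return YcayTable(gene_id=gene.gene_id, counts=counts, total=total, partial=partial)


def ycay_table(rows: list[YcayTable]) -> pd.DataFrame:
    feature_order: list[str] = []
    for r in rows:
        for f in r.counts:
            if f not in feature_order:
                feature_order.append(f)
    data = []
    for r in rows:
        row: dict[str, object] = {"gene_id": r.gene_id}
        for f in feature_order:
            v = r.counts.get(f)
            row[f] = pd.NA if v is None else v
        row["total"] = r.total
        row["partial"] = r.partial
        data.append(row)
    return pd.DataFrame(data, columns=["gene_id", *feature_order, "total", "partial"])
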