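"""Degenerate motif scanning, splice-site audits, branch points, YCAY."""

import re
import random

import pandas as pd
import pytest

from dupfate.gene_models import GeneModel, splice
from dupfate.motif_scan import (
    MotifPattern,
    audit_splice_sites,
    count_ycay,
    find_branch_points,
    scan_iupac,
)

IUPAC_RE = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]", "K": "[GT]",
    "M": "[AC]", "B": "[CGT]", "D": "[AGT]", "H": "[ACT]", "V": "[ACG]",
    "N": "[ACGT]",
}


def regex_oracle(seq: str, pattern: str) -> list[int]:
    """Lookahead-regex window matcher (independent of scan_iupac)."""
    rx = re.compile("(?=" + "".join(IUPAC_RE[c] for c in pattern) + ")")
    return [m.start() + 1 for m in rx.finditer(seq)]


class TestScanIupac:
    def test_ycay_example(self):
        assert [h.start for h in scan_iupac("TCACGCCAT", "YCAY")] == [1, 6]

    def test_tnctray_example(self):
        (hit,) = scan_iupac("GGTTCTAACG", "TNCTRAY")
        assert hit.start == 3 and hit.matched == "TTCTAAC"

    def test_no_match_is_empty(self):
        assert scan_iupac("AAAA", "YCAY") == []

    def test_pattern_longer_than_sequence_is_empty(self):
        assert scan_iupac("AC", "YCAY") == []

    def test_overlap_control(self):
        assert len(scan_iupac("TCATCAT", "YCAY")) == 2
        assert len(scan_iupac("TCATCAT", "YCAY", allow_overlap=False)) == 1

    def test_invalid_pattern_symbol_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern(pattern="YCXY", name="bad")

    def test_subject_ambiguity_matches_only_subset(self):
        # Y in the subject is a subset of Y and of N, but not of A
        assert scan_iupac("YCAY", "YCAY")
        assert not scan_iupac("NCAT", "YCAY")

    def test_matches_regex_oracle_on_random_sequences(self):
        rng = random.Random(42)
        for _ in range(200):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 80)))
            for pat in ("YCAY", "TNCTRAY", "RAG", "CAG"):
                got = [h.start for h in scan_iupac(seq, pat)]
                assert got == regex_oracle(seq, pat)

    def test_feature_relative_coordinates_ignore_flanks(self):
        inner = "TCACGCCAT"
        plain = [h.start for h in scan_iupac(inner, "YCAY")]
        offset = [
            h.start for h in scan_iupac(inner, "YCAY", gene_offset=100)
        ]
        assert plain == offset  # feature-relative starts unchanged
        genes = [h.gene_start for h in scan_iupac(inner, "YCAY", gene_offset=100)]
        assert genes == [s + 100 for s in plain]


def _gene_with_introns(intron1: str, intron2: str, exon_ends="AAG") -> GeneModel:
    e1 = "ATGAAACCCGGGTTTCAA" + exon_ends
    e2 = "G" + "ATCATCATCATCATCA" + exon_ends
    e3 = "G" + "CCTTTAAAGGGCCCTAA"
    seq = e1 + intron1 + e2 + intron2 + e3
    o1 = len(e1)
    o2 = o1 + len(intron1)
    o3 = o2 + len(e2)
    o4 = o3 + len(intron2)
    return GeneModel(
        gene_id="g",
        species="s",
        paralog_label="2a",
        sequence=seq,
        exons=((0, o1), (o2, o3), (o4, o4 + len(e3))),
    )


class TestSpliceAudit:
    def test_pristine_boundaries_intact_under_both_dialects(self):
        g = _gene_with_introns("GTAAGT" + "C" * 20 + "TTTCAG", "GTAAGT" + "A" * 20 + "CAG")
        audits = audit_splice_sites(splice(g))
        assert len(audits) == 4
        for a in audits:
            assert a.critical_intact
            assert all(c.overall_intact for c in a.per_consensus)

    def test_broken_donor_plus_two_position(self):
        g = _gene_with_introns("GCAAGT" + "C" * 20 + "CAG", "GTAAGT" + "A" * 20 + "CAG")
        audits = {a.boundary_id: a for a in audit_splice_sites(splice(g))}
        assert not audits["intron1_donor"].critical_intact
        assert audits["intron2_donor"].critical_intact

    def test_broken_acceptor(self):
        g = _gene_with_introns("GTAAGT" + "C" * 20 + "CAT", "GTAAGT" + "A" * 20 + "CAG")
        audits = {a.boundary_id: a for a in audit_splice_sites(splice(g))}
        a = audits["intron1_acceptor"]
        assert not a.critical_intact
        assert not any(c.overall_intact for c in a.per_consensus)

    def test_donor_dialects_disagree_on_cag_exon_end(self):
        # exon ending CAG satisfies MAG (M = A/C) but not RAG (R = A/G)
        g = _gene_with_introns(
            "GTAAGT" + "C" * 20 + "CAG", "GTAAGT" + "A" * 20 + "CAG",
            exon_ends="CAG",
        )
        audits = {a.boundary_id: a for a in audit_splice_sites(splice(g))}
        by_name = {
            c.consensus: c.overall_intact
            for c in audits["intron1_donor"].per_consensus
        }
        assert by_name["MAG/GTRAGT"] and not by_name["RAG/GTRAGT"]

    def test_short_intron_unevaluable(self):
        g = GeneModel(
            gene_id="g", species="s", paralog_label="2a",
            sequence="ATGAAAAAGGTAGGCCCTAA",
            exons=((0, 9), (11, 20)),
        )
        audits = audit_splice_sites(splice(g))
        assert any(not a.evaluable for a in audits)


class TestBranchPoints:
    def test_hit_with_distance_to_3ss(self):
        g = _gene_with_introns("GGTTCTAACGGGG", "A" * 13)
        bp = find_branch_points(splice(g))
        (hit,) = bp[1]
        assert hit.intron_start == 3
        assert hit.matched == "TTCTAAC"
        assert hit.distance_to_3ss == 4

    def test_hitless_intron_reported_empty(self):
        g = _gene_with_introns("A" * 13, "A" * 13)
        bp = find_branch_points(splice(g))
        assert bp[1] == [] and bp[2] == []

    def test_two_hits_in_one_intron_both_reported(self):
        g = _gene_with_introns("GGTTCTAACGGTACTGACGG", "A" * 13)
        bp = find_branch_points(splice(g))
        assert [h.matched for h in bp[1]] == ["TTCTAAC", "TACTGAC"]


class TestYcay:
    def test_per_feature_counts_and_total(self):
        g = _gene_with_introns("GTAAGT" + "TCAT" * 3 + "CAG", "GTAAGT" + "G" * 10 + "CAG")
        tab = count_ycay(splice(g))
        assert tab.counts["intron1"] == 3
        assert tab.total == sum(v for v in tab.counts.values() if v is not None)
        assert not tab.partial

    def test_unsequenced_feature_is_na_and_total_partial(self):
        g = _gene_with_introns("GTAAGT" + "TCAT" * 3 + "CAG", "GTAAGT" + "G" * 10 + "CAG")
        g2 = GeneModel(
            gene_id=g.gene_id, species=g.species, paralog_label=g.paralog_label,
            sequence=g.sequence, exons=g.exons,
            missing_features=frozenset({"intron1"}),
        )
        tab = count_ycay(splice(g2))
        assert tab.counts["intron1"] is None
        assert tab.partial
        assert tab.total == sum(v for v in tab.counts.values() if v is not None)

    def test_motif_free_gene_counts_zero(self):
        g = GeneModel(
            gene_id="g", species="s", paralog_label="2b",
            sequence="G" * 40, exons=((0, 15), (25, 40)),
        )
        tab = count_ycay(splice(g))
        assert tab.total == 0
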